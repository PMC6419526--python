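"""Core typed containers and delimited-text readers/writers shared by all stages.

The central object is the :class:`OmicsBundle`: a set of sample-aligned named
blocks (each a samples x features matrix with feature names) plus per-sample
survival outcomes.  Expression matrices are stored feature-major
(features x samples) to match the on-disk layout of expression tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SurvivalData",
    "CovariateTable",
    "Block",
    "OmicsBundle",
    "read_expression",
    "write_expression",
    "read_clinical",
    "align_samples",
]

#: Clinical columns required by :func:`read_clinical`.
CLINICAL_COLUMNS = ("sample_id", "os_months", "os_event", "age", "er", "pr", "cnb", "tmb")


def _check_unique(ids: list[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {what}: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """A features x samples real matrix with row and column identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_features, n_samples)
    feature_ids : list of str
    sample_ids : list of str
    """

    values: np.ndarray
    feature_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = list(map(str, self.feature_ids))
        self.sample_ids = list(map(str, self.sample_ids))
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (features x samples)")
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        _check_unique(self.feature_ids, "feature id")
        _check_unique(self.sample_ids, "sample id")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite value at feature {self.feature_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}"
            )

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_features(self, keep: np.ndarray | list) -> "ExpressionMatrix":
        """Return a copy restricted to the given feature indices (order kept)."""
        keep = np.asarray(keep)
        return ExpressionMatrix(
            self.values[keep], [self.feature_ids[i] for i in keep], list(self.sample_ids)
        )

    def subset_samples(self, keep: np.ndarray | list) -> "ExpressionMatrix":
        keep = np.asarray(keep)
        return ExpressionMatrix(
            self.values[:, keep], list(self.feature_ids), [self.sample_ids[i] for i in keep]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.sample_ids)


@dataclass
class SurvivalData:
    """Per-sample follow-up time (months) and event indicator (1 = death observed)."""

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise ValueError("time and event must be 1-D arrays of equal length")
        if np.any(self.time < 0):
            raise ValueError("negative survival time")
        if not np.all(np.isin(self.event, (0, 1))):
            raise ValueError("event indicator must be 0 or 1")

    def __len__(self) -> int:
        return len(self.time)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, keep: np.ndarray | list) -> "SurvivalData":
        keep = np.asarray(keep)
        return SurvivalData(self.time[keep], self.event[keep])


@dataclass
class CovariateTable:
    """Per-sample scalar covariates: copy-number burden (Kb), mutation burden,
    diagnosis age, and binary ER/PR receptor status (1 = positive)."""

    sample_ids: list[str]
    cnb: np.ndarray
    tmb: np.ndarray
    age: np.ndarray
    er_status: np.ndarray
    pr_status: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = list(map(str, self.sample_ids))
        _check_unique(self.sample_ids, "sample id")
        n = len(self.sample_ids)
        for name in ("cnb", "tmb", "age", "er_status", "pr_status"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one value per sample")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains missing/non-finite values")
            setattr(self, name, arr)
        for name in ("er_status", "pr_status"):
            arr = getattr(self, name)
            if not np.all(np.isin(arr, (0.0, 1.0))):
                raise ValueError(f"{name} must be binary 0/1")
        if np.any(self.tmb < 0):
            raise ValueError("tmb must be non-negative")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset(self, keep: np.ndarray | list) -> "CovariateTable":
        keep = np.asarray(keep)
        return CovariateTable(
            [self.sample_ids[i] for i in keep],
            self.cnb[keep],
            self.tmb[keep],
            self.age[keep],
            self.er_status[keep],
            self.pr_status[keep],
        )


@dataclass
class Block:
    """A named samples x features sub-matrix of an :class:`OmicsBundle`."""

    name: str
    values: np.ndarray  # (n_samples, n_features)
    feature_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.feature_ids):
            raise ValueError(
                f"block {self.name!r}: values must be samples x {len(self.feature_ids)} features"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"block {self.name!r} contains non-finite values")

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)


@dataclass
class OmicsBundle:
    """Sample-aligned named blocks plus survival outcomes.

    All blocks share the same ordered ``sample_ids``; block matrices are
    samples x features.
    """

    sample_ids: list[str]
    blocks: dict[str, Block] = field(default_factory=dict)
    survival: SurvivalData | None = None

    def __post_init__(self) -> None:
        _check_unique(self.sample_ids, "sample id")
        n = len(self.sample_ids)
        for b in self.blocks.values():
            if b.values.shape[0] != n:
                raise ValueError(
                    f"block {b.name!r} has {b.values.shape[0]} samples, bundle has {n}"
                )
        if self.survival is not None and len(self.survival) != n:
            raise ValueError("survival length does not match sample count")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return sum(b.n_features for b in self.blocks.values())

    def feature_names(self) -> list[tuple[str, str]]:
        """Flat (block, feature) list in block order — the Cox-input ordering."""
        return [(b.name, f) for b in self.blocks.values() for f in b.feature_ids]

    def subset_samples(self, keep: np.ndarray | list) -> "OmicsBundle":
        keep = np.asarray(keep)
        return OmicsBundle(
            [self.sample_ids[i] for i in keep],
            {n: Block(n, b.values[keep], list(b.feature_ids)) for n, b in self.blocks.items()},
            self.survival.subset(keep) if self.survival is not None else None,
        )

    def select_blocks(self, names: list[str]) -> "OmicsBundle":
        missing = [n for n in names if n not in self.blocks]
        if missing:
            raise KeyError(f"bundle is missing required block(s): {missing}")
        return OmicsBundle(
            list(self.sample_ids),
            {n: self.blocks[n] for n in names},
            self.survival,
        )

    def subset_features(self, keep: dict[str, list[str]]) -> "OmicsBundle":
        """Restrict each block to the named features; blocks reduced to zero
        features are dropped."""
        blocks: dict[str, Block] = {}
        for name, b in self.blocks.items():
            wanted = keep.get(name, [])
            idx = [b.feature_ids.index(f) for f in wanted]
            if idx:
                blocks[name] = Block(name, b.values[:, idx], [b.feature_ids[i] for i in idx])
        if not blocks:
            raise ValueError("feature selection removed every input feature")
        return OmicsBundle(list(self.sample_ids), blocks, self.survival)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: str, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if str(path).endswith(".csv") else "tsv"
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_expression(path: str, dialect: str | None = None) -> ExpressionMatrix:
    """Read a features x samples expression table.

    The first row holds sample ids, the first column feature ids.  Raises on
    duplicate ids (naming the duplicate) and on non-numeric cells (with the
    row/column location).
    """
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    feature_ids = [str(i) for i in df.index]
    sample_ids = [str(c) for c in df.columns]
    _check_unique(feature_ids, "feature id")
    _check_unique(sample_ids, "sample id")
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        for i, fid in enumerate(feature_ids):
            for j, sid in enumerate(sample_ids):
                try:
                    float(df.iat[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric cell {df.iat[i, j]!r} at feature {fid!r}, sample {sid!r}"
                    ) from None
        raise
    return ExpressionMatrix(values, feature_ids, sample_ids)


def write_expression(expr: ExpressionMatrix, path: str, dialect: str | None = None) -> None:
    """Write a features x samples table; values use repr-round-trip precision."""
    sep = _sep_for(path, dialect)
    expr.to_frame().to_csv(path, sep=sep, float_format="%.17g")


def read_clinical(path: str, dialect: str | None = None) -> tuple[CovariateTable, SurvivalData]:
    """Read a clinical table with columns ``sample_id, os_months, os_event,
    age, er, pr, cnb, tmb``.

    Samples with any missing required field are dropped (count logged); ER/PR
    values other than 0/1 are treated as missing.
    """
    sep = _sep_for(path, dialect)
    df = pd.read_csv(path, sep=sep)
    missing_cols = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"clinical table missing column(s): {missing_cols}")
    df = df.copy()
    for c in CLINICAL_COLUMNS[1:]:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    for c in ("er", "pr", "os_event"):
        df.loc[~df[c].isin([0, 1]), c] = np.nan
    n0 = len(df)
    df = df.dropna(subset=list(CLINICAL_COLUMNS[1:]))
    if len(df) < n0:
        logger.info("dropped %d/%d samples with missing clinical fields", n0 - len(df), n0)
    cov = CovariateTable(
        sample_ids=[str(s) for s in df["sample_id"]],
        cnb=df["cnb"].to_numpy(),
        tmb=df["tmb"].to_numpy(),
        age=df["age"].to_numpy(),
        er_status=df["er"].to_numpy(),
        pr_status=df["pr"].to_numpy(),
    )
    surv = SurvivalData(df["os_months"].to_numpy(), df["os_event"].to_numpy(dtype=int))
    return cov, surv


# ---------------------------------------------------------------------------
# Sample alignment
# ---------------------------------------------------------------------------

def _sample_ids_of(obj) -> list[str]:
    if isinstance(obj, (ExpressionMatrix, CovariateTable, OmicsBundle)):
        return obj.sample_ids
    raise TypeError(f"cannot align object of type {type(obj).__name__}")


def align_samples(
    named: dict[str, ExpressionMatrix | CovariateTable],
    survival: SurvivalData | None = None,
    survival_sample_ids: list[str] | None = None,
) -> OmicsBundle:
    """Intersect sample ids across blocks and return an aligned bundle.

    Canonical sample order after alignment is lexicographic.  Dropped samples
    are logged per block.  Expression blocks are transposed to samples x
    features; covariate tables become two blocks: ``burden`` (cnb, tmb) and
    ``clinical`` (age, er, pr).

    Raises ``ValueError`` if the intersection is empty.
    """
    if not named:
        raise ValueError("need at least one block to align")
    common: set[str] | None = None
    for obj in named.values():
        ids = set(_sample_ids_of(obj))
        common = ids if common is None else (common & ids)
    if survival is not None:
        if survival_sample_ids is None:
            raise ValueError("survival requires survival_sample_ids for alignment")
        common &= set(survival_sample_ids)
    if not common:
        raise ValueError("sample-id intersection across blocks is empty")
    order = sorted(common)
    for name, obj in named.items():
        dropped = len(obj.sample_ids) - len(order)
        if dropped:
            logger.info("align_samples: dropped %d samples from block %r", dropped, name)

    blocks: dict[str, Block] = {}
    for name, obj in named.items():
        pos = {s: i for i, s in enumerate(obj.sample_ids)}
        idx = [pos[s] for s in order]
        if isinstance(obj, ExpressionMatrix):
            blocks[name] = Block(name, obj.values[:, idx].T, list(obj.feature_ids))
        else:  # CovariateTable -> burden + clinical column groups
            sub = obj.subset(idx)
            blocks["burden"] = Block(
                "burden", np.column_stack([sub.cnb, sub.tmb]), ["cnb", "tmb"]
            )
            blocks["clinical"] = Block(
                "clinical",
                np.column_stack([sub.age, sub.er_status, sub.pr_status]),
                ["age", "er", "pr"],
            )
    surv = None
    if survival is not None:
        pos = {s: i for i, s in enumerate(survival_sample_ids)}
        surv = survival.subset([pos[s] for s in order])
    return OmicsBundle(order, blocks, surv)
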