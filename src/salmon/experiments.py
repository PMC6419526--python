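"""Cross-validated experiment harness: fold construction, the six
omics-combination designs, concatenated-fold survival analysis, and the
pairwise paired-t comparison table."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxnet import SalmonModel, TrainConfig, architecture_for_bundle, train
from .data_model import OmicsBundle
from .evaluate import concordance_index, dichotomize_by_median, logrank_test, paired_t_test

__all__ = [
    "COMBOS",
    "make_folds",
    "run_cv",
    "run_combination",
    "compare_combinations",
    "CVResult",
    "CombinationResult",
]

#: Block requirements for each published input combination.
COMBOS: dict[str, list[str]] = {
    "i": ["mrna"],
    "ii": ["mirna"],
    "iii": ["mrna", "mirna"],
    "iv": ["mrna", "mirna", "burden"],
    "v": ["mrna", "mirna", "clinical"],
    "vi": ["mrna", "mirna", "burden", "clinical"],
    "covariates_only": ["burden", "clinical"],
}


def make_folds(
    n: int,
    k: int = 5,
    seed: int = 0,
    stratify_event: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Disjoint, exhaustive fold index sets with sizes differing by <= 1.

    ``stratify_event`` (a 0/1 vector) deals events and non-events round-robin
    so every fold carries events even at small n.
    """
    if not 1 <= k <= n:
        raise ValueError(f"need 1 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    if stratify_event is None:
        perm = rng.permutation(n)
        for pos, idx in enumerate(perm):
            folds[pos % k].append(int(idx))
    else:
        stratify_event = np.asarray(stratify_event)
        pos = 0
        for value in (1, 0):
            group = np.flatnonzero(stratify_event == value)
            for idx in rng.permutation(group):
                folds[pos % k].append(int(idx))
                pos += 1
    return [np.sort(np.array(f, dtype=int)) for f in folds]


@dataclass
class CVResult:
    models: list[SalmonModel]
    folds: list[np.ndarray]
    fold_cindex: list[float]
    risks: np.ndarray  # concatenated test risks, aligned to bundle sample order

    @property
    def median_cindex(self) -> float:
        return float(np.median(self.fold_cindex))

    @property
    def mean_cindex(self) -> float:
        return float(np.mean(self.fold_cindex))


def run_cv(
    bundle: OmicsBundle,
    folds: list[np.ndarray],
    config: TrainConfig,
    hidden: dict[str, int] | None = None,
    **arch_kw,
) -> CVResult:
    """Train/test over the folds; each fold's model is trained on the
    complement and evaluated on the fold.  Test risks are written back into
    one vector over all samples ("concatenated folds")."""
    if bundle.survival is None:
        raise ValueError("bundle has no survival data")
    n = bundle.n_samples
    risks = np.full(n, np.nan)
    models: list[SalmonModel] = []
    cis: list[float] = []
    for f, test_idx in enumerate(folds):
        mask = np.ones(n, dtype=bool)
        mask[test_idx] = False
        train_idx = np.flatnonzero(mask)
        b_train = bundle.subset_samples(train_idx)
        b_test = bundle.subset_samples(test_idx)
        arch = architecture_for_bundle(b_train, hidden=hidden, **arch_kw)
        cfg = TrainConfig(**{**vars(config), "seed": config.seed + f})
        model, _ = train(arch, b_train, cfg)
        risk = model.predict_risk(b_test)
        risks[test_idx] = risk
        cis.append(concordance_index(risk, b_test.survival))
        models.append(model)
    return CVResult(models, list(folds), cis, risks)


@dataclass
class CombinationResult:
    combo: str
    n_features: int
    cv: CVResult
    logrank_chi2: float
    logrank_p: float

    def summary(self) -> dict:
        return {
            "combo": self.combo,
            "n_features": self.n_features,
            "fold_cindex": list(self.cv.fold_cindex),
            "median_cindex": self.cv.median_cindex,
            "mean_cindex": self.cv.mean_cindex,
            "logrank_chi2": self.logrank_chi2,
            "logrank_p": self.logrank_p,
        }


def run_combination(
    bundle: OmicsBundle,
    combo: str,
    config: TrainConfig,
    k: int = 5,
    folds: list[np.ndarray] | None = None,
    hidden: dict[str, int] | None = None,
    stratify: bool = False,
) -> CombinationResult:
    """Run one omics-combination design end to end.

    Selects the combo's blocks (unused branches are simply absent from the
    architecture), cross-validates, concatenates the per-fold test risks, and
    runs the median-split log-rank test on the concatenated risks.
    """
    if combo not in COMBOS:
        raise KeyError(f"unknown combo {combo!r}; choose from {sorted(COMBOS)}")
    try:
        sub = bundle.select_blocks(COMBOS[combo])
    except KeyError as exc:
        raise KeyError(f"combo {combo!r} requires blocks {COMBOS[combo]}: {exc}") from exc
    if folds is None:
        folds = make_folds(
            sub.n_samples,
            k,
            config.seed,
            stratify_event=sub.survival.event if stratify else None,
        )
    cv = run_cv(sub, folds, config, hidden=hidden)
    labels = dichotomize_by_median(cv.risks)
    high = np.flatnonzero(labels == 1)
    low = np.flatnonzero(labels == 0)
    if len(high) and len(low):
        chi2, p = logrank_test(sub.survival.subset(low), sub.survival.subset(high))
    else:  # constant risks: no split possible
        chi2, p = 0.0, 1.0
    return CombinationResult(combo, sub.n_features, cv, chi2, p)


def compare_combinations(results: dict[str, list[float]]) -> pd.DataFrame:
    """Pairwise paired t-table over per-fold c-index vectors.

    One row per ordered pair (set1, set2) with the t statistic of
    ``set1 - set2`` and its two-sided p; t(a, b) = -t(b, a).
    """
    rows = []
    names = list(results)
    for a in names:
        for b in names:
            if a == b:
                continue
            t, p = paired_t_test(np.asarray(results[a]), np.asarray(results[b]))
            rows.append({"set1": a, "set2": b, "t": t, "p": p})
    return pd.DataFrame(rows)
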