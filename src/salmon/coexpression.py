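"""Quasi-clique co-expression module mining and SVD eigengene summarisation.

Pipeline: correlation matrix (Spearman by default) -> spectral-style locally
normalised absolute weights -> greedy quasi-clique expansion seeded from the
heaviest edges -> overlap merge -> size filter -> per-module first right
singular vector ("eigengene") of the row-standardised sub-matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .data_model import ExpressionMatrix

__all__ = [
    "LmqcmParams",
    "ModuleSet",
    "EigengeneMatrix",
    "correlation_matrix",
    "lmqcm_weights",
    "lmqcm_mine",
    "eigengene",
    "eigengene_matrix",
    "mine_modules",
]


@dataclass
class LmqcmParams:
    """Mining parameters.

    gamma : seed-edge threshold (relative to the max weight by default)
    lam, t : density-decay schedule, alpha_n = 1 - 1/(2*lam*(n+t))
    beta : merge-overlap threshold, |A&B|/min(|A|,|B|)
    min_size : minimum cluster size kept
    correlation : {"spearman", "pearson"}
    seed_mode : {"relative", "absolute"} — seed threshold gamma*w_max vs gamma
    density_mode : {"relative", "absolute"} — accept a vertex while the new
        density stays >= alpha_n * current density (relative) or >= alpha_n.
    normalize : apply the spectral-style weight normalisation before mining.
    """

    gamma: float = 0.7
    lam: float = 1.0
    t: float = 1.0
    beta: float = 0.4
    min_size: int = 10
    correlation: str = "spearman"
    seed_mode: str = "relative"
    density_mode: str = "relative"
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.lam <= 0 or self.t < 0:
            raise ValueError("gamma, lam must be > 0 and t >= 0")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must be in (0, 1]")
        if self.min_size < 1:
            raise ValueError("min_size must be positive")
        if self.correlation not in ("spearman", "pearson"):
            raise ValueError(f"unknown correlation {self.correlation!r}")
        if self.seed_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown seed_mode {self.seed_mode!r}")
        if self.density_mode not in ("relative", "absolute"):
            raise ValueError(f"unknown density_mode {self.density_mode!r}")


@dataclass
class ModuleSet:
    """Ordered list of mined gene-id modules (overlap allowed)."""

    modules: list[list[str]]
    params: LmqcmParams
    source: str = ""

    def __post_init__(self) -> None:
        for m in self.modules:
            if len(m) < self.params.min_size:
                raise ValueError(
                    f"module of size {len(m)} below min_size {self.params.min_size}"
                )

    def __len__(self) -> int:
        return len(self.modules)

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "params": vars(self.params).copy(),
            "modules": [list(m) for m in self.modules],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModuleSet":
        return cls(
            modules=[list(m) for m in d["modules"]],
            params=LmqcmParams(**d["params"]),
            source=d.get("source", ""),
        )


@dataclass
class EigengeneMatrix:
    """modules x samples summary matrix; each row has unit Euclidean norm."""

    values: np.ndarray
    module_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.module_ids), len(self.sample_ids)):
            raise ValueError("eigengene matrix shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("eigengene matrix contains non-finite values")


def correlation_matrix(expr: ExpressionMatrix, method: str = "spearman") -> np.ndarray:
    """Pairwise feature correlation (symmetric, unit diagonal, in [-1, 1]).

    Spearman uses average ranks for ties.  Zero-variance features cannot be
    ranked/correlated; their off-diagonal correlations are set to 0 with a
    warning.
    """
    if expr.n_samples < 3:
        raise ValueError("need at least 3 samples for a correlation matrix")
    if method == "spearman":
        data = np.apply_along_axis(rankdata, 1, expr.values)
    elif method == "pearson":
        data = expr.values
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    sd = data.std(axis=1)
    degenerate = sd == 0
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} zero-variance feature(s); correlations set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    corr = np.atleast_2d(corr)
    corr[degenerate, :] = 0.0
    corr[:, degenerate] = 0.0
    np.fill_diagonal(corr, 1.0)
    return np.clip(corr, -1.0, 1.0)


def lmqcm_weights(corr: np.ndarray) -> np.ndarray:
    """Spectral-style locally normalised edge weights.

    w_ij = |corr_ij| (diagonal zeroed), then w'_ij = w_ij / sqrt(d_i * d_j)
    with d_i the weighted degree.  Isolated vertices keep zero edges.
    """
    w = np.abs(np.asarray(corr, dtype=float))
    np.fill_diagonal(w, 0.0)
    d = w.sum(axis=1)
    with np.errstate(divide="ignore"):
        inv_sqrt = np.where(d > 0, 1.0 / np.sqrt(np.where(d > 0, d, 1.0)), 0.0)
    return w * inv_sqrt[:, None] * inv_sqrt[None, :]


def _density(total_weight: float, n: int) -> float:
    return 2.0 * total_weight / (n * (n - 1)) if n > 1 else 0.0


def _expand_cluster(weights: np.ndarray, i: int, j: int, params: LmqcmParams) -> list[int]:
    """Greedily grow a cluster from seed edge (i, j) under the density-decay
    acceptance schedule."""
    members = [i, j]
    in_cluster = np.zeros(weights.shape[0], dtype=bool)
    in_cluster[[i, j]] = True
    total = float(weights[i, j])
    # per-vertex total weight into the current cluster
    attach = weights[:, i] + weights[:, j]
    while True:
        n = len(members)
        cand = np.where(~in_cluster)[0]
        if cand.size == 0:
            break
        best = cand[np.argmax(attach[cand])]
        gain = float(attach[best])
        if gain <= 0:
            break
        new_density = _density(total + gain, n + 1)
        alpha = 1.0 - 1.0 / (2.0 * params.lam * (n + params.t))
        bar = alpha * _density(total, n) if params.density_mode == "relative" else alpha
        if new_density < bar:
            break
        members.append(int(best))
        in_cluster[best] = True
        total += gain
        attach = attach + weights[:, best]
    return members


def _merge_clusters(clusters: list[set[int]], beta: float) -> list[set[int]]:
    """Repeatedly merge the pair with the highest overlap ratio >= beta."""
    clusters = [set(c) for c in clusters]
    while True:
        best_ratio, best_pair = 0.0, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                inter = len(clusters[a] & clusters[b])
                if inter == 0:
                    continue
                ratio = inter / min(len(clusters[a]), len(clusters[b]))
                if ratio > best_ratio:
                    best_ratio, best_pair = ratio, (a, b)
        if best_pair is None or best_ratio < beta:
            return clusters
        a, b = best_pair
        clusters[a] = clusters[a] | clusters[b]
        del clusters[b]


def lmqcm_mine(
    weights: np.ndarray,
    params: LmqcmParams,
    feature_ids: list[str] | None = None,
) -> ModuleSet:
    """Mine overlapping quasi-clique modules from a non-negative symmetric
    weight matrix with zero diagonal.

    Edges are visited by descending weight; an edge whose weight passes the
    seed threshold and whose endpoints are not yet absorbed into a cluster
    seeds a new cluster, which is greedily expanded, then clusters are merged
    by overlap and filtered by size.  Modules are returned sorted by size
    descending (ties: by smallest member index) with genes in input order.
    """
    w = np.asarray(weights, dtype=float)
    n = w.shape[0]
    if w.shape != (n, n):
        raise ValueError("weights must be square")
    if feature_ids is None:
        feature_ids = [str(i) for i in range(n)]
    if n < 2:
        return ModuleSet([], params)

    iu, ju = np.triu_indices(n, 1)
    vals = w[iu, ju]
    wmax = float(vals.max(initial=0.0))
    threshold = params.gamma * wmax if params.seed_mode == "relative" else params.gamma
    if wmax <= 0 or threshold <= 0:
        return ModuleSet([], params)

    order = np.argsort(-vals, kind="stable")
    absorbed = np.zeros(n, dtype=bool)
    raw: list[set[int]] = []
    for e in order:
        if vals[e] < threshold:
            break
        i, j = int(iu[e]), int(ju[e])
        if absorbed[i] or absorbed[j]:
            continue
        members = _expand_cluster(w, i, j, params)
        raw.append(set(members))
        absorbed[members] = True

    merged = _merge_clusters(raw, params.beta)
    kept = [c for c in merged if len(c) >= params.min_size]
    kept.sort(key=lambda c: (-len(c), min(c)))
    modules = [[feature_ids[i] for i in sorted(c)] for c in kept]
    return ModuleSet(modules, params)


def eigengene(expr: ExpressionMatrix, module: list[str]) -> np.ndarray:
    """First right singular vector of the row-standardised module sub-matrix.

    Each member gene is centred to mean 0 and scaled to unit variance across
    samples before the SVD.  The sign is fixed so the vector correlates
    non-negatively with the module's mean expression profile; the result has
    unit Euclidean norm.
    """
    if len(module) < 2:
        raise ValueError("eigengene needs at least 2 genes")
    index = {g: i for i, g in enumerate(expr.feature_ids)}
    missing = [g for g in module if g not in index]
    if missing:
        raise KeyError(f"module gene(s) absent from expression matrix: {missing}")
    sub = expr.values[[index[g] for g in module]]
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(f"{int(flat.sum())} constant gene(s) in module ignored for SVD", stacklevel=2)
        sd = np.where(sd == 0, 1.0, sd)
    z = (sub - mu) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    v = vt[0]
    mean_profile = sub.mean(axis=0)
    centred = mean_profile - mean_profile.mean()
    align = float(v @ centred)
    if align < 0:
        v = -v
    elif align == 0:  # degenerate: fall back to first-nonzero-positive
        nz = np.flatnonzero(v)
        if nz.size and v[nz[0]] < 0:
            v = -v
    return v


def eigengene_matrix(expr: ExpressionMatrix, modules: ModuleSet) -> EigengeneMatrix:
    """Stack per-module eigengenes into a modules x samples matrix (module
    order preserved; ids are 1-based)."""
    rows = [eigengene(expr, m) for m in modules.modules]
    values = np.vstack(rows) if rows else np.empty((0, expr.n_samples))
    ids = [str(i + 1) for i in range(len(rows))]
    return EigengeneMatrix(values, ids, list(expr.sample_ids))


def mine_modules(expr: ExpressionMatrix, params: LmqcmParams, source: str = "") -> ModuleSet:
    """Convenience: correlation -> (optional) normalisation -> mining."""
    corr = correlation_matrix(expr, params.correlation)
    w = lmqcm_weights(corr) if params.normalize else np.abs(corr) - np.eye(len(corr))
    ms = lmqcm_mine(w, params, expr.feature_ids)
    ms.source = source
    return ms
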