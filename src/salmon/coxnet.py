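"""Multi-branch Cox proportional-hazards network.

Each omics block feeds its own forward branch (a single sigmoid hidden layer,
or a pass-through for scalar covariates); branch outputs are concatenated and
mapped by a final linear Cox layer to the per-sample linear predictor eta.
``sigmoid(eta)`` is reported as the displayed relative risk in (0, 1), while
the negative log partial likelihood (Breslow ties) is evaluated on eta itself,
keeping the loss well conditioned; a config switch restores the literal
sigmoid-likelihood reading.  Training is mini-batch Adam on the partial
likelihood plus an L1 penalty over all parameters, with analytic gradients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import OmicsBundle, SurvivalData

__all__ = [
    "BranchSpec",
    "SalmonArchitecture",
    "TrainConfig",
    "SalmonModel",
    "sigmoid",
    "count_trainable_weights",
    "neg_log_partial_likelihood",
    "partial_likelihood_gradient",
    "objective",
    "train",
    "architecture_for_bundle",
]

#: Default hidden-layer widths by block name.
DEFAULT_HIDDEN = {"mrna": 8, "mirna": 4}


def sigmoid(x):
    """Numerically stable logistic function 1/(1+exp(-x))."""
    x = np.asarray(x, dtype=float)
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    if out.ndim == 0:
        return float(out)
    return out


@dataclass
class BranchSpec:
    """One input branch: ``hidden_dim=None`` passes inputs straight to the
    Cox layer as covariates."""

    name: str
    input_dim: int
    hidden_dim: int | None = None

    @property
    def output_dim(self) -> int:
        return self.input_dim if self.hidden_dim is None else self.hidden_dim


@dataclass
class SalmonArchitecture:
    branches: list[BranchSpec]
    use_bias: bool = True
    activation: str = "sigmoid"  # or "identity"
    likelihood_on: str = "linear"  # or "sigmoid"

    def __post_init__(self) -> None:
        if self.activation not in ("sigmoid", "identity"):
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.likelihood_on not in ("linear", "sigmoid"):
            raise ValueError(f"unknown likelihood_on {self.likelihood_on!r}")
        names = [b.name for b in self.branches]
        if len(set(names)) != len(names):
            raise ValueError("duplicate branch names")

    @property
    def cox_input_dim(self) -> int:
        return sum(b.output_dim for b in self.branches)


def count_trainable_weights(arch: SalmonArchitecture, include_bias: bool = True) -> int:
    """Number of trainable parameters: sum over layers of in*out
    (+ out per layer when biases are counted)."""
    total = 0
    for b in arch.branches:
        if b.hidden_dim is not None:
            total += b.input_dim * b.hidden_dim
            if include_bias:
                total += b.hidden_dim
    total += arch.cox_input_dim * 1
    if include_bias:
        total += 1
    return total


@dataclass
class TrainConfig:
    epochs: int = 100
    batch_size: int = 64
    learning_rate: float = 1e-2
    l1_lambda: float = 1e-5
    seed: int = 0
    full_batch: bool = False
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0 or self.learning_rate <= 0:
            raise ValueError("epochs, batch_size and learning_rate must be positive")
        if self.l1_lambda < 0:
            raise ValueError("l1_lambda must be non-negative")


@dataclass
class SalmonModel:
    """Fitted (or freshly initialised) parameter set.

    ``weights[name] = (W, b)`` per hidden branch (W: hidden x input); ``beta``
    is the Cox layer, ``beta0`` its optional bias.  ``scaler[name] = (mean,
    std)`` holds the training-fold standardisation applied to every input.
    """

    arch: SalmonArchitecture
    weights: dict[str, tuple[np.ndarray, np.ndarray | None]]
    beta: np.ndarray
    beta0: float = 0.0
    scaler: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    # -- plumbing ----------------------------------------------------------
    def _blocks_from(self, bundle: OmicsBundle) -> dict[str, np.ndarray]:
        blocks = {}
        for spec in self.arch.branches:
            if spec.name not in bundle.blocks:
                raise KeyError(f"bundle is missing block {spec.name!r}")
            x = bundle.blocks[spec.name].values
            if x.shape[1] != spec.input_dim:
                raise ValueError(
                    f"branch {spec.name!r} expects {spec.input_dim} features, "
                    f"got {x.shape[1]}"
                )
            blocks[spec.name] = x
        return blocks

    def standardize(self, bundle: OmicsBundle) -> dict[str, np.ndarray]:
        """Apply the stored training-fold z-score transform to a bundle."""
        blocks = self._blocks_from(bundle)
        if self.scaler is None:
            return blocks
        out = {}
        for name, x in blocks.items():
            mean, std = self.scaler[name]
            out[name] = (x - mean) / std
        return out

    def _branch_outputs(self, xs: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        outs = {}
        for spec in self.arch.branches:
            x = xs[spec.name]
            if spec.hidden_dim is None:
                outs[spec.name] = x
            else:
                w, b = self.weights[spec.name]
                a = x @ w.T
                if b is not None:
                    a = a + b
                outs[spec.name] = sigmoid(a) if self.arch.activation == "sigmoid" else a
        return outs

    def _eta_from_std(self, xs: dict[str, np.ndarray]) -> np.ndarray:
        z = np.concatenate(
            [self._branch_outputs(xs)[s.name] for s in self.arch.branches], axis=1
        )
        return z @ self.beta + self.beta0

    # -- public API --------------------------------------------------------
    def linear_predictor(
        self,
        bundle: OmicsBundle,
        ablate: tuple[str, int] | None = None,
        ablate_scale: str = "standardized",
    ) -> np.ndarray:
        """Per-sample Cox linear predictor eta; ``ablate=(block, column)``
        zeroes one input feature, on the standardised scale by default."""
        if ablate is not None and ablate_scale == "raw":
            blocks = {k: v.copy() for k, v in self._blocks_from(bundle).items()}
            name, col = ablate
            blocks[name][:, col] = 0.0
            if self.scaler is not None:
                blocks = {
                    k: (v - self.scaler[k][0]) / self.scaler[k][1] for k, v in blocks.items()
                }
            return self._eta_from_std(blocks)
        xs = self.standardize(bundle)
        if ablate is not None:
            name, col = ablate
            if name not in xs:
                raise KeyError(f"unknown block {name!r}")
            xs = {k: (v.copy() if k == name else v) for k, v in xs.items()}
            xs[name][:, col] = 0.0
        return self._eta_from_std(xs)

    def predict_risk(self, bundle: OmicsBundle, **kw) -> np.ndarray:
        """Displayed relative risk, sigmoid(eta), one value in (0,1) per sample."""
        return sigmoid(self.linear_predictor(bundle, **kw))

    def parameters(self) -> list[np.ndarray]:
        ps: list[np.ndarray] = []
        for spec in self.arch.branches:
            if spec.hidden_dim is not None:
                w, b = self.weights[spec.name]
                ps.append(w)
                if b is not None:
                    ps.append(b)
        ps.append(self.beta)
        return ps

    def l1_norm(self) -> float:
        total = sum(float(np.abs(p).sum()) for p in self.parameters())
        if self.arch.use_bias:
            total += abs(self.beta0)
        return total

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "architecture": {
                "branches": [
                    {"name": b.name, "input_dim": b.input_dim, "hidden_dim": b.hidden_dim}
                    for b in self.arch.branches
                ],
                "use_bias": self.arch.use_bias,
                "activation": self.arch.activation,
                "likelihood_on": self.arch.likelihood_on,
            },
            "beta": self.beta.tolist(),
            "beta0": self.beta0,
            "weights": {
                name: {"W": w.tolist(), "b": None if b is None else b.tolist()}
                for name, (w, b) in self.weights.items()
            },
            "scaler": None
            if self.scaler is None
            else {
                k: {"mean": m.tolist(), "std": s.tolist()}
                for k, (m, s) in self.scaler.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SalmonModel":
        arch = SalmonArchitecture(
            [BranchSpec(**b) for b in d["architecture"]["branches"]],
            d["architecture"]["use_bias"],
            d["architecture"]["activation"],
            d["architecture"]["likelihood_on"],
        )
        weights = {
            name: (np.asarray(wb["W"]), None if wb["b"] is None else np.asarray(wb["b"]))
            for name, wb in d["weights"].items()
        }
        scaler = None
        if d["scaler"] is not None:
            scaler = {
                k: (np.asarray(v["mean"]), np.asarray(v["std"]))
                for k, v in d["scaler"].items()
            }
        return cls(arch, weights, np.asarray(d["beta"], dtype=float), d["beta0"], scaler)


def initialize_model(
    arch: SalmonArchitecture, rng: np.random.Generator
) -> SalmonModel:
    """Seeded uniform init in [-1/sqrt(fan_in), +1/sqrt(fan_in)]."""
    weights: dict[str, tuple[np.ndarray, np.ndarray | None]] = {}
    for spec in arch.branches:
        if spec.hidden_dim is None:
            continue
        bound = 1.0 / np.sqrt(spec.input_dim)
        w = rng.uniform(-bound, bound, size=(spec.hidden_dim, spec.input_dim))
        b = rng.uniform(-bound, bound, size=spec.hidden_dim) if arch.use_bias else None
        weights[spec.name] = (w, b)
    k = arch.cox_input_dim
    bound = 1.0 / np.sqrt(k)
    beta = rng.uniform(-bound, bound, size=k)
    beta0 = float(rng.uniform(-bound, bound)) if arch.use_bias else 0.0
    return SalmonModel(arch, weights, beta, beta0)


# ---------------------------------------------------------------------------
# Partial likelihood
# ---------------------------------------------------------------------------

def _sorted_risk_sets(surv: SurvivalData):
    order = np.argsort(surv.time, kind="stable")
    t = surv.time[order]
    e = surv.event[order].astype(bool)
    # risk set of an event at sorted position i starts at the first index with
    # time >= t[i]; tied event times share the full risk set (Breslow)
    starts = np.searchsorted(t, t, side="left")
    return order, t, e, starts


def neg_log_partial_likelihood(eta: np.ndarray, surv: SurvivalData) -> float:
    """Negative Breslow log partial likelihood of linear predictors ``eta``.

    Risk sets are taken within the evaluated set of samples.  With no events
    the value is defined as 0 (with a warning).
    """
    eta = np.asarray(eta, dtype=float).ravel()
    if len(eta) != len(surv):
        raise ValueError("eta and survival data lengths differ")
    if surv.n_events == 0:
        warnings.warn("no events in batch; partial likelihood defined as 0", stacklevel=2)
        return 0.0
    order, _, e, starts = _sorted_risk_sets(surv)
    es = eta[order]
    # suffix log-sum-exp: lse[i] = log sum_{j >= i} exp(es[j])
    lse = np.logaddexp.accumulate(es[::-1])[::-1]
    return float(-(es[e] - lse[starts[e]]).sum())


def partial_likelihood_gradient(eta: np.ndarray, surv: SurvivalData) -> np.ndarray:
    """Analytic gradient of :func:`neg_log_partial_likelihood` w.r.t. eta."""
    eta = np.asarray(eta, dtype=float).ravel()
    n = len(eta)
    if surv.n_events == 0:
        return np.zeros(n)
    order, _, e, starts = _sorted_risk_sets(surv)
    es = eta[order]
    lse = np.logaddexp.accumulate(es[::-1])[::-1]
    # inv_sum[k] = 1 / sum_{j in risk set of event k} exp(eta_j)
    inv_sum = np.exp(-lse[starts[e]])
    scatter = np.zeros(n + 1)
    np.add.at(scatter, starts[e], inv_sum)
    coef = np.cumsum(scatter[:-1])  # coef[i] = sum of inv_sum over events whose risk set contains i
    g_sorted = -e.astype(float) + np.exp(es) * coef
    g = np.empty(n)
    g[order] = g_sorted
    return g


def objective(
    model: SalmonModel,
    bundle: OmicsBundle,
    l1_lambda: float = 1e-5,
) -> float:
    """Negative log partial likelihood plus ``l1_lambda * ||Theta||_1``."""
    eta = model.linear_predictor(bundle)
    scores = sigmoid(eta) if model.arch.likelihood_on == "sigmoid" else eta
    return neg_log_partial_likelihood(scores, bundle.survival) + l1_lambda * model.l1_norm()


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def architecture_for_bundle(
    bundle: OmicsBundle,
    hidden: dict[str, int] | None = None,
    use_bias: bool = True,
    activation: str = "sigmoid",
    likelihood_on: str = "linear",
) -> SalmonArchitecture:
    """Build branch specs from a bundle; blocks named in ``hidden`` get a
    hidden layer of that width, all others pass through."""
    hidden = DEFAULT_HIDDEN if hidden is None else hidden
    branches = [
        BranchSpec(name, blk.n_features, hidden.get(name))
        for name, blk in bundle.blocks.items()
    ]
    return SalmonArchitecture(branches, use_bias, activation, likelihood_on)


def _fit_scaler(blocks: dict[str, np.ndarray]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    scaler = {}
    for name, x in blocks.items():
        mean = x.mean(axis=0)
        std = x.std(axis=0, ddof=0)
        std = np.where(std > 0, std, 1.0)  # constant columns pass through centred
        scaler[name] = (mean, std)
    return scaler


def _forward_backward(model, xs_batch, surv_batch, l1_lambda):
    """One loss + gradient evaluation on a (standardised) mini-batch."""
    arch = model.arch
    outs = model._branch_outputs(xs_batch)
    z = np.concatenate([outs[s.name] for s in arch.branches], axis=1)
    eta = z @ model.beta + model.beta0
    if arch.likelihood_on == "sigmoid":
        scores = sigmoid(eta)
        loss = neg_log_partial_likelihood(scores, surv_batch)
        g_eta = partial_likelihood_gradient(scores, surv_batch) * scores * (1.0 - scores)
    else:
        loss = neg_log_partial_likelihood(eta, surv_batch)
        g_eta = partial_likelihood_gradient(eta, surv_batch)
    loss += l1_lambda * model.l1_norm()

    grads: dict[str, object] = {"beta": z.T @ g_eta + l1_lambda * np.sign(model.beta)}
    if arch.use_bias:
        grads["beta0"] = float(g_eta.sum()) + l1_lambda * np.sign(model.beta0)
    offset = 0
    for spec in arch.branches:
        dim = spec.output_dim
        if spec.hidden_dim is not None:
            g_z = np.outer(g_eta, model.beta[offset : offset + dim])
            zb = outs[spec.name]
            g_a = g_z * zb * (1.0 - zb) if arch.activation == "sigmoid" else g_z
            w, b = model.weights[spec.name]
            gw = g_a.T @ xs_batch[spec.name] + l1_lambda * np.sign(w)
            gb = g_a.sum(axis=0) + l1_lambda * np.sign(b) if b is not None else None
            grads[spec.name] = (gw, gb)
        offset += dim
    return loss, grads


class _Adam:
    def __init__(self, shapes, cfg: TrainConfig):
        self.cfg = cfg
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        c = self.cfg
        self.t += 1
        for k, g in grads.items():
            self.m[k] = c.adam_beta1 * self.m[k] + (1 - c.adam_beta1) * g
            self.v[k] = c.adam_beta2 * self.v[k] + (1 - c.adam_beta2) * g * g
            mhat = self.m[k] / (1 - c.adam_beta1**self.t)
            vhat = self.v[k] / (1 - c.adam_beta2**self.t)
            params[k] = params[k] - c.learning_rate * mhat / (np.sqrt(vhat) + c.adam_eps)
        return params


def train(
    arch: SalmonArchitecture,
    bundle_train: OmicsBundle,
    config: TrainConfig,
) -> tuple[SalmonModel, list[float]]:
    """Fit the network by seeded mini-batch Adam; returns the model and the
    per-epoch mean objective.  Inputs are z-scored on the training bundle and
    the transform is stored on the model.  Risk sets are computed within each
    batch (``config.full_batch`` uses exact risk sets over the whole set).
    """
    if bundle_train.survival is None:
        raise ValueError("training bundle has no survival data")
    if bundle_train.survival.n_events < 2:
        raise ValueError("need at least 2 events to train")

    rng = np.random.default_rng(config.seed)
    model = initialize_model(arch, rng)
    raw = model._blocks_from(bundle_train)
    model.scaler = _fit_scaler(raw)
    xs = {k: (v - model.scaler[k][0]) / model.scaler[k][1] for k, v in raw.items()}

    # flatten parameters into a dict for the optimizer
    def to_flat() -> dict[str, np.ndarray]:
        flat = {"beta": model.beta}
        if arch.use_bias:
            flat["beta0"] = np.asarray(model.beta0)
        for spec in arch.branches:
            if spec.hidden_dim is not None:
                w, b = model.weights[spec.name]
                flat[f"{spec.name}.W"] = w
                if b is not None:
                    flat[f"{spec.name}.b"] = b
        return flat

    def from_flat(flat: dict[str, np.ndarray]) -> None:
        model.beta = flat["beta"]
        if arch.use_bias:
            model.beta0 = float(flat["beta0"])
        for spec in arch.branches:
            if spec.hidden_dim is not None:
                b = flat.get(f"{spec.name}.b")
                model.weights[spec.name] = (flat[f"{spec.name}.W"], b)

    flat = to_flat()
    adam = _Adam({k: v.shape for k, v in flat.items()}, config)
    n = bundle_train.n_samples
    batch_size = n if config.full_batch else min(config.batch_size, n)
    trace: list[float] = []

    for _ in range(config.epochs):
        perm = rng.permutation(n)
        epoch_losses: list[float] = []
        for lo in range(0, n, batch_size):
            idx = perm[lo : lo + batch_size]
            surv_b = bundle_train.survival.subset(idx)
            if surv_b.n_events == 0:
                continue  # no likelihood contribution from an event-free batch
            xs_b = {k: v[idx] for k, v in xs.items()}
            loss, grads = _forward_backward(model, xs_b, surv_b, config.l1_lambda)
            if not np.isfinite(loss):
                raise RuntimeError(
                    "non-finite training loss; reduce the learning rate or check inputs"
                )
            gflat = {"beta": grads["beta"]}
            if arch.use_bias:
                gflat["beta0"] = np.asarray(grads["beta0"])
            for spec in arch.branches:
                if spec.hidden_dim is not None:
                    gw, gb = grads[spec.name]
                    gflat[f"{spec.name}.W"] = gw
                    if gb is not None:
                        gflat[f"{spec.name}.b"] = gb
            flat = adam.step(flat, gflat)
            from_flat(flat)
            epoch_losses.append(loss)
        trace.append(float(np.mean(epoch_losses)) if epoch_losses else float("nan"))
    return model, trace
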