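"""Zero-ablation feature importance, ranked by the median c-index drop across
cross-validation folds, plus feature-selection retraining and age-stratified
experiment support.

Ablation zeroes one Cox-input feature of the *test* data at the network input
scale (after the training-fold standardisation) under a fixed trained model;
a raw-scale variant is available.  More negative median drops mean more
important features.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coxnet import SalmonModel, TrainConfig
from .data_model import OmicsBundle
from .evaluate import concordance_index, paired_t_test
from .experiments import run_cv

__all__ = [
    "ImportanceTable",
    "ablate_feature",
    "rank_features",
    "select_and_retrain",
    "stratify_by_age",
]


@dataclass
class ImportanceTable:
    """Per-feature ablation results.

    ``table`` has one row per Cox-input feature with columns ``feature``,
    ``block``, ``delta_fold_<k>`` per fold, ``median_delta`` and
    ``mean_delta``, sorted ascending by (median, mean, name) — most important
    (most negative) first.
    """

    table: pd.DataFrame

    def __len__(self) -> int:
        return len(self.table)

    def top(self, n: int = 10) -> pd.DataFrame:
        return self.table.head(n)

    def selected(self, rule=None) -> list[tuple[str, str]]:
        """(block, feature) pairs passing the selection rule
        (default: median delta < 0)."""
        if rule is None:
            rule = lambda row: row["median_delta"] < 0  # noqa: E731
        return [
            (row["block"], row["feature"])
            for _, row in self.table.iterrows()
            if rule(row)
        ]

    def to_tsv(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def ablate_feature(
    bundle_test: OmicsBundle, feature: tuple[str, str] | str
) -> OmicsBundle:
    """Copy of the bundle with one feature's column zeroed for every sample.

    ``feature`` is a (block, feature) pair or a ``"block/feature"`` string.
    Note this zeroes the *raw* stored column; model-input-scale ablation is
    performed inside :func:`rank_features` via the model's scaler.
    """
    if isinstance(feature, str):
        if "/" not in feature:
            raise KeyError(f"feature {feature!r} must be 'block/name'")
        block_name, feat = feature.split("/", 1)
    else:
        block_name, feat = feature
    if block_name not in bundle_test.blocks:
        raise KeyError(f"unknown block {block_name!r}")
    block = bundle_test.blocks[block_name]
    if feat not in block.feature_ids:
        raise KeyError(f"unknown feature {feat!r} in block {block_name!r}")
    col = block.feature_ids.index(feat)
    out = bundle_test.subset_samples(np.arange(bundle_test.n_samples))
    out.blocks[block_name].values[:, col] = 0.0
    return out


def rank_features(
    models: list[SalmonModel],
    bundles_test: list[OmicsBundle],
    ablate_scale: str = "standardized",
) -> ImportanceTable:
    """Zero-ablation importance across folds.

    For every fold and Cox-input feature, delta = C(ablated) - C(baseline) on
    that fold's test set; the table is sorted ascending by median delta (ties:
    mean delta, then feature name).
    """
    if not models or len(models) != len(bundles_test):
        raise ValueError("need one test bundle per fold model")
    features = bundles_test[0].feature_names()
    deltas = np.zeros((len(features), len(models)))
    for f, (model, bt) in enumerate(zip(models, bundles_test)):
        if bt.feature_names() != features:
            raise ValueError("test bundles disagree on the feature layout")
        base = concordance_index(model.predict_risk(bt), bt.survival)
        col_of: dict[str, int] = {}
        for i, (block, feat) in enumerate(features):
            col = bt.blocks[block].feature_ids.index(feat)
            risk = model.predict_risk(
                bt, ablate=(block, col), ablate_scale=ablate_scale
            )
            deltas[i, f] = concordance_index(risk, bt.survival) - base
    df = pd.DataFrame(
        {
            "feature": [f for _, f in features],
            "block": [b for b, _ in features],
        }
    )
    for f in range(len(models)):
        df[f"delta_fold_{f + 1}"] = deltas[:, f]
    df["median_delta"] = np.median(deltas, axis=1)
    df["mean_delta"] = deltas.mean(axis=1)
    df = df.sort_values(
        ["median_delta", "mean_delta", "feature"], kind="stable"
    ).reset_index(drop=True)
    return ImportanceTable(df)


def select_and_retrain(
    table: ImportanceTable,
    bundle: OmicsBundle,
    folds: list[np.ndarray],
    config: TrainConfig,
    hidden: dict[str, int] | None = None,
    rule=None,
) -> dict:
    """Retrain using only features passing the rule (default median delta < 0)
    and compare per-fold c-indices before/after with a paired t-test.

    Raises ``ValueError`` when the rule selects no features.
    """
    selected = table.selected(rule)
    if not selected:
        raise ValueError("selection rule retained no features; nothing to retrain on")
    keep: dict[str, list[str]] = {}
    for block, feat in selected:
        keep.setdefault(block, []).append(feat)
    # preserve each block's original feature order
    for block in keep:
        order = bundle.blocks[block].feature_ids
        keep[block] = [f for f in order if f in keep[block]]
    sub = bundle.subset_features(keep)
    baseline = run_cv(bundle, folds, config, hidden=hidden)
    retrained = run_cv(sub, folds, config, hidden=hidden)
    t, p = paired_t_test(np.asarray(baseline.fold_cindex), np.asarray(retrained.fold_cindex))
    return {
        "selected": selected,
        "baseline_cindex": baseline.fold_cindex,
        "retrained_cindex": retrained.fold_cindex,
        "baseline_median": baseline.median_cindex,
        "retrained_median": retrained.median_cindex,
        "t": t,
        "p": p,
        "baseline": baseline,
        "retrained": retrained,
    }


def stratify_by_age(
    bundle: OmicsBundle,
    bounds: list[tuple[float, float]],
    age_block: str = "clinical",
    age_feature: str = "age",
) -> list[OmicsBundle]:
    """Partition samples by closed age intervals [low, high].

    Samples outside every interval are dropped (the first matching interval
    wins when bounds overlap).  Returns one sub-bundle per interval.
    """
    if age_block not in bundle.blocks:
        raise KeyError(f"bundle has no block {age_block!r}")
    block = bundle.blocks[age_block]
    if age_feature not in block.feature_ids:
        raise KeyError(f"block {age_block!r} has no feature {age_feature!r}")
    age = block.values[:, block.feature_ids.index(age_feature)]
    taken = np.zeros(len(age), dtype=bool)
    strata: list[OmicsBundle] = []
    for low, high in bounds:
        mask = (age >= low) & (age <= high) & ~taken
        taken |= mask
        strata.append(bundle.subset_samples(np.flatnonzero(mask)))
    return strata
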