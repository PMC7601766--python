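"""Expanding harvest-by-harvest validation and classification metrics.

The protocol trains on the earliest harvest and predicts the next one, then
augments the training set with the predicted harvest, re-optimises every
hyper-parameter (latent-variable count by LOO-CV, PCA dimensionality, SIMCA
limits) and predicts the following harvest, and so on.  All fitted state —
preprocessing statistics included — derives from training-year rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import plsda as _plsda
from . import simca as _simca
from .config import default_pipeline, default_regions
from .fusion import high_level_vote, low_level_fuse, mid_level_fuse
from .preprocess import PipelineStep, fit_pipeline
from .spectra_io import SampleTable, SpectralBlock, select_regions

__all__ = [
    "SplitStep",
    "SplitPlan",
    "StepResult",
    "ValidationReport",
    "PLSDAPair",
    "SIMCATarget",
    "FusionLevel",
    "build_split_plan",
    "run_yearly_validation",
    "confusion_and_ccr",
]


@dataclass(frozen=True)
class SplitStep:
    train_years: frozenset[int]
    test_year: int

    def __post_init__(self):
        if any(y >= self.test_year for y in self.train_years):
            raise ValueError("test year must be strictly later than all training years")


SplitPlan = tuple  # of SplitStep


def build_split_plan(years: Sequence[int]) -> tuple[SplitStep, ...]:
    """Expanding-window steps: ({y1}, y2), ({y1, y2}, y3), ...  (nested training sets)."""
    ordered = sorted(set(int(y) for y in years))
    if len(ordered) < 2:
        raise ValueError("at least two distinct harvest years are required")
    return tuple(
        SplitStep(train_years=frozenset(ordered[:i]), test_year=ordered[i])
        for i in range(1, len(ordered))
    )


def confusion_and_ccr(predicted: Sequence, truth: Sequence) -> tuple[pd.DataFrame, float]:
    """Confusion matrix (rows = truth) and the correct classification rate in %.

    The CCR is reported to one decimal place; internal metrics elsewhere keep
    full precision.
    """
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.size != truth.size:
        raise ValueError("predicted and truth vectors differ in length")
    labels = sorted(set(truth.tolist()) | set(predicted.tolist()))
    matrix = pd.crosstab(pd.Categorical(truth, categories=labels),
                         pd.Categorical(predicted, categories=labels), dropna=False)
    matrix.index.name, matrix.columns.name = "truth", "predicted"
    ccr = round(100.0 * float(np.mean(predicted == truth)), 1)
    return matrix, ccr


# ---------------------------------------------------------------------------
# Method specifications


@dataclass(frozen=True)
class PLSDAPair:
    """Binary PLS-DA on one platform; ``pair[1]`` is coded 1."""

    pair: tuple[str, str]
    platform: str = "ftmir"
    a_max: int = 10


@dataclass(frozen=True)
class SIMCATarget:
    """One-class SIMCA of ``target`` on one platform; aliens are everything else."""

    target: str = "BA"
    platform: str = "ftmir"
    alpha: float = 0.05
    k: int | None = None  # None -> cumulative-variance rule
    variance_threshold: float = 0.95


@dataclass(frozen=True)
class FusionLevel:
    """Binary PLS-DA on fused platforms at the given fusion level."""

    level: str  # "low" | "mid" | "high"
    pair: tuple[str, str]
    a_max: int = 10
    k_rule: float = 0.95


@dataclass
class StepResult:
    train_years: frozenset[int]
    test_year: int
    n_train: int
    n_test: int
    params: dict
    confusion: pd.DataFrame | None
    ccr: float | None
    metrics: dict = field(default_factory=dict)
    predicted: np.ndarray | None = None
    truth: np.ndarray | None = None
    model_state: dict = field(default_factory=dict)  # fitted arrays, for audit


@dataclass
class ValidationReport:
    method: object
    steps: list[StepResult]

    def summary(self) -> pd.DataFrame:
        rows = []
        for step in self.steps:
            row = {
                "train_years": "+".join(str(y) for y in sorted(step.train_years)),
                "test_year": step.test_year,
                "n_train": step.n_train,
                "n_test": step.n_test,
                "ccr": step.ccr,
            }
            row.update(step.metrics)
            row.update({f"param_{k}": v for k, v in step.params.items()})
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Orchestration


def _resolve(blocks: "Mapping[str, SpectralBlock] | SpectralBlock", platform: str) -> SpectralBlock:
    if isinstance(blocks, SpectralBlock):
        return blocks
    return blocks[platform]


def _prepare(block: SpectralBlock, steps: Sequence[PipelineStep], regions,
             fit_rows: Sequence[int], other_rows: Sequence[int]):
    """Region-select, then fit the pipeline on ``fit_rows`` and apply to the rest."""
    if regions is not None:
        block = select_regions(block, regions)
    train_block, fitted = fit_pipeline(block.take(fit_rows), steps)
    test_block = fitted.apply(block.take(other_rows)) if len(other_rows) else None
    return train_block, test_block, fitted


def _row_indices(table: pd.DataFrame, years: "set[int] | frozenset[int]",
                 classes: "set[str] | None") -> list[int]:
    mask = table["harvest_year"].isin(list(years))
    if classes is not None:
        mask &= table["class_label"].isin(list(classes))
    return list(np.nonzero(mask.to_numpy())[0])


def run_yearly_validation(blocks: "Mapping[str, SpectralBlock] | SpectralBlock",
                          table: SampleTable, method,
                          plan: "tuple[SplitStep, ...] | None" = None,
                          pipelines: "Mapping[str, Sequence[PipelineStep]] | None" = None,
                          regions: "Mapping[str, object] | None" = None,
                          apply_regions: bool = True) -> ValidationReport:
    """Run the expanding harvest-by-harvest protocol for one method.

    ``blocks`` maps platform name to a replicate-averaged block aligned to
    ``table`` (one row per sample, identical order).  Pipelines and retained
    regions default to the per-platform optima.
    """
    frame = table.per_sample()
    if plan is None:
        plan = build_split_plan(frame["harvest_year"].unique())
    for prev, step in zip(plan, plan[1:]):
        if not prev.train_years < step.train_years:
            raise ValueError("training sets must be strictly nested across steps")

    def steps_for(platform: str):
        if pipelines is not None and platform in pipelines:
            return tuple(pipelines[platform])
        return default_pipeline(platform)

    def regions_for(platform: str):
        if not apply_regions:
            return None
        if regions is not None and platform in regions:
            return regions[platform]
        return default_regions(platform)

    results = []
    for split in plan:
        if isinstance(method, PLSDAPair):
            result = _step_plsda(blocks, frame, method, split, steps_for, regions_for)
        elif isinstance(method, SIMCATarget):
            result = _step_simca(blocks, frame, method, split, steps_for, regions_for)
        elif isinstance(method, FusionLevel):
            result = _step_fusion(blocks, frame, method, split, steps_for, regions_for)
        else:
            raise TypeError(f"unknown method {method!r}")
        results.append(result)
    return ValidationReport(method=method, steps=results)


def _fit_binary_pls(X_tr: np.ndarray, y_tr: np.ndarray, a_max: int):
    a_cap = min(a_max, X_tr.shape[0] - 2, X_tr.shape[1])
    a_star = _plsda.loo_cv_select_A(X_tr, y_tr, a_cap)
    return _plsda.fit_pls(X_tr, y_tr, a_star), a_star


def _step_plsda(blocks, frame, method: PLSDAPair, split: SplitStep, steps_for, regions_for) -> StepResult:
    neg, pos = method.pair
    tr = _row_indices(frame, split.train_years, {neg, pos})
    te = _row_indices(frame, {split.test_year}, {neg, pos})
    tr_labels = frame.iloc[tr]["class_label"].to_numpy()
    te_labels = frame.iloc[te]["class_label"].to_numpy()
    for subset, where in ((tr_labels, "training"), (te_labels, "test")):
        present = set(subset.tolist())
        if not {neg, pos} <= present:
            raise ValueError(f"{where} years lack samples of class {sorted({neg, pos} - present)}")
    block = _resolve(blocks, method.platform)
    train_block, test_block, fitted = _prepare(block, steps_for(method.platform),
                                               regions_for(method.platform), tr, te)
    y_tr = (tr_labels == pos).astype(float)
    model, a_star = _fit_binary_pls(train_block.intensities, y_tr, method.a_max)
    yhat = _plsda.predict_response(model, test_block.intensities)
    predicted = np.where(yhat >= model.threshold, pos, neg)
    confusion, ccr = confusion_and_ccr(predicted, te_labels)
    return StepResult(
        train_years=split.train_years, test_year=split.test_year,
        n_train=len(tr), n_test=len(te),
        params={"A": a_star, "platform": method.platform},
        confusion=confusion, ccr=ccr, predicted=predicted, truth=te_labels,
        model_state={"coef": model.coef, "intercept": model.intercept,
                     "pipeline": fitted},
    )


def _step_simca(blocks, frame, method: SIMCATarget, split: SplitStep, steps_for, regions_for) -> StepResult:
    tr = _row_indices(frame, split.train_years, {method.target})
    te = _row_indices(frame, {split.test_year}, None)
    if not tr:
        raise ValueError(f"no training samples of target class {method.target!r}")
    if not te:
        raise ValueError(f"no test samples in year {split.test_year}")
    te_labels = frame.iloc[te]["class_label"].to_numpy()
    block = _resolve(blocks, method.platform)
    train_block, test_block, fitted = _prepare(block, steps_for(method.platform),
                                               regions_for(method.platform), tr, te)
    model = _simca.fit_simca(train_block.intensities, k=method.k, alpha=method.alpha,
                             target=method.target, variance_threshold=method.variance_threshold)
    decisions = _simca.score_samples(model, test_block.intensities)
    is_target = te_labels == method.target
    metrics: dict = {}
    # specificity is computed over whatever aliens the test year offers;
    # missing targets or aliens leave the corresponding metric unset
    if is_target.any() and (~is_target).any():
        m = _simca.sensitivity_specificity(decisions.accepted, te_labels, method.target)
        metrics = {"sensitivity": m.sensitivity, "specificity": m.specificity,
                   "n_target": m.n_target, "n_alien": m.n_alien}
        ccr = m.ccr
    else:
        correct = decisions.accepted == is_target
        ccr = round(100.0 * float(correct.mean()), 1)
    alien_label = f"non-{method.target}"
    predicted = np.where(decisions.accepted, method.target, alien_label)
    truth = np.where(is_target, method.target, alien_label)
    confusion, _ = confusion_and_ccr(predicted, truth)
    return StepResult(
        train_years=split.train_years, test_year=split.test_year,
        n_train=len(tr), n_test=len(te),
        params={"k": model.k, "alpha": model.alpha, "t2_lim": model.t2_lim,
                "q_lim": model.q_lim, "platform": method.platform},
        confusion=confusion, ccr=ccr, metrics=metrics,
        predicted=predicted, truth=truth,
        model_state={"center": model.pca.center, "loadings": model.pca.loadings,
                     "t2_lim": model.t2_lim, "q_lim": model.q_lim,
                     "pipeline": fitted, "decisions": decisions},
    )


def _step_fusion(blocks, frame, method: FusionLevel, split: SplitStep, steps_for, regions_for) -> StepResult:
    if isinstance(blocks, SpectralBlock):
        raise ValueError("fusion needs a mapping of platform blocks")
    neg, pos = method.pair
    # preprocessing and the per-block PCA are fitted once on the whole
    # training set (every class); the binary discriminant then uses only the
    # pair's rows of the transformed data
    tr_all = _row_indices(frame, split.train_years, None)
    te = _row_indices(frame, {split.test_year}, {neg, pos})
    tr_all_labels = frame.iloc[tr_all]["class_label"].to_numpy()
    te_labels = frame.iloc[te]["class_label"].to_numpy()
    pair_mask_tr = np.isin(tr_all_labels, (neg, pos))
    for subset, where in ((tr_all_labels[pair_mask_tr], "training"), (te_labels, "test")):
        present = set(subset.tolist())
        if not {neg, pos} <= present:
            raise ValueError(f"{where} years lack samples of class {sorted({neg, pos} - present)}")
    y_tr = (tr_all_labels[pair_mask_tr] == pos).astype(float)

    prepped = {}
    for platform in blocks:
        train_block, test_block, _ = _prepare(blocks[platform], steps_for(platform),
                                              regions_for(platform), tr_all, te)
        prepped[platform] = (train_block, test_block)
    n_tr, n_te = len(tr_all), len(te)
    train_mask = np.zeros(n_tr + n_te, dtype=bool)
    train_mask[:n_tr] = True
    pair_rows = np.nonzero(pair_mask_tr)[0]

    params: dict = {"level": method.level}
    state: dict = {}
    if method.level in ("low", "mid"):
        keys = [str(i) for i in range(n_tr + n_te)]  # train rows first, then test
        stacked = [
            SpectralBlock(platform=train_block.platform, axis=train_block.axis,
                          intensities=np.vstack([train_block.intensities, test_block.intensities]),
                          sample_keys=keys)
            for train_block, test_block in prepped.values()
        ]
        if method.level == "low":
            fused = low_level_fuse(stacked, train_mask=train_mask, drop_constant=True)
        else:
            fused = mid_level_fuse(stacked, train_mask=train_mask, k_rule=method.k_rule)
            params["k_per_block"] = [m.k for m in fused.block_models]
        model, a_star = _fit_binary_pls(fused.data[train_mask][pair_rows], y_tr, method.a_max)
        params["A"] = a_star
        params["fused_width"] = fused.width
        yhat = _plsda.predict_response(model, fused.data[~train_mask])
        predicted = np.where(yhat >= model.threshold, pos, neg)
        state = {"coef": model.coef, "intercept": model.intercept,
                 "scale_mean": fused.scale_mean, "scale_sd": fused.scale_sd}
    elif method.level == "high":
        votes = []
        for platform, (train_block, test_block) in prepped.items():
            model, a_star = _fit_binary_pls(train_block.intensities[pair_rows], y_tr, method.a_max)
            params[f"A_{platform}"] = a_star
            yhat = _plsda.predict_response(model, test_block.intensities)
            votes.append(np.where(yhat >= model.threshold, pos, neg))
            state[f"coef_{platform}"] = model.coef
        predicted = high_level_vote(votes)
    else:
        raise ValueError(f"unknown fusion level {method.level!r}")

    confusion, ccr = confusion_and_ccr(predicted, te_labels)
    return StepResult(
        train_years=split.train_years, test_year=split.test_year,
        n_train=n_tr, n_test=n_te, params=params,
        confusion=confusion, ccr=ccr, predicted=predicted, truth=te_labels,
        model_state=state,
    )
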