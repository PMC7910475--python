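"""Cross-validation, hyperparameter calibration and reference-overlap
validation for inferred cross-feeding links.

Cross-validation asks whether links learned on a training subset of
samples generalize: the inference ensemble runs on the training samples
only, the consensus links augment the network, and the performance
metrics are compared on held-out test samples against the un-augmented
baseline.

Overlap validation compares an inferred link set with an independently
derived reference list (e.g. flattened genome-scale-model predictions):
the observed overlap fraction is contrasted with uniformly random link
draws from the candidate space and an exact one-sided binomial test.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .bias_metrics import PerformanceReport, performance_report
from .consensus import consensus_atlas, run_ensemble
from .link_sampler import ObjectiveConfig
from .network_core import (
    CrossFeedingNetwork,
    Diet,
    Link,
    OmicsDataset,
)
from .trophic_model import TrophicParams, predict_dataset

logger = logging.getLogger("gutcp")


@dataclass
class FoldReport:
    fold: int
    n_added: int
    train: PerformanceReport
    test: PerformanceReport
    baseline_train: PerformanceReport
    baseline_test: PerformanceReport


@dataclass
class CVReport:
    """Per-fold and aggregate train/test performance."""

    folds: list[FoldReport]
    summary: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.folds and not self.summary:
            for name in ("train", "test", "baseline_train", "baseline_test"):
                for metric in ("mean_correlation", "log_error", "n_predicted_metabolites"):
                    vals = [getattr(getattr(f, name), metric) for f in self.folds]
                    self.summary[f"{name}.{metric}"] = (
                        float(np.mean(vals)), float(np.std(vals)),
                    )


def kfold_split(
    dataset: OmicsDataset, k: int = 4, rng: np.random.Generator | int | None = None
) -> list[tuple[list[str], list[str]]]:
    """Random partition of samples into k near-equal folds.

    Returns (train_ids, test_ids) pairs; each sample appears in exactly
    one test fold.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if dataset.n_samples < k:
        raise ValueError("fewer samples than folds")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    ids = np.array(dataset.sample_ids)
    perm = rng.permutation(len(ids))
    folds = np.array_split(perm, k)
    out = []
    for f in range(k):
        test = ids[folds[f]].tolist()
        train = ids[np.concatenate([folds[g] for g in range(k) if g != f])].tolist()
        out.append((train, test))
    return out


def cross_validate(
    network: CrossFeedingNetwork,
    dataset: OmicsDataset,
    diet: Diet,
    trophic_params: TrophicParams,
    objective_config: ObjectiveConfig,
    k: int = 4,
    R_per_fold: int = 5,
    rng: np.random.Generator | int | None = None,
    threshold: float = 1e-3,
    **run_kwargs,
) -> CVReport:
    """k-fold cross-validation of the inference pipeline.

    Per fold: run an ensemble on the training samples, augment the
    network with the fold's consensus links, and score both the
    augmented and original networks on train and test samples.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    eps = trophic_params.detection_floor
    folds = kfold_split(dataset, k, rng)
    reports: list[FoldReport] = []
    for f, (train_ids, test_ids) in enumerate(folds):
        train = dataset.subset(train_ids)
        test = dataset.subset(test_ids)
        base_seed = int(rng.integers(2**31 - 1 - R_per_fold))
        ensemble = run_ensemble(
            network, train, diet, trophic_params, objective_config,
            R=R_per_fold, base_seed=base_seed, **run_kwargs,
        )
        atlas = consensus_atlas(ensemble, threshold=threshold)
        augmented = network.copy()
        for link in atlas.links:
            augmented.add_link(link, provenance="added")
        reports.append(FoldReport(
            fold=f,
            n_added=len(atlas.links),
            train=performance_report(
                predict_dataset(augmented, train, diet, trophic_params), train, eps
            ),
            test=performance_report(
                predict_dataset(augmented, test, diet, trophic_params), test, eps
            ),
            baseline_train=performance_report(
                predict_dataset(network, train, diet, trophic_params), train, eps
            ),
            baseline_test=performance_report(
                predict_dataset(network, test, diet, trophic_params), test, eps
            ),
        ))
    return CVReport(folds=reports)


def hyperparameter_grid(
    network: CrossFeedingNetwork,
    dataset: OmicsDataset,
    diet: Diet,
    trophic_params: TrophicParams,
    lambda_reg_values: list[float],
    lambda_reward_values: list[float],
    R: int = 5,
    rng: np.random.Generator | int | None = None,
    inv_kT: float = 5000.0,
    **run_kwargs,
) -> dict[tuple[float, float], PerformanceReport]:
    """Mean performance over R runs for every hyperparameter pair."""
    if not lambda_reg_values or not lambda_reward_values:
        raise ValueError("hyperparameter value lists must be non-empty")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    eps = trophic_params.detection_floor
    grid: dict[tuple[float, float], PerformanceReport] = {}
    for lreg, lrew in itertools.product(lambda_reg_values, lambda_reward_values):
        config = ObjectiveConfig(lambda_reg=lreg, lambda_reward=lrew, inv_kT=inv_kT)
        base_seed = int(rng.integers(2**31 - 1 - R))
        ensemble = run_ensemble(
            network, dataset, diet, trophic_params, config,
            R=R, base_seed=base_seed, **run_kwargs,
        )
        reports = []
        for run in ensemble.runs:
            preds = predict_dataset(run.final_network, dataset, diet, trophic_params)
            reports.append(performance_report(preds, dataset, eps))
        grid[(lreg, lrew)] = PerformanceReport(
            mean_correlation=float(np.mean([r.mean_correlation for r in reports])),
            log_error=float(np.mean([r.log_error for r in reports])),
            n_predicted_metabolites=int(
                np.round(np.mean([r.n_predicted_metabolites for r in reports]))
            ),
        )
    return grid


@dataclass
class OverlapReport:
    """Overlap of an inferred link set with a reference list."""

    overlap_fraction: float
    control_fraction_mean: float
    control_fraction_sd: float
    p_value: float
    n_predicted: int
    n_hits: int


def overlap_fraction(
    predicted: list[Link],
    reference: list[Link],
    candidate_space: list[Link],
    n_controls: int = 500,
    rng: np.random.Generator | int | None = None,
    test: str = "binomial",
) -> OverlapReport:
    """Fraction of predicted links present in the reference, with a
    random-draw control and a one-sided significance test.

    ``test``: "binomial" (rate = |reference in candidate space| /
    |candidate space|) or "hypergeometric" (sampling without
    replacement).
    """
    if not predicted:
        raise ValueError("predicted link set is empty")
    pred = set(predicted)
    cand = list(candidate_space)
    if not pred <= set(cand):
        raise ValueError("predicted links must lie in the candidate space")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)

    ref = set(reference) & set(cand)
    n_hits = len(pred & ref)
    frac = n_hits / len(pred)

    controls = np.empty(n_controls)
    for c in range(n_controls):
        idx = rng.choice(len(cand), size=len(pred), replace=False)
        controls[c] = sum(1 for i in idx if cand[i] in ref) / len(pred)

    rate = len(ref) / len(cand)
    if test == "binomial":
        p = float(stats.binomtest(n_hits, len(pred), rate, alternative="greater").pvalue)
    elif test == "hypergeometric":
        p = float(stats.hypergeom.sf(n_hits - 1, len(cand), len(ref), len(pred)))
    else:
        raise ValueError(f"unknown test {test!r}")
    return OverlapReport(
        overlap_fraction=frac,
        control_fraction_mean=float(controls.mean()),
        control_fraction_sd=float(controls.std()),
        p_value=p,
        n_predicted=len(pred),
        n_hits=n_hits,
    )
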