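"""Systematic bias and prediction-performance metrics.

The systematic bias of an entity (species or metabolite) is the mean over
samples of log10(predicted / measured): positive means the model
over-predicts it, negative under-predicts.  Biases drive the link
proposal priors during inference.

Performance is summarized by three measures: the mean per-sample Pearson
correlation between predicted and measured (log10) metabolomes, the mean
absolute log10 prediction error, and the number of measured metabolites
the model predicts at all.

Unit matching: measured metabolomes are relative levels while the
forward model emits flux units.  When ``normalize=True`` the predicted
and measured vectors of each sample are independently rescaled to sum to
1 over the overlapping metabolite set before log comparison, making the
error metrics scale-free; the inference loop uses this mode.  With
``normalize=False`` raw values are compared.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network_core import OmicsDataset
from .trophic_model import SamplePrediction

import logging

logger = logging.getLogger("gutcp")


@dataclass
class BiasVector:
    """Per-entity systematic bias (log10 units) and sample support."""

    bias: dict[str, float]
    support: dict[str, int]

    def get(self, entity: str, default: float = 0.0) -> float:
        return self.bias.get(entity, default)


@dataclass
class PerformanceReport:
    """The three headline performance measures."""

    mean_correlation: float
    log_error: float
    n_predicted_metabolites: int
    median_predicted_per_sample: float = float("nan")


# ---------------------------------------------------------------------------
# Array assembly
# ---------------------------------------------------------------------------

def _metabolome_arrays(
    predictions: dict[str, SamplePrediction], dataset: OmicsDataset
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Aligned (N, M) predicted / measured arrays over shared metabolites."""
    sample_ids = [s for s in dataset.sample_ids if s in predictions]
    if not sample_ids:
        raise ValueError("predictions and dataset share no samples")
    some_pred = predictions[sample_ids[0]].predicted_metabolome
    mets = [m for m in dataset.metabolome.columns if m in some_pred]
    pred = np.array(
        [[predictions[s].predicted_metabolome[m] for m in mets] for s in sample_ids]
    )
    meas = dataset.metabolome.loc[sample_ids, mets].to_numpy(dtype=float)
    return pred, meas, mets


def overlap_metabolites(
    predictions: dict[str, SamplePrediction],
    dataset: OmicsDataset,
    eps: float = 1e-6,
) -> list[str]:
    """Metabolites predicted above the detection floor in at least one
    sample AND measured above zero in at least one sample."""
    pred, meas, mets = _metabolome_arrays(predictions, dataset)
    keep = (pred > eps).any(axis=0) & (meas > 0).any(axis=0)
    return [m for m, k in zip(mets, keep) if k]


def _restrict_to_overlap(
    pred: np.ndarray, meas: np.ndarray, eps: float, normalize: bool
) -> tuple[np.ndarray, np.ndarray, int]:
    """Restrict aligned (N, M) arrays to the overlap set.

    Returns per-sample (optionally sum-1 normalized) predicted and
    measured arrays over overlapping metabolites, with predicted zeros
    floored at eps, plus the overlap count.  This is the single shared
    core behind the error metrics; the inference loop calls it directly
    on raw arrays so that its objective values agree bit-for-bit with the
    public functions.
    """
    keep = (pred > eps).any(axis=0) & (meas > 0).any(axis=0)
    if not keep.any():
        raise ValueError("no overlap between predicted and measured metabolites")
    pred = pred[:, keep]
    meas = meas[:, keep]
    if normalize:
        psum = pred.sum(axis=1, keepdims=True)
        msum = meas.sum(axis=1, keepdims=True)
        pred = np.divide(pred, psum, out=pred.copy(), where=psum > 0)
        meas = np.divide(meas, msum, out=meas.copy(), where=msum > 0)
    return np.maximum(pred, eps), meas, int(keep.sum())


def error_and_overlap_from_arrays(
    pred: np.ndarray, meas: np.ndarray, eps: float, normalize: bool
) -> tuple[float, int]:
    """Mean absolute log10 error and overlap count from aligned arrays."""
    p, m, n_overlap = _restrict_to_overlap(pred, meas, eps, normalize)
    valid = m > 0
    if not valid.any():
        raise ValueError("no positive measured levels in the overlap set")
    err = np.abs(np.log10(p[valid]) - np.log10(m[valid]))
    return float(err.mean()), n_overlap


def _overlap_arrays(
    predictions: dict[str, SamplePrediction],
    dataset: OmicsDataset,
    eps: float,
    normalize: bool,
) -> tuple[np.ndarray, np.ndarray]:
    pred, meas, _ = _metabolome_arrays(predictions, dataset)
    p, m, _ = _restrict_to_overlap(pred, meas, eps, normalize)
    return p, m


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def systematic_bias(
    predictions: dict[str, SamplePrediction],
    dataset: OmicsDataset,
    eps: float = 1e-6,
    normalize: bool = False,
    include_species: bool = True,
) -> BiasVector:
    """Per-entity mean of log10(predicted) - log10(measured).

    A sample contributes to entity i only where the measured level is
    positive; a predicted zero is floored at ``eps`` before the log.
    Entities never measured above zero are absent from the result.
    Species biases compare the predicted microbiome (growth shares) with
    measured relative abundances; both are already relative so they are
    never re-normalized.
    """
    bias: dict[str, float] = {}
    support: dict[str, int] = {}

    pred, meas, mets = _metabolome_arrays(predictions, dataset)
    if normalize:
        keep = (pred > eps).any(axis=0) & (meas > 0).any(axis=0)
        psub, msub = pred[:, keep], meas[:, keep]
        psum = psub.sum(axis=1, keepdims=True)
        msum = msub.sum(axis=1, keepdims=True)
        pred = pred.copy()
        meas = meas.copy()
        pred[:, keep] = np.divide(psub, psum, out=psub.copy(), where=psum > 0)
        meas[:, keep] = np.divide(msub, msum, out=msub.copy(), where=msum > 0)
    _accumulate_bias(pred, meas, mets, eps, bias, support)

    if include_species:
        sample_ids = [s for s in dataset.sample_ids if s in predictions]
        some = predictions[sample_ids[0]].predicted_microbiome
        species = [s for s in dataset.abundance.columns if s in some]
        if species:
            p_sp = np.array(
                [[predictions[a].predicted_microbiome[s] for s in species]
                 for a in sample_ids]
            )
            m_sp = dataset.abundance.loc[sample_ids, species].to_numpy(dtype=float)
            _accumulate_bias(p_sp, m_sp, species, eps, bias, support)

    return BiasVector(bias=bias, support=support)


def _accumulate_bias(
    pred: np.ndarray,
    meas: np.ndarray,
    names: list[str],
    eps: float,
    bias: dict[str, float],
    support: dict[str, int],
) -> None:
    valid = meas > 0
    with np.errstate(divide="ignore"):
        logratio = np.log10(np.maximum(pred, eps)) - np.log10(
            np.where(valid, meas, 1.0)
        )
    counts = valid.sum(axis=0)
    sums = np.where(valid, logratio, 0.0).sum(axis=0)
    for j, name in enumerate(names):
        if counts[j] >= 1:
            bias[name] = float(sums[j] / counts[j])
            support[name] = int(counts[j])


def mean_log_error(
    predictions: dict[str, SamplePrediction],
    dataset: OmicsDataset,
    eps: float = 1e-6,
    normalize: bool = False,
) -> float:
    """Mean absolute log10(predicted/measured) over sample x overlapping
    metabolite pairs with positive measured level."""
    pred, meas, _ = _metabolome_arrays(predictions, dataset)
    return error_and_overlap_from_arrays(pred, meas, eps, normalize)[0]


def metabolome_correlation(
    predictions: dict[str, SamplePrediction],
    dataset: OmicsDataset,
    eps: float = 1e-6,
    pooled: bool = False,
) -> float:
    """Pearson correlation between log10 predicted and measured levels
    over the overlap set, averaged over samples (or pooled).

    Samples with a constant vector (undefined correlation) are skipped
    with a warning.  The statistic is invariant to per-sample rescaling
    of either vector, so no normalization option is needed.
    """
    pred, meas = _overlap_arrays(predictions, dataset, eps, normalize=False)
    lp = np.log10(pred)
    with np.errstate(divide="ignore"):
        lm = np.log10(np.where(meas > 0, meas, np.nan))
    if pooled:
        mask = np.isfinite(lm).ravel()
        x, y = lp.ravel()[mask], lm.ravel()[mask]
        return float(np.corrcoef(x, y)[0, 1])
    rs = []
    for a in range(lp.shape[0]):
        mask = np.isfinite(lm[a])
        x, y = lp[a][mask], lm[a][mask]
        if mask.sum() < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("sample %d skipped in correlation (constant or short)", a)
            continue
        rs.append(np.corrcoef(x, y)[0, 1])
    if not rs:
        raise ValueError("no sample admits a defined correlation")
    return float(np.mean(rs))


def predicted_metabolite_count(
    predictions: dict[str, SamplePrediction],
    dataset: OmicsDataset,
    eps: float = 1e-6,
) -> int:
    """Number of metabolites predicted above the floor in >= 1 sample and
    measured above zero in >= 1 sample."""
    try:
        return len(overlap_metabolites(predictions, dataset, eps))
    except ValueError:
        return 0


def median_predicted_per_sample(
    predictions: dict[str, SamplePrediction],
    dataset: OmicsDataset,
    eps: float = 1e-6,
) -> float:
    """Median across samples of the per-sample overlap count."""
    pred, meas, _ = _metabolome_arrays(predictions, dataset)
    per_sample = ((pred > eps) & (meas > 0)).sum(axis=1)
    return float(np.median(per_sample))


def performance_report(
    predictions: dict[str, SamplePrediction],
    dataset: OmicsDataset,
    eps: float = 1e-6,
    normalize: bool = True,
) -> PerformanceReport:
    """Bundle the three performance measures into one report.

    A dataset where no sample admits a defined correlation (fewer than 3
    overlapping metabolites, or constant vectors) reports NaN for the
    correlation instead of failing; the other measures are unaffected.
    """
    try:
        corr = metabolome_correlation(predictions, dataset, eps)
    except ValueError:
        logger.warning("correlation undefined for this dataset; reporting NaN")
        corr = float("nan")
    return PerformanceReport(
        mean_correlation=corr,
        log_error=mean_log_error(predictions, dataset, eps, normalize=normalize),
        n_predicted_metabolites=predicted_metabolite_count(predictions, dataset, eps),
        median_predicted_per_sample=median_predicted_per_sample(
            predictions, dataset, eps
        ),
    )
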