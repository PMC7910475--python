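"""Stochastic link inference: bias-weighted priors, Metropolis acceptance.

One inference run starts from a known cross-feeding network, measures the
systematic bias of every species and metabolite, and then repeatedly

1. computes a prior over all candidate links from the biases
   (underpredicted species attract consumption links, underpredicted
   metabolites attract production links),
2. proposes one candidate from that prior,
3. re-runs the forward model with the proposed link and evaluates a
   regularized objective E (mean absolute log10 error, plus a penalty
   per added link, minus a reward per predicted metabolite),
4. accepts the proposal with Metropolis probability min(1, e^(-dE/kT)),
5. stops once the change of E over a trailing window is no larger than
   the expected change from the same number of uniformly random steps.

The run returns the best-objective network visited.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .bias_metrics import (
    BiasVector,
    _accumulate_bias,
    error_and_overlap_from_arrays,
)
from .network_core import (
    CONSUMPTION,
    CrossFeedingNetwork,
    Diet,
    Link,
    OmicsDataset,
    enumerate_candidate_links,
)
from .trophic_model import TrophicParams, forward_flux

logger = logging.getLogger("gutcp")

_CLIP = 50.0  # |exponent| cap in prior weights, guards non-finite biases


@dataclass
class PriorDistribution:
    """Categorical proposal distribution over candidate links."""

    candidates: list[Link]
    probabilities: np.ndarray
    kappa: float = 0.1
    gamma: float = 3.0

    def __post_init__(self) -> None:
        total = float(self.probabilities.sum())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-9):
            raise ValueError(f"prior probabilities sum to {total}, not 1")


@dataclass
class ObjectiveConfig:
    """Hyperparameters of the objective and the acceptance rule.

    lambda_reg penalizes each added link; lambda_reward rewards each
    predicted metabolite that overlaps the measurements; inv_kT is the
    effective inverse temperature of the Metropolis step.
    """

    lambda_reg: float = 1e-3
    lambda_reward: float = 1e-3
    inv_kT: float = 5000.0

    def __post_init__(self) -> None:
        if self.lambda_reg < 0 or self.lambda_reward < 0:
            raise ValueError("penalty/reward hyperparameters must be >= 0")
        if self.inv_kT <= 0:
            raise ValueError("inv_kT must be positive")


@dataclass
class RunResult:
    """Outcome of one inference run."""

    final_network: CrossFeedingNetwork
    added_links: list[Link]
    removed_links: list[Link]
    E_trajectory: list[float]
    seed: int | None
    n_iterations: int
    stopped_by_budget: bool = False


def compute_link_priors(
    bias: BiasVector,
    candidates: list[Link],
    kappa: float = 0.1,
    gamma: float = 3.0,
    bias_cap: float = 1.0,
) -> PriorDistribution:
    """Bias-weighted prior over candidate links.

    Unnormalized weights: e^(-gamma*(b_species - b_metabolite)) + kappa
    for a consumption candidate, e^(-gamma*b_metabolite) + kappa for a
    production candidate; entities without a measured bias contribute
    b = 0.  Consumption and production candidates are normalized jointly
    into one categorical distribution.

    Biases are saturated at +-bias_cap (default one order of magnitude)
    before entering the exponent.  An entity whose predicted level sits
    at the detection floor can have a formally huge |bias| that would
    collapse the prior onto its candidates alone and starve the uniform
    kappa mixing the proposal scheme relies on; beyond an order of
    magnitude the bias carries direction, not additional evidence.
    """
    if not candidates:
        raise ValueError("candidate set is empty")

    def b(entity: str) -> float:
        return float(np.clip(bias.get(entity), -bias_cap, bias_cap))

    exponents = np.empty(len(candidates))
    for k, link in enumerate(candidates):
        if link.link_type == CONSUMPTION:
            exponents[k] = -gamma * (b(link.species_id) - b(link.metabolite_id))
        else:
            exponents[k] = -gamma * b(link.metabolite_id)
    if np.abs(exponents).max() > _CLIP:  # unreachable for sane gamma * bias_cap
        logger.warning("clipping extreme prior exponents")
        exponents = np.clip(exponents, -_CLIP, _CLIP)
    weights = np.exp(exponents) + kappa
    return PriorDistribution(
        candidates=list(candidates),
        probabilities=weights / weights.sum(),
        kappa=kappa,
        gamma=gamma,
    )


def propose_link(prior: PriorDistribution, rng: np.random.Generator) -> Link:
    """Draw one candidate link from the prior."""
    if not prior.candidates:
        raise ValueError("no candidate links left to propose (network saturated)")
    idx = rng.choice(len(prior.candidates), p=prior.probabilities)
    return prior.candidates[int(idx)]


def objective_from_arrays(
    pred: np.ndarray,
    meas: np.ndarray,
    n_added: int,
    config: ObjectiveConfig,
    eps: float,
    normalize: bool = True,
) -> float:
    mle, n_overlap = error_and_overlap_from_arrays(pred, meas, eps, normalize)
    return mle + config.lambda_reg * n_added - config.lambda_reward * n_overlap


def objective(
    predictions,
    dataset: OmicsDataset,
    n_added: int,
    config: ObjectiveConfig,
    eps: float = 1e-6,
    normalize: bool = False,
) -> float:
    """E = mean_log_error + lambda_reg * N_added - lambda_reward * M."""
    from .bias_metrics import _metabolome_arrays

    pred, meas, _ = _metabolome_arrays(predictions, dataset)
    return objective_from_arrays(pred, meas, n_added, config, eps, normalize)


def metropolis_accept(
    dE: float, config: ObjectiveConfig, rng: np.random.Generator
) -> bool:
    """Accept with probability min(1, e^(-dE * inv_kT))."""
    if not math.isfinite(dE):
        raise ValueError("dE must be finite")
    if dE <= 0:
        return True
    return rng.random() < math.exp(-dE * config.inv_kT)


def should_stop(
    E_trajectory: list[float], random_baseline: float, window: int = 500
) -> bool:
    """Stop when the trailing-window change in E is within the change
    expected from the same number of uniformly random steps."""
    if window < 1:
        raise ValueError("window must be >= 1")
    if len(E_trajectory) <= window:
        return False
    return abs(E_trajectory[-1] - E_trajectory[-1 - window]) <= random_baseline


# ---------------------------------------------------------------------------
# The full run
# ---------------------------------------------------------------------------

class _State:
    """Mutable array-level view of the network during a run.

    Keeps the aligned measured arrays fixed and re-runs the forward model
    on edited adjacency matrices; metabolite/species column order matches
    the public metric functions so objective values agree exactly."""

    def __init__(
        self,
        network: CrossFeedingNetwork,
        dataset: OmicsDataset,
        diet: Diet,
        params: TrophicParams,
        normalize: bool,
    ):
        self.network = network
        self.params = params
        self.normalize = normalize
        self.C, self.P = network.adjacency()
        self.s_idx = {s: i for i, s in enumerate(network.species)}
        self.m_idx = {m: j for j, m in enumerate(network.metabolites)}
        self.abund = (
            dataset.abundance.reindex(columns=network.species, fill_value=0.0)
            .to_numpy(dtype=float)
        )
        self.diet_vec = diet.vector(network.metabolites)
        # column selections matching bias_metrics._metabolome_arrays
        self.met_cols = [
            self.m_idx[m] for m in dataset.metabolome.columns if m in self.m_idx
        ]
        self.met_names = [m for m in dataset.metabolome.columns if m in self.m_idx]
        self.meas_met = dataset.metabolome.loc[:, self.met_names].to_numpy(dtype=float)
        self.sp_cols = [
            self.s_idx[s] for s in dataset.abundance.columns if s in self.s_idx
        ]
        self.sp_names = [s for s in dataset.abundance.columns if s in self.s_idx]
        self.meas_sp = dataset.abundance.loc[:, self.sp_names].to_numpy(dtype=float)

    def predict(self) -> tuple[np.ndarray, np.ndarray]:
        growth, metab = forward_flux(
            self.C, self.P, self.abund, self.diet_vec,
            self.params.byproduct_fraction, self.params.n_levels,
            self.params.carry_through,
        )
        return growth, metab

    def evaluate(self, n_added: int, config: ObjectiveConfig) -> float:
        growth, metab = self.predict()
        return objective_from_arrays(
            metab[:, self.met_cols], self.meas_met, n_added, config,
            self.params.detection_floor, self.normalize,
        )

    def flip(self, link: Link) -> None:
        mat = self.C if link.link_type == CONSUMPTION else self.P
        i, j = self.s_idx[link.species_id], self.m_idx[link.metabolite_id]
        mat[i, j] = not mat[i, j]

    def bias(self) -> BiasVector:
        growth, metab = self.predict()
        totals = growth.sum(axis=1, keepdims=True)
        micro = np.divide(growth, totals, out=np.zeros_like(growth), where=totals > 0)
        bias: dict[str, float] = {}
        support: dict[str, int] = {}
        eps = self.params.detection_floor
        pred_met = metab[:, self.met_cols]
        meas_met = self.meas_met
        if self.normalize:
            keep = (pred_met > eps).any(axis=0) & (meas_met > 0).any(axis=0)
            if keep.any():
                psub, msub = pred_met[:, keep], meas_met[:, keep]
                psum = psub.sum(axis=1, keepdims=True)
                msum = msub.sum(axis=1, keepdims=True)
                pred_met = pred_met.copy()
                meas_met = meas_met.copy()
                pred_met[:, keep] = np.divide(psub, psum, out=psub.copy(), where=psum > 0)
                meas_met[:, keep] = np.divide(msub, msum, out=msub.copy(), where=msum > 0)
        _accumulate_bias(pred_met, meas_met, self.met_names, eps, bias, support)
        _accumulate_bias(
            micro[:, self.sp_cols], self.meas_sp, self.sp_names, eps, bias, support
        )
        return BiasVector(bias=bias, support=support)


def estimate_random_baseline(
    state: _State,
    candidates: list[Link],
    n_added: int,
    config: ObjectiveConfig,
    rng: np.random.Generator,
    window: int,
    n_probe: int = 50,
) -> float:
    """Expected |change in E| over ``window`` uniformly random steps.

    Probes ``n_probe`` uniformly random candidate links at the current
    network.  Only worsening probes contribute: a random link that
    happens to lower E is signal the search should pursue, not the noise
    floor the stopping rule compares against.  Each worsening probe
    contributes its Metropolis-expected drift |dE| * e^(-dE * inv_kT);
    the baseline is the window-length sum of the per-step mean."""
    if not candidates:
        return 0.0
    E0 = state.evaluate(n_added, config)
    idx = rng.choice(len(candidates), size=min(n_probe, len(candidates)), replace=False)
    dEs = np.empty(len(idx))
    for k, ci in enumerate(idx):
        link = candidates[int(ci)]
        state.flip(link)
        dEs[k] = state.evaluate(n_added + 1, config) - E0
        state.flip(link)
    drift = np.where(
        dEs > 0, dEs * np.exp(-np.clip(dEs * config.inv_kT, -_CLIP, _CLIP)), 0.0
    )
    return float(window * drift.mean())


def run_gutcp(
    network: CrossFeedingNetwork,
    dataset: OmicsDataset,
    diet: Diet,
    trophic_params: TrophicParams,
    objective_config: ObjectiveConfig,
    rng: np.random.Generator | int | None = None,
    allow_removal: bool = False,
    max_iter: int = 20_000,
    window: int = 500,
    kappa: float = 0.1,
    gamma: float = 3.0,
    bias_cap: float = 1.0,
    normalize: bool = True,
) -> RunResult:
    """Run one full inference pass and return the best network visited.

    When ``allow_removal`` is set, each iteration is an add-move with
    probability 0.5 and otherwise a remove-move on a uniformly chosen
    existing link (added or original).
    """
    seed = rng if isinstance(rng, int) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    net = network.copy()
    state = _State(net, dataset, diet, trophic_params, normalize)
    candidates = enumerate_candidate_links(net)
    cand_set = set(candidates)

    added: list[Link] = []
    removed: list[Link] = []
    n_added = 0
    E_cur = state.evaluate(n_added, objective_config)
    trajectory = [E_cur]

    best_E = E_cur
    best_links = set(net.links)

    baseline = estimate_random_baseline(
        state, candidates, n_added, objective_config, rng, window
    )
    prior = (
        compute_link_priors(state.bias(), candidates, kappa, gamma, bias_cap)
        if candidates else None
    )

    stopped_by_budget = True
    n_iterations = 0
    for _ in range(max_iter):
        do_remove = allow_removal and net.links and rng.random() < 0.5
        if do_remove:
            link = sorted(net.links)[int(rng.integers(len(net.links)))]
            d_added = -1 if net.provenance.get(link) == "added" else 0
        else:
            if prior is None:
                stopped_by_budget = False
                break
            link = propose_link(prior, rng)
            d_added = 1

        state.flip(link)
        E_new = state.evaluate(n_added + d_added, objective_config)
        if metropolis_accept(E_new - E_cur, objective_config, rng):
            E_cur = E_new
            n_added += d_added
            if do_remove:
                removed.append(link)
                net.remove_link(link)
                candidates.append(link)
                cand_set.add(link)
            else:
                added.append(link)
                net.add_link(link)
                if link in cand_set:
                    candidates.remove(link)
                    cand_set.remove(link)
            if E_cur < best_E:
                best_E = E_cur
                best_links = set(net.links)
            prior = (
                compute_link_priors(state.bias(), candidates, kappa, gamma, bias_cap)
                if candidates else None
            )
        else:
            state.flip(link)
        trajectory.append(E_cur)
        n_iterations += 1
        if should_stop(trajectory, baseline, window):
            stopped_by_budget = False
            break

    # report the best-E network visited
    final = network.copy()
    for link in best_links - network.links:
        final.add_link(link, provenance="added")
    for link in network.links - best_links:
        final.remove_link(link)
    final_added = list(dict.fromkeys(l for l in added if l in best_links))
    final_removed = list(dict.fromkeys(l for l in removed if l not in best_links))
    # the trajectory ends at the value of the network actually reported
    if trajectory[-1] != best_E:
        trajectory.append(best_E)
    return RunResult(
        final_network=final,
        added_links=final_added,
        removed_links=final_removed,
        E_trajectory=trajectory,
        seed=seed,
        n_iterations=n_iterations,
        stopped_by_budget=stopped_by_budget,
    )
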