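"""Ensemble runs, link prevalence and the consensus atlas.

Because a single stochastic run discovers a mixture of real and spurious
links, many independent runs are pooled.  For each link ever discovered
we record its prevalence (fraction of runs containing it) and compare it
with a binomial chance-discovery null: if each run added links uniformly
at random, a given candidate would appear in any one run with probability
q = (mean links added per run) / (number of candidate links).  Links
whose prevalence is significantly above this null (one-sided exact
binomial tail) form the consensus atlas.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .link_sampler import ObjectiveConfig, RunResult, run_gutcp
from .network_core import (
    CrossFeedingNetwork,
    Diet,
    Link,
    OmicsDataset,
    enumerate_candidate_links,
)
from .trophic_model import TrophicParams


@dataclass
class EnsembleResult:
    """A collection of independent inference runs on the same inputs."""

    runs: list[RunResult]
    candidate_count: int

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def mean_links_per_run(self) -> float:
        return float(np.mean([len(r.added_links) for r in self.runs]))


@dataclass
class ConsensusAtlas:
    """Links significantly more prevalent than the chance-discovery null.

    ``entries`` maps every link seen in at least one run to its
    (prevalence, one-sided binomial P value); ``links`` is the subset
    passing the threshold.
    """

    entries: dict[Link, tuple[float, float]]
    threshold: float

    @property
    def links(self) -> list[Link]:
        return sorted(l for l, (_, p) in self.entries.items() if p < self.threshold)

    def prevalence(self, link: Link) -> float:
        return self.entries.get(link, (0.0, 1.0))[0]


def run_ensemble(
    network: CrossFeedingNetwork,
    dataset: OmicsDataset,
    diet: Diet,
    trophic_params: TrophicParams,
    objective_config: ObjectiveConfig,
    R: int = 100,
    base_seed: int = 0,
    **run_kwargs,
) -> EnsembleResult:
    """R independent runs seeded base_seed .. base_seed + R - 1."""
    if R < 1:
        raise ValueError("R must be >= 1")
    runs: list[RunResult] = []
    for r in range(R):
        try:
            runs.append(
                run_gutcp(
                    network, dataset, diet, trophic_params, objective_config,
                    rng=base_seed + r, **run_kwargs,
                )
            )
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"ensemble run with seed {base_seed + r} failed") from exc
    return EnsembleResult(
        runs=runs, candidate_count=len(enumerate_candidate_links(network))
    )


def link_prevalence(ensemble: EnsembleResult) -> dict[Link, float]:
    """Fraction of runs in which each discovered link was added."""
    counts: dict[Link, int] = {}
    for run in ensemble.runs:
        for link in set(run.added_links):
            counts[link] = counts.get(link, 0) + 1
    R = ensemble.n_runs
    return {link: c / R for link, c in counts.items()}


def binomial_tail_pvalue(k: int, R: int, q: float) -> float:
    """Exact one-sided tail P(X >= k), X ~ Binomial(R, q)."""
    if k <= 0:
        return 1.0
    return float(stats.binom.sf(k - 1, R, q))


def consensus_atlas(
    ensemble: EnsembleResult, threshold: float = 1e-3
) -> ConsensusAtlas:
    """Assign each discovered link a prevalence and binomial P value."""
    if ensemble.candidate_count <= 0:
        raise ValueError("candidate space is empty")
    q = ensemble.mean_links_per_run / ensemble.candidate_count
    if q >= 1:
        raise ValueError(f"degenerate null: per-run discovery probability q={q:.3f} >= 1")
    R = ensemble.n_runs
    entries: dict[Link, tuple[float, float]] = {}
    for link, prev in link_prevalence(ensemble).items():
        k = round(prev * R)
        entries[link] = (prev, binomial_tail_pvalue(k, R, q))
    return ConsensusAtlas(entries=entries, threshold=threshold)


def collapse_bidirectional(atlas: ConsensusAtlas) -> list[Link]:
    """Atlas links with bidirectional pairs collapsed to the direction
    with the smaller P value (for reporting)."""
    by_pair: dict[tuple[str, str], Link] = {}
    for link in atlas.links:
        key = (link.species_id, link.metabolite_id)
        if key not in by_pair or atlas.entries[link][1] < atlas.entries[by_pair[key]][1]:
            by_pair[key] = link
    return sorted(by_pair.values())
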