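"""Synthetic ground-truth networks and paired omics datasets.

The generator builds a layered cross-feeding network — diet metabolites
at level 0, species at levels 0..L-1 each consuming from their level and
secreting to the next — then simulates per-sample species presence and
abundance, runs the trophic forward model under the full (truth) network,
and perturbs the resulting metabolomes with multiplicative log-normal
noise.  Withholding a random subset of links from the truth network
yields a degraded network plus a known answer key, so link-recovery
performance of the inference loop can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .consensus import ConsensusAtlas
from .network_core import (
    CONSUMPTION,
    PRODUCTION,
    CrossFeedingNetwork,
    Diet,
    Link,
    OmicsDataset,
)
from .trophic_model import TrophicParams, predict_dataset


def _met_name(level: int, k: int) -> str:
    return f"met_L{level}_{k:02d}"


def metabolite_level(metabolite_id: str) -> int:
    """Trophic level encoded in a generated metabolite identifier."""
    return int(metabolite_id.split("_")[1][1:])


@dataclass
class SyntheticTruth:
    """A truth network, its degraded version, and the withheld answer key."""

    truth_network: CrossFeedingNetwork
    degraded_network: CrossFeedingNetwork
    withheld: set[Link]
    generation_params: dict = field(default_factory=dict)


def generate_truth_network(
    S: int,
    M: int,
    n_levels: int,
    links_per_species: int,
    rng: np.random.Generator | int | None = None,
) -> CrossFeedingNetwork:
    """Layered bipartite cross-feeding network.

    Metabolites are spread over levels 0..n_levels (level 0 = diet);
    each species sits at a home level l in 0..n_levels-1 with at least
    one consumption link to a level-l metabolite and one production link
    to a level-(l+1) metabolite, plus random extra links up to
    ``links_per_species`` per species.  Every metabolite above level 0
    gets at least one producer, so the whole network is reachable from
    the diet set.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    if S < 2:
        raise ValueError("need at least 2 species")
    if M < n_levels + 1:
        raise ValueError("need at least one metabolite per level (M >= n_levels + 1)")
    if S < n_levels:
        raise ValueError("need at least one species per trophic level (S >= n_levels)")
    if links_per_species < 2:
        raise ValueError("links_per_species must be >= 2 (one consumption + one production)")

    # metabolites spread over levels 0..n_levels, each level nonempty
    levels = [int(x) for x in np.sort(rng.integers(0, n_levels + 1, size=M))]
    for lv in range(n_levels + 1):
        if lv not in levels:
            levels[int(np.argmin([abs(l - lv) for l in levels]))] = lv
    levels.sort()
    metabolites = [_met_name(lv, k) for k, lv in enumerate(levels)]
    by_level = {lv: [m for m, l in zip(metabolites, levels) if l == lv]
                for lv in range(n_levels + 1)}
    species = [f"sp_{i:02d}" for i in range(S)]
    home = {sp: i % n_levels for i, sp in enumerate(species)}

    net = CrossFeedingNetwork(species=species, metabolites=metabolites)
    for sp in species:
        lv = home[sp]
        eat = by_level[lv][int(rng.integers(len(by_level[lv])))]
        make = by_level[lv + 1][int(rng.integers(len(by_level[lv + 1])))]
        net.add_link(Link(sp, eat, CONSUMPTION), provenance="original")
        net.add_link(Link(sp, make, PRODUCTION), provenance="original")

    # guarantee every metabolite above level 0 has a producer
    produced = {l.metabolite_id for l in net.links if l.link_type == PRODUCTION}
    for mb, lv in zip(metabolites, levels):
        if lv >= 1 and mb not in produced:
            makers = [sp for sp in species if home[sp] == lv - 1]
            sp = makers[int(rng.integers(len(makers)))]
            net.add_link(Link(sp, mb, PRODUCTION), provenance="original")

    # random extra links, respecting the layering (consume from the home
    # level or below, produce to the level above the home level or above)
    def n_links(sp: str) -> int:
        return sum(1 for l in net.links if l.species_id == sp)

    for sp in species:
        lv = home[sp]
        tries = 0
        while n_links(sp) < links_per_species and tries < 50:
            tries += 1
            if rng.random() < 0.5:
                pool = [m for m, l in zip(metabolites, levels) if l <= lv]
                link = Link(sp, pool[int(rng.integers(len(pool)))], CONSUMPTION)
            else:
                pool = [m for m, l in zip(metabolites, levels) if l >= lv + 1]
                link = Link(sp, pool[int(rng.integers(len(pool)))], PRODUCTION)
            if link not in net.links:
                net.add_link(link, provenance="original")
    return net


def diet_for_network(network: CrossFeedingNetwork, amount: float = 1.0) -> Diet:
    """Uniform intake over the generated network's level-0 metabolites."""
    intake = {m: amount for m in network.metabolites if metabolite_level(m) == 0}
    if not intake:
        raise ValueError("network has no level-0 (diet) metabolites")
    return Diet(intake=intake)


def simulate_dataset(
    truth: CrossFeedingNetwork,
    n_samples: int,
    species_prevalence: float,
    noise_sd: float,
    diet: Diet,
    trophic_params: TrophicParams,
    rng: np.random.Generator | int | None = None,
    abundance_log_sd: float = 1.0,
    max_retries: int = 100,
) -> OmicsDataset:
    """Simulate paired microbiome/metabolome measurements.

    Each species is present in each sample independently with probability
    ``species_prevalence``; present species get log-normal abundances
    (sigma ``abundance_log_sd`` in natural log), normalized per sample.
    Measured metabolomes are the truth network's forward predictions
    multiplied by 10^N(0, noise_sd) independently per entry; predicted
    zeros stay zero.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    S = truth.n_species
    rows = []
    for _ in range(n_samples):
        for _try in range(max_retries):
            present = rng.random(S) < species_prevalence
            if present.any():
                break
        else:
            raise RuntimeError(
                "could not draw a sample with at least one present species"
            )
        ab = np.where(present, rng.lognormal(0.0, abundance_log_sd, size=S), 0.0)
        rows.append(ab / ab.sum())
    sample_ids = [f"sample_{a:03d}" for a in range(n_samples)]
    abundance = pd.DataFrame(rows, index=sample_ids, columns=truth.species)

    clean = OmicsDataset(
        abundance=abundance,
        metabolome=pd.DataFrame(
            0.0, index=sample_ids, columns=truth.metabolites
        ),
    )
    preds = predict_dataset(truth, clean, diet, trophic_params)
    metab = pd.DataFrame(
        [[preds[s].predicted_metabolome[m] for m in truth.metabolites]
         for s in sample_ids],
        index=sample_ids, columns=truth.metabolites,
    )
    if noise_sd > 0:
        noise = 10.0 ** rng.normal(0.0, noise_sd, size=metab.shape)
        metab = metab * noise
    return OmicsDataset(abundance=abundance, metabolome=metab)


def withhold_links(
    truth: CrossFeedingNetwork,
    fraction: float,
    rng: np.random.Generator | int | None = None,
    protect_connectivity: bool = True,
) -> SyntheticTruth:
    """Remove floor(fraction * |links|) links uniformly at random.

    With ``protect_connectivity`` (default), draws are rejected when they
    would leave a metabolite that previously had producers with none, or
    a species with no consumption link at all — such removals make parts
    of the truth unreachable rather than merely unknown.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must lie in [0, 1)")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    links = sorted(truth.links)
    n_out = int(np.floor(fraction * len(links)))
    if n_out == 0:
        return SyntheticTruth(
            truth_network=truth, degraded_network=truth.copy(), withheld=set(),
            generation_params={"fraction": fraction},
        )

    chosen: set[Link] = set()
    if protect_connectivity:
        # greedy feasible draw: walk a random permutation, keeping a link
        # out only if every metabolite retains a producer and every
        # consuming species retains a consumption link
        n_producers: dict[str, int] = {}
        n_consumption: dict[str, int] = {}
        for l in truth.links:
            if l.link_type == PRODUCTION:
                n_producers[l.metabolite_id] = n_producers.get(l.metabolite_id, 0) + 1
            else:
                n_consumption[l.species_id] = n_consumption.get(l.species_id, 0) + 1
        for i in rng.permutation(len(links)):
            if len(chosen) == n_out:
                break
            l = links[int(i)]
            if l.link_type == PRODUCTION:
                if n_producers[l.metabolite_id] <= 1:
                    continue
                n_producers[l.metabolite_id] -= 1
            else:
                if n_consumption[l.species_id] <= 1:
                    continue
                n_consumption[l.species_id] -= 1
            chosen.add(l)
        if len(chosen) < n_out:
            raise RuntimeError(
                "could not withhold links without disconnecting the network; "
                "try a lower fraction or protect_connectivity=False"
            )
    else:
        chosen = {links[i] for i in rng.choice(len(links), size=n_out, replace=False)}

    remaining = truth.links - chosen
    degraded = CrossFeedingNetwork(
        species=list(truth.species),
        metabolites=list(truth.metabolites),
        links=set(remaining),
        provenance={l: "original" for l in remaining},
    )
    return SyntheticTruth(
        truth_network=truth,
        degraded_network=degraded,
        withheld=chosen,
        generation_params={"fraction": fraction},
    )


def recovery_metrics(
    atlas: ConsensusAtlas,
    withheld: set[Link],
    candidate_space: list[Link],
) -> dict[str, float | None]:
    """Score a consensus atlas against the withheld answer key.

    precision = |atlas & withheld| / |atlas| (None when the atlas is
    empty); recall = |atlas & withheld| / |withheld|; ranking_auc = the
    probability that a random withheld link has strictly higher
    prevalence than a random non-withheld candidate (ties count 1/2).
    """
    if not set(withheld) <= set(candidate_space):
        raise ValueError("withheld links must lie in the candidate space")
    atlas_links = set(atlas.links)
    hits = atlas_links & withheld
    precision = len(hits) / len(atlas_links) if atlas_links else None
    recall = len(hits) / len(withheld) if withheld else 0.0

    pos = np.array([atlas.prevalence(l) for l in sorted(withheld)])
    neg = np.array(
        [atlas.prevalence(l) for l in candidate_space if l not in withheld]
    )
    if pos.size and neg.size:
        greater = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        auc = (greater + 0.5 * ties) / (pos.size * neg.size)
    else:
        auc = float("nan")
    return {"precision": precision, "recall": recall, "ranking_auc": float(auc)}


# ---------------------------------------------------------------------------
# Frozen benchmark preset
# ---------------------------------------------------------------------------

BENCHMARK1 = dict(
    S=10, M=20, n_levels=3, links_per_species=3,
    n_samples=30, species_prevalence=0.8, noise_sd=0.0,
    byproduct_fraction=0.5, withheld_fraction=0.15, R=20,
)


def make_benchmark(
    seed: int,
    noise_sd: float | None = None,
    preset: dict = BENCHMARK1,
) -> tuple[SyntheticTruth, OmicsDataset, Diet, TrophicParams]:
    """Build the standard recovery-benchmark instance for one seed."""
    p = dict(preset)
    if noise_sd is not None:
        p["noise_sd"] = noise_sd
    rng = np.random.default_rng(seed)
    truth = generate_truth_network(
        p["S"], p["M"], p["n_levels"], p["links_per_species"], rng
    )
    diet = diet_for_network(truth)
    params = TrophicParams(
        byproduct_fraction=p["byproduct_fraction"], n_levels=p["n_levels"] + 1
    )
    dataset = simulate_dataset(
        truth, p["n_samples"], p["species_prevalence"], p["noise_sd"],
        diet, params, rng,
    )
    synth = withhold_links(truth, p["withheld_fraction"], rng)
    synth.generation_params.update(p, seed=seed)
    return synth, dataset, diet, params


def benchmark_recovery(
    seed: int,
    noise_sd: float | None = None,
    max_iter: int = 8000,
    threshold: float = 1e-3,
) -> dict:
    """Run the full recovery benchmark for one instance seed.

    Generates the benchmark instance, runs the standard inference
    ensemble (R from the preset) on the degraded network, builds the
    consensus atlas and scores it against the withheld answer key.
    Returns the recovery metrics plus the random-expectation precision
    |withheld| / |candidate space|.
    """
    from .consensus import consensus_atlas, run_ensemble
    from .link_sampler import ObjectiveConfig
    from .network_core import enumerate_candidate_links

    synth, dataset, diet, params = make_benchmark(seed, noise_sd=noise_sd)
    ensemble = run_ensemble(
        synth.degraded_network, dataset, diet, params, ObjectiveConfig(),
        R=synth.generation_params["R"], base_seed=1000 * seed, max_iter=max_iter,
    )
    atlas = consensus_atlas(ensemble, threshold=threshold)
    candidates = enumerate_candidate_links(synth.degraded_network)
    metrics = recovery_metrics(atlas, synth.withheld, candidates)
    metrics.update(
        n_withheld=len(synth.withheld),
        n_atlas=len(atlas.links),
        random_precision=len(synth.withheld) / len(candidates),
        mean_links_per_run=ensemble.mean_links_per_run,
    )
    return metrics


def benchmark_cv_improvement(
    seed: int,
    R_per_fold: int = 5,
    max_iter: int = 4000,
) -> tuple[float, float]:
    """Fold-mean test log error after augmentation vs degraded baseline
    for one noiseless benchmark replicate; returns (augmented, baseline)."""
    from .evaluation import cross_validate
    from .link_sampler import ObjectiveConfig

    synth, dataset, diet, params = make_benchmark(seed)
    report = cross_validate(
        synth.degraded_network, dataset, diet, params, ObjectiveConfig(),
        k=4, R_per_fold=R_per_fold, rng=seed, max_iter=max_iter,
    )
    return (
        report.summary["test.log_error"][0],
        report.summary["baseline_test.log_error"][0],
    )
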