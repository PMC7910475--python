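"""Multi-level consumer-resource forward model.

The model propagates a nutrient intake (diet) through a fixed number of
trophic levels.  At each level, every metabolite with a positive available
amount is split among the species present in the sample that hold a
consumption link for it, in proportion to their measured relative
abundances.  Each consumer keeps a fraction (1 - f) of its intake as
growth and re-secretes the fraction f, divided equally among all
metabolites it holds production links for, into the next level's pool.
Metabolites nobody present can consume carry through to the next level.
Whatever remains unconsumed after the last level is the predicted (fecal)
metabolome; growth accumulated over all levels, normalized to 1, is the
predicted microbiome.

Mass is conserved by construction: sum(diet) = sum(growth) +
sum(predicted metabolome).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .network_core import CrossFeedingNetwork, Diet, OmicsDataset


@dataclass
class TrophicParams:
    """Forward-model parameters.

    byproduct_fraction
        Fraction f in (0, 1) of consumed flux re-secreted as byproducts;
        the remaining (1 - f) becomes growth.
    n_levels
        Number of trophic levels L (default 4, the depth observed for the
        human gut).
    detection_floor
        Predicted levels at or below this value are treated as absent
        when counting predicted metabolites.
    carry_through
        If True (default), a metabolite left unconsumed at one level
        remains available at later levels; if False each metabolite is
        offered exactly once and unconsumed amounts exit to the
        metabolome immediately.
    """

    byproduct_fraction: float = 0.9
    n_levels: int = 4
    detection_floor: float = 1e-6
    carry_through: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.byproduct_fraction < 1.0:
            raise ValueError("byproduct_fraction must lie in (0, 1)")
        if self.n_levels < 1:
            raise ValueError("n_levels must be >= 1")
        if self.detection_floor <= 0:
            raise ValueError("detection_floor must be positive")


@dataclass
class SamplePrediction:
    """Forward-model output for one sample."""

    predicted_metabolome: dict[str, float]
    predicted_microbiome: dict[str, float]
    growth: dict[str, float] = field(default_factory=dict)


def forward_flux(
    C: np.ndarray,
    P: np.ndarray,
    abundance: np.ndarray,
    diet_vec: np.ndarray,
    f: float,
    n_levels: int,
    carry_through: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized flux propagation for a batch of samples.

    Parameters
    ----------
    C, P
        Boolean (S, M) consumption / production adjacency matrices.
    abundance
        (N, S) relative abundances (zero = species absent in the sample).
    diet_vec
        (M,) nutrient intake shared by all samples.
    f
        Byproduct fraction.
    n_levels
        Number of trophic levels.
    carry_through
        Whether unconsumed metabolites stay available at later levels.

    Returns
    -------
    growth : (N, S) accumulated biomass flux per species.
    metabolome : (N, M) unconsumed amounts after the last level.
    """
    Cf = C.astype(float)
    # Secretion is split equally across a species' production links.
    out_deg = P.sum(axis=1)
    Pnorm = np.divide(
        P.astype(float), out_deg[:, None], out=np.zeros(P.shape, dtype=float),
        where=out_deg[:, None] > 0,
    )
    # A species with no production links cannot re-secrete; its consumed
    # flux would vanish.  Mass balance is preserved by routing the
    # byproduct share of such species to growth as well.
    no_outlet = out_deg == 0

    N = abundance.shape[0]
    avail = np.broadcast_to(diet_vec, (N, diet_vec.size)).copy()
    growth = np.zeros_like(abundance, dtype=float)
    exported = np.zeros_like(avail)

    for _ in range(n_levels):
        # (N, S, M) share weights: abundance of present consumers.
        weights = abundance[:, :, None] * Cf[None, :, :]
        totals = weights.sum(axis=1)  # (N, M)
        consumed_frac = np.divide(
            weights, totals[:, None, :], out=np.zeros_like(weights),
            where=totals[:, None, :] > 0,
        )
        intake = consumed_frac * avail[:, None, :]  # (N, S, M)
        per_species = intake.sum(axis=2)  # (N, S)
        growth += (1.0 - f) * per_species + f * per_species * no_outlet[None, :]
        secreted = (f * per_species * ~no_outlet[None, :]) @ Pnorm  # (N, M)
        unconsumed = avail * (totals == 0)
        if carry_through:
            avail = unconsumed + secreted
        else:
            exported += unconsumed
            avail = secreted
    metabolome = exported + avail
    return growth, metabolome


def predict_sample(
    network: CrossFeedingNetwork,
    sample_abundance: dict[str, float],
    diet: Diet,
    params: TrophicParams,
) -> SamplePrediction:
    """Predict one sample's metabolome and microbiome.

    ``sample_abundance`` maps species to nonnegative relative abundance;
    species absent from the mapping are treated as absent from the gut.
    """
    if any(v < 0 for v in sample_abundance.values()):
        raise ValueError("abundances must be nonnegative")
    C, P = network.adjacency()
    abund = np.array(
        [[sample_abundance.get(s, 0.0) for s in network.species]], dtype=float
    )
    diet_vec = diet.vector(network.metabolites)
    growth, metab = forward_flux(
        C, P, abund, diet_vec,
        params.byproduct_fraction, params.n_levels, params.carry_through,
    )
    return _to_prediction(network, growth[0], metab[0])


def _to_prediction(
    network: CrossFeedingNetwork, growth: np.ndarray, metab: np.ndarray
) -> SamplePrediction:
    total = growth.sum()
    micro = growth / total if total > 0 else np.zeros_like(growth)
    return SamplePrediction(
        predicted_metabolome={
            m: float(v) for m, v in zip(network.metabolites, metab)
        },
        predicted_microbiome={
            s: float(v) for s, v in zip(network.species, micro)
        },
        growth={s: float(v) for s, v in zip(network.species, growth)},
    )


def predict_dataset(
    network: CrossFeedingNetwork,
    dataset: OmicsDataset,
    diet: Diet,
    params: TrophicParams,
) -> dict[str, SamplePrediction]:
    """One independent, deterministic prediction per sample."""
    C, P = network.adjacency()
    abund = dataset.abundance.reindex(columns=network.species, fill_value=0.0)
    diet_vec = diet.vector(network.metabolites)
    growth, metab = forward_flux(
        C, P, abund.to_numpy(dtype=float), diet_vec,
        params.byproduct_fraction, params.n_levels, params.carry_through,
    )
    return {
        sid: _to_prediction(network, growth[k], metab[k])
        for k, sid in enumerate(dataset.sample_ids)
    }
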