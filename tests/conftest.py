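import numpy as np
import pandas as pd
import pytest

from gutcp import (
    CrossFeedingNetwork,
    Diet,
    Link,
    OmicsDataset,
    SamplePrediction,
    TrophicParams,
)


@pytest.fixture
def chain_network() -> CrossFeedingNetwork:
    """X eats A and secretes B; Y eats B and secretes C."""
    return CrossFeedingNetwork(
        species=["X", "Y"],
        metabolites=["A", "B", "C"],
        links={
            Link("X", "A", "consumption"),
            Link("X", "B", "production"),
            Link("Y", "B", "consumption"),
            Link("Y", "C", "production"),
        },
    )


@pytest.fixture
def chain_diet() -> Diet:
    return Diet(intake={"A": 1.0})


@pytest.fixture
def chain_params() -> TrophicParams:
    return TrophicParams(byproduct_fraction=0.5, n_levels=4)


def random_toy_instance(rng: np.random.Generator, max_S: int = 4, max_M: int = 6):
    """Random small network + abundances + diet for property tests."""
    S = int(rng.integers(1, max_S + 1))
    M = int(rng.integers(2, max_M + 1))
    species = [f"s{i}" for i in range(S)]
    metabolites = [f"m{j}" for j in range(M)]
    net = CrossFeedingNetwork(species=species, metabolites=metabolites)
    for sp in species:
        for mb in metabolites:
            for lt in ("consumption", "production"):
                if rng.random() < 0.3:
                    net.add_link(Link(sp, mb, lt), provenance="original")
    abund = {sp: float(rng.random()) if rng.random() < 0.8 else 0.0 for sp in species}
    diet = Diet(intake={metabolites[0]: 1.0,
                        metabolites[1]: float(rng.random()) + 0.1})
    f = float(rng.uniform(0.05, 0.95))
    L = int(rng.integers(1, 5))
    return net, abund, diet, TrophicParams(byproduct_fraction=f, n_levels=L)


def build_dataset(sample_ids, metabolome: dict, abundance: dict | None = None):
    """Assemble an OmicsDataset from plain dicts of per-sample values."""
    mb = pd.DataFrame(metabolome, index=sample_ids)
    if abundance is None:
        ab = pd.DataFrame({"sp_dummy": [1.0] * len(sample_ids)}, index=sample_ids)
    else:
        ab = pd.DataFrame(abundance, index=sample_ids)
        ab = ab.div(ab.sum(axis=1), axis=0)
    return OmicsDataset(abundance=ab, metabolome=mb)


def build_predictions(sample_ids, metabolome: dict, microbiome: dict | None = None):
    """Assemble a predictions mapping from plain dicts of per-sample values."""
    preds = {}
    for k, sid in enumerate(sample_ids):
        met = {m: float(vals[k]) for m, vals in metabolome.items()}
        mic = (
            {s: float(vals[k]) for s, vals in microbiome.items()}
            if microbiome else {"sp_dummy": 1.0}
        )
        preds[sid] = SamplePrediction(
            predicted_metabolome=met, predicted_microbiome=mic, growth=dict(mic)
        )
    return preds
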