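"""Domain types and file I/O for bipartite cross-feeding networks.

A cross-feeding network links microbial species to the metabolites they
consume (uptake) and produce (secretion).  The network is bipartite and
directed: a consumption link points from a metabolite to a species, a
production link from a species to a metabolite.  Both directions between
the same pair may coexist (a species can consume and produce the same
compound).

Paired omics datasets carry, per sample, species relative abundances and
measured metabolite levels; they are the observations the forward model
is compared against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("gutcp")

CONSUMPTION = "consumption"
PRODUCTION = "production"
LINK_TYPES = (CONSUMPTION, PRODUCTION)


class FormatError(ValueError):
    """Malformed input table (bad link type, negative level, ...)."""


@dataclass(frozen=True, order=True)
class Link:
    """One directed species-metabolite interaction."""

    species_id: str
    metabolite_id: str
    link_type: str

    def __post_init__(self) -> None:
        if self.link_type not in LINK_TYPES:
            raise FormatError(
                f"unknown link_type {self.link_type!r}; "
                f"expected one of {LINK_TYPES}"
            )


def _norm_name(name: str) -> str:
    return str(name).strip().casefold()


@dataclass
class CrossFeedingNetwork:
    """Bipartite directed link set between species and metabolites.

    ``provenance`` distinguishes links read from the curated input
    (``original``) from links added by the inference loop (``added``).
    """

    species: list[str]
    metabolites: list[str]
    links: set[Link] = field(default_factory=set)
    provenance: dict[Link, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sp = set(self.species)
        mb = set(self.metabolites)
        if sp & mb:
            raise ValueError(
                f"species and metabolite namespaces overlap: {sorted(sp & mb)[:5]}"
            )
        for link in self.links:
            if link.species_id not in sp:
                raise ValueError(f"link references unknown species {link.species_id!r}")
            if link.metabolite_id not in mb:
                raise ValueError(
                    f"link references unknown metabolite {link.metabolite_id!r}"
                )
        for link in self.links:
            self.provenance.setdefault(link, "original")

    @property
    def n_species(self) -> int:
        return len(self.species)

    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    def copy(self) -> "CrossFeedingNetwork":
        return CrossFeedingNetwork(
            species=list(self.species),
            metabolites=list(self.metabolites),
            links=set(self.links),
            provenance=dict(self.provenance),
        )

    def add_link(self, link: Link, provenance: str = "added") -> None:
        if link in self.links:
            raise ValueError(f"duplicate link {link}")
        if link.species_id not in set(self.species):
            raise ValueError(f"unknown species {link.species_id!r}")
        if link.metabolite_id not in set(self.metabolites):
            raise ValueError(f"unknown metabolite {link.metabolite_id!r}")
        self.links.add(link)
        self.provenance[link] = provenance

    def remove_link(self, link: Link) -> None:
        self.links.remove(link)
        self.provenance.pop(link, None)

    def adjacency(self) -> tuple[np.ndarray, np.ndarray]:
        """Boolean (S, M) consumption and production matrices.

        Row/column order follows ``self.species`` / ``self.metabolites``.
        """
        s_idx = {s: i for i, s in enumerate(self.species)}
        m_idx = {m: j for j, m in enumerate(self.metabolites)}
        C = np.zeros((len(self.species), len(self.metabolites)), dtype=bool)
        P = np.zeros_like(C)
        for link in self.links:
            target = C if link.link_type == CONSUMPTION else P
            target[s_idx[link.species_id], m_idx[link.metabolite_id]] = True
        return C, P


@dataclass
class Diet:
    """Nutrient intake: metabolite -> amount (arbitrary mass-flux units)."""

    intake: dict[str, float]

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.intake.values()):
            raise ValueError("diet amounts must be nonnegative")
        if not any(v > 0 for v in self.intake.values()):
            raise ValueError("diet must contain at least one positive intake")

    def vector(self, metabolites: Iterable[str]) -> np.ndarray:
        mets = list(metabolites)
        missing = set(self.intake) - set(mets)
        if missing:
            raise ValueError(
                f"diet metabolites absent from network: {sorted(missing)}"
            )
        return np.array([self.intake.get(m, 0.0) for m in mets], dtype=float)


@dataclass
class OmicsDataset:
    """Paired per-sample species abundances and measured metabolite levels.

    ``abundance``: DataFrame samples x species, each row renormalized to
    sum to 1.  ``metabolome``: DataFrame samples x metabolites, raw
    nonnegative relative levels.
    """

    abundance: pd.DataFrame
    metabolome: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.abundance.index.equals(self.metabolome.index):
            raise ValueError("abundance and metabolome sample indices differ")
        if len(self.abundance) < 1:
            raise ValueError("dataset must contain at least one sample")
        if (self.abundance.values < 0).any():
            raise ValueError("abundance table contains negative entries")
        if (self.metabolome.values < 0).any():
            raise ValueError("metabolome table contains negative entries")
        if (self.abundance.values > 1).any():
            raise ValueError("abundance entries must lie in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def n_samples(self) -> int:
        return len(self.abundance)

    def subset(self, sample_ids: Iterable[str]) -> "OmicsDataset":
        ids = list(sample_ids)
        return OmicsDataset(
            abundance=self.abundance.loc[ids].copy(),
            metabolome=self.metabolome.loc[ids].copy(),
        )


# ---------------------------------------------------------------------------
# File I/O (tab-separated, UTF-8, '#' comment lines ignored)
# ---------------------------------------------------------------------------

def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str)


def read_link_table(path) -> CrossFeedingNetwork:
    """Read a cross-feeding link table.

    Expected columns: ``species``, ``metabolite``, ``link_type`` (and an
    optional ``provenance`` column, defaulting to ``original``).
    Duplicate rows collapse to a single link with a logged warning.

    Comment lines ``# species:`` / ``# metabolites:`` (written by
    :func:`write_link_table`) register entities with no incident links,
    so the candidate space survives a round trip.
    """
    registry: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            for key in ("species:", "metabolites:"):
                if body.startswith(key):
                    registry[key[:-1]] = [
                        t.strip() for t in body[len(key):].split("\t") if t.strip()
                    ]
    df = _read_tsv(path)
    if df.empty and df.columns.size == 0:
        raise FormatError(f"{path}: empty link table")
    required = {"species", "metabolite", "link_type"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: missing columns {sorted(required - set(df.columns))}"
        )
    if df.empty:
        raise FormatError(f"{path}: link table has a header but no rows")

    links: set[Link] = set()
    provenance: dict[Link, str] = {}
    species: list[str] = []
    metabolites: list[str] = []
    seen_sp: set[str] = set()
    seen_mb: set[str] = set()
    n_dup = 0
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        lt = str(row.link_type).strip().lower()
        if lt not in LINK_TYPES:
            raise FormatError(
                f"{path}: row {row_no}: unknown link_type {row.link_type!r}"
            )
        sp = str(row.species).strip()
        mb = str(row.metabolite).strip()
        link = Link(sp, mb, lt)
        if link in links:
            n_dup += 1
            continue
        links.add(link)
        provenance[link] = getattr(row, "provenance", "original") or "original"
        if sp not in seen_sp:
            seen_sp.add(sp)
            species.append(sp)
        if mb not in seen_mb:
            seen_mb.add(mb)
            metabolites.append(mb)
    if n_dup:
        logger.warning("%s: collapsed %d duplicate link rows", path, n_dup)
    if "species" in registry:
        extra = [s for s in registry["species"] if s not in seen_sp]
        species = registry["species"] if set(registry["species"]) >= seen_sp \
            else species + extra
    if "metabolites" in registry:
        extra = [m for m in registry["metabolites"] if m not in seen_mb]
        metabolites = registry["metabolites"] if set(registry["metabolites"]) >= seen_mb \
            else metabolites + extra
    return CrossFeedingNetwork(
        species=species, metabolites=metabolites, links=links, provenance=provenance
    )


def write_link_table(network: CrossFeedingNetwork, path) -> None:
    """Write a network as a TSV link table with deterministic row order.

    The full species/metabolite registries go into leading comment lines
    so that entities without links survive a round trip.
    """
    rows = sorted(
        (l.species_id, l.metabolite_id, l.link_type,
         network.provenance.get(l, "original"))
        for l in network.links
    )
    df = pd.DataFrame(rows, columns=["species", "metabolite", "link_type", "provenance"])
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# species: " + "\t".join(network.species) + "\n")
        fh.write("# metabolites: " + "\t".join(network.metabolites) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def read_omics_dataset(abundance_path, metabolome_path) -> OmicsDataset:
    """Read paired abundance and metabolome tables sharing a sample column.

    Abundance rows are renormalized to sum to 1; samples present in only
    one table are dropped with a warning.
    """
    ab = pd.read_csv(abundance_path, sep="\t", comment="#", index_col=0)
    mb = pd.read_csv(metabolome_path, sep="\t", comment="#", index_col=0)
    ab.index = ab.index.astype(str)
    mb.index = mb.index.astype(str)
    if (ab.values < 0).any():
        raise ValueError(f"{abundance_path}: negative abundance entries")
    if (mb.values < 0).any():
        raise ValueError(f"{metabolome_path}: negative metabolome entries")

    shared = [s for s in ab.index if s in set(mb.index)]
    if not shared:
        raise ValueError("no shared samples between abundance and metabolome tables")
    dropped = (set(ab.index) | set(mb.index)) - set(shared)
    if dropped:
        logger.warning("dropping %d samples present in only one table", len(dropped))
    ab = ab.loc[shared]
    mb = mb.loc[shared]

    row_sums = ab.sum(axis=1)
    if (row_sums <= 0).any():
        raise ValueError("abundance table contains all-zero sample rows")
    if not np.allclose(row_sums, 1.0):
        logger.info("renormalizing abundance rows to sum to 1")
    ab = ab.div(row_sums, axis=0)
    return OmicsDataset(abundance=ab, metabolome=mb)


def write_omics_dataset(dataset: OmicsDataset, abundance_path, metabolome_path) -> None:
    dataset.abundance.to_csv(abundance_path, sep="\t", index_label="sample_id")
    dataset.metabolome.to_csv(metabolome_path, sep="\t", index_label="sample_id")


def align_dataset(
    network: CrossFeedingNetwork, dataset: OmicsDataset
) -> OmicsDataset:
    """Align dataset columns to network identifiers.

    Matching is exact after case-folding and whitespace trimming.
    Unmatched dataset columns are retained but flagged with a warning.
    """
    def _match(cols: Iterable[str], names: list[str]) -> dict[str, str]:
        lookup = {_norm_name(n): n for n in names}
        return {c: lookup[_norm_name(c)] for c in cols if _norm_name(c) in lookup}

    sp_map = _match(dataset.abundance.columns, network.species)
    mb_map = _match(dataset.metabolome.columns, network.metabolites)
    unmatched = (set(dataset.abundance.columns) - set(sp_map)) | (
        set(dataset.metabolome.columns) - set(mb_map)
    )
    if unmatched:
        logger.warning(
            "%d dataset columns have no network counterpart: %s",
            len(unmatched), sorted(unmatched)[:10],
        )
    ab = dataset.abundance.rename(columns=sp_map)
    mb = dataset.metabolome.rename(columns=mb_map)
    return OmicsDataset(abundance=ab, metabolome=mb)


def enumerate_candidate_links(network: CrossFeedingNetwork) -> list[Link]:
    """All (species, metabolite, type) triples NOT already in the network.

    This is the proposal space for link inference: for S species and M
    metabolites there are 2*S*M combinatorially possible links, minus the
    ones the network already holds.  Deterministic order (species, then
    metabolite, then consumption before production).
    """
    existing = network.links
    out: list[Link] = []
    for sp in network.species:
        for mb in network.metabolites:
            for lt in LINK_TYPES:
                link = Link(sp, mb, lt)
                if link not in existing:
                    out.append(link)
    return out
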