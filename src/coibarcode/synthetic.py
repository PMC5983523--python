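"""Synthetic COI-like barcode data with controlled divergence tiers.

The generator emulates the statistical structure a barcoding analysis
assumes: a four-rank taxonomy (order / family / genus / species), an
alignment of equal-length protein-coding sequences free of in-frame stop
codons, codon-position composition bias (including the third-position
anti-G bias typical of fish COI), and expected pairwise K2P divergences
that increase tier by tier.

Divergence tiers are imposed by a fixed-depth ultrametric rank tree,
star-like within each rank: two conspecific individuals coalesce at
height t_species/2, two congeneric species at t_genus/2, and so on, so
the expected number of substitutions per site between two leaves of a
tier equals the configured tier divergence exactly (path length = 2 x
height).  Sequences evolve by a continuous-time Kimura two-parameter
process: per branch of length t, each site receives Poisson(t)
substitution events, each a transition with probability kappa/(kappa+2)
and otherwise one of the two transversions.  Events that would create an
in-frame stop codon are resampled among the remaining target bases, so
the no-stop invariant holds by construction at negligible distortion of
the process.

This is deliberately not a coalescent: there is no shared polymorphism,
no rate heterogeneity across sites, and no indel process, which keeps
every tier mean analytically checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .barcode_io import (
    BarcodeDataset,
    BarcodeError,
    BarcodeRecord,
    TaxonomyEntry,
    MITO_STOP_CODONS,
)
from .njtree import PhyloTree, TreeNode

BASES = "ACGT"
_STOP_CODES = {tuple(BASES.index(c) for c in codon) for codon in MITO_STOP_CODONS}


@dataclass(frozen=True)
class TierDivergences:
    """Expected pairwise divergence per tier, substitutions/site.

    Defaults follow the tier structure of published fish COI barcoding
    surveys: conspecific 0.0021, congeneric 0.065, confamilial 0.237,
    conordinal 0.256, with cross-order pairs slightly deeper still.
    """

    species: float = 0.0021
    genus: float = 0.065
    family: float = 0.237
    order: float = 0.256
    cross_order: float = 0.28

    def as_tuple(self) -> tuple[float, ...]:
        return (self.species, self.genus, self.family, self.order,
                self.cross_order)


#: Per-codon-position base probabilities (A, C, G, T), reproducing the
#: composition bias of fish COI: GC-rich first positions, T-rich second
#: positions, and a strong anti-G bias at third positions.
DEFAULT_COMPOSITION = {
    1: (0.2554, 0.2554, 0.3102, 0.1790),
    2: (0.1499, 0.2837, 0.1469, 0.4196),
    3: (0.3226, 0.3116, 0.0952, 0.2705),
}


@dataclass
class SimulationConfig:
    n_orders: int = 4
    families_per_order: int = 2
    genera_per_family: int = 2
    species_per_genus: int = 5
    individuals_per_species: int = 3
    length: int = 655
    codon_offset: int = 0
    kappa: float = 4.0
    tiers: TierDivergences = field(default_factory=TierDivergences)
    composition: dict[int, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    seed: int | None = None

    def __post_init__(self) -> None:
        counts = (self.n_orders, self.families_per_order,
                  self.genera_per_family, self.species_per_genus,
                  self.individuals_per_species)
        if any(c < 1 for c in counts):
            raise BarcodeError("all taxon counts must be >= 1")
        tiers = self.tiers.as_tuple()
        if any(b <= a for a, b in zip(tiers, tiers[1:])):
            raise BarcodeError("tier divergences must be strictly increasing")
        for pos, probs in self.composition.items():
            p = np.asarray(probs, dtype=float)
            if pos not in (1, 2, 3) or len(p) != 4 or np.any(p < 0) or \
                    not np.isclose(p.sum(), 1.0, atol=1e-3):
                raise BarcodeError(
                    f"composition profile for position {pos} must be 4 "
                    "probabilities summing to 1")

    @property
    def n_species(self) -> int:
        return (self.n_orders * self.families_per_order *
                self.genera_per_family * self.species_per_genus)

    @property
    def n_sequences(self) -> int:
        return self.n_species * self.individuals_per_species


@dataclass
class SimulatedDataset:
    """A generated dataset plus its generating tree and true parameters."""

    dataset: BarcodeDataset
    tree: PhyloTree
    config: SimulationConfig
    taxonomy: dict[str, TaxonomyEntry]


# ---------------------------------------------------------------------------
# taxonomy
# ---------------------------------------------------------------------------

def simulate_taxonomy(config: SimulationConfig) -> dict[str, TaxonomyEntry]:
    """Systematic four-rank taxonomy for every individual.

    IDs are ``O1.F2.G3.S4_i1`` style; taxon names carry their full path so
    ranks are globally unique and internally consistent by construction.
    The layout is fully deterministic (seed-independent).
    """
    taxonomy: dict[str, TaxonomyEntry] = {}
    for o in range(1, config.n_orders + 1):
        order = f"O{o}"
        for f in range(1, config.families_per_order + 1):
            family = f"{order}.F{f}"
            for g in range(1, config.genera_per_family + 1):
                genus = f"{family}.G{g}"
                for s in range(1, config.species_per_genus + 1):
                    species = f"{genus}.S{s}"
                    for i in range(1, config.individuals_per_species + 1):
                        taxonomy[f"{species}_i{i}"] = TaxonomyEntry(
                            species=species, genus=genus, family=family,
                            order=order, source="synthetic",
                        )
    return taxonomy


def _rank_tree(config: SimulationConfig,
               taxonomy: dict[str, TaxonomyEntry]) -> TreeNode:
    """Ultrametric rank tree: node heights are half the tier divergences."""
    t = config.tiers
    h_sp, h_gen = t.species / 2, t.genus / 2
    h_fam, h_ord, h_root = t.family / 2, t.order / 2, t.cross_order / 2

    by_species: dict[str, list[str]] = {}
    nesting: dict[str, dict[str, dict[str, list[str]]]] = {}
    for rid, tx in taxonomy.items():
        by_species.setdefault(tx.species, []).append(rid)
        nesting.setdefault(tx.order, {}).setdefault(
            tx.family, {}).setdefault(tx.genus, [])
        if tx.species not in nesting[tx.order][tx.family][tx.genus]:
            nesting[tx.order][tx.family][tx.genus].append(tx.species)

    root = TreeNode()
    for order, families in nesting.items():
        o_node = TreeNode(length=h_root - h_ord)
        root.children.append(o_node)
        for family, genera in families.items():
            f_node = TreeNode(length=h_ord - h_fam)
            o_node.children.append(f_node)
            for genus, species_list in genera.items():
                g_node = TreeNode(length=h_fam - h_gen)
                f_node.children.append(g_node)
                for species in species_list:
                    s_node = TreeNode(length=h_gen - h_sp)
                    g_node.children.append(s_node)
                    for rid in by_species[species]:
                        s_node.children.append(
                            TreeNode(name=rid, length=h_sp))
    return root


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------

def _codon_start(site: int, offset: int, length: int) -> int | None:
    """Start column of the complete codon containing ``site``; None if the
    site falls in a leading/trailing partial codon."""
    if site < offset:
        return None
    start = site - (site - offset) % 3
    return start if start + 3 <= length else None


def _draw_root(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Root sequence from the per-position composition profile, rejecting
    stop codons codon-by-codon."""
    L, off = config.length, config.codon_offset
    probs = {k: np.asarray(v) / np.sum(v) for k, v in config.composition.items()}
    seq = np.empty(L, dtype=np.int64)
    # leading partial codon: positions cycle ... so column c has position
    # ((c - off) % 3) + 1
    for c in range(min(off, L)):
        pos = (c - off) % 3 + 1
        seq[c] = rng.choice(4, p=probs[pos])
    start = off
    while start + 3 <= L:
        for _ in range(1000):
            codon = tuple(int(rng.choice(4, p=probs[k])) for k in (1, 2, 3))
            if codon not in _STOP_CODES:
                break
        else:
            raise BarcodeError(
                "composition profile cannot produce a stop-free codon")
        seq[start:start + 3] = codon
        start += 3
    for c in range(start, L):
        pos = (c - off) % 3 + 1
        seq[c] = rng.choice(4, p=probs[pos])
    return seq


def _mutate(seq: np.ndarray, t: float, config: SimulationConfig,
            rng: np.random.Generator) -> np.ndarray:
    """Evolve a sequence for branch length t under the K2P process.

    Each site receives Poisson(t) events; an event is a transition with
    probability kappa/(kappa+2), else one of the two transversions.  A
    mutation creating an in-frame stop codon is resampled among the
    remaining targets (site left unchanged if all three would create
    stops).
    """
    out = seq.copy()
    L, off, kappa = config.length, config.codon_offset, config.kappa
    n_events = rng.poisson(t, size=L)
    p_ts = kappa / (kappa + 2.0)
    for site in np.flatnonzero(n_events):
        start = _codon_start(site, off, L)
        for _ in range(n_events[site]):
            b = int(out[site])
            transition = b ^ 2
            transversions = [b ^ 1, b ^ 3]
            targets = [transition] + transversions
            weights = [p_ts, (1 - p_ts) / 2, (1 - p_ts) / 2]
            while targets:
                k = rng.choice(len(targets), p=np.asarray(weights) / sum(weights))
                cand = targets.pop(k)
                weights.pop(k)
                if start is None:
                    out[site] = cand
                    break
                codon = out[start:start + 3].copy()
                codon[site - start] = cand
                if tuple(codon) not in _STOP_CODES:
                    out[site] = cand
                    break
    return out


def _decode(seq: np.ndarray) -> str:
    return "".join(BASES[b] for b in seq)


def simulate_sequences(taxonomy: dict[str, TaxonomyEntry],
                       config: SimulationConfig) -> SimulatedDataset:
    """Evolve sequences down the ultrametric rank tree.

    Returns the assembled :class:`BarcodeDataset` together with the
    generating tree and configuration, for parameter-recovery tests.
    With all tier divergences zero-length branches the output sequences
    are identical to the root.
    """
    rng = np.random.default_rng(config.seed)
    root_node = _rank_tree(config, taxonomy)
    root_seq = _draw_root(config, rng)

    records: list[BarcodeRecord] = []

    def descend(node: TreeNode, seq: np.ndarray) -> None:
        for child in node.children:
            child_seq = _mutate(seq, child.length, config, rng) \
                if child.length > 0 else seq.copy()
            if child.is_leaf:
                tx = taxonomy[child.name]
                records.append(BarcodeRecord(
                    id=child.name, sequence=_decode(child_seq),
                    species=tx.species, genus=tx.genus, family=tx.family,
                    order=tx.order, source="synthetic",
                ))
            else:
                descend(child, child_seq)

    descend(root_node, root_seq)
    records.sort(key=lambda r: r.id)
    dataset = BarcodeDataset(records, config.length, config.codon_offset)
    return SimulatedDataset(dataset, PhyloTree(root_node), config, taxonomy)


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Convenience: taxonomy + sequences in one call."""
    return simulate_sequences(simulate_taxonomy(config), config)


# ---------------------------------------------------------------------------
# planted errors
# ---------------------------------------------------------------------------

def as_inputs(dataset: BarcodeDataset
              ) -> tuple[list[tuple[str, str]], dict[str, TaxonomyEntry]]:
    """Decompose a dataset into reader-level inputs (for re-assembly)."""
    seqs = [(r.id, r.sequence) for r in dataset.records]
    taxonomy = {r.id: TaxonomyEntry(r.species, r.genus, r.family, r.order,
                                    r.accession, r.source)
                for r in dataset.records}
    return seqs, taxonomy


def inject_errors(dataset: BarcodeDataset, n_mislabels: int, n_numts: int,
                  seed: int | None) -> tuple[BarcodeDataset, pd.DataFrame]:
    """Plant species mislabels and NUMT-like stop codons.

    A mislabel reassigns one record's full taxonomy to a uniformly chosen
    other species; a NUMT overwrites one random in-frame codon with TAA.
    The returned truth table lists every planted error (columns: id,
    error_type, original_species, assigned_species, codon_start).
    """
    if n_mislabels + n_numts > len(dataset):
        raise BarcodeError("more planted errors than records")
    rng = np.random.default_rng(seed)
    records = list(dataset.records)
    victims = rng.choice(len(records), size=n_mislabels + n_numts,
                         replace=False)
    species_ranks = {r.species: (r.species, r.genus, r.family, r.order)
                     for r in records}
    truth = []

    for idx in victims[:n_mislabels]:
        rec = records[idx]
        others = sorted(set(species_ranks) - {rec.species})
        if not others:
            raise BarcodeError("mislabel injection needs >= 2 species")
        target = others[int(rng.integers(len(others)))]
        sp, genus, family, order = species_ranks[target]
        records[idx] = BarcodeRecord(
            id=rec.id, sequence=rec.sequence, species=sp, genus=genus,
            family=family, order=order, accession=rec.accession,
            source=rec.source,
        )
        truth.append({"id": rec.id, "error_type": "mislabel",
                      "original_species": rec.species,
                      "assigned_species": target, "codon_start": None})

    off, L = dataset.codon_offset, dataset.alignment_length
    starts = list(range(off, L - 2, 3))
    for idx in victims[n_mislabels:]:
        rec = records[idx]
        start = starts[int(rng.integers(len(starts)))]
        seq = rec.sequence[:start] + "TAA" + rec.sequence[start + 3:]
        records[idx] = BarcodeRecord(
            id=rec.id, sequence=seq, species=rec.species, genus=rec.genus,
            family=rec.family, order=rec.order, accession=rec.accession,
            source=rec.source,
        )
        truth.append({"id": rec.id, "error_type": "numt",
                      "original_species": rec.species,
                      "assigned_species": rec.species, "codon_start": start})

    out = BarcodeDataset(records, dataset.alignment_length,
                         dataset.codon_offset)
    return out, pd.DataFrame(
        truth, columns=["id", "error_type", "original_species",
                        "assigned_species", "codon_start"])
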