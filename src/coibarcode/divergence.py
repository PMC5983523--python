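"""Kimura two-parameter (K2P) distances and rank-stratified divergence.

The K2P model corrects observed differences for multiple hits while
distinguishing transitions from transversions.  With P and Q the
proportions of transitional and transversional differences over the
comparable sites of a pair,

    d = -1/2 * ln[(1 - 2P - Q) * sqrt(1 - 2Q)]

in substitutions per site.  The distance is undefined (saturated) when
either logarithm argument is non-positive; saturated pairs are recorded,
excluded from summaries, and make tree building fail loudly rather than
being silently capped.

Sites with a gap or ambiguity code in either sequence of a pair are
excluded for that pair only (pairwise deletion).  Distances are stored as
proportions; percentages appear only in report objects and writers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from ._seqcodes import MISSING, encode_alignment, encode_sequence
from .barcode_io import BarcodeDataset, BarcodeError

logger = logging.getLogger(__name__)

RANK_LEVELS = ("within_species", "within_genus", "within_family", "within_order")


class NoComparableSitesError(BarcodeError):
    """No site is unambiguous in both sequences — distinct from saturation."""


@dataclass(frozen=True)
class PairwiseComparison:
    id_a: str
    id_b: str
    n_comparable: int
    P: float
    Q: float
    d: float | None
    defined: bool


@dataclass
class DistanceMatrix:
    """Symmetric K2P matrix with per-pair comparable-site counts.

    ``d`` holds NaN where a pair is saturated (``defined`` False).
    """

    ids: list[str]
    d: np.ndarray          # (n, n) float, NaN where undefined
    n_comparable: np.ndarray  # (n, n) int
    defined: np.ndarray    # (n, n) bool

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise BarcodeError("distance matrix shape does not match ID list")

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int(np.count_nonzero(~self.defined[iu]))

    def undefined_pairs(self) -> list[tuple[str, str]]:
        iu = np.triu_indices(len(self.ids), k=1)
        bad = ~self.defined[iu]
        return [(self.ids[i], self.ids[j])
                for i, j in zip(iu[0][bad], iu[1][bad])]

    def index_of(self, rid: str) -> int:
        return self.ids.index(rid)


@dataclass(frozen=True)
class RankDivergenceSummary:
    """One taxonomic tier of pairwise divergence, in percent.

    ``n_taxa`` counts the distinct taxa at the stratum's grouping level
    that contribute at least one pair (e.g. genera with two or more
    species for the within-genus tier); ``se`` is the sample standard
    deviation of pair distances divided by sqrt(n_pairs).
    """

    level: str
    n_taxa: int
    n_pairs: int
    mean: float
    min: float
    max: float
    se: float


@dataclass(frozen=True)
class SpeciesGapRecord:
    """Barcoding gap of one species: distance (in %) from its deepest
    conspecific divergence to its nearest heterospecific neighbour."""

    species: str
    n_individuals: int
    max_intraspecific: float | None      # None for singletons
    nearest_neighbor: str | None
    min_to_nearest_heterospecific: float | None
    gap: float | None                    # min_NN - max_intra; negative = overlap


# ---------------------------------------------------------------------------
# pairwise distance
# ---------------------------------------------------------------------------

def _k2p_from_counts(transitions: int, transversions: int,
                     n_comparable: int) -> tuple[float, float, float | None, bool]:
    P = transitions / n_comparable
    Q = transversions / n_comparable
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        return P, Q, None, False
    return P, Q, -0.5 * math.log(w1 * math.sqrt(w2)), True


def k2p_distance(seq_a: str, seq_b: str,
                 id_a: str = "a", id_b: str = "b") -> PairwiseComparison:
    """K2P distance between two aligned sequences with pairwise deletion."""
    if len(seq_a) != len(seq_b):
        raise BarcodeError(
            f"sequences {id_a!r}/{id_b!r} differ in length "
            f"({len(seq_a)} vs {len(seq_b)})"
        )
    a = encode_sequence(seq_a.upper())
    b = encode_sequence(seq_b.upper())
    ok = (a != MISSING) & (b != MISSING)
    n_comp = int(np.count_nonzero(ok))
    if n_comp == 0:
        raise NoComparableSitesError(
            f"no comparable sites between {id_a!r} and {id_b!r}"
        )
    diff = ok & (a != b)
    ts = int(np.count_nonzero(diff & ((a & 1) == (b & 1))))
    tv = int(np.count_nonzero(diff)) - ts
    P, Q, d, defined = _k2p_from_counts(ts, tv, n_comp)
    return PairwiseComparison(id_a, id_b, n_comp, P, Q, d, defined)


def p_distance(seq_a: str, seq_b: str) -> float:
    """Uncorrected proportion of differing comparable sites (internal use:
    sanity bounds for the K2P correction)."""
    a = encode_sequence(seq_a.upper())
    b = encode_sequence(seq_b.upper())
    ok = (a != MISSING) & (b != MISSING)
    n_comp = int(np.count_nonzero(ok))
    if n_comp == 0:
        raise NoComparableSitesError("no comparable sites")
    return int(np.count_nonzero(ok & (a != b))) / n_comp


def k2p_matrix_from_codes(codes: np.ndarray
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All-pairs K2P kernel on an encoded alignment.

    Returns (d, n_comparable, defined); pairs with zero comparable sites
    or a saturated correction are NaN with ``defined`` False.  This is the
    shared engine behind :func:`distance_matrix` and the bootstrap.
    """
    n = codes.shape[0]
    valid = codes != MISSING
    parity = codes & 1

    d = np.zeros((n, n))
    ncomp = np.zeros((n, n), dtype=int)
    defined = np.ones((n, n), dtype=bool)
    for i in range(n):
        ncomp[i, i] = int(valid[i].sum())
    for i in range(n - 1):
        rest = slice(i + 1, n)
        ok = valid[i] & valid[rest]
        diff = ok & (codes[i] != codes[rest])
        ts = (diff & (parity[i] == parity[rest])).sum(axis=1)
        tv = diff.sum(axis=1) - ts
        nc = ok.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            P = np.where(nc > 0, ts / np.maximum(nc, 1), np.nan)
            Q = np.where(nc > 0, tv / np.maximum(nc, 1), np.nan)
            w1 = 1.0 - 2.0 * P - Q
            w2 = 1.0 - 2.0 * Q
            ok_pair = (nc > 0) & (w1 > 0) & (w2 > 0)
            dv = np.where(ok_pair, -0.5 * np.log(
                np.where(ok_pair, w1, 1.0) * np.sqrt(np.where(ok_pair, w2, 1.0))
            ), np.nan) + 0.0  # normalise -0.0 from log(1)
        d[i, rest] = d[rest, i] = dv
        ncomp[i, rest] = ncomp[rest, i] = nc
        defined[i, rest] = defined[rest, i] = ok_pair
    return d, ncomp, defined


def distance_matrix(dataset: BarcodeDataset) -> DistanceMatrix:
    """All-pairs K2P distances for an assembled dataset.

    Saturated pairs are stored as NaN with ``defined`` False and reported
    via the matrix object rather than raising; a pair with no comparable
    sites at all is an error.
    """
    n = len(dataset)
    if n < 2:
        raise BarcodeError("distance matrix needs at least 2 sequences")
    codes = encode_alignment(r.sequence for r in dataset.records)
    d, ncomp, defined = k2p_matrix_from_codes(codes)
    empty = (ncomp == 0) & ~np.eye(n, dtype=bool)
    if empty.any():
        i, j = np.argwhere(empty)[0]
        raise NoComparableSitesError(
            f"no comparable sites between {dataset.ids[i]!r} "
            f"and {dataset.ids[j]!r}"
        )
    mat = DistanceMatrix(list(dataset.ids), d, ncomp, defined)
    if mat.n_undefined_pairs:
        logger.warning("%d saturated (undefined) pair(s) excluded from summaries",
                       mat.n_undefined_pairs)
    return mat


# ---------------------------------------------------------------------------
# rank-stratified summaries
# ---------------------------------------------------------------------------

def _stratum_of(ta: tuple[str, str, str, str],
                tb: tuple[str, str, str, str]) -> str | None:
    """Tier of a pair: conspecific, congeneric (different species),
    confamilial (different genera), conordinal (different families), or
    None for cross-order pairs."""
    if ta[0] == tb[0]:
        return "within_species"
    if ta[1] == tb[1]:
        return "within_genus"
    if ta[2] == tb[2]:
        return "within_family"
    if ta[3] == tb[3]:
        return "within_order"
    return None


_GROUP_INDEX = {"within_species": 0, "within_genus": 1,
                "within_family": 2, "within_order": 3}


def summarize_by_rank(matrix: DistanceMatrix,
                      taxonomy: dict[str, tuple[str, str, str, str]],
                      ) -> list[RankDivergenceSummary]:
    """Divergence summaries per taxonomic tier (percent K2P).

    Pair strata: conspecific; congeneric heterospecific; confamilial
    across genera; conordinal across families.  Saturated pairs are
    excluded.  Empty strata are omitted with a warning.
    """
    ids = matrix.ids
    missing = [i for i in ids if i not in taxonomy]
    if missing:
        raise BarcodeError(f"taxonomy missing for IDs {missing[:5]}")
    ranks = [taxonomy[i] for i in ids]
    values: dict[str, list[float]] = {lv: [] for lv in RANK_LEVELS}
    groups: dict[str, set[str]] = {lv: set() for lv in RANK_LEVELS}
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if not matrix.defined[i, j]:
                continue
            level = _stratum_of(ranks[i], ranks[j])
            if level is None:
                continue
            values[level].append(matrix.d[i, j])
            groups[level].add(ranks[i][_GROUP_INDEX[level]])
    out = []
    for level in RANK_LEVELS:
        vals = np.array(values[level])
        if vals.size == 0:
            logger.warning("no pairs in stratum %s; omitted", level)
            continue
        se = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size > 1 else 0.0
        out.append(RankDivergenceSummary(
            level=level,
            n_taxa=len(groups[level]),
            n_pairs=int(vals.size),
            mean=float(vals.mean()) * 100.0,
            min=float(vals.min()) * 100.0,
            max=float(vals.max()) * 100.0,
            se=se * 100.0,
        ))
    return out


def interspecific_fold_ratio(
        summaries: list[RankDivergenceSummary]) -> float | None:
    """Mean congeneric-interspecific divergence over mean conspecific
    divergence; None (undefined) when the conspecific mean is zero."""
    by_level = {s.level: s for s in summaries}
    try:
        intra = by_level["within_species"]
        inter = by_level["within_genus"]
    except KeyError as exc:
        raise BarcodeError(f"missing stratum for fold ratio: {exc}") from exc
    if intra.mean == 0:
        return None
    return inter.mean / intra.mean


def barcoding_gap(matrix: DistanceMatrix,
                  taxonomy: dict[str, tuple[str, str, str, str]],
                  congeners_only: bool = False) -> list[SpeciesGapRecord]:
    """Per-species barcoding gap: minimum heterospecific (nearest-
    neighbour) distance minus maximum conspecific distance, in percent.

    Singletons get a nearest-neighbour distance but no gap.  With
    ``congeners_only`` the neighbour search is restricted to congeneric
    species (the minimum-congeneric convention)."""
    ids = matrix.ids
    ranks = {i: taxonomy[i] for i in ids}
    species_ids: dict[str, list[int]] = {}
    for idx, rid in enumerate(ids):
        species_ids.setdefault(ranks[rid][0], []).append(idx)

    records = []
    for sp in sorted(species_ids):
        members = species_ids[sp]
        genus = ranks[ids[members[0]]][1]
        max_intra = None
        if len(members) >= 2:
            vals = [matrix.d[i, j] for a, i in enumerate(members)
                    for j in members[a + 1:] if matrix.defined[i, j]]
            if vals:
                max_intra = max(vals) * 100.0
        nn_species, nn_dist = None, None
        for other_sp, other_members in species_ids.items():
            if other_sp == sp:
                continue
            if congeners_only and ranks[ids[other_members[0]]][1] != genus:
                continue
            for i in members:
                for j in other_members:
                    if not matrix.defined[i, j]:
                        continue
                    dij = matrix.d[i, j] * 100.0
                    if nn_dist is None or dij < nn_dist:
                        nn_dist, nn_species = dij, other_sp
        gap = None
        if max_intra is not None and nn_dist is not None:
            gap = nn_dist - max_intra
        records.append(SpeciesGapRecord(
            species=sp,
            n_individuals=len(members),
            max_intraspecific=max_intra,
            nearest_neighbor=nn_species,
            min_to_nearest_heterospecific=nn_dist,
            gap=gap,
        ))
    return records
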