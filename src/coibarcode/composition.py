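"""Base composition, site classification and nucleotide pair frequencies.

These are the descriptive statistics of a barcode alignment: per-order and
overall base frequencies split by codon position (COI shows a strong
anti-G bias at third positions), conserved / variable / parsimony-
informative site counts, and the mean numbers of identical, transitional
and transversional site pairs (ii, si, sv) over all sequence pairs with
their ratio R = si/sv.

Composition averages weight each sequence equally (mean of per-sequence
percentages), so records with more missing data are not down-weighted.
Ambiguity codes and gaps are never counted, fractionally or otherwise.
All statistics are kept at full precision; rounding happens only in the
table writers.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seqcodes import MISSING, encode_alignment, pair_site_counts
from .barcode_io import BarcodeDataset, BarcodeError

BASES = ("T", "C", "A", "G")
_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class CompositionTable:
    """Per-group base frequencies (%); rows are orders plus an overall row.

    Columns: T, C, A, G, AT, GC (whole sequence) and GC1, GC2, GC3 per
    codon position, all as percentages; ``n_sequences`` per group.
    """

    table: pd.DataFrame  # index: group name; "Avg." = overall row

    def to_tsv(self, path: str | Path, decimals: int = 2) -> None:
        """Write the GC-content layout: rows = orders + Avg., columns
        Total / 1st / 2nd / 3rd."""
        out = self.table[["GC", "GC1", "GC2", "GC3"]].round(decimals)
        out.columns = ["Total", "1st", "2nd", "3rd"]
        out.to_csv(path, sep="\t", index_label="Order")


@dataclass(frozen=True)
class SiteClassCounts:
    n_sites: int
    n_conserved: int
    n_variable: int
    n_parsimony_informative: int
    n_singleton: int

    def __post_init__(self) -> None:
        assert self.n_conserved + self.n_variable == self.n_sites
        assert self.n_parsimony_informative + self.n_singleton <= self.n_variable


@dataclass(frozen=True)
class PairFrequencyStats:
    """Mean identical / transition / transversion site pairs over all
    unordered sequence pairs, overall and per codon position (index 0 = all
    sites, 1..3 = codon positions)."""

    mean_identical: float
    mean_transitions: float
    mean_transversions: float
    by_position: pd.DataFrame  # rows 1..3, columns ii, si, sv
    n_pairs: int

    @property
    def ratio(self) -> float | None:
        """R = si/sv; None when no transversions were observed."""
        if self.mean_transversions == 0:
            return None
        return self.mean_transitions / self.mean_transversions

    def rounded(self) -> dict:
        """Reporting form: ii/si/sv to nearest integer, R to 2 decimals."""
        return {
            "ii": round(self.mean_identical),
            "si": round(self.mean_transitions),
            "sv": round(self.mean_transversions),
            "R": None if self.ratio is None else round(self.ratio, 2),
        }


def _percent_composition(codes: np.ndarray) -> np.ndarray | None:
    """Per-sequence percentages of T, C, A, G over unambiguous sites;
    rows with no unambiguous site return None and are dropped by callers."""
    valid = codes != MISSING
    totals = valid.sum(axis=1).astype(float)
    if np.any(totals == 0):
        raise BarcodeError("sequence with no unambiguous sites")
    freqs = np.empty((codes.shape[0], 4))
    for j, base in enumerate(BASES):
        freqs[:, j] = (codes == _BASE_CODE[base]).sum(axis=1) / totals * 100.0
    return freqs


def _gc_percent(codes: np.ndarray) -> np.ndarray:
    valid = codes != MISSING
    totals = valid.sum(axis=1).astype(float)
    totals[totals == 0] = np.nan
    gc = ((codes == _BASE_CODE["G"]) | (codes == _BASE_CODE["C"])).sum(axis=1)
    return gc / totals * 100.0


def base_composition(dataset: BarcodeDataset,
                     group_by_order: bool = True) -> CompositionTable:
    """Mean base frequencies and GC content by codon position.

    Each sequence contributes its own percentage composition with equal
    weight; the "Avg." row averages over all sequences regardless of
    order.  GC1/GC2/GC3 use the dataset's codon offset.
    """
    if not dataset.records:
        raise BarcodeError("empty dataset")
    codes = encode_alignment(r.sequence for r in dataset.records)
    L = dataset.alignment_length
    positions = (np.arange(L) - dataset.codon_offset) % 3 + 1

    per_seq = pd.DataFrame(_percent_composition(codes), columns=list(BASES))
    per_seq["GC"] = _gc_percent(codes)
    per_seq["AT"] = 100.0 - per_seq["GC"]
    for k in (1, 2, 3):
        per_seq[f"GC{k}"] = _gc_percent(codes[:, positions == k])
    per_seq["order"] = [r.order for r in dataset.records]

    groups = []
    if group_by_order:
        for order, sub in per_seq.groupby("order", sort=True):
            row = sub.drop(columns="order").mean()
            row["n_sequences"] = len(sub)
            row.name = order
            groups.append(row)
    overall = per_seq.drop(columns="order").mean()
    overall["n_sequences"] = len(per_seq)
    overall.name = "Avg."
    groups.append(overall)
    table = pd.DataFrame(groups)
    table["n_sequences"] = table["n_sequences"].astype(int)
    return CompositionTable(table)


def classify_sites(dataset: BarcodeDataset) -> SiteClassCounts:
    """Count conserved / variable / parsimony-informative / singleton sites.

    Per column, using unambiguous characters only: conserved = at most one
    distinct state; variable = two or more; parsimony-informative = at
    least two states each present in at least two sequences; singleton =
    variable but not informative.
    """
    if len(dataset) < 2:
        raise BarcodeError("site classification needs at least 2 sequences")
    codes = encode_alignment(r.sequence for r in dataset.records)
    n_var = n_pi = 0
    for c in range(codes.shape[1]):
        col = codes[:, c]
        counts = np.bincount(col[col != MISSING], minlength=4)
        states = np.count_nonzero(counts)
        if states >= 2:
            n_var += 1
            if np.count_nonzero(counts >= 2) >= 2:
                n_pi += 1
    L = dataset.alignment_length
    return SiteClassCounts(
        n_sites=L,
        n_conserved=L - n_var,
        n_variable=n_var,
        n_parsimony_informative=n_pi,
        n_singleton=n_var - n_pi,
    )


def pair_frequencies(dataset: BarcodeDataset) -> PairFrequencyStats:
    """Mean ii / si / sv over all unordered sequence pairs, split by codon
    position, counting only sites where both sequences are unambiguous."""
    n = len(dataset)
    if n < 2:
        raise BarcodeError("pair frequencies need at least 2 sequences")
    codes = encode_alignment(r.sequence for r in dataset.records)
    L = dataset.alignment_length
    positions = (np.arange(L) - dataset.codon_offset) % 3 + 1

    sums = np.zeros((4, 3))  # rows: all,pos1..3; cols: ii,si,sv
    n_pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            n_pairs += 1
            sums[0] += pair_site_counts(codes[i], codes[j])
            for k in (1, 2, 3):
                mask = positions == k
                sums[k] += pair_site_counts(codes[i][mask], codes[j][mask])
    means = sums / n_pairs
    by_pos = pd.DataFrame(means[1:], index=[1, 2, 3], columns=["ii", "si", "sv"])
    return PairFrequencyStats(
        mean_identical=float(means[0, 0]),
        mean_transitions=float(means[0, 1]),
        mean_transversions=float(means[0, 2]),
        by_position=by_pos,
        n_pairs=n_pairs,
    )
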