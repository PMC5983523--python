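"""Misidentification and species-complex diagnostics for barcode libraries.

Three case types recur when a COI reference library is screened against
its own taxonomy:

* deep conspecific divergence — individuals sharing a species name but
  separated by more than the intraspecific ceiling (default 2%), the
  classic signature of a mislabelled voucher or a cryptic species;
* (near-)zero heterospecific distance — sequences under different species
  names that are barcode-identical, compatible with either morphological
  misidentification or mitochondrial introgression (COI alone cannot tell
  the two apart, so flags carry a combined label, never a causal claim);
* an unresolved species complex — a genus whose species are separated by
  less than the intraspecific ceiling, so the barcoding gap collapses
  genus-wide (recent, rapid speciation).

Thresholds are percentages of K2P distance and are configurable; the
defaults are 2.0% for the intraspecific ceiling and 0.1% for "near zero"
(about one substitution in a 655-site barcode, tolerating sequencing
error).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .barcode_io import BarcodeError
from .divergence import DistanceMatrix, SpeciesGapRecord
from .njtree import MonophylyRecord

DEFAULT_INTRA_THRESHOLD_PCT = 2.0
DEFAULT_EPSILON_PCT = 0.1

FLAG_TYPES = (
    "deep_conspecific_divergence",
    "zero_distance_heterospecific",
    "species_complex_unresolved",
    "non_monophyletic",
)


@dataclass(frozen=True)
class FlagRecord:
    flag_type: str
    species: tuple[str, ...]       # species (or genus members) involved
    sequence_ids: tuple[str, ...]  # triggering sequences, when applicable
    statistic: float | None        # triggering distance, %
    threshold: float               # threshold it violates, %
    note: str = ""


@dataclass
class IdentificationReport:
    """Per-species join of gap, monophyly and flag information."""

    rows: pd.DataFrame            # one row per species
    flags: list[FlagRecord]

    def to_tsv(self, path: str | Path, decimals: int = 2) -> None:
        out = self.rows.copy()
        for col in ("max_intra_pct", "nn_distance_pct", "gap_pct", "support_pct"):
            out[col] = pd.to_numeric(out[col], errors="coerce").round(decimals)
        out.to_csv(path, sep="\t", index=False, na_rep="NA")

    def summary_text(self) -> str:
        n_sp = len(self.rows)
        n_mono = int(self.rows["monophyletic"].sum())
        lines = [
            f"{n_sp} species; {n_mono} monophyletic "
            f"({100.0 * n_mono / n_sp:.1f}%)",
            f"{len(self.flags)} diagnostic flag(s)",
        ]
        for f in self.flags:
            stat = "" if f.statistic is None else f" ({f.statistic:.2f}%)"
            lines.append(
                f"  [{f.flag_type}] {', '.join(f.species)}{stat}"
                + (f" — {f.note}" if f.note else "")
            )
        return "\n".join(lines)

    @property
    def any_flags(self) -> bool:
        return bool(self.flags)


def _species_members(matrix: DistanceMatrix,
                     taxonomy: dict[str, tuple[str, str, str, str]],
                     ) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for idx, rid in enumerate(matrix.ids):
        if rid not in taxonomy:
            raise BarcodeError(f"taxonomy missing for {rid!r}")
        out.setdefault(taxonomy[rid][0], []).append(idx)
    return out


def flag_deep_conspecific(matrix: DistanceMatrix,
                          taxonomy: dict[str, tuple[str, str, str, str]],
                          threshold_pct: float = DEFAULT_INTRA_THRESHOLD_PCT,
                          ) -> list[FlagRecord]:
    """One flag per species whose maximum conspecific distance reaches the
    intraspecific ceiling, naming the most divergent pair."""
    flags = []
    for sp, members in sorted(_species_members(matrix, taxonomy).items()):
        best = None
        for a, i in enumerate(members):
            for j in members[a + 1:]:
                if not matrix.defined[i, j]:
                    continue
                dij = matrix.d[i, j] * 100.0
                if best is None or dij > best[0]:
                    best = (dij, matrix.ids[i], matrix.ids[j])
        if best is not None and best[0] >= threshold_pct:
            flags.append(FlagRecord(
                flag_type="deep_conspecific_divergence",
                species=(sp,),
                sequence_ids=(best[1], best[2]),
                statistic=best[0],
                threshold=threshold_pct,
                note="possible misidentification or cryptic species",
            ))
    return flags


def flag_zero_heterospecific(matrix: DistanceMatrix,
                             taxonomy: dict[str, tuple[str, str, str, str]],
                             epsilon_pct: float = DEFAULT_EPSILON_PCT,
                             ) -> list[FlagRecord]:
    """Flag every heterospecific pair at (near-)zero distance: a
    misidentification-or-introgression candidate."""
    ids = matrix.ids
    flags = []
    n = len(ids)
    for i in range(n):
        for j in range(i + 1, n):
            if taxonomy[ids[i]][0] == taxonomy[ids[j]][0]:
                continue
            if not matrix.defined[i, j]:
                continue
            dij = matrix.d[i, j] * 100.0
            if dij <= epsilon_pct:
                flags.append(FlagRecord(
                    flag_type="zero_distance_heterospecific",
                    species=(taxonomy[ids[i]][0], taxonomy[ids[j]][0]),
                    sequence_ids=(ids[i], ids[j]),
                    statistic=dij,
                    threshold=epsilon_pct,
                    note="misidentification or introgression candidate",
                ))
    return flags


def flag_species_complex(matrix: DistanceMatrix,
                         taxonomy: dict[str, tuple[str, str, str, str]],
                         threshold_pct: float = DEFAULT_INTRA_THRESHOLD_PCT,
                         ) -> list[FlagRecord]:
    """Flag genera whose minimum interspecific distance falls at or below
    the intraspecific ceiling — the barcoding gap collapses genus-wide.
    Single-species genera are skipped."""
    ids = matrix.ids
    genus_species: dict[str, dict[str, list[int]]] = {}
    for idx, rid in enumerate(ids):
        sp, genus = taxonomy[rid][0], taxonomy[rid][1]
        genus_species.setdefault(genus, {}).setdefault(sp, []).append(idx)
    flags = []
    for genus in sorted(genus_species):
        species = genus_species[genus]
        if len(species) < 2:
            continue
        best = None
        sp_names = sorted(species)
        for a, sp1 in enumerate(sp_names):
            for sp2 in sp_names[a + 1:]:
                for i in species[sp1]:
                    for j in species[sp2]:
                        if not matrix.defined[i, j]:
                            continue
                        dij = matrix.d[i, j] * 100.0
                        if best is None or dij < best[0]:
                            best = (dij, ids[i], ids[j])
        if best is not None and best[0] <= threshold_pct:
            flags.append(FlagRecord(
                flag_type="species_complex_unresolved",
                species=tuple(sp_names),
                sequence_ids=(best[1], best[2]),
                statistic=best[0],
                threshold=threshold_pct,
                note=f"genus {genus}: minimum interspecific distance "
                     f"{best[0]:.2f}% — species not discriminable",
            ))
    return flags


def flags_from_monophyly(monophyly: list[MonophylyRecord]) -> list[FlagRecord]:
    """Non-monophyly flags from tree-based assessment."""
    return [
        FlagRecord(
            flag_type="non_monophyletic",
            species=(m.species,),
            sequence_ids=(),
            statistic=None,
            threshold=0.0,
            note="individuals do not form one side of any branch",
        )
        for m in monophyly if not m.monophyletic
    ]


def build_report(gap_records: list[SpeciesGapRecord],
                 monophyly_records: list[MonophylyRecord],
                 flags: list[FlagRecord]) -> IdentificationReport:
    """Consolidate per-species gap, monophyly and flag information.

    Every species appears exactly once; the gap and monophyly inputs must
    cover the same species set (stage outputs from one dataset).
    """
    gap_by_sp = {g.species: g for g in gap_records}
    mono_by_sp = {m.species: m for m in monophyly_records}
    if set(gap_by_sp) != set(mono_by_sp):
        only_gap = sorted(set(gap_by_sp) - set(mono_by_sp))[:5]
        only_mono = sorted(set(mono_by_sp) - set(gap_by_sp))[:5]
        raise BarcodeError(
            "stage outputs cover different species sets "
            f"(gap-only: {only_gap}, monophyly-only: {only_mono})"
        )
    flags_by_sp: dict[str, list[str]] = {}
    for f in flags:
        for sp in f.species:
            flags_by_sp.setdefault(sp, []).append(f.flag_type)

    rows = []
    for sp in sorted(gap_by_sp):
        g, m = gap_by_sp[sp], mono_by_sp[sp]
        rows.append({
            "species": sp,
            "n_individuals": g.n_individuals,
            "max_intra_pct": g.max_intraspecific,
            "nn_species": g.nearest_neighbor,
            "nn_distance_pct": g.min_to_nearest_heterospecific,
            "gap_pct": g.gap,
            "monophyletic": m.monophyletic,
            "support_pct": m.support,
            "flags": ";".join(sorted(set(flags_by_sp.get(sp, [])))),
        })
    return IdentificationReport(pd.DataFrame(rows), list(flags))
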