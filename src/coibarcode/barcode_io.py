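"""Reading, validation and writing of COI barcode data.

A barcode dataset couples an aligned set of IUPAC DNA sequences (nominally
655 bp of the COI 5' region, no indels expected) with a four-rank taxonomy
(species, genus, family, order).  Quality control enforces the conventions
of barcode reference libraries: a minimum-length filter, reading-frame
detection, and screening for nuclear mitochondrial pseudogenes (NUMTs),
which betray themselves through in-frame stop codons in a protein-coding
marker.
"""

from __future__ import annotations

import csv
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: IUPAC nucleotide one-letter codes plus the alignment gap symbol.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN-")

#: Unambiguous bases; everything else is treated as missing downstream.
UNAMBIGUOUS = frozenset("ACGT")

#: Stop codons of the vertebrate mitochondrial genetic code (translation
#: table 2): TAA, TAG plus AGA/AGG, which are stops in table 2 although
#: they encode arginine in the standard code.
MITO_STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})

#: Minimum post-trim length, in sites, for a record to enter the analysis.
DEFAULT_MIN_LENGTH = 600

#: Fish COI amplification primers, recorded as provenance metadata only.
COI_PRIMERS = {
    "FishF1": "TCAACCAACCACAAAGACATTGGCAC",
    "FishF2": "TCGACTAATCATAAAGATATCGGCAC",
    "FishR1": "TAGACTTCTGGGTGGCCAAAGAATCA",
    "FishR2": "ACTTCAGGGTGACCGAAGAATCAGAA",
}

VALID_SOURCES = ("sampled", "downloaded", "synthetic")


class BarcodeError(ValueError):
    """Raised for malformed or inconsistent barcode inputs."""


@dataclass(frozen=True)
class BarcodeRecord:
    """One barcode sequence with its four-rank taxonomy and provenance."""

    id: str
    sequence: str
    species: str
    genus: str
    family: str
    order: str
    accession: str | None = None
    source: str = "sampled"

    def __post_init__(self) -> None:
        bad = set(self.sequence) - IUPAC_CODES
        if bad:
            raise BarcodeError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if self.source not in VALID_SOURCES:
            raise BarcodeError(
                f"record {self.id!r}: source {self.source!r} not in {VALID_SOURCES}"
            )
        for rank in ("species", "genus", "family", "order"):
            if not getattr(self, rank):
                raise BarcodeError(f"record {self.id!r}: empty {rank}")


@dataclass
class BarcodeDataset:
    """An aligned, QC-passed collection of barcode records.

    ``codon_offset`` is the 0-based alignment column at which codon
    position 1 starts; the codon position of column ``c`` is
    ``((c - codon_offset) % 3) + 1``.
    """

    records: list[BarcodeRecord]
    alignment_length: int
    codon_offset: int = 0

    def __post_init__(self) -> None:
        if self.alignment_length < 1:
            raise BarcodeError("alignment_length must be >= 1")
        if self.codon_offset not in (0, 1, 2):
            raise BarcodeError("codon_offset must be in {0, 1, 2}")
        for rec in self.records:
            if len(rec.sequence) != self.alignment_length:
                raise BarcodeError(
                    f"record {rec.id!r} has length {len(rec.sequence)}, "
                    f"expected {self.alignment_length}"
                )
        check_rank_consistency(
            {r.id: (r.species, r.genus, r.family, r.order) for r in self.records}
        )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def taxonomy(self) -> dict[str, tuple[str, str, str, str]]:
        return {r.id: (r.species, r.genus, r.family, r.order) for r in self.records}

    def codon_position(self, column: int) -> int:
        """1-based codon position of a 0-based alignment column."""
        return ((column - self.codon_offset) % 3) + 1

    def rank_counts(self) -> dict[str, int]:
        """Distinct taxa per rank, derived from the records themselves."""
        return {
            "species": len({r.species for r in self.records}),
            "genera": len({r.genus for r in self.records}),
            "families": len({r.family for r in self.records}),
            "orders": len({r.order for r in self.records}),
        }

    def filter_source(self, source: str) -> "BarcodeDataset":
        """Restrict to one provenance class ('sampled', 'downloaded', 'synthetic')."""
        if source == "all":
            return self
        if source not in VALID_SOURCES:
            raise BarcodeError(f"unknown source filter {source!r}")
        kept = [r for r in self.records if r.source == source]
        if not kept:
            raise BarcodeError(f"no records with source {source!r}")
        return BarcodeDataset(kept, self.alignment_length, self.codon_offset)


@dataclass
class QcRecordResult:
    id: str
    length: int
    n_ambiguous: int
    passes_length_filter: bool
    n_internal_stops: int
    has_indel_relative_to_consensus: bool


@dataclass
class QcReport:
    per_record: list[QcRecordResult]
    codon_offset: int
    n_pass: int
    n_fail: int

    def __post_init__(self) -> None:
        if self.n_pass + self.n_fail != len(self.per_record):
            raise BarcodeError("QcReport counts do not sum to record count")

    @property
    def numt_suspects(self) -> list[str]:
        return [r.id for r in self.per_record if r.n_internal_stops > 0]


def check_rank_consistency(
    taxonomy: Mapping[str, tuple[str, str, str, str]]
) -> None:
    """Ensure each taxon maps to a single parent taxon across all records.

    A species must sit in exactly one genus, a genus in one family, and a
    family in one order; violations are reported with the conflicting
    parents so the offending rows can be found.
    """
    for child_i, parent_i, label in ((0, 1, "species->genus"),
                                     (1, 2, "genus->family"),
                                     (2, 3, "family->order")):
        seen: dict[str, str] = {}
        for rid, ranks in taxonomy.items():
            child, parent = ranks[child_i], ranks[parent_i]
            if child in seen and seen[child] != parent:
                raise BarcodeError(
                    f"taxonomy inconsistency ({label}): {child!r} mapped to both "
                    f"{seen[child]!r} and {parent!r} (record {rid!r})"
                )
            seen[child] = parent


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``[(id, sequence), ...]`` preserving order.

    Sequences are upper-cased and RNA ``U`` is mapped to ``T``.  Duplicate
    IDs and empty files are errors.
    """
    path = Path(path)
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise BarcodeError(f"duplicate FASTA ID {rec.id!r} in {path}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq).upper().replace("U", "T")))
    if not out:
        raise BarcodeError(f"no FASTA records found in {path}")
    return out


@dataclass(frozen=True)
class TaxonomyEntry:
    species: str
    genus: str
    family: str
    order: str
    accession: str | None = None
    source: str = "sampled"


REQUIRED_TAXONOMY_COLUMNS = ("id", "species", "genus", "family", "order")


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyEntry]:
    """Read a taxonomy TSV with header ``id species genus family order``.

    Optional columns ``accession`` and ``source`` are honoured; all fields
    are whitespace-trimmed.  Rank inconsistencies (e.g. one genus placed in
    two families) are errors.
    """
    path = Path(path)
    entries: dict[str, TaxonomyEntry] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in REQUIRED_TAXONOMY_COLUMNS if c not in header]
        if missing:
            raise BarcodeError(f"taxonomy file {path} missing columns {missing}")
        for row in reader:
            rid = (row["id"] or "").strip()
            if not rid:
                continue
            if rid in entries:
                raise BarcodeError(f"duplicate taxonomy ID {rid!r} in {path}")
            accession = (row.get("accession") or "").strip() or None
            source = (row.get("source") or "").strip() or "sampled"
            entries[rid] = TaxonomyEntry(
                species=row["species"].strip(),
                genus=row["genus"].strip(),
                family=row["family"].strip(),
                order=row["order"].strip(),
                accession=accession,
                source=source,
            )
    if not entries:
        raise BarcodeError(f"no taxonomy rows found in {path}")
    check_rank_consistency(
        {k: (v.species, v.genus, v.family, v.order) for k, v in entries.items()}
    )
    return entries


# ---------------------------------------------------------------------------
# QC / assembly
# ---------------------------------------------------------------------------

def count_internal_stops(sequence: str, offset: int) -> int:
    """Count stop codons (vertebrate mito code) in complete codons at ``offset``.

    The barcode is an internal fragment of the COI gene, so every complete
    codon is internal; gap or ambiguity characters make a codon uncounted.
    """
    n = 0
    for start in range(offset, len(sequence) - 2, 3):
        codon = sequence[start : start + 3]
        if set(codon) <= UNAMBIGUOUS and codon in MITO_STOP_CODONS:
            n += 1
    return n


def choose_codon_offset(sequences: Iterable[str]) -> int:
    """Reading-frame detection: the offset minimising total stop codons.

    Ties are broken toward the smallest offset.
    """
    seqs = list(sequences)
    totals = [sum(count_internal_stops(s, off) for s in seqs) for off in (0, 1, 2)]
    return int(min(range(3), key=lambda off: (totals[off], off)))


def _consensus(sequences: Sequence[str], length: int) -> str:
    cols = []
    for c in range(length):
        counts: dict[str, int] = {}
        for s in sequences:
            counts[s[c]] = counts.get(s[c], 0) + 1
        cols.append(max(sorted(counts), key=lambda ch: counts[ch]))
    return "".join(cols)


def assemble_dataset(
    seqs: Sequence[tuple[str, str]],
    taxonomy: Mapping[str, TaxonomyEntry],
    min_length: int = DEFAULT_MIN_LENGTH,
    frame_policy: int | str = "min_stops",
    exclude_numts: bool = True,
) -> tuple[BarcodeDataset, QcReport]:
    """Apply QC and join sequences with taxonomy into a :class:`BarcodeDataset`.

    QC steps, in order: every ID must have a taxonomy entry; records whose
    ungapped length is below ``min_length`` are excluded; the reading frame
    is chosen by ``frame_policy`` ('min_stops', or an explicit offset in
    {0,1,2}); records with in-frame stop codons are flagged NUMT-suspect
    and excluded when ``exclude_numts`` is true.  Surviving sequences must
    be of one common length — no aligner is provided.
    """
    missing = [sid for sid, _ in seqs if sid not in taxonomy]
    if missing:
        raise BarcodeError(f"IDs without taxonomy entries: {missing[:5]}")

    # length filter on ungapped length (gaps are alignment padding)
    lengths = {sid: len(s.replace("-", "")) for sid, s in seqs}
    passing = [(sid, s) for sid, s in seqs if lengths[sid] >= min_length]
    failing_length = {sid for sid, _ in seqs} - {sid for sid, _ in passing}
    if failing_length:
        logger.info("length filter removed %d record(s): %s",
                    len(failing_length), sorted(failing_length))
    if not passing:
        raise BarcodeError("no records pass the length filter")

    if frame_policy == "min_stops":
        offset = choose_codon_offset(s for _, s in passing)
    else:
        offset = int(frame_policy)
        if offset not in (0, 1, 2):
            raise BarcodeError(f"frame_policy offset must be 0, 1 or 2, got {offset}")

    aln_lengths = {len(s) for _, s in passing}
    if len(aln_lengths) != 1:
        raise BarcodeError(
            f"sequences of unequal length after QC ({sorted(aln_lengths)}); "
            "inputs must be pre-aligned"
        )
    aln_len = aln_lengths.pop()
    consensus = _consensus([s for _, s in passing], aln_len)

    stops = {sid: count_internal_stops(s, offset) for sid, s in passing}
    numt_suspects = {sid for sid, n in stops.items() if n > 0}
    if numt_suspects:
        logger.warning("NUMT-suspect record(s) with in-frame stops: %s",
                       sorted(numt_suspects))

    passing_ids = {sid for sid, _ in passing}
    per_record = []
    for sid, s in seqs:
        aligned = sid in passing_ids
        per_record.append(QcRecordResult(
            id=sid,
            length=lengths[sid],
            n_ambiguous=sum(1 for ch in s if ch not in UNAMBIGUOUS and ch != "-"),
            passes_length_filter=sid not in failing_length,
            n_internal_stops=stops.get(sid, 0),
            has_indel_relative_to_consensus=(
                aligned and any(
                    (a == "-") != (b == "-") for a, b in zip(s, consensus)
                )
            ),
        ))

    excluded = set(failing_length)
    if exclude_numts:
        excluded |= numt_suspects

    records = []
    for sid, s in seqs:
        if sid in excluded:
            continue
        t = taxonomy[sid]
        records.append(BarcodeRecord(
            id=sid, sequence=s, species=t.species, genus=t.genus,
            family=t.family, order=t.order, accession=t.accession,
            source=t.source,
        ))
    if not records:
        raise BarcodeError("all records excluded by QC")

    dataset = BarcodeDataset(records, aln_len, offset)
    report = QcReport(
        per_record=per_record,
        codon_offset=offset,
        n_pass=len(records),
        n_fail=len(seqs) - len(records),
    )
    logger.info("QC: %d/%d records pass (codon offset %d)",
                report.n_pass, len(seqs), offset)
    return dataset, report


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_fasta(records: Iterable[tuple[str, str] | BarcodeRecord],
                path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if isinstance(rec, BarcodeRecord):
                rid, seq = rec.id, rec.sequence
            else:
                rid, seq = rec
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")


def write_taxonomy(entries: Mapping[str, TaxonomyEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["id", "species", "genus", "family", "order", "accession", "source"])
        for rid, t in entries.items():
            w.writerow([rid, t.species, t.genus, t.family, t.order,
                        t.accession or "", t.source])


def write_distance_csv(ids: Sequence[str], matrix, path: str | Path) -> None:
    """Square distance matrix as CSV with an ID header row/column."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["id", *ids])
        for i, rid in enumerate(ids):
            w.writerow([rid, *(f"{matrix[i][j]:.8f}" for j in range(len(ids)))])


def write_phylip(ids: Sequence[str], matrix, path: str | Path) -> None:
    """Lower-triangular relaxed PHYLIP distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(ids)}\n")
        for i, rid in enumerate(ids):
            row = " ".join(f"{matrix[i][j]:.8f}" for j in range(i))
            fh.write(f"{rid} {row}".rstrip() + "\n")


def write_rank_summaries(summaries, path: str | Path) -> None:
    """Tier-divergence TSV: level, n_taxa, n_pairs, mean/min/max/se in %."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["level", "n_taxa", "n_pairs", "mean", "min", "max", "se"])
        for s in summaries:
            w.writerow([s.level, s.n_taxa, s.n_pairs,
                        f"{s.mean:.2f}", f"{s.min:.2f}", f"{s.max:.2f}",
                        f"{s.se:.2f}"])


def write_outputs(result, out_dir: str | Path, config=None) -> dict[str, Path]:
    """Write every analysis artifact of a pipeline result to ``out_dir``.

    Files: square CSV and lower-triangular PHYLIP distance matrices,
    Newick tree, composition TSV, tier-divergence TSV, identification
    report TSV + text summary, site/pair statistics TSV, and a JSON run
    manifest.  ``result`` is a pipeline results bundle.
    """
    from .njtree import to_newick  # deferred: njtree imports this module

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise BarcodeError(f"output directory {out_dir} not writable: {exc}")

    paths = {
        "distance_csv": out_dir / "distance_matrix.csv",
        "distance_phylip": out_dir / "distance_matrix.phy",
        "tree": out_dir / "tree.nwk",
        "composition": out_dir / "composition.tsv",
        "rank_divergence": out_dir / "divergence_by_rank.tsv",
        "report": out_dir / "identification_report.tsv",
        "summary": out_dir / "summary.txt",
        "site_stats": out_dir / "site_and_pair_stats.tsv",
        "manifest": out_dir / "manifest.json",
    }
    write_distance_csv(result.matrix.ids, result.matrix.d, paths["distance_csv"])
    write_phylip(result.matrix.ids, result.matrix.d, paths["distance_phylip"])
    paths["tree"].write_text(to_newick(result.tree) + "\n")
    result.composition_table.to_tsv(paths["composition"])
    write_rank_summaries(result.summaries, paths["rank_divergence"])
    result.report.to_tsv(paths["report"])
    paths["summary"].write_text(result.report.summary_text() + "\n")

    sc, pf = result.site_classes, result.pair_stats
    rounded = pf.rounded()
    with open(paths["site_stats"], "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["statistic", "value"])
        for key, val in (("n_sites", sc.n_sites),
                         ("n_conserved", sc.n_conserved),
                         ("n_variable", sc.n_variable),
                         ("n_parsimony_informative", sc.n_parsimony_informative),
                         ("n_singleton", sc.n_singleton),
                         ("ii", rounded["ii"]), ("si", rounded["si"]),
                         ("sv", rounded["sv"]), ("R", rounded["R"]),
                         ("fold_ratio",
                          None if result.fold_ratio is None
                          else round(result.fold_ratio))):
            w.writerow([key, "NA" if val is None else val])

    parameters = {}
    seed = None
    if config is not None:
        parameters = {
            k: str(v) for k, v in vars(config).items()
            if k not in ("simulation",)
        }
        if getattr(config, "simulation", None) is not None:
            parameters["simulation"] = repr(config.simulation)
        seed = getattr(config, "seed", None)
    write_manifest(paths["manifest"], parameters=parameters, seed=seed,
                   counts=getattr(result, "counts", {}))
    return paths


def write_manifest(path: str | Path, *, parameters: Mapping, seed: int | None,
                   counts: Mapping[str, int]) -> None:
    """JSON run manifest: parameters, seed, package versions, filter counts."""
    import Bio
    import numpy
    import pandas

    from . import __version__

    manifest = {
        "parameters": dict(parameters),
        "seed": seed,
        "counts": dict(counts),
        "versions": {
            "coibarcode": __version__,
            "numpy": numpy.__version__,
            "pandas": pandas.__version__,
            "biopython": Bio.__version__,
        },
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
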