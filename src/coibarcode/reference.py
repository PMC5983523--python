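"""The Taiwan Strait fish COI reference library: taxonomy and fetch helpers.

The package ships the accession-level taxonomy of a published COI barcode
reference library of Taiwan Strait fishes (354 GenBank accessions, 86
species, 68 genera, 38 families, 11 orders; 284 sequences sampled in that
survey plus 70 downloaded from NCBI) as ``data/taiwan_strait_reference.tsv``.
The sequences themselves are not shipped; :func:`fetch_reference_sequences`
retrieves them from GenBank when network access is available, and
:func:`prepare_reference_dataset` turns the raw records into an aligned,
equal-length dataset using an external ``mafft`` binary (the package
itself implements no multiple alignment).

Transcription notes: one accession (KX254540, *Lateolabrax japonicus*)
appears in the source table both as sampled and as downloaded and is kept
once as sampled; two Gobiidae accessions are printed as "G574460" and
"G574461" (no valid prefix) and are transcribed verbatim — the fetch
helper skips accessions GenBank does not resolve, with a warning.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from importlib import resources
from pathlib import Path

from .barcode_io import (
    BarcodeDataset,
    BarcodeError,
    QcReport,
    TaxonomyEntry,
    assemble_dataset,
    read_fasta,
    read_taxonomy,
    write_fasta,
)

logger = logging.getLogger(__name__)

REFERENCE_TSV = "taiwan_strait_reference.tsv"


def reference_taxonomy_path() -> Path:
    return Path(resources.files("coibarcode") / "data" / REFERENCE_TSV)


def load_reference_taxonomy() -> dict[str, TaxonomyEntry]:
    """Accession → four-rank taxonomy for the shipped reference library."""
    return read_taxonomy(reference_taxonomy_path())


def fetch_reference_sequences(out_fasta: str | Path, email: str,
                              timeout: float = 30.0,
                              accessions: list[str] | None = None) -> list[str]:
    """Fetch the library's GenBank records and write a FASTA of COI regions.

    Requires network access.  For records longer than 2 kb (complete
    mitogenomes among the downloaded accessions) the COI/COX1 CDS feature
    is extracted; accessions that do not resolve are skipped with a
    warning.  Returns the accessions successfully written.
    """
    import socket

    from Bio import Entrez, SeqIO

    Entrez.email = email
    Entrez.max_tries = 1  # fail fast; we handle skips ourselves
    socket.setdefaulttimeout(timeout)
    if accessions is None:
        accessions = list(load_reference_taxonomy())
    written: list[tuple[str, str]] = []
    consecutive_failures = 0
    for acc in accessions:
        try:
            with Entrez.efetch(db="nucleotide", id=acc, rettype="gb",
                               retmode="text") as handle:
                rec = SeqIO.read(handle, "genbank")
            consecutive_failures = 0
        except Exception as exc:  # noqa: BLE001 - network/id errors alike
            logger.warning("accession %s not fetched (%s); skipped", acc, exc)
            consecutive_failures += 1
            if consecutive_failures >= 3 and not written:
                raise BarcodeError(
                    "GenBank unreachable: first accessions all failed "
                    f"(last error: {exc})"
                ) from exc
            continue
        seq = str(rec.seq)
        if len(seq) > 2000:
            coi = None
            for feat in rec.features:
                if feat.type != "CDS":
                    continue
                gene = " ".join(feat.qualifiers.get("gene", []) +
                                feat.qualifiers.get("product", [])).upper()
                if "COX1" in gene or "COI" in gene or "OXIDASE SUBUNIT I" in gene:
                    coi = str(feat.extract(rec.seq))
                    break
            if coi is None:
                logger.warning("accession %s: no COI CDS found; skipped", acc)
                continue
            seq = coi
        written.append((acc, seq.upper().replace("U", "T")))
    if not written:
        raise BarcodeError("no reference sequences could be fetched")
    write_fasta(written, out_fasta)
    return [acc for acc, _ in written]


def align_with_mafft(in_fasta: str | Path, out_fasta: str | Path) -> None:
    """Align raw fetched sequences with an external mafft binary."""
    mafft = shutil.which("mafft")
    if mafft is None:
        raise BarcodeError("mafft not found on PATH; cannot align")
    with open(out_fasta, "w") as fh:
        subprocess.run([mafft, "--auto", "--quiet", str(in_fasta)],
                       stdout=fh, check=True)


def _trim_sparse_columns(seqs: list[tuple[str, str]],
                         min_occupancy: float = 0.95) -> list[tuple[str, str]]:
    """Drop alignment columns that are gaps in more than 1-min_occupancy
    of sequences (primer overhangs, mitogenome flanks)."""
    n = len(seqs)
    L = len(seqs[0][1])
    keep = [c for c in range(L)
            if sum(s[1][c] != "-" for s in seqs) >= min_occupancy * n]
    return [(sid, "".join(s[c] for c in keep)) for sid, s in seqs]


def prepare_reference_dataset(aligned_fasta: str | Path,
                              min_length: int = 600,
                              min_occupancy: float = 0.95,
                              ) -> tuple[BarcodeDataset, QcReport]:
    """Assemble a fetched-and-aligned reference FASTA into a dataset."""
    seqs = _trim_sparse_columns(read_fasta(aligned_fasta), min_occupancy)
    taxonomy = load_reference_taxonomy()
    return assemble_dataset(seqs, taxonomy, min_length=min_length)


def reproduce_reference_analysis(out_dir: str | Path, email: str,
                                 timeout: float = 30.0):
    """End-to-end reproduction from GenBank: fetch, align, analyse.

    Network- and mafft-dependent; everything downstream of the aligned
    FASTA is the ordinary pipeline.  Returns the pipeline result.
    """
    from .pipeline import RunConfig, run

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    raw = out_dir / "reference_raw.fasta"
    aligned = out_dir / "reference_aligned.fasta"
    fetch_reference_sequences(raw, email=email, timeout=timeout)
    align_with_mafft(raw, aligned)
    config = RunConfig(fasta=aligned, taxonomy=reference_taxonomy_path(),
                       out_dir=out_dir, bootstrap_replicates=0,
                       trim_occupancy=0.95)
    return run(config)
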