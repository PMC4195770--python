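"""File formats: FASTA + dot-bracket companion, FASTQ, BED-like site
tables and TSV exports.

Conventions: sequential coordinates are 0-based half-open in BED and in
the in-memory containers, 1-based in report TSVs (stated in each header).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import TRNAGene

__all__ = [
    "read_gene_set",
    "write_gene_set",
    "read_fastq",
    "write_fastq",
    "read_sites_bed",
    "write_sites_bed",
    "write_structural_maps",
]


def _parse_meta(record) -> tuple[str, str]:
    """Isotype / isoacceptor from the FASTA description (key=value
    tokens) or from a tRNA-<Iso>-<NNN>-... style identifier."""
    meta = {}
    for token in record.description.split()[1:]:
        if "=" in token:
            key, value = token.split("=", 1)
            meta[key] = value
    if "isotype" in meta and "isoacceptor" in meta:
        return meta["isotype"], meta["isoacceptor"]
    parts = record.id.split("-")
    if len(parts) >= 3 and parts[0].lower().startswith("trna"):
        return parts[1], parts[2]
    raise ValueError(
        f"cannot determine isotype/isoacceptor for {record.id!r}: annotate the "
        "FASTA description with isotype=XXX isoacceptor=NNN"
    )


def read_gene_set(fasta_path: str | Path, structure_path: str | Path) -> list[TRNAGene]:
    """Load genes from FASTA plus the companion structure file
    (``gene_id<TAB>dot_bracket`` lines).  Genes lacking a structure are a
    hard error naming the IDs affected."""
    structures: dict[str, str] = {}
    for line in Path(structure_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        gene_id, db = line.split("\t")
        structures[gene_id] = db

    genes = []
    missing = []
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id not in structures:
            missing.append(record.id)
            continue
        isotype, isoacceptor = _parse_meta(record)
        cca = "cca_included=1" in record.description
        genes.append(
            TRNAGene.from_structure(
                record.id, isotype, isoacceptor, str(record.seq),
                structures[record.id], cca_included=cca,
            )
        )
    if missing:
        raise ValueError(
            "no secondary structure supplied for gene(s): " + ", ".join(missing)
        )
    return genes


def write_gene_set(genes: list[TRNAGene], fasta_path: str | Path, structure_path: str | Path) -> None:
    records = []
    for g in genes:
        desc = f"isotype={g.isotype} isoacceptor={g.isoacceptor}"
        if g.cca_included:
            desc += " cca_included=1"
        records.append(SeqRecord(Seq(g.sequence), id=g.gene_id, description=desc))
    SeqIO.write(records, str(fasta_path), "fasta")
    with open(structure_path, "w") as fh:
        for g in genes:
            fh.write(f"{g.gene_id}\t{g.dot_bracket}\n")


def read_fastq(path: str | Path) -> list[tuple[str, str]]:
    reads = []
    for record in SeqIO.parse(str(path), "fastq"):
        seq = str(record.seq).upper().replace("U", "T")
        if not seq:
            warnings.warn(f"skipping empty read {record.id}")
            continue
        reads.append((record.id, seq))
    return reads


def write_fastq(reads: list[tuple[str, str]], path: str | Path, quality: int = 40) -> None:
    """Write reads with a constant quality (the pipeline never uses base
    qualities)."""
    records = []
    for read_id, seq in reads:
        rec = SeqRecord(Seq(seq), id=read_id, description="")
        rec.letter_annotations["phred_quality"] = [quality] * len(seq)
        records.append(rec)
    SeqIO.write(records, str(path), "fastq")


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    """Cross-link site table: BED-like, 0-based half-open single-base
    intervals with a count column (chrom = gene_id)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["gene_id", "start", "end", "count"],
        dtype={"gene_id": str, "start": int, "end": int, "count": int},
    )
    return df


def write_sites_bed(sites: pd.DataFrame, path: str | Path) -> None:
    sites.to_csv(path, sep="\t", header=False, index=False,
                 columns=["gene_id", "start", "end", "count"])


def write_structural_maps(genes: list[TRNAGene], path: str | Path) -> None:
    rows = []
    for g in genes:
        for i in range(len(g.sequence)):
            rows.append((g.gene_id, i + 1, str(g.label_of(i)), g.sequence[i]))
    with open(path, "w") as fh:
        fh.write("# seq_index is 1-based\n")
        pd.DataFrame(rows, columns=["gene_id", "seq_index", "structural_label", "base"]) \
            .to_csv(fh, sep="\t", index=False)
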