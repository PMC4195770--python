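"""RNA bisulfite methylation calling against the tRNA reference.

Reads are aligned in three-letter space (every C collapsed to T in both
read and reference) so that conversion state does not penalise the
alignment; methylation states are then called from the original bases at
reference cytosines: read C -> +1 (methylated), read T -> -1
(converted), anything else NA.  Read-level and gene-level filters
reproduce the standard practice for this chemistry: reads with more
than 30% unconverted cytosines are discarded as conversion failures,
and genes with fewer than 10 retained reads are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align import ReadAlignment, _encode, _best_per_gene
from .model import TRNAGene, StructuralLabel

__all__ = [
    "MethylationMatrix",
    "bisulfite_align",
    "call_states",
    "build_matrices",
    "filter_matrix",
    "position_table",
    "methylation_profile",
    "call_substrate_genes",
]

NSUN2_LABELS = (34, 48, 49, 50)


@dataclass
class MethylationMatrix:
    """Per-read x per-cytosine states for one gene: +1 methylated, -1
    converted, 0 not covered / other base."""

    gene_id: str
    positions: list[int]                       # 0-based reference C positions
    data: pd.DataFrame = field(repr=False)     # rows: read ids, cols: positions
    n_input_reads: int = 0
    n_filtered_reads: int = 0

    def fractions(self) -> pd.DataFrame:
        """Per-position methylated fraction with informative coverage."""
        rows = []
        for pos in self.positions:
            col = self.data[pos]
            n_meth = int((col == 1).sum())
            n_conv = int((col == -1).sum())
            cov = n_meth + n_conv
            frac = n_meth / cov if cov else np.nan
            rows.append((pos, n_meth, n_conv, frac))
        return pd.DataFrame(rows, columns=["position", "n_meth", "n_conv", "fraction"])


def bisulfite_align(
    reads: list[tuple[str, str]],
    genes: list[TRNAGene],
    max_mismatch: int = 2,
) -> list[ReadAlignment]:
    """Three-letter alignment: C->T in both read and reference before the
    exhaustive ungapped scan.  Only reads with a unique best-stratum hit
    are kept (ambiguous reads dropped); the stored ``read_seq`` keeps the
    original bases for state calling.  Sense strand only (RNA bisulfite
    chemistry converts the read strand)."""
    if not genes:
        raise ValueError("empty gene set")
    conv_arrays = [_encode(g.sequence.replace("C", "T")) for g in genes]
    alignments = []
    for read_id, seq in reads:
        if not seq:
            continue
        conv_read = _encode(seq.replace("C", "T"))
        best = max_mismatch + 1
        hits: list[tuple[int, int, int]] = []
        for gi, garr in enumerate(conv_arrays):
            placement = _best_per_gene(conv_read, garr)
            if placement is None:
                continue
            mm, off = placement
            if mm <= max_mismatch:
                hits.append((gi, off, mm))
                best = min(best, mm)
        hits = [h for h in hits if h[2] == best and best <= max_mismatch]
        if len(hits) != 1:
            continue
        gi, off, mm = hits[0]
        alignments.append(
            ReadAlignment(
                read_id=read_id,
                gene_id=genes[gi].gene_id,
                start=off,
                end=off + len(seq),
                n_mismatch=mm,
                is_unique=True,
                n_hits=1,
                read_seq=seq,
            )
        )
    return alignments


def call_states(alignment: ReadAlignment, gene: TRNAGene) -> dict[int, int]:
    """Methylation state at every reference cytosine the read covers:
    C -> +1, T -> -1, other base (e.g. sequencing error) -> 0 (NA)."""
    states: dict[int, int] = {}
    for pos in gene.cytosine_positions():
        if not (alignment.start <= pos < alignment.end):
            continue
        base = alignment.read_seq[pos - alignment.start]
        states[pos] = 1 if base == "C" else (-1 if base == "T" else 0)
    return states


def build_matrices(
    alignments: list[ReadAlignment], genes: list[TRNAGene]
) -> dict[str, MethylationMatrix]:
    """One methylation matrix per gene; reads covering no reference C are
    dropped."""
    gene_by_id = {g.gene_id: g for g in genes}
    rows_by_gene: dict[str, dict[str, dict[int, int]]] = {}
    for aln in alignments:
        gene = gene_by_id[aln.gene_id]
        states = call_states(aln, gene)
        if not states:
            continue
        rows_by_gene.setdefault(aln.gene_id, {})[aln.read_id] = states

    matrices = {}
    for gene_id, rows in rows_by_gene.items():
        gene = gene_by_id[gene_id]
        positions = gene.cytosine_positions()
        frame = pd.DataFrame(
            [[states.get(p, 0) for p in positions] for states in rows.values()],
            index=list(rows.keys()),
            columns=positions,
            dtype=int,
        )
        matrices[gene_id] = MethylationMatrix(
            gene_id, positions, frame, n_input_reads=len(frame)
        )
    return matrices


def filter_matrix(
    matrix: MethylationMatrix,
    max_nonconversion: float = 0.30,
    min_reads: int = 10,
) -> MethylationMatrix | None:
    """Drop reads whose unconverted fraction (+1 cells over informative
    +1/-1 cells) exceeds ``max_nonconversion``; drop the gene entirely if
    fewer than ``min_reads`` reads remain."""
    data = matrix.data
    n_meth = (data == 1).sum(axis=1)
    informative = n_meth + (data == -1).sum(axis=1)
    with np.errstate(invalid="ignore"):
        frac = n_meth / informative.replace(0, np.nan)
    keep = frac.fillna(0.0) <= max_nonconversion
    retained = data[keep]
    if len(retained) < min_reads:
        return None
    return MethylationMatrix(
        matrix.gene_id, matrix.positions, retained,
        n_input_reads=matrix.n_input_reads, n_filtered_reads=len(retained),
    )


def position_table(
    matrices: dict[str, MethylationMatrix], genes: list[TRNAGene]
) -> pd.DataFrame:
    """Per-gene per-cytosine table: gene_id, seq_index (1-based),
    structural_label, n_meth, n_conv, fraction."""
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for gene_id, matrix in matrices.items():
        gene = gene_by_id[gene_id]
        for _, rec in matrix.fractions().iterrows():
            pos = int(rec.position)
            rows.append((
                gene_id, pos + 1, str(gene.label_of(pos)),
                int(rec.n_meth), int(rec.n_conv), rec.fraction,
            ))
    return pd.DataFrame(
        rows, columns=["gene_id", "seq_index", "structural_label", "n_meth", "n_conv", "fraction"]
    )


def methylation_profile(
    matrices: dict[str, MethylationMatrix], genes: list[TRNAGene]
) -> pd.DataFrame:
    """Mean methylated fraction per structural position, averaged over
    genes carrying a cytosine there (each gene counts once)."""
    table = position_table(matrices, genes)
    if table.empty:
        return pd.DataFrame(columns=["structural_label", "mean_fraction", "n_genes"])
    table = table.dropna(subset=["fraction"])
    grouped = table.groupby("structural_label")["fraction"].agg(["mean", "count"]).reset_index()
    grouped.columns = ["structural_label", "mean_fraction", "n_genes"]
    grouped = grouped.sort_values(
        by="structural_label", key=lambda s: s.map(lambda x: StructuralLabel.parse(x).sort_key)
    ).reset_index(drop=True)
    return grouped


def call_substrate_genes(
    control_table: pd.DataFrame,
    ko_table: pd.DataFrame,
    site_min_fraction: float = 0.1,
    site_min_coverage: int = 10,
    labels: tuple[int, ...] = NSUN2_LABELS,
) -> pd.DataFrame:
    """Call NSun2 substrate genes from two genotype position tables.

    A site is called methylated when its fraction >= ``site_min_fraction``
    with informative coverage >= ``site_min_coverage``.  A gene is a
    substrate when at least one site at structural 34/48/49/50 is called
    in the control and is confirmed below threshold in the knockout
    (which requires knockout coverage at the site).
    """
    wanted = {str(l) for l in labels}

    def _calls(table: pd.DataFrame) -> dict[tuple[str, str], str]:
        status = {}
        for _, row in table.iterrows():
            if row.structural_label not in wanted:
                continue
            cov = row.n_meth + row.n_conv
            if cov < site_min_coverage:
                status[(row.gene_id, row.structural_label)] = "no_call"
            elif row.fraction >= site_min_fraction:
                status[(row.gene_id, row.structural_label)] = "methylated"
            else:
                status[(row.gene_id, row.structural_label)] = "unmethylated"
        return status

    ctrl = _calls(control_table)
    ko = _calls(ko_table)
    gene_ids = sorted(
        set(control_table.gene_id) | set(ko_table.gene_id)
    )
    rows = []
    for gene_id in gene_ids:
        lost = [
            lab for (g, lab), st in ctrl.items()
            if g == gene_id and st == "methylated"
            and ko.get((g, lab)) == "unmethylated"
        ]
        rows.append((gene_id, bool(lost), ",".join(sorted(lost))))
    return pd.DataFrame(rows, columns=["gene_id", "is_substrate", "lost_sites"])
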