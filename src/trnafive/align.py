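"""Ungapped read alignment to a small tRNA reference, CCA-aware
realignment, proportional multi-mapper redistribution, and per-position
mismatch profiles.

The reference is tiny (tens of ~73-nt genes), so alignment is an
exhaustive scan over every gene, offset and orientation, keeping the
best mismatch stratum.  Reads needing gaps are reported unaligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from collections import defaultdict

import numpy as np
import pandas as pd

from .model import TRNAGene, revcomp

__all__ = [
    "ReadAlignment",
    "WeightedCounts",
    "align_reads",
    "cca_realign",
    "redistribute_multimappers",
    "mismatch_profile",
]


@dataclass
class ReadAlignment:
    """One read-to-gene placement.  ``start``/``end`` are 0-based
    half-open gene coordinates; ``read_seq`` is the (CCA-trimmed) read
    oriented to the gene 5'->3'."""

    read_id: str
    gene_id: str
    start: int
    end: int
    n_mismatch: int
    cca_trimmed: int = 0       # 0, 3 or 6 bases stripped before alignment
    is_unique: bool = True
    n_hits: int = 1
    strand: str = "+"
    read_seq: str = ""


@dataclass
class WeightedCounts:
    """Per-gene unique counts U_g and weighted totals C_g (unique mass
    plus proportionally redistributed multi-mapper mass)."""

    unique: dict[str, float] = field(default_factory=dict)
    weighted: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        gene_ids = sorted(set(self.unique) | set(self.weighted))
        return pd.DataFrame(
            {
                "gene_id": gene_ids,
                "unique_count": [self.unique.get(g, 0.0) for g in gene_ids],
                "weighted_count": [self.weighted.get(g, 0.0) for g in gene_ids],
            }
        )


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _best_per_gene(read_arr: np.ndarray, gene_arr: np.ndarray) -> tuple[int, int] | None:
    """Best (mismatches, offset) of one oriented read against one gene;
    ties go to the 5'-most offset."""
    L = len(read_arr)
    n = len(gene_arr)
    if L > n:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(gene_arr, L)
    mm = (windows != read_arr).sum(axis=1)
    off = int(mm.argmin())
    return int(mm[off]), off


def _scan_read(
    seq: str,
    genes: list[TRNAGene],
    gene_arrays: list[np.ndarray],
    max_mismatch: int,
    both_strands: bool = True,
) -> list[tuple[int, int, int, str]]:
    """All best-stratum placements of one read: (gene_idx, start,
    n_mismatch, strand).  At most one placement per gene (5'-most,
    forward preferred)."""
    fwd = _encode(seq)
    rev = _encode(revcomp(seq)) if both_strands else None
    candidates: list[tuple[int, int, int, str]] = []
    best = max_mismatch + 1
    for gi, garr in enumerate(gene_arrays):
        placements = []
        hit = _best_per_gene(fwd, garr)
        if hit is not None:
            placements.append((hit[0], hit[1], "+"))
        if rev is not None:
            hit = _best_per_gene(rev, garr)
            if hit is not None:
                placements.append((hit[0], hit[1], "-"))
        if not placements:
            continue
        # best score, then 5'-most offset, then forward strand
        mm, off, strand = min(placements, key=lambda t: (t[0], t[1], t[2] != "+"))
        if mm < best:
            best = mm
        candidates.append((gi, off, mm, strand))
    return [c for c in candidates if c[2] == best and best <= max_mismatch]


def align_reads(
    reads: list[tuple[str, str]],
    genes: list[TRNAGene],
    max_mismatch: int = 2,
    max_hits: int = 500,
    both_strands: bool = True,
) -> tuple[list[ReadAlignment], list[tuple[str, str]]]:
    """Align reads by exhaustive ungapped scan, keeping only the best
    mismatch stratum (<= ``max_mismatch``).  Reads whose best stratum has
    more than ``max_hits`` placements are discarded.  Returns
    (alignments, unaligned_reads)."""
    if not genes:
        raise ValueError("empty gene set")
    gene_arrays = [_encode(g.sequence) for g in genes]
    alignments: list[ReadAlignment] = []
    unaligned: list[tuple[str, str]] = []
    for read_id, seq in reads:
        if not seq:
            warnings.warn(f"skipping empty read {read_id}")
            continue
        hits = _scan_read(seq, genes, gene_arrays, max_mismatch, both_strands)
        if not hits or len(hits) > max_hits:
            unaligned.append((read_id, seq))
            continue
        unique = len(hits) == 1
        for gi, off, mm, strand in hits:
            oriented = seq if strand == "+" else revcomp(seq)
            alignments.append(
                ReadAlignment(
                    read_id=read_id,
                    gene_id=genes[gi].gene_id,
                    start=off,
                    end=off + len(seq),
                    n_mismatch=mm,
                    cca_trimmed=0,
                    is_unique=unique,
                    n_hits=len(hits),
                    strand=strand,
                    read_seq=oriented,
                )
            )
    return alignments, unaligned


def cca_realign(
    unaligned: list[tuple[str, str]],
    genes: list[TRNAGene],
    max_mismatch: int = 2,
    max_hits: int = 500,
) -> tuple[list[ReadAlignment], list[tuple[str, str]]]:
    """Strip a non-templated CCA suffix (then CCACCA) from still-unaligned
    reads and realign, requiring the trimmed read to end exactly at the
    gene 3' terminus.  Only reads actually ending in CCA/CCACCA are
    retried; sense orientation only (the tail marks the mature 3' end)."""
    alignments: list[ReadAlignment] = []
    still: list[tuple[str, str]] = []
    for read_id, seq in unaligned:
        placed = False
        for trim in (3, 6):
            if len(seq) <= trim or not seq.endswith("CCA" * (trim // 3)):
                continue
            core = seq[:-trim]
            core_arr = _encode(core)
            hits = []
            best = max_mismatch + 1
            for gene in genes:
                if len(core) > len(gene.sequence):
                    continue
                off = len(gene.sequence) - len(core)
                mm = int((_encode(gene.sequence[off:]) != core_arr).sum())
                if mm <= max_mismatch:
                    hits.append((gene, off, mm))
                    best = min(best, mm)
            hits = [h for h in hits if h[2] == best]
            if not hits or len(hits) > max_hits:
                continue
            unique = len(hits) == 1
            for gene, off, mm in hits:
                alignments.append(
                    ReadAlignment(
                        read_id=read_id,
                        gene_id=gene.gene_id,
                        start=off,
                        end=off + len(core),
                        n_mismatch=mm,
                        cca_trimmed=trim,
                        is_unique=unique,
                        n_hits=len(hits),
                        strand="+",
                        read_seq=core,
                    )
                )
            placed = True
            break
        if not placed:
            still.append((read_id, seq))
    return alignments, still


def redistribute_multimappers(alignments: list[ReadAlignment]) -> WeightedCounts:
    """Distribute multi-mapping reads proportionally to the fraction of
    uniquely matching reads at their candidate genes.

    For a multi-read r hitting genes M(r), the weight given to gene g is
    U_g / sum_{g' in M(r)} U_{g'}; when no candidate has unique reads the
    read is split uniformly.  C_g = U_g + redistributed mass, so the
    total weighted count equals the number of assigned reads exactly.
    """
    by_read: dict[str, list[ReadAlignment]] = defaultdict(list)
    for aln in alignments:
        by_read[aln.read_id].append(aln)

    unique: dict[str, float] = defaultdict(float)
    for alns in by_read.values():
        if len(alns) == 1:
            unique[alns[0].gene_id] += 1.0

    weighted: dict[str, float] = dict(unique)
    for alns in by_read.values():
        if len(alns) == 1:
            continue
        gene_ids = [a.gene_id for a in alns]
        denom = sum(unique.get(g, 0.0) for g in gene_ids)
        for g in gene_ids:
            w = unique.get(g, 0.0) / denom if denom > 0 else 1.0 / len(gene_ids)
            weighted[g] = weighted.get(g, 0.0) + w
    return WeightedCounts(unique=dict(unique), weighted=weighted)


def mismatch_profile(
    alignments: list[ReadAlignment],
    genes: list[TRNAGene],
    min_counts: int = 100,
) -> pd.DataFrame:
    """Average per-structural-position mismatch fraction over genes with
    at least ``min_counts`` uniquely aligned reads.

    Returns columns (structural_label, mean_fraction, n_genes); empty
    with a warning when no gene passes the threshold.
    """
    gene_by_id = {g.gene_id: g for g in genes}
    per_gene: dict[str, list[ReadAlignment]] = defaultdict(list)
    for aln in alignments:
        if aln.is_unique:
            per_gene[aln.gene_id].append(aln)

    label_values: dict[str, list[float]] = defaultdict(list)
    n_qualifying = 0
    for gene_id, alns in per_gene.items():
        if len(alns) < min_counts:
            continue
        n_qualifying += 1
        gene = gene_by_id[gene_id]
        L = len(gene.sequence)
        cov = np.zeros(L, dtype=float)
        mism = np.zeros(L, dtype=float)
        garr = _encode(gene.sequence)
        for aln in alns:
            span = slice(aln.start, aln.end)
            cov[span] += 1
            if aln.read_seq:
                mism[span] += (_encode(aln.read_seq) != garr[span])
        with np.errstate(invalid="ignore", divide="ignore"):
            rate = np.where(cov > 0, mism / np.maximum(cov, 1), np.nan)
        for i in range(L):
            if cov[i] > 0:
                label_values[str(gene.label_of(i))].append(float(rate[i]))
    if n_qualifying == 0:
        warnings.warn(f"no gene reached {min_counts} unique reads; empty mismatch profile")
        return pd.DataFrame(columns=["structural_label", "mean_fraction", "n_genes"])
    rows = [
        (label, float(np.mean(vals)), len(vals))
        for label, vals in label_values.items()
    ]
    from .model import StructuralLabel
    rows.sort(key=lambda r: StructuralLabel.parse(r[0]).sort_key)
    return pd.DataFrame(rows, columns=["structural_label", "mean_fraction", "n_genes"])
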