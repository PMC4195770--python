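"""Seeded generator of synthetic tRNA repertoires and sequencing reads.

The generator emulates the statistical structure the analysis stages
assume: a repertoire of short (~73 nt) highly similar genes grouped by
isotype/isoacceptor, genotype-dependent cytosine-5 methylation at
structural positions 34/38/48/49/50, non-templated CCA(CCA) tails on
mature molecules, anticodon-loop cleavage whose rate increases for
unmethylated target isotypes, bisulfite conversion chemistry with
imperfect efficiency, and cross-link sites displaced downstream of
methylated cytosines.  Every simulation is fully determined by the seed
and returns a truth table with one record per emitted read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd

from .model import TRNAGene

__all__ = [
    "SimConfig",
    "TruthTable",
    "build_gene_set",
    "simulate_tseq_reads",
    "simulate_bsseq_reads",
    "simulate_miclip_sites",
    "simulate_polIII_counts",
    "CANONICAL_DOT_BRACKET",
]

#: isotypes emitted round-robin by the generator, with their anticodons
ISOTYPE_ANTICODONS: dict[str, str] = {
    "Asp": "GTC",
    "Gly": "GCC",
    "Glu": "TTC",
    "Val": "AAC",
    "Lys": "CTT",
    "Cys": "GCA",
    "His": "GTG",
    "Leu": "CAA",
}

#: isotypes whose C38 is written by Dnmt2 (methylation persists without NSun2)
DNMT2_ISOTYPES = frozenset({"Asp", "Gly", "Val"})

#: isotypes whose 5' fragments accumulate when NSun2-dependent
#: methylation is lost (the cleavage boost applies to these)
DEFAULT_TARGET_ISOTYPES = ("Asp", "Glu", "Gly", "His", "Lys", "Val")

# canonical 73-nt cloverleaf: 7-bp acceptor, 2-nt linker, 4-bp D stem,
# 8-nt D loop, 1-nt linker, 5-bp anticodon stem, 7-nt loop, 5-nt variable
# loop, 5-bp T stem, 7-nt loop, discriminator.  Structural label equals
# sequential position at every base.
CANONICAL_DOT_BRACKET = (
    "(((((((" + ".." + "((((" + "........" + "))))" + "." +
    "(((((" + "......." + ")))))" + "....." +
    "(((((" + "......." + ")))))" + ")))))))" + "."
)

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}
_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """All knobs of the generator.  Probabilities are in [0, 1]; the seed
    fully determines every output."""

    seed: int = 0
    n_genes: int = 24
    duplicate_fraction: float = 0.15
    expression_mean: float = 150.0
    expression_sigma: float = 0.6
    inactive_fraction: float = 0.0
    genotype: str = "WT"                      # WT | KO (NSun2 null)
    fraction_c4849: float = 0.6               # per-position P(C) at 48 and 49
    nsun2_level: float = 0.85                 # methylation level at 48/49 (WT)
    dnmt2_level: float = 0.90                 # methylation level at 38
    methylation_sites: Optional[dict] = None  # gene_id -> [(label, writer, level)]
    cleavage_base_rate: float = 0.1           # p0
    cleavage_boost: float = 9.0               # beta, applied to unmethylated targets
    target_isotypes: tuple = DEFAULT_TARGET_ISOTYPES
    cleavage_site_label: int = 35             # cut 3' of this structural position
    cleavage_jitter: int = 2
    capture_5p: float = 0.8
    capture_3p: float = 0.4
    seq_error_rate: float = 0.002
    cca_double_fraction: float = 0.1          # reads ending CCACCA
    bs_conversion_efficiency: float = 0.99
    bs_protection: float = 0.97
    bs_fragment_len_range: tuple = (50, 120)
    miclip_offset: int = 3
    miclip_noise_fraction: float = 0.05
    depth: float = 1.0
    polIII_background: float = 0.5

    def __post_init__(self):
        for name in (
            "duplicate_fraction", "fraction_c4849", "nsun2_level", "dnmt2_level",
            "cleavage_base_rate", "capture_5p", "capture_3p", "seq_error_rate",
            "cca_double_fraction", "bs_conversion_efficiency", "bs_protection",
            "miclip_noise_fraction", "inactive_fraction",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {value}")
        if self.cleavage_boost < 0:
            raise ValueError("cleavage_boost must be >= 0")
        if self.genotype not in ("WT", "KO"):
            raise ValueError("genotype must be WT or KO")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TruthTable:
    """Ground truth for one simulation: per-gene expression and cleavage
    rates, per-site methylation levels, and one record per emitted read."""

    genes: pd.DataFrame = field(default_factory=pd.DataFrame)
    sites: pd.DataFrame = field(default_factory=pd.DataFrame)
    reads: pd.DataFrame = field(default_factory=pd.DataFrame)


def _fill_template(rng: np.random.Generator, constraints: dict[int, str]) -> str:
    """Random canonical-geometry sequence honouring fixed bases and
    Watson-Crick pairing of the canonical stems."""
    n = len(CANONICAL_DOT_BRACKET)
    pairs = {}
    stack = []
    for i, c in enumerate(CANONICAL_DOT_BRACKET):
        if c == "(":
            stack.append(i)
        elif c == ")":
            j = stack.pop()
            pairs[i] = j
            pairs[j] = i
    seq: list[Optional[str]] = [None] * n
    for pos, base in constraints.items():
        seq[pos] = base
        if pos in pairs and seq[pairs[pos]] is None:
            seq[pairs[pos]] = _COMP[base]
    for i in range(n):
        if seq[i] is not None:
            continue
        base = str(rng.choice(_BASES))
        seq[i] = base
        if i in pairs and seq[pairs[i]] is None:
            seq[pairs[i]] = _COMP[base]
    return "".join(seq)


def _default_sites(gene: TRNAGene, config: SimConfig) -> list[tuple[int, str, float]]:
    """NSun2 sites at C48/C49 (when the gene has a C there) and a Dnmt2
    site at C38 for the Dnmt2-written isotypes."""
    sites = []
    for label in (48, 49):
        try:
            i = gene.seq_index_of(label)
        except KeyError:
            continue
        if gene.sequence[i] == "C":
            sites.append((label, "NSun2", config.nsun2_level))
    if gene.isotype in DNMT2_ISOTYPES:
        try:
            i = gene.seq_index_of(38)
            if gene.sequence[i] == "C":
                sites.append((38, "Dnmt2", config.dnmt2_level))
        except KeyError:
            pass
    return sites


def build_gene_set(config: SimConfig) -> tuple[list[TRNAGene], TruthTable]:
    """Construct the synthetic repertoire plus its truth table.

    ``duplicate_fraction`` of the genes are emitted as copies of an
    earlier gene differing by at most one base, to exercise
    multi-mapping.  NSun2-class methylation levels are forced to zero
    when ``genotype == "KO"``; Dnmt2-class sites are unchanged.
    """
    if config.n_genes < 2:
        raise ValueError("n_genes must be >= 2")
    rng = np.random.default_rng(config.seed)
    isotypes = list(ISOTYPE_ANTICODONS)
    n_copies = int(round(config.n_genes * config.duplicate_fraction))
    n_orig = config.n_genes - n_copies

    genes: list[TRNAGene] = []
    for i in range(n_orig):
        isotype = isotypes[i % len(isotypes)]
        anticodon = ISOTYPE_ANTICODONS[isotype]
        constraints = {33 + k: anticodon[k] for k in range(3)}  # anticodon 34-36
        # C at 48 and 49 drawn independently: real repertoires mix genes
        # carrying a cytosine at only one of the two junction positions
        for pos in (47, 48):  # structural 48/49 (0-based 47/48)
            with_c = bool(rng.random() < config.fraction_c4849)
            constraints[pos] = "C" if with_c else str(rng.choice(np.array(list("AGT"))))
        if isotype in DNMT2_ISOTYPES:
            constraints[37] = "C"  # structural 38
        # eukaryotic T-arm consensus: the 5' T-stem strand is purine-rich
        # (pairing a C-rich 3' strand), G53 is conserved, and the loop
        # carries the classic T54-Psi55-C56-G57 motif
        for pos in (49, 50, 51):  # structural 50-52
            constraints.setdefault(pos, str(rng.choice(np.array(list("GAT")), p=[0.5, 0.25, 0.25])))
        constraints[52] = "G"  # structural 53
        for k, base in enumerate("TTCGAAT"):
            constraints[53 + k] = base
        seq = _fill_template(rng, constraints)
        gene = TRNAGene.from_structure(
            f"tRNA-{isotype}-{anticodon}-{i + 1}", isotype, anticodon,
            seq, CANONICAL_DOT_BRACKET,
        )
        genes.append(gene)

    for j in range(n_copies):
        src = genes[int(rng.integers(0, n_orig))]
        seq = src.sequence
        if rng.random() < 0.5:
            # one substitution in an unpaired, unconstrained position
            loop_pos = [p for p in range(len(seq))
                        if CANONICAL_DOT_BRACKET[p] == "."
                        and p not in (33, 34, 35, 37, 47, 48)]
            p = int(rng.choice(loop_pos))
            alt = str(rng.choice(np.array([b for b in "ACGT" if b != seq[p]])))
            seq = seq[:p] + alt + seq[p + 1:]
        gene = TRNAGene.from_structure(
            f"{src.gene_id}-dup{j + 1}", src.isotype, src.isoacceptor,
            seq, CANONICAL_DOT_BRACKET,
        )
        genes.append(gene)

    expressions = rng.lognormal(
        mean=np.log(config.expression_mean) - config.expression_sigma ** 2 / 2,
        sigma=config.expression_sigma, size=len(genes),
    )
    if config.inactive_fraction > 0:
        inactive = rng.random(len(genes)) < config.inactive_fraction
        expressions[inactive] = 0.0

    site_rows = []
    gene_rows = []
    for gene, expr in zip(genes, expressions):
        if config.methylation_sites is not None:
            sites = config.methylation_sites.get(gene.gene_id, [])
        else:
            sites = _default_sites(gene, config)
        for label, writer, level in sites:
            if config.genotype == "KO" and writer == "NSun2":
                level = 0.0
            site_rows.append((gene.gene_id, int(label), writer, float(level)))
        gene_rows.append((gene.gene_id, gene.isotype, gene.isoacceptor, float(expr)))

    sites_df = pd.DataFrame(site_rows, columns=["gene_id", "structural_label", "writer", "level"])
    genes_df = pd.DataFrame(gene_rows, columns=["gene_id", "isotype", "isoacceptor", "expression"])
    genes_df["cleavage_rate"] = [
        _cleavage_rate(g, sites_df, config) for g in genes
    ]
    return genes, TruthTable(genes=genes_df, sites=sites_df)


def _cleavage_rate(gene: TRNAGene, sites: pd.DataFrame, config: SimConfig) -> float:
    """p = min(1, p0 * (1 + beta)) for unmethylated-at-48/49 genes of the
    target isotypes, p0 otherwise."""
    gene_sites = sites[(sites.gene_id == gene.gene_id) & (sites.writer == "NSun2")
                       & (sites.structural_label.isin([48, 49]))]
    methylated = bool((gene_sites.level > 0).any())
    boost = (not methylated) and (gene.isotype in config.target_isotypes)
    p = config.cleavage_base_rate * (1.0 + (config.cleavage_boost if boost else 0.0))
    return float(min(1.0, p))


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    arr = list(seq)
    for p in rng.choice(len(seq), size=n_err, replace=False):
        arr[p] = str(rng.choice(np.array([b for b in "ACGT" if b != arr[p]])))
    return "".join(arr)


def _site_positions(gene: TRNAGene, sites: pd.DataFrame) -> list[tuple[int, float, str, int]]:
    """(seq_index, level, writer, label) for this gene's truth sites."""
    out = []
    for _, row in sites[sites.gene_id == gene.gene_id].iterrows():
        try:
            i = gene.seq_index_of(int(row.structural_label))
        except KeyError:
            continue
        out.append((i, float(row.level), str(row.writer), int(row.structural_label)))
    return out


def simulate_tseq_reads(
    genes: list[TRNAGene], truth: TruthTable, config: SimConfig
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Small-RNA (tRNA-seq) reads.

    Per molecule: cleaved in the anticodon loop with the gene's truth
    cleavage rate; an uncleaved molecule yields one full-length read with
    a non-templated CCA (CCACCA for ``cca_double_fraction`` of reads);
    a cleaved molecule yields a 5' read [start..site] and a 3' read
    [site+1..end]+CCA, each retained with its capture probability.
    Substitution errors are applied at ``seq_error_rate``.
    """
    rng = np.random.default_rng(config.seed + 1)
    reads: list[tuple[str, str]] = []
    rows = []
    gene_info = truth.genes.set_index("gene_id")
    for gene in genes:
        expr = gene_info.loc[gene.gene_id, "expression"]
        p_cleave = gene_info.loc[gene.gene_id, "cleavage_rate"]
        n_mol = int(rng.poisson(expr))
        if n_mol == 0:
            continue
        cut_anchor = gene.seq_index_of(config.cleavage_site_label)
        loop_a, loop_b = gene.annotation["anticodon_loop"]
        cleaved = rng.random(n_mol) < p_cleave
        jitters = rng.integers(-config.cleavage_jitter, config.cleavage_jitter + 1, n_mol)
        doubles = rng.random(n_mol) < config.cca_double_fraction
        keep5 = rng.random(n_mol) < config.capture_5p
        keep3 = rng.random(n_mol) < config.capture_3p
        for k in range(n_mol):
            tail = "CCACCA" if doubles[k] else "CCA"
            if not cleaved[k]:
                seq = _apply_errors(gene.sequence + tail, rng, config.seq_error_rate)
                read_id = f"ts:{gene.gene_id}:{k}:full"
                reads.append((read_id, seq))
                rows.append((read_id, gene.gene_id, "full", -1, len(seq)))
                continue
            cut = int(np.clip(cut_anchor + jitters[k], loop_a, loop_b - 2))
            if keep5[k]:
                seq = _apply_errors(gene.sequence[: cut + 1], rng, config.seq_error_rate)
                read_id = f"ts:{gene.gene_id}:{k}:5p"
                reads.append((read_id, seq))
                rows.append((read_id, gene.gene_id, "five_prime", cut, len(seq)))
            if keep3[k]:
                seq = _apply_errors(gene.sequence[cut + 1:] + tail, rng, config.seq_error_rate)
                read_id = f"ts:{gene.gene_id}:{k}:3p"
                reads.append((read_id, seq))
                rows.append((read_id, gene.gene_id, "three_prime", cut, len(seq)))
    read_truth = pd.DataFrame(
        rows, columns=["read_id", "gene_id", "klass", "cleavage_pos", "length"]
    )
    return reads, read_truth


def simulate_bsseq_reads(
    genes: list[TRNAGene], truth: TruthTable, config: SimConfig
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Bisulfite-converted reads.

    Each molecule samples a methylation state per truth site, is
    fragmented to a window of length uniform in ``bs_fragment_len_range``
    (clipped to the gene), and every unmethylated C reads as T with
    probability ``bs_conversion_efficiency`` while every methylated C
    survives as C with probability ``bs_protection``.
    """
    rng = np.random.default_rng(config.seed + 2)
    lo, hi = config.bs_fragment_len_range
    reads: list[tuple[str, str]] = []
    rows = []
    gene_info = truth.genes.set_index("gene_id")
    for gene in genes:
        expr = gene_info.loc[gene.gene_id, "expression"]
        n_mol = int(rng.poisson(expr))
        if n_mol == 0:
            continue
        gene_len = len(gene.sequence)
        c_positions = np.array(gene.cytosine_positions(), dtype=int)
        site_list = _site_positions(gene, truth.sites)
        site_pos = np.array([s[0] for s in site_list], dtype=int)
        site_level = np.array([s[1] for s in site_list], dtype=float)
        for k in range(n_mol):
            meth = rng.random(len(site_pos)) < site_level if len(site_pos) else np.array([], bool)
            meth_set = set(site_pos[meth]) if len(site_pos) else set()
            frag_len = int(min(rng.integers(lo, hi + 1), gene_len))
            start = int(rng.integers(0, gene_len - frag_len + 1))
            arr = list(gene.sequence[start: start + frag_len])
            for c in c_positions:
                if not (start <= c < start + frag_len):
                    continue
                if c in meth_set:
                    converted = rng.random() >= config.bs_protection
                else:
                    converted = rng.random() < config.bs_conversion_efficiency
                if converted:
                    arr[c - start] = "T"
            read_id = f"bs:{gene.gene_id}:{k}"
            reads.append((read_id, "".join(arr)))
            states = ";".join(
                f"{lab}:{int(pos in meth_set)}" for pos, _, _, lab in site_list
            )
            rows.append((read_id, gene.gene_id, start, frag_len, states))
    read_truth = pd.DataFrame(
        rows, columns=["read_id", "gene_id", "start", "length", "site_states"]
    )
    return reads, read_truth


def simulate_miclip_sites(
    genes: list[TRNAGene], truth: TruthTable, config: SimConfig
) -> pd.DataFrame:
    """Cross-link site table (BED-like, 0-based half-open single-base
    intervals with counts).

    Each methylated molecule-site emits one cross-link event at
    (methylated C + ``miclip_offset``); a ``miclip_noise_fraction`` of
    events land uniformly at random on the gene instead.
    """
    rng = np.random.default_rng(config.seed + 3)
    counts: dict[tuple[str, int], int] = {}
    gene_info = truth.genes.set_index("gene_id")
    for gene in genes:
        expr = gene_info.loc[gene.gene_id, "expression"]
        n_mol = int(rng.poisson(expr))
        gene_len = len(gene.sequence)
        for pos, level, _writer, _lab in _site_positions(gene, truth.sites):
            n_meth = int(rng.binomial(n_mol, level)) if n_mol else 0
            if n_meth == 0:
                continue
            noisy = rng.random(n_meth) < config.miclip_noise_fraction
            for is_noise in noisy:
                if is_noise:
                    p = int(rng.integers(0, gene_len))
                else:
                    p = pos + config.miclip_offset
                    if p >= gene_len:
                        continue
                counts[(gene.gene_id, p)] = counts.get((gene.gene_id, p), 0) + 1
    rows = [
        (gene_id, p, p + 1, c)
        for (gene_id, p), c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["gene_id", "start", "end", "count"])


def simulate_polIII_counts(
    genes: list[TRNAGene], truth: TruthTable, config: SimConfig, n_replicates: int = 1
) -> pd.DataFrame:
    """Per-gene occupancy counts standing in for Pol III ChIP: Poisson
    around expression * depth, with a background rate for inactive
    genes."""
    rng = np.random.default_rng(config.seed + 4)
    gene_info = truth.genes.set_index("gene_id")
    data = {}
    for rep in range(n_replicates):
        col = []
        for gene in genes:
            expr = gene_info.loc[gene.gene_id, "expression"]
            lam = expr * config.depth if expr > 0 else config.polIII_background
            col.append(int(rng.poisson(lam)))
        data[f"rep{rep + 1}"] = col
    return pd.DataFrame(data, index=[g.gene_id for g in genes])
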