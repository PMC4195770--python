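"""Fragment classification, positional coverage profiles, and
differential 5' fragment abundance between genotypes.

Aligned reads are partitioned into mature tRNAs (non-templated CCA and
>= 90% gene coverage), 5' fragments (25-40 nt anchored at the gene
start), CCA-tagged 3' fragments, boundary-violating reads, and an
internal remainder.  Normalisation uses median-of-ratios size factors
and the differential test is a negative-binomial exact test with a
method-of-moments pooled dispersion; it reproduces the normalisation of
the DESeq family but is not numerically identical to any DESeq release.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from collections import defaultdict

import numpy as np
import pandas as pd
from scipy import stats

from .align import ReadAlignment
from .model import TRNAGene, StructuralLabel

__all__ = [
    "FragmentCall",
    "classify_read",
    "classify_all",
    "coverage_profile",
    "size_factors",
    "fragment_enrichment",
    "fragment_counts_by_isotype",
]

CLASSES = ("mature", "five_prime", "three_prime_cca", "internal", "discarded_boundary")


@dataclass
class FragmentCall:
    read_id: str
    gene_id: str
    klass: str
    length: int


def classify_read(
    alignment: ReadAlignment,
    gene: TRNAGene,
    min_len: int = 25,
    max_len: int = 40,
    mature_min_cov: float = 0.9,
    boundary_tol: float = 0.10,
    strict_start: bool = False,
) -> FragmentCall:
    """Assign exactly one class to a retained alignment.

    Rules, applied in order:
      1. the read overhangs the gene start or end by more than
         ``boundary_tol`` of the gene length -> discarded_boundary;
      2. non-templated CCA present and aligned span >= ``mature_min_cov``
         of the gene -> mature;
      3. length 25-40 nt, alignment starting at gene position 0 with a
         matching first base -> five_prime (``strict_start`` requires the
         first three bases to match);
      4. length 25-40 nt, non-templated CCA and alignment ending at the
         gene 3' terminus -> three_prime_cca;
      5. otherwise internal.

    Length counts the trimmed CCA bases, i.e. the read as sequenced.
    """
    gene_len = len(gene.sequence)
    length = (alignment.end - alignment.start) + alignment.cca_trimmed
    overhang = max(-alignment.start, alignment.end - gene_len, 0)
    if overhang > boundary_tol * gene_len:
        return FragmentCall(alignment.read_id, gene.gene_id, "discarded_boundary", length)

    span = min(alignment.end, gene_len) - max(alignment.start, 0)
    if alignment.cca_trimmed > 0 and span >= mature_min_cov * gene_len:
        return FragmentCall(alignment.read_id, gene.gene_id, "mature", length)

    if min_len <= length <= max_len:
        if alignment.start == 0:
            n_check = 3 if strict_start else 1
            read = alignment.read_seq
            start_ok = (
                read[:n_check] == gene.sequence[:n_check]
                if read
                else alignment.n_mismatch == 0
            )
            if start_ok:
                return FragmentCall(alignment.read_id, gene.gene_id, "five_prime", length)
        if alignment.cca_trimmed > 0 and alignment.end == gene_len:
            return FragmentCall(alignment.read_id, gene.gene_id, "three_prime_cca", length)

    return FragmentCall(alignment.read_id, gene.gene_id, "internal", length)


def classify_all(
    alignments: list[ReadAlignment], genes: list[TRNAGene], **kwargs
) -> list[FragmentCall]:
    gene_by_id = {g.gene_id: g for g in genes}
    return [classify_read(a, gene_by_id[a.gene_id], **kwargs) for a in alignments]


def coverage_profile(
    calls: list[FragmentCall],
    alignments: list[ReadAlignment],
    genes: list[TRNAGene],
    grouping: str = "c4849",
    classes: tuple[str, ...] = ("five_prime", "three_prime_cca"),
    read_weighted: bool = False,
) -> dict[str, pd.DataFrame]:
    """Fraction of fragment reads covering each structural position.

    Per gene, the fraction of that gene's fragment reads covering each
    label; per group, the unweighted mean over genes with at least one
    fragment read (each gene counts once).  ``read_weighted`` pools reads
    across genes instead.  Groups without any fragment are omitted with a
    warning.
    """
    from .model import group_genes

    gene_by_id = {g.gene_id: g for g in genes}
    wanted = {(c.read_id, c.gene_id) for c in calls if c.klass in classes}
    per_gene_cov: dict[str, np.ndarray] = {}
    per_gene_n: dict[str, int] = defaultdict(int)
    for aln in alignments:
        if (aln.read_id, aln.gene_id) not in wanted:
            continue
        gene = gene_by_id[aln.gene_id]
        cov = per_gene_cov.setdefault(aln.gene_id, np.zeros(len(gene.sequence)))
        cov[max(aln.start, 0): min(aln.end, len(gene.sequence))] += 1
        per_gene_n[aln.gene_id] += 1

    groups = group_genes(genes, grouping)
    out: dict[str, pd.DataFrame] = {}
    for key, members in groups.items():
        label_fracs: dict[str, list[float]] = defaultdict(list)
        pooled_cov: dict[str, float] = defaultdict(float)
        pooled_n = 0
        used = 0
        for gene in members:
            n = per_gene_n.get(gene.gene_id, 0)
            if n == 0:
                continue
            used += 1
            cov = per_gene_cov[gene.gene_id]
            for i in range(len(gene.sequence)):
                lab = str(gene.label_of(i))
                label_fracs[lab].append(float(cov[i]) / n)
                pooled_cov[lab] += float(cov[i])
            pooled_n += n
        if used == 0:
            warnings.warn(f"group {key!r} has no fragment reads; omitted")
            continue
        if read_weighted:
            rows = [(lab, pooled_cov[lab] / pooled_n, used) for lab in pooled_cov]
        else:
            rows = [(lab, float(np.mean(v)), len(v)) for lab, v in label_fracs.items()]
        rows.sort(key=lambda r: StructuralLabel.parse(r[0]).sort_key)
        out[key] = pd.DataFrame(rows, columns=["structural_label", "mean_fraction", "n_genes"])
    return out


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios per-sample normalisation factors.

    factor_s = median over genes of count_gs / geometric-mean_g; genes
    with a zero in any sample are excluded from the median.  A single
    sample gets factor 1 by convention.
    """
    if counts.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    positive = counts[(counts > 0).all(axis=1)]
    if positive.empty:
        raise ValueError("cannot normalize: every gene has a zero count in some sample")
    log_gm = np.log(positive).mean(axis=1)
    ratios = np.log(positive).sub(log_gm, axis=0)
    return np.exp(ratios.median(axis=0))


def fragment_counts_by_isotype(
    calls: list[FragmentCall], genes: list[TRNAGene], klass: str = "five_prime"
) -> pd.Series:
    gene_iso = {g.gene_id: g.isotype for g in genes}
    counts: dict[str, int] = defaultdict(int)
    for c in calls:
        if c.klass == klass:
            counts[gene_iso[c.gene_id]] += 1
    return pd.Series(counts, dtype=float).sort_index()


def _nb_pmf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    if var <= mean * (1 + 1e-12):
        return stats.poisson.pmf(x, mean)
    r = mean * mean / (var - mean)
    p = r / (r + mean)
    return stats.nbinom.pmf(x, r, p)


def _nb_exact_test(kA: int, kB: int, mA: float, mB: float, vA: float, vB: float) -> float:
    """Conditional two-sided test: the probability, given kA + kB, of
    splits at most as likely as the observed one under independent NB
    marginals with the supplied moments."""
    s = kA + kB
    if s == 0:
        return 1.0
    if s > 200_000:  # normal approximation for very deep groups
        z = (kA - mA) / np.sqrt(vA + vB * (mA / mB) ** 2) if mB > 0 else 0.0
        return float(2 * stats.norm.sf(abs(z)))
    a = np.arange(s + 1)
    joint = _nb_pmf(a, mA, vA) * _nb_pmf(s - a, mB, vB)
    total = joint.sum()
    if total <= 0:
        return 1.0
    p_obs = joint[kA]
    return float(min(1.0, joint[joint <= p_obs * (1 + 1e-7)].sum() / total))


def _pooled_dispersion(norm: pd.DataFrame, factors: pd.Series, cond: pd.Series) -> float:
    """Method-of-moments common dispersion across groups: for each group
    and condition with >= 2 replicates, alpha = (var(q) - mean(q) *
    mean(1/s)) / mean(q)^2; pooled as the median, floored at 0."""
    alphas = []
    for level in cond.unique():
        cols = cond[cond == level].index
        if len(cols) < 2:
            continue
        inv_s = float(np.mean(1.0 / factors[cols]))
        sub = norm[cols]
        mu = sub.mean(axis=1)
        w = sub.var(axis=1, ddof=1)
        ok = mu > 0
        alphas.extend(((w[ok] - mu[ok] * inv_s) / mu[ok] ** 2).tolist())
    if not alphas:
        return 0.0
    return max(0.0, float(np.median(alphas)))


def fragment_enrichment(
    counts: pd.DataFrame,
    conditions: pd.Series | list[str] | dict[str, str],
    treatment: str = "KO",
    reference: str = "control",
    pseudocount: float = 0.5,
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Differential 5'-fragment abundance per group (isotype) between two
    conditions.

    ``counts`` is groups x samples (nonnegative integers); ``conditions``
    labels each sample column.  Counts are normalised with
    median-of-ratios size factors; the log2 fold change compares mean
    normalised counts (treatment over reference) and the p-value comes
    from the NB exact test with a method-of-moments pooled dispersion.
    With fewer than two replicates on either side only the fold change is
    reported.  P-values are Benjamini-Hochberg adjusted across groups;
    groups with zero counts in both conditions are skipped.

    ``factors`` overrides the size factors.  Computing them on the
    fragment table itself is only sound when most groups are unchanged;
    with few groups prefer factors derived from a stable reference such
    as per-gene mature-tRNA counts (mature abundances do not depend on
    genotype).
    """
    if isinstance(conditions, dict):
        conditions = pd.Series(conditions)
    else:
        conditions = pd.Series(list(conditions), index=counts.columns)
    for level in (treatment, reference):
        if level not in set(conditions):
            raise ValueError(f"condition {level!r} absent from labels")

    counts = counts.fillna(0.0)
    if factors is None:
        factors = size_factors(counts)
    else:
        factors = factors.reindex(counts.columns)
        if factors.isna().any() or (factors <= 0).any():
            raise ValueError("supplied size factors must be positive for every sample")
    norm = counts.div(factors, axis=1)
    cols_t = conditions[conditions == treatment].index
    cols_r = conditions[conditions == reference].index
    have_reps = len(cols_t) >= 2 and len(cols_r) >= 2
    alpha = _pooled_dispersion(norm, factors, conditions) if have_reps else 0.0

    S_t = float(factors[cols_t].sum())
    S_r = float(factors[cols_r].sum())
    S2_t = float((factors[cols_t] ** 2).sum())
    S2_r = float((factors[cols_r] ** 2).sum())

    rows = []
    for group in counts.index:
        k_t = float(counts.loc[group, cols_t].sum())
        k_r = float(counts.loc[group, cols_r].sum())
        if k_t == 0 and k_r == 0:
            continue
        mean_t = float(norm.loc[group, cols_t].mean())
        mean_r = float(norm.loc[group, cols_r].mean())
        if mean_t > 0 and mean_r > 0:
            log2fc = float(np.log2(mean_t / mean_r))
        else:
            log2fc = float(np.log2((mean_t + pseudocount) / (mean_r + pseudocount)))
        q0 = (k_t + k_r) / (S_t + S_r)
        m_t, m_r = q0 * S_t, q0 * S_r
        v_t = m_t + alpha * q0 * q0 * S2_t
        v_r = m_r + alpha * q0 * q0 * S2_r
        stat = (k_t - m_t) / np.sqrt(v_t) if v_t > 0 else 0.0
        pval = (
            _nb_exact_test(int(round(k_t)), int(round(k_r)), m_t, m_r, v_t, v_r)
            if have_reps else np.nan
        )
        rows.append((group, log2fc, float(stat), pval))

    out = pd.DataFrame(rows, columns=["group", "log2fc", "stat", "pvalue"])
    mask = out["pvalue"].notna()
    out["padj"] = np.nan
    if mask.any():
        out.loc[mask, "padj"] = _bh_adjust(out.loc[mask, "pvalue"].to_numpy())
    return out


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    n = len(pvals)
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.empty(n)
    adj[order] = np.minimum(ranked, 1.0)
    return adj
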