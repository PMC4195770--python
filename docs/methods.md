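# Methods

This note documents the models, conventions and numerical choices
behind `trnafive`, and what the synthetic-data generator does and does
not emulate.

## Structural coordinate system

Cross-gene aggregation is meaningless in raw sequence coordinates
because tRNA genes differ in D-loop and variable-loop length.  Every
gene is therefore mapped onto a canonical 1..76 coordinate system
derived from its cloverleaf (supplied as a dot-bracket string alongside
the FASTA; the package does not fold sequences — references for real
data come from covariance-model databases whose alignments already
imply the structure, and the simulator emits its own structures).

Anchors, in order of precedence:

* **Position 49** is the first paired 5′ nucleoside of the T (TΨC)
  stem.  This is the load-bearing convention: the methylation sites of
  interest flank it (48 = last variable-loop base, 49/50 = first T-stem
  bases).
* The **anticodon** (centre 3 nt of the second hairpin loop) is 34–36.
* The **variable loop** is numbered backwards from 48; loops longer
  than 5 nt (type II tRNAs) receive insertion labels `47a, 47b, …`
  between 47 and 48.
* The **D loop** absorbs length variation by compressing/padding labels
  14..21 toward its 3′ end; extra 5′ bases (loops over 8 nt) get
  insertions on 13.  The same 3′-anchoring applies to the T loop
  (54..60) and the short 32/33 and 37/38 runs flanking the anticodon.
* Stem 3′ strands are labelled through their pairing partner
  (label sums 73 for the acceptor stem, 35 for the D stem, 70 for the
  anticodon stem, 114 for the T stem), so a 3 bp D stem yields 11–13 /
  22–24 with 25 simply absent.
* The base after the acceptor stem is the discriminator (73); up to
  three further trailing bases are a templated/annotated CCA (74–76).

The mapping is total, injective, and non-decreasing along the sequence;
these invariants are asserted at construction time.  The D-loop
compression convention is our own choice (3′-anchored, ties toward
lower numbers) — any consistent convention works because all cross-gene
aggregation uses the same labels — and is stated here because other
numbering tools may disagree by one in short D loops.

Stems larger than canonical (acceptor > 7 bp, D > 4 bp, anticodon or T
stem > 5 bp) are rejected rather than guessed at; they do not occur in
cytoplasmic cloverleaves.

Sequential coordinates are 0-based half-open internally and in BED
files, 1-based in report TSVs (each export states this).

## Alignment

The reference is tiny (tens of genes x ~73 nt), so alignment is an
exhaustive ungapped scan over every gene, offset and orientation,
keeping the minimum-mismatch stratum with at most 2 mismatches and
discarding reads whose best stratum exceeds 500 placements.  Indels are
not supported; a read needing a gap counts as unaligned.  Ties between
equal-scoring offsets within one gene keep the 5′-most placement
(relevant only for pathological repeats).  Reads still unaligned are
retried after stripping a `CCA` (then `CCACCA`) suffix, with the
realignment required to end at the gene 3′ terminus — only a
non-templated tail marks maturity, so a read ending in genomically
templated CCA that aligned without trimming is *not* CCA-tagged.

Multi-mapping reads are redistributed at whole-gene granularity:
read *r* hitting gene set *M(r)* gives gene *g* weight
U_g / Σ_{g′∈M(r)} U_{g′} (uniform if the denominator is zero), where
U_g counts reads unique to *g* in the same library.  Per-read weights
sum to one, so Σ_g C_g equals the number of assigned reads exactly.

Boundary handling: alignments are produced strictly within gene bounds,
but the fragment classifier accepts coordinates outside them (as arise
when a reference carries genomic flanks) and discards reads overhanging
either terminus by more than 10 % of the gene length.

## Fragment classes and differential abundance

Each retained alignment receives exactly one class, applying rules in
order: boundary-discarded (>10 % overhang); mature (non-templated CCA
and aligned span ≥ 90 % of the gene); 5′ fragment (25–40 nt, alignment
begins at gene position 0 with a matching first base — a stricter
first-three-bases mode is available); CCA-tagged 3′ fragment (25–40 nt,
non-templated CCA, ends at the 3′ terminus); otherwise internal.
Fragment length counts the trimmed CCA bases, i.e. the read as
sequenced.

Coverage profiles average per-gene coverage *fractions* with equal gene
weight (each expressed gene counts once); a read-weighted pooled mode
exists behind a flag.  Whether published figures of this kind are gene-
or read-weighted is generally ambiguous; gene-weighted is the default
because it is robust to one dominant gene.

Differential 5′ fragment abundance per isotype uses median-of-ratios
size factors and an exact conditional negative-binomial test: given the
summed counts of the two conditions, the p-value accumulates all splits
at most as probable as the observed one under independent NB marginals
whose variance uses a method-of-moments dispersion pooled across
isotypes (median of per-isotype estimates, floored at zero; with Poisson
data the test reduces to a conservative binomial-type test).  This
reproduces the normalisation and test *family* of the DESeq lineage but
is deliberately self-contained and is not numerically identical to any
DESeq release.  With fewer than two replicates per side only the fold
change is reported.  P-values are Benjamini–Hochberg adjusted across
isotypes.

**Normalisation caveat.**  Size factors computed on a per-isotype
fragment table are only meaningful when most isotypes are unchanged.
At desk scale most simulated isotypes are cleavage targets, so the
pipeline derives factors from per-gene *mature* counts instead —
mature tRNA abundances are genotype-independent — and passes them into
the test (`fragment_enrichment(..., factors=...)`).  The CLI `report`
command does this automatically when mature counts are available.

## Bisulfite methylation calling

Bisulfite chemistry deaminates unmethylated C to U (read T) and leaves
5-methylcytosine intact; only read-strand C→T conversion is modelled
(RNA protocol).  Reads are aligned in three-letter space (C collapsed
to T in both read and reference) so conversion state cannot penalise
placement; a unique best-stratum hit is required and ambiguous reads
are dropped — with near-identical gene copies this is a real loss and
is reported in the manifest.  States at reference cytosines are called
from the original read bases: C → +1, T → −1, other → NA.

Filters: a read whose unconverted fraction — +1 cells over informative
(+1/−1) cells, NA excluded so uncovered positions are not penalised —
exceeds 30 % is discarded as a conversion failure; genes with fewer
than 10 retained reads are dropped.  Per-position methylated fractions
are aggregated to structural-position profiles with equal gene weight.

Substrate calls compare a control and a knockout run: a site at
structural 34/48/49/50 is "methylated" at fraction ≥ 0.1 with coverage
≥ 10 (both explicit config; no published cutoff exists for this call,
so the defaults are deliberately conservative and visible), and a gene
is a substrate when at least one such site is methylated in the control
and confirmed below threshold — which requires coverage — in the
knockout.  Dnmt2-written C38 methylation persists in the knockout and
never triggers a substrate call.

## Cross-link site analysis

Sites are consumed as a position table (BED-like single-base intervals
with counts), not raw CLIP reads; truncation calling from raw reads is
upstream of this package.  The offset estimator histograms, per site,
the distance to the nearest *upstream* cytosine within 10 nt (the
cross-link chemistry places the adduct downstream of the target C; a
symmetric search is a config option) and reports the modal offset, ties
broken toward the smaller absolute value.  Because near-adjacent target
cytosines shadow each other (a site 3 nt downstream of C48 is only 2 nt
downstream of C49), the histogram spreads over small offsets even in
clean data; the mode remains at the true displacement as long as a
reasonable fraction of genes carry a single junction cytosine.

Confidence is judged against the sequence-composition null: the
distance histogram expected from uniformly placed sites (computed from
the gene sequences themselves, since random placement already favours
short distances).  The estimate is flagged confident when the modal
bin's observed fraction is at least twice its null fraction.

Candidate methylated cytosines are recovered by projecting each site
back by the modal offset onto the nearest cytosine within ±1; sites
with no such cytosine are counted as unassigned.

## The synthetic-data generator

The generator defines the study conditions for all statistical tests.
It emulates:

* a repertoire of canonical-geometry 73-nt genes over eight isotypes
  (Asp, Gly, Glu, Val, Lys, Cys, His, Leu) with their anticodons at
  34–36; a configurable fraction of genes emitted as exact or
  1-mismatch copies (default 0.15) to exercise multi-mapping;
* cytosines at 48 and 49 drawn *independently* (default P = 0.6 each),
  reflecting repertoires in which many tRNAs carry a junction cytosine
  at only one of the two positions; the T-stem 5′ strand is purine-rich
  with conserved G53 and the loop carries the T54-Ψ55-C56-G57 motif, as
  in real cytoplasmic tRNAs (this composition, not a tuning choice,
  keeps the region downstream of the junction cytosine C-poor);
* methylation truth: NSun2-class sites at C48/C49 (level 0.85 in the
  wild type, forced to 0 in the knockout) and Dnmt2-class C38 sites
  (level 0.9, genotype-independent) on Asp/Gly/Val.  C50/C34 sites can
  be supplied explicitly but are not in the defaults;
* anticodon-loop cleavage at base rate p0 = 0.1 per molecule, boosted
  to min(1, p0·(1+β)) with β = 9 for genes of the target isotypes
  (Asp, Glu, Gly, His, Lys, Val) that are unmethylated at 48/49; the
  cut falls 3′ of structural 35 with ±2 jitter clipped to the anticodon
  loop.  No quantitative cleavage rates are published; p0 and β are
  free parameters of the simulator chosen to give a clear but not
  degenerate contrast;
* library structure: full-length molecules read with a non-templated
  CCA (CCACCA for 10 %); cleavage products captured independently at
  0.8 (5′) and 0.4 (3′), mimicking 5′-biased half libraries;
  substitution errors at 0.002/base; constant high base qualities (the
  analysis never uses qualities);
* bisulfite libraries: per-molecule site states sampled from the truth
  level, fragments of length uniform in 50–120 nt (clipped to the
  gene), conversion efficiency 0.99 and methylation protection 0.97, so
  an estimated fraction recovers m·0.97 + (1−m)·0.01;
* cross-link site tables displaced +3 from each methylated cytosine,
  with 5 % of events placed uniformly at random; and per-gene occupancy
  counts (Poisson around expression) standing in for polymerase-III
  binding, with a background rate for inactive genes.

Expression is log-normal (mean 150 reads/gene, σ = 0.6).  Every output
is fully determined by the seed; truth tables carry one record per
emitted read.

Not emulated: indels, adapters, UMIs, PCR duplicates, quality decay,
intron-containing pre-tRNAs, mitochondrial geometry, other RT-blocking
modifications, and genomic flanking sequence.  Passing tests therefore
demonstrate the correctness of the computations under this generative
model, not robustness to every artefact of real libraries — in real
data the multi-mapping structure is heavier and reverse-transcription
stops at modified bases add mismatch/termination signal that this
generator leaves out (the mismatch-profile stage exists to surface
exactly that signal in real data).

## Problem sizes

The statistical checks run at desk scale by design: type-I error of the
enrichment test is measured over 25 independent 2-vs-2 simulations of a
16-gene repertoire (~200 isotype contrasts) with the cleavage boost
disabled, and power over 10 such simulations with the default boost;
methylation recovery uses 4-gene repertoires at ~150 reads/gene, which
gives ≥ 50x informative coverage per site after filtering.  These sizes
give stable pass/fail behaviour across seeds while keeping the whole
suite fast.

## Known limitations

* Redistribution operates at whole-gene granularity; sub-gene regions
  are not modelled.
* The NB test's dispersion pooling assumes isotypes share a dispersion
  scale; with two replicates per side per group there is no power to
  check this.
* Three-letter alignment discards reads that are ambiguous between
  near-identical genes rather than redistributing them; methylation
  profiles are therefore biased toward genes with unique sequence.
* The structural numbering of severely non-canonical cloverleaves
  (bulged stems, branched arms) is refused rather than approximated.
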