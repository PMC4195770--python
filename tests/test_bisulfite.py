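"""Three-letter bisulfite alignment, state calling, read/gene filters
and methylation profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from trnafive.align import ReadAlignment
from trnafive.bisulfite import (
    MethylationMatrix,
    bisulfite_align,
    build_matrices,
    call_states,
    call_substrate_genes,
    filter_matrix,
    methylation_profile,
    position_table,
)
from trnafive.simulate import SimConfig, build_gene_set, simulate_bsseq_reads


@pytest.fixture(scope="module")
def genes():
    gs, _ = build_gene_set(SimConfig(seed=44, n_genes=4, duplicate_fraction=0.0))
    return gs


class TestThreeLetterAlignment:
    def test_fully_converted_read_aligns_with_zero_mismatches(self, genes):
        gene = genes[0]
        read = gene.sequence[5:55].replace("C", "T")
        alns = bisulfite_align([("r1", read)], genes)
        assert len(alns) == 1
        assert alns[0].gene_id == gene.gene_id
        assert alns[0].n_mismatch == 0
        assert alns[0].read_seq == read  # original bases preserved

    def test_unconverted_read_still_aligns(self, genes):
        gene = genes[0]
        read = gene.sequence[5:55]  # every C retained
        alns = bisulfite_align([("r1", read)], genes)
        assert len(alns) == 1 and alns[0].n_mismatch == 0

    def test_ambiguous_read_dropped(self, genes):
        twin_a = genes[0]
        twin_b = genes[0]
        both = [twin_a, twin_b]
        read = twin_a.sequence[0:50].replace("C", "T")
        # identical genes: two best hits -> ambiguous
        assert bisulfite_align([("r1", read)], both) == []

    def test_never_beaten_by_a_closer_gene(self, genes):
        """Oracle check: the assigned gene minimises three-letter Hamming
        distance over all genes and offsets."""
        rng = np.random.default_rng(0)
        for trial in range(20):
            gene = genes[rng.integers(0, len(genes))]
            start = int(rng.integers(0, 20))
            read = gene.sequence[start: start + 45]
            read = "".join(
                "T" if (b == "C" and rng.random() < 0.9) else b for b in read
            )
            alns = bisulfite_align([("r", read)], genes)
            if not alns:
                continue
            t_read = read.replace("C", "T")

            def best_dist(g):
                t_gene = g.sequence.replace("C", "T")
                return min(
                    sum(a != b for a, b in zip(t_read, t_gene[o: o + len(read)]))
                    for o in range(len(t_gene) - len(read) + 1)
                )

            winner = best_dist(next(g for g in genes if g.gene_id == alns[0].gene_id))
            assert all(best_dist(g) >= winner for g in genes)


class TestStateCalling:
    def test_states_follow_read_bases(self, genes):
        gene = genes[0]
        c_pos = gene.cytosine_positions()
        keep = set(c_pos[:2])
        read = "".join(
            b if (b != "C" or i in keep) else "T"
            for i, b in enumerate(gene.sequence)
        )
        aln = ReadAlignment("r", gene.gene_id, 0, len(read), 0, read_seq=read)
        states = call_states(aln, gene)
        for p in c_pos:
            assert states[p] == (1 if p in keep else -1)

    def test_sequencing_error_base_is_na(self, genes):
        gene = genes[0]
        p = gene.cytosine_positions()[0]
        read = gene.sequence[:40]
        read = read[:p] + "A" + read[p + 1:]
        aln = ReadAlignment("r", gene.gene_id, 0, 40, 1, read_seq=read)
        assert call_states(aln, gene)[p] == 0

    def test_read_without_cytosines_dropped(self, genes):
        gene = genes[0]
        c_pos = gene.cytosine_positions()
        # find a window without reference C
        window = None
        for a in range(len(gene.sequence) - 5):
            if not any(a <= p < a + 5 for p in c_pos):
                window = (a, a + 5)
                break
        if window is None:
            pytest.skip("no C-free window in this gene")
        aln = ReadAlignment("r", gene.gene_id, window[0], window[1], 0,
                            read_seq=gene.sequence[window[0]:window[1]])
        matrices = build_matrices([aln], genes)
        assert matrices == {}


def _matrix(gene_id, rows):
    positions = list(range(len(rows[0])))
    frame = pd.DataFrame(rows, columns=positions,
                         index=[f"r{i}" for i in range(len(rows))])
    return MethylationMatrix(gene_id, positions, frame, n_input_reads=len(rows))


class TestFilters:
    def test_forty_percent_unconverted_read_dropped(self):
        rows = [[1] * 4 + [-1] * 6] + [[-1] * 10] * 10  # 40% then clean reads
        filtered = filter_matrix(_matrix("g", rows))
        assert len(filtered.data) == 10

    def test_twenty_percent_kept(self):
        rows = [[1] * 2 + [-1] * 8] + [[-1] * 10] * 9
        filtered = filter_matrix(_matrix("g", rows))
        assert len(filtered.data) == 10

    def test_exactly_thirty_percent_kept(self):
        rows = [[1] * 3 + [-1] * 7] + [[-1] * 10] * 9
        assert len(filter_matrix(_matrix("g", rows)).data) == 10

    def test_gene_with_nine_retained_reads_dropped(self):
        rows = [[-1] * 10] * 9
        assert filter_matrix(_matrix("g", rows)) is None

    def test_na_cells_not_counted_as_unconverted(self):
        # 3 methylated of 6 informative (50%) -> dropped;
        # 3 of 10 informative (30%) -> kept
        dropped = [[1, 1, 1, -1, -1, -1] + [0] * 4] + [[-1] * 10] * 10
        kept = [[1, 1, 1] + [-1] * 7] + [[-1] * 10] * 10
        assert len(filter_matrix(_matrix("g", dropped)).data) == 10
        assert len(filter_matrix(_matrix("g", kept)).data) == 11

    @settings(max_examples=30, deadline=None)
    @given(st.floats(min_value=0.0, max_value=1.0), st.floats(min_value=0.0, max_value=1.0),
           st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_filter_monotone_in_threshold(self, t1, t2, seed):
        """Lowering max_nonconversion never increases retained rows."""
        rng = np.random.default_rng(seed)
        rows = rng.choice([1, -1, 0], size=(30, 8), p=[0.3, 0.5, 0.2]).tolist()
        lo, hi = sorted([t1, t2])
        m_lo = filter_matrix(_matrix("g", rows), max_nonconversion=lo, min_reads=0)
        m_hi = filter_matrix(_matrix("g", rows), max_nonconversion=hi, min_reads=0)
        n_lo = 0 if m_lo is None else len(m_lo.data)
        n_hi = 0 if m_hi is None else len(m_hi.data)
        assert n_lo <= n_hi


class TestProfiles:
    @pytest.mark.parametrize("level", [0.0, 0.25, 0.5, 0.9])
    def test_simulated_level_recovered(self, level):
        """Estimated fraction falls in the 99% binomial interval around
        level * protection + (1 - level) * (1 - efficiency)."""
        config = SimConfig(
            seed=int(level * 100) + 7, n_genes=4, duplicate_fraction=0.0,
            expression_mean=120, nsun2_level=level,
        )
        genes, truth = build_gene_set(config)
        reads, _ = simulate_bsseq_reads(genes, truth, config)
        alns = bisulfite_align(reads, genes)
        matrices = build_matrices(alns, genes)
        filtered = {g: m for g, m in ((g, filter_matrix(m)) for g, m in matrices.items())
                    if m is not None}
        table = position_table(filtered, genes)
        expected = level * config.bs_protection + (1 - level) * (1 - config.bs_conversion_efficiency)
        nsun2 = truth.sites[(truth.sites.writer == "NSun2")]
        checked = 0
        from scipy import stats as sps
        for site in nsun2.itertuples():
            rows = table[(table.gene_id == site.gene_id)
                         & (table.structural_label == str(site.structural_label))]
            if rows.empty:
                continue
            row = rows.iloc[0]
            n = row.n_meth + row.n_conv
            if n < 50:
                continue
            lo, hi = sps.binom.interval(0.99, n, expected)
            assert lo <= row.n_meth <= hi, (site.gene_id, site.structural_label)
            checked += 1
        assert checked >= 3

    def test_ko_collapses_4849_but_not_dnmt2_c38(self):
        """Knocking out the 48/49 writer flattens the junction peak while
        the position-38 signal written by the other enzyme persists."""
        profiles = {}
        tables = {}
        for genotype in ("WT", "KO"):
            config = SimConfig(seed=55, n_genes=8, duplicate_fraction=0.0,
                               expression_mean=120, genotype=genotype)
            genes, truth = build_gene_set(config)
            reads, _ = simulate_bsseq_reads(genes, truth, config)
            alns = bisulfite_align(reads, genes)
            matrices = build_matrices(alns, genes)
            filtered = {g: m for g, m in ((g, filter_matrix(m)) for g, m in matrices.items())
                        if m is not None}
            profiles[genotype] = methylation_profile(filtered, genes) \
                .set_index("structural_label").mean_fraction
            tables[genotype] = position_table(filtered, genes)
            if genotype == "WT":
                dnmt2_genes = set(truth.sites[truth.sites.writer == "Dnmt2"].gene_id)
        for lab in ("48", "49"):
            assert profiles["WT"].get(lab, 0) > 0.4
            assert profiles["KO"].get(lab, 1) < 0.1
        for genotype in ("WT", "KO"):
            t = tables[genotype]
            c38 = t[(t.structural_label == "38") & (t.gene_id.isin(dnmt2_genes))]
            assert not c38.empty and (c38.fraction > 0.6).all()

    def test_no_methylation_perfect_conversion_gives_zero_profile(self):
        config = SimConfig(seed=60, n_genes=4, duplicate_fraction=0.0,
                           methylation_sites={}, bs_conversion_efficiency=1.0)
        genes, truth = build_gene_set(config)
        reads, _ = simulate_bsseq_reads(genes, truth, config)
        alns = bisulfite_align(reads, genes)
        matrices = build_matrices(alns, genes)
        filtered = {g: m for g, m in ((g, filter_matrix(m)) for g, m in matrices.items())
                    if m is not None}
        profile = methylation_profile(filtered, genes)
        assert (profile.mean_fraction == 0).all()


class TestSubstrateCalls:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["gene_id", "seq_index", "structural_label",
                           "n_meth", "n_conv", "fraction"],
        )

    def test_lost_site_marks_substrate(self):
        ctrl = self._table([("g1", 48, "48", 45, 5, 0.9)])
        ko = self._table([("g1", 48, "48", 1, 49, 0.02)])
        calls = call_substrate_genes(ctrl, ko)
        assert calls.set_index("gene_id").loc["g1", "is_substrate"]

    def test_dnmt2_only_gene_is_not_substrate(self):
        ctrl = self._table([("g1", 38, "38", 45, 5, 0.9)])
        ko = self._table([("g1", 38, "38", 44, 6, 0.88)])
        calls = call_substrate_genes(ctrl, ko)
        assert not calls.set_index("gene_id").loc["g1", "is_substrate"]

    def test_low_coverage_gives_no_call(self):
        ctrl = self._table([("g1", 48, "48", 4, 1, 0.8)])  # coverage 5
        ko = self._table([("g1", 48, "48", 0, 30, 0.0)])
        calls = call_substrate_genes(ctrl, ko)
        assert not calls.set_index("gene_id").loc["g1", "is_substrate"]
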