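import numpy as np
import pytest

from duosnp import (MISSING, GenotypeMatrix, IntervalSet, MarkerTable,
                    SelectionError, SelectionParams, allele_stats,
                    exclude_gene_regions, hwe_exact, ld_prune, ld_r2,
                    panel_subset, prune_related_samples, qc_filter,
                    run_selection, select_candidates)
from duosnp.popgen_stats import hwe_exact_matrix


def mk_markers(specs):
    """specs: list of (chrom, bp, freq)."""
    return MarkerTable.from_records([
        {"marker_id": f"m{i}", "chrom": c, "bp": b, "allele_minor": "A",
         "allele_major": "G", "cm": np.nan, "freq_minor": f}
        for i, (c, b, f) in enumerate(specs)])


class TestExcludeGeneRegions:
    def test_marker_inside_interval_removed(self):
        markers = mk_markers([(1, b, 0.5) for b in (100, 200, 300, 400, 500)])
        genes = IntervalSet({1: np.array([[250, 350]])})  # contains bp 300
        out = exclude_gene_regions(markers, genes)
        assert len(out) == 4
        assert "m2" not in out.marker_ids

    def test_empty_interval_set_keeps_all(self):
        markers = mk_markers([(1, 100, 0.5), (2, 200, 0.4)])
        assert len(exclude_gene_regions(markers, IntervalSet())) == 2

    def test_planted_gene_fraction_recovered(self, cohort):
        g, markers, genes, truth = cohort
        out = exclude_gene_regions(markers, genes)
        removed = len(markers) - len(out)
        assert removed == len(truth.gene_markers)
        assert abs(removed / len(markers) - 0.30) < 0.02


class TestQcFilter:
    def base(self, n=500, m=40, seed=0):
        rng = np.random.default_rng(seed)
        dos = (rng.binomial(1, 0.3, (n, m)) + rng.binomial(1, 0.3, (n, m))).astype(np.int8)
        markers = mk_markers([(1, 1000 * (j + 1), 0.3) for j in range(m)])
        return dos, markers

    def test_high_missing_sample_removed_first(self):
        dos, markers = self.base()
        dos[0, : int(0.06 * dos.shape[1])] = MISSING  # 6% missing
        g = GenotypeMatrix([f"s{i}" for i in range(dos.shape[0])], dos)
        g2, _, audit = qc_filter(g, markers, SelectionParams())
        assert g2.n_samples == g.n_samples - 1
        assert audit.stages[0][:3] == ("sample_missingness", "samples", 1)

    def test_high_missing_marker_removed(self):
        dos, markers = self.base()
        dos[: int(0.02 * dos.shape[0]), 3] = MISSING  # 2% missing marker
        g = GenotypeMatrix([f"s{i}" for i in range(dos.shape[0])], dos)
        _, m2, audit = qc_filter(g, markers, SelectionParams())
        assert "m3" not in m2.marker_ids
        assert dict((s[0], s[2]) for s in audit.stages)["marker_missingness"] == 1

    def test_all_heterozygote_marker_fails_hwe(self):
        dos, markers = self.base()
        dos[:, 5] = 1  # 500 heterozygotes: exact p far below 1e-5
        assert hwe_exact(0, 500, 0).p_value < 1e-5
        g = GenotypeMatrix([f"s{i}" for i in range(dos.shape[0])], dos)
        _, m2, audit = qc_filter(g, markers, SelectionParams())
        assert "m5" not in m2.marker_ids

    def test_audit_counts_are_consistent(self):
        dos, markers = self.base()
        g = GenotypeMatrix([f"s{i}" for i in range(dos.shape[0])], dos)
        _, _, audit = qc_filter(g, markers, SelectionParams())
        for stage, axis, removed, remaining in audit.stages:
            assert removed >= 0 and remaining >= 0
        marker_rows = [s for s in audit.stages if s[1] == "markers"]
        assert marker_rows[0][2] + marker_rows[0][3] == len(markers)


class TestPruneRelatedSamples:
    def simulate(self, seed=0):
        rng = np.random.default_rng(seed)
        n_loci, p = 4000, 0.5
        draw = lambda: (rng.binomial(1, p, n_loci) + rng.binomial(1, p, n_loci)).astype(np.int8)
        child_of = lambda a, b: (np.where(a == 1, rng.integers(0, 2, n_loci), a // 2)
                                 + np.where(b == 1, rng.integers(0, 2, n_loci), b // 2)).astype(np.int8)
        return rng, draw, child_of

    def test_planted_parent_child_pair_loses_one_member(self):
        rng, draw, child_of = self.simulate()
        parent = draw()
        rows = [parent, child_of(parent, draw())] + [draw() for _ in range(6)]
        g = GenotypeMatrix([f"s{i}" for i in range(8)], np.array(rows))
        keep, _ = prune_related_samples(g, SelectionParams())
        assert len(keep) == 7
        assert len({0, 1} & set(keep.tolist())) == 1

    def test_unrelated_cohort_untouched(self):
        _, draw, _ = self.simulate(1)
        g = GenotypeMatrix([f"s{i}" for i in range(6)], np.array([draw() for _ in range(6)]))
        keep, _ = prune_related_samples(g, SelectionParams())
        assert len(keep) == 6

    def test_trio_drops_the_child_with_two_partners(self):
        rng, draw, child_of = self.simulate(2)
        father, mother = draw(), draw()
        child = child_of(father, mother)
        rows = [father, mother, child] + [draw() for _ in range(3)]
        g = GenotypeMatrix([f"s{i}" for i in range(6)], np.array(rows))
        keep, _ = prune_related_samples(g, SelectionParams())
        # child (index 2) is related to both parents -> removed first and alone
        assert 2 not in keep
        assert len(keep) == 5

    def test_threshold_one_never_binds(self):
        rng, draw, child_of = self.simulate(3)
        parent = draw()
        g = GenotypeMatrix(["a", "b"], np.array([parent, child_of(parent, draw())]))
        keep, _ = prune_related_samples(g, SelectionParams(kinship_max=1.0))
        assert len(keep) == 2


class TestLdPrune:
    def test_duplicated_marker_column_loses_one_copy(self):
        rng = np.random.default_rng(0)
        base = (rng.binomial(1, 0.4, (300, 5)) + rng.binomial(1, 0.4, (300, 5))).astype(np.int8)
        dos = np.column_stack([base, base[:, 2]])
        markers = mk_markers([(1, 1000 * (j + 1), 0.4) for j in range(6)])
        g = GenotypeMatrix([f"s{i}" for i in range(300)], dos)
        _, m2 = ld_prune(g, markers, SelectionParams())
        assert len(m2) == 5

    def test_independent_markers_mostly_retained(self):
        rng = np.random.default_rng(1)
        n, m = 8000, 30
        dos = (rng.binomial(1, 0.5, (n, m)) + rng.binomial(1, 0.5, (n, m))).astype(np.int8)
        markers = mk_markers([(1, 10_000 * (j + 1), 0.5) for j in range(m)])
        g = GenotypeMatrix([f"s{i}" for i in range(n)], dos)
        _, m2 = ld_prune(g, markers, SelectionParams())
        assert len(m2) >= m - 2

    def test_mutually_correlated_triple_keeps_exactly_one(self):
        rng = np.random.default_rng(2)
        a = (rng.binomial(1, 0.5, 400) + rng.binomial(1, 0.5, 400)).astype(np.int8)
        noise = lambda: np.clip(a + rng.integers(-1, 2, 400) * (rng.random(400) < 0.05), 0, 2)
        dos = np.column_stack([a, noise(), noise()]).astype(np.int8)
        markers = mk_markers([(1, 1000 * (j + 1), 0.5) for j in range(3)])
        g = GenotypeMatrix([f"s{i}" for i in range(400)], dos)
        _, m2 = ld_prune(g, markers, SelectionParams())
        assert len(m2) == 1

    def test_no_retained_pair_exceeds_threshold(self):
        rng = np.random.default_rng(3)
        n, m = 400, 60
        dos = (rng.binomial(1, 0.5, (n, m)) + rng.binomial(1, 0.5, (n, m))).astype(np.int8)
        markers = mk_markers([(1, 1000 * (j + 1), 0.5) for j in range(m)])
        g = GenotypeMatrix([f"s{i}" for i in range(n)], dos)
        g2, m2 = ld_prune(g, markers, SelectionParams())
        for i in range(g2.n_markers):
            for j in range(i + 1, g2.n_markers):
                assert ld_r2(g2.dosages[:, i], g2.dosages[:, j]) <= 0.01 + 1e-12


class TestSelectCandidates:
    def test_spacing_excludes_close_lower_maf_marker(self):
        markers = mk_markers([(1, 1_000_000, 0.50), (1, 6_000_000, 0.49)])
        out = select_candidates(markers, SelectionParams(n_candidates=1))
        assert out.freq_minor[0] == pytest.approx(0.50)
        with pytest.raises(SelectionError):
            select_candidates(markers, SelectionParams(n_candidates=2))

    def test_different_chromosomes_never_conflict(self):
        markers = mk_markers([(1, 100, 0.50), (2, 100, 0.49)])
        out = select_candidates(markers, SelectionParams(n_candidates=2))
        assert len(out) == 2

    def test_exactly_ten_mbp_is_too_close(self):
        markers = mk_markers([(1, 1, 0.50), (1, 10_000_001, 0.49)])
        with pytest.raises(SelectionError):
            select_candidates(markers, SelectionParams(n_candidates=2))
        markers2 = mk_markers([(1, 1, 0.50), (1, 10_000_002, 0.49)])
        assert len(select_candidates(markers2, SelectionParams(n_candidates=2))) == 2


class TestPanelSubset:
    def test_full_subset_is_identity(self, panel200):
        out = panel_subset(panel200, len(panel200))
        assert set(out.marker_ids) == set(panel200.marker_ids)

    def test_subsets_are_nested_maf_prefixes(self, panel200):
        s70 = set(panel_subset(panel200, 70).marker_ids)
        s80 = set(panel_subset(panel200, 80).marker_ids)
        s160 = set(panel_subset(panel200, 160).marker_ids)
        assert s70 < s80 < s160
        # the 160-set contains the 160 highest-MAF candidates
        freq = dict(zip(panel200.marker_ids, panel200.freq_minor))
        cut = sorted(panel200.freq_minor)[::-1][159]
        assert all(freq[m] >= cut for m in s160)

    def test_out_of_range_rejected(self, panel200):
        with pytest.raises(ValueError):
            panel_subset(panel200, 0)
        with pytest.raises(ValueError):
            panel_subset(panel200, 201)


class TestFullPipeline:
    @pytest.fixture(scope="class")
    def selection(self, cohort):
        g, markers, genes, truth = cohort
        params = SelectionParams(n_candidates=50)
        panel, audit = run_selection(g, markers, genes, truth.subpop_labels, params)
        return g, markers, genes, truth, params, panel, audit

    def test_postconditions(self, selection):
        g, markers, genes, truth, params, panel, audit = selection
        assert len(panel) == 50
        for chrom in np.unique(panel.chrom):
            bp = panel.bp[panel.chrom == chrom]
            assert not genes.contains(int(chrom), bp).any()
            if len(bp) > 1:
                assert np.min(np.diff(np.sort(bp))) > params.min_spacing_bp
        # retained candidates satisfy QC on the retained samples
        id_to_col = {m: j for j, m in enumerate(markers.marker_ids)}
        cols = [id_to_col[m] for m in panel.marker_ids]
        sub = g.subset_markers(cols)
        _, call_rate, _ = allele_stats(sub)
        assert (call_rate >= 0.99).all()
        assert not (hwe_exact_matrix(sub) < 1e-5).any()

    def test_audit_remaining_counts_non_increasing(self, selection):
        *_, audit = selection
        for axis in ("markers", "samples"):
            remaining = [s[3] for s in audit.stages if s[1] == axis]
            assert remaining == sorted(remaining, reverse=True)

    def test_pipeline_is_deterministic(self, cohort):
        g, markers, genes, truth = cohort
        params = SelectionParams(n_candidates=50)
        p1, _ = run_selection(g, markers, genes, truth.subpop_labels, params)
        p2, _ = run_selection(g, markers, genes, truth.subpop_labels, params)
        assert p1.df.equals(p2.df)
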