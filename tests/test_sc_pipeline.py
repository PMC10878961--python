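import itertools

import numpy as np
import pytest

from iersig import (
    CellQC, ExpressionMatrix, GeneAnnotationTable, GeneSet, QCThresholds,
    combine_and_intersect, compute_cell_qc, gene_length_comparison,
    hto_demultiplex, phase_stratified_de, qc_filter, rank_sum_test, select_hvg,
    wilcoxon_de,
)
from iersig.core_io import MatrixError, log_normalize_cp10k
from iersig.sc_pipeline import DegRecord


def cell(cid="c", mito=0.02, feats=3000, counts=10_000, hto=100):
    return CellQC(cid, feats, counts, mito, hto)


class TestQcFilter:
    def test_mito_violation_attributed_first(self):
        kept, tally = qc_filter([cell(mito=0.07)])
        assert kept == [] and tally["mito_fraction"] == 1

    def test_boundary_values_kept(self):
        # exclusion rules fire strictly beyond the bounds
        kept, _ = qc_filter([cell(mito=0.06, feats=2000, counts=5000, hto=20)])
        assert kept == ["c"]
        kept, _ = qc_filter([cell(mito=0.06, feats=9000, counts=60000, hto=400)])
        assert kept == ["c"]

    def test_feature_violation(self):
        kept, tally = qc_filter([cell(mito=0.05, feats=1999)])
        assert kept == [] and tally["n_features"] == 1

    def test_tally_sums_to_excluded_and_order_independent(self):
        cells = [cell("a"), cell("b", mito=0.2), cell("d", counts=100),
                 cell("e", hto=500), cell("f", feats=100)]
        kept1, tally1 = qc_filter(cells)
        kept2, tally2 = qc_filter(cells[::-1])
        assert sorted(kept1) == sorted(kept2)
        assert tally1 == tally2
        assert sum(tally1.values()) == len(cells) - len(kept1)

    def test_worked_ten_cell_example(self):
        """One violation of each rule plus boundary cases: the survivor set
        and per-rule tally follow by hand from the exclusion rules."""
        cells = [
            cell("ok1"),
            cell("ok_low_edge", mito=0.06, feats=2000, counts=5000, hto=20),
            cell("ok_high_edge", feats=9000, counts=60000, hto=400),
            cell("bad_mito", mito=0.061),
            cell("bad_feat_low", feats=1999),
            cell("bad_feat_high", feats=9001),
            cell("bad_counts_low", counts=4999),
            cell("bad_counts_high", counts=60001),
            cell("bad_hto_low", hto=19),
            cell("bad_hto_high", hto=401),
        ]
        kept, tally = qc_filter(cells)
        assert kept == ["ok1", "ok_low_edge", "ok_high_edge"]
        assert tally == {"mito_fraction": 1, "n_features": 2,
                         "n_counts": 2, "hto_total": 2}


class TestComputeCellQc:
    def test_mito_prefix_case_insensitive(self):
        m = ExpressionMatrix(["mt-co1", "MT-nd1", "actb"], ["c1"],
                             np.array([[2.0], [3.0], [5.0]]))
        qc = compute_cell_qc(m)[0]
        assert qc.mito_fraction == pytest.approx(0.5)
        assert qc.n_features == 3 and qc.n_counts == 10


class TestHtoDemultiplex:
    def _hto(self, *cols):
        arr = np.array(cols, dtype=float).T
        return ExpressionMatrix([f"hto{i+1}" for i in range(arr.shape[0])],
                                [f"c{j}" for j in range(arr.shape[1])], arr)

    def test_clear_winner_assigned(self):
        out = hto_demultiplex(self._hto([300, 5, 2, 1]))
        assert out["c0"] == "hto1"

    def test_close_race_is_doublet(self):
        out = hto_demultiplex(self._hto([150, 140, 3, 2]))
        assert out["c0"] == "doublet"

    def test_low_total_is_negative(self):
        out = hto_demultiplex(self._hto([4, 3, 2, 1]))
        assert out["c0"] == "negative"

    def test_single_feature_rejected(self):
        m = ExpressionMatrix(["hto1"], ["c0"], np.array([[50.0]]))
        with pytest.raises(MatrixError, match="2 HTO"):
            hto_demultiplex(m)


class TestSelectHvg:
    def test_planted_high_dispersion_genes_recovered(self):
        rng = np.random.default_rng(12)
        n_genes, n_cells = 300, 150
        base = rng.lognormal(np.log(5.0), 0.4, n_genes)
        counts = rng.poisson(base[:, None], size=(n_genes, n_cells)).astype(float)
        # 10 genes at typical mean expression but strongly over-dispersed
        hot = rng.gamma(1.0, base[:10, None], size=(10, n_cells))
        counts[:10] = rng.poisson(hot)
        m = ExpressionMatrix([f"g{i}" for i in range(n_genes)],
                             [f"c{j}" for j in range(n_cells)], counts)
        hvg = select_hvg(m, n_top=50)
        assert set(f"g{i}" for i in range(10)) <= set(hvg)

    def test_zero_variance_gene_never_selected(self):
        # totals kept constant across cells so flat genes stay flat after
        # the per-cell normalization inside the selector
        vals = np.ones((5, 10))
        vals[0] = [4, 6] * 5
        vals[1] = [6, 4] * 5
        m = ExpressionMatrix([f"g{i}" for i in range(5)],
                             [f"c{j}" for j in range(10)], vals)
        hvg = select_hvg(m, n_top=2)
        assert set(hvg) == {"g0", "g1"}

    def test_deterministic(self):
        rng = np.random.default_rng(1)
        vals = rng.poisson(4.0, size=(50, 30)).astype(float) + 1
        m = ExpressionMatrix([f"g{i}" for i in range(50)],
                             [f"c{j}" for j in range(30)], vals)
        assert select_hvg(m, n_top=20) == select_hvg(m, n_top=20)

    def test_n_top_capped_with_warning(self):
        m = ExpressionMatrix(["g0", "g1"], ["c0", "c1", "c2"],
                             np.arange(6, dtype=float).reshape(2, 3) + 1)
        with pytest.warns(UserWarning, match="exceeds"):
            hvg = select_hvg(m, n_top=10)
        assert sorted(hvg) == ["g0", "g1"]


class TestRankSum:
    def test_exact_enumeration_values(self):
        u, p = rank_sum_test([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_groups_p_one(self):
        _, p = rank_sum_test([2, 2, 2], [2, 2, 2])
        assert p == 1.0

    def test_exact_and_asymptotic_agree_at_n15(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            x = rng.normal(0, 1, 15)
            y = rng.normal(0.3, 1, 15)
            _, p_exact = rank_sum_test(x, y, method="exact")
            _, p_asym = rank_sum_test(x, y, method="asymptotic")
            assert abs(p_exact - p_asym) < 0.02


class TestWilcoxonDe:
    def _matrix(self, n_genes=20, n_a=8, n_b=8, seed=0, effect_rows=(),
                effect=2.0):
        rng = np.random.default_rng(seed)
        counts = rng.poisson(8.0, size=(n_genes, n_a + n_b)).astype(float)
        for i in effect_rows:
            counts[i, :n_a] = rng.poisson(8.0 * effect, n_a)
        m = ExpressionMatrix([f"g{i}" for i in range(n_genes)],
                             [f"c{j}" for j in range(n_a + n_b)], counts)
        logm = log_normalize_cp10k(m)
        a = [f"c{j}" for j in range(n_a)]
        b = [f"c{j}" for j in range(n_a, n_a + n_b)]
        return logm, a, b

    def test_identical_gene_p_one_lfc_zero(self):
        logm, a, b = self._matrix()
        logm.values[0] = 1.0
        recs = wilcoxon_de(logm, a, b, ["g0"])
        assert recs[0].p == 1.0 and recs[0].log2_fc == 0.0

    def test_group_swap_flips_direction(self):
        logm, a, b = self._matrix(effect_rows=(1,), effect=3.0)
        r1 = wilcoxon_de(logm, a, b, [f"g{i}" for i in range(20)])
        r2 = wilcoxon_de(logm, b, a, [f"g{i}" for i in range(20)])
        for x, y in zip(r1, r2):
            assert x.p == pytest.approx(y.p, abs=1e-12)
            assert x.log2_fc == pytest.approx(-y.log2_fc, abs=1e-10)

    def test_planted_effect_detected(self):
        logm, a, b = self._matrix(n_a=30, n_b=30, effect_rows=(0, 1, 2),
                                  effect=4.0)
        recs = wilcoxon_de(logm, a, b, [f"g{i}" for i in range(20)])
        by_gene = {r.gene_id: r for r in recs}
        for g in ("g0", "g1", "g2"):
            assert by_gene[g].q < 0.05 and by_gene[g].direction == "up"

    def test_small_groups_rejected(self):
        logm, a, b = self._matrix()
        with pytest.raises(ValueError, match=">= 3"):
            wilcoxon_de(logm, a[:2], b, ["g0"])


class TestPhaseStratifiedDe:
    def test_phase_restricted_effect_found_only_in_that_phase(self):
        rng = np.random.default_rng(31)
        n = 60  # per group
        counts = rng.poisson(10.0, size=(15, 2 * n)).astype(float)
        phases = {}
        for j in range(2 * n):
            phases[f"c{j}"] = ["G1", "S", "G2M"][j % 3]
        # induce g0 in group A's G1 cells only
        for j in range(n):
            if phases[f"c{j}"] == "G1":
                counts[0, j] = rng.poisson(60.0)
        m = ExpressionMatrix([f"g{i}" for i in range(15)],
                             [f"c{j}" for j in range(2 * n)], counts)
        logm = log_normalize_cp10k(m)
        a = [f"c{j}" for j in range(n)]
        b = [f"c{j}" for j in range(n, 2 * n)]
        recs = phase_stratified_de(logm, a, b, phases,
                                   [f"g{i}" for i in range(15)])
        sig = {(r.phase, r.gene_id) for r in recs if r.q < 0.05}
        assert ("G1", "g0") in sig
        assert ("S", "g0") not in sig and ("G2M", "g0") not in sig

    def test_row_count_is_phases_times_genes(self):
        rng = np.random.default_rng(32)
        counts = rng.poisson(5.0, size=(6, 36)).astype(float) + 1
        phases = {f"c{j}": ["G1", "S", "G2M"][j % 3] for j in range(36)}
        m = ExpressionMatrix([f"g{i}" for i in range(6)],
                             [f"c{j}" for j in range(36)], counts)
        logm = log_normalize_cp10k(m)
        recs = phase_stratified_de(logm, [f"c{j}" for j in range(18)],
                                   [f"c{j}" for j in range(18, 36)], phases,
                                   [f"g{i}" for i in range(6)])
        assert len(recs) == 3 * 6

    def test_sparse_phase_skipped_with_warning(self):
        rng = np.random.default_rng(33)
        counts = rng.poisson(5.0, size=(4, 20)).astype(float) + 1
        phases = {f"c{j}": ("G1" if j != 0 else "G2M") for j in range(20)}
        m = ExpressionMatrix([f"g{i}" for i in range(4)],
                             [f"c{j}" for j in range(20)], counts)
        logm = log_normalize_cp10k(m)
        with pytest.warns(UserWarning, match="skipped"):
            recs = phase_stratified_de(logm, [f"c{j}" for j in range(10)],
                                       [f"c{j}" for j in range(10, 20)],
                                       phases, ["g0"])
        assert {r.phase for r in recs} == {"G1"}


def rec(gene, lfc, q, contrast, phase="G1"):
    return DegRecord(gene, lfc, q / 2, q, "up" if lfc > 0 else "down",
                     contrast, phase)


class TestCombineAndIntersect:
    def test_basic_set_algebra(self):
        a = [rec("gA", 2.0, 0.01, "37_vs_ice"),
             rec("gB", 1.5, 0.01, "37_vs_ice"),
             rec("gC", -1.0, 0.01, "37_vs_ice"),
             rec("gD", 1.0, 0.9, "37_vs_ice")]
        b = [rec("gA", 0.1, 0.9, "37tp_vs_ice"),
             rec("gB", 1.2, 0.01, "37tp_vs_ice"),
             rec("gC", 0.2, 0.9, "37tp_vs_ice"),
             rec("gD", 3.0, 0.01, "37tp_vs_ice")]
        inter = combine_and_intersect(a, b)
        assert inter.up_37_only == {"gA"}
        assert inter.up_shared == {"gB"}
        assert inter.up_37tp_only == {"gD"}
        assert inter.down_37_only == {"gC"}

    def test_conflicting_phase_directions_dropped(self):
        a = [rec("gA", 2.0, 0.01, "c1", "G1"), rec("gA", -2.0, 0.01, "c1", "S")]
        b = [rec("gA", 0.0, 0.9, "c2", "G1"), rec("gA", 0.0, 0.9, "c2", "S")]
        with pytest.warns(UserWarning, match="opposite"):
            inter = combine_and_intersect(a, b)
        assert "gA" not in inter.up_37_only | inter.down_37_only

    def test_up_sets_pairwise_disjoint(self):
        rng = np.random.default_rng(41)
        genes = [f"g{i}" for i in range(30)]
        a = [rec(g, rng.normal(), float(rng.random()), "c1") for g in genes]
        b = [rec(g, rng.normal(), float(rng.random()), "c2") for g in genes]
        inter = combine_and_intersect(a, b, q_threshold=0.3)
        assert not (inter.up_37_only & inter.up_shared)
        assert not (inter.up_37_only & inter.up_37tp_only)
        assert not (inter.down_37_only & inter.down_shared)

    def test_different_universes_rejected(self):
        with pytest.raises(ValueError, match="universes"):
            combine_and_intersect([rec("gA", 1.0, 0.01, "c1")],
                                  [rec("gB", 1.0, 0.01, "c2")])


class TestGeneLengthComparison:
    def _ann(self, lengths):
        return GeneAnnotationTable({f"g{i}": l for i, l in enumerate(lengths)})

    def test_exact_u_and_p(self):
        ann = self._ann([1, 2, 3, 4])
        res = gene_length_comparison(["g0", "g1"], ["g2", "g3"], ann)
        assert res.u_statistic == 0.0
        assert res.p_two_sided == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_multisets_p_one(self):
        ann = self._ann([5, 5, 5, 5])
        res = gene_length_comparison(["g0", "g1"], ["g2", "g3"], ann)
        assert res.p_two_sided == 1.0

    def test_quartiles_match_order_statistics_on_seven_values(self):
        lengths = [100, 200, 300, 400, 500, 600, 700]
        ann = self._ann(lengths + [10, 20])
        res = gene_length_comparison([f"g{i}" for i in range(7)],
                                     ["g7", "g8"], ann)
        s = res.group_a
        assert s.median == 400
        assert s.q25 == np.quantile(np.array(lengths, float), 0.25)
        assert s.q75 == np.quantile(np.array(lengths, float), 0.75)
        assert (s.min, s.max) == (100, 700)

    def test_unannotated_genes_dropped_and_counted(self):
        ann = self._ann([1, 2, 3, 4])
        res = gene_length_comparison(["g0", "g1", "missing"], ["g2", "g3"], ann)
        assert res.n_dropped_a == 1

    def test_short_vs_long_groups_detected(self):
        rng = np.random.default_rng(55)
        short = np.exp(rng.normal(np.log(2000), 0.5, 60))
        long_ = np.exp(rng.normal(np.log(20000), 0.5, 60))
        ann = GeneAnnotationTable(
            {f"s{i}": int(v) + 1 for i, v in enumerate(short)}
            | {f"l{i}": int(v) + 1 for i, v in enumerate(long_)}
        )
        res = gene_length_comparison([f"s{i}" for i in range(60)],
                                     [f"l{i}" for i in range(60)], ann)
        assert res.group_a.median < res.group_b.median
        assert res.p_two_sided < 1e-3
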