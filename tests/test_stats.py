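"""Spearman and rank-sum statistics against hand and enumeration oracles."""

import itertools

import numpy as np
import pytest

from mritexture.stats import (
    StatRecord,
    correlation_matrix_table,
    count_significant,
    high_correlation_abs_r,
    ranksum_disease_vs_control,
    spearman_feature_volume,
)

from _oracles import oracle_ranksum_p


class TestSpearman:
    def test_perfect_monotone(self):
        rec = spearman_feature_volume([10, 20, 30], [1, 2, 3])
        assert rec.value == pytest.approx(1.0)
        assert not rec.degenerate

    def test_perfect_antitone(self):
        rec = spearman_feature_volume([30, 20, 10], [1, 2, 3])
        assert rec.value == pytest.approx(-1.0)

    def test_tied_values_average_ranks_hand_computation(self):
        # volumes (1,2,3,4,5); feature (5, 7, 7, 9, 12): ranks of the
        # feature are (1, 2.5, 2.5, 4, 5); Pearson of ranks vs (1..5):
        volumes = np.array([1.0, 2, 3, 4, 5])
        feature = np.array([5.0, 7, 7, 9, 12])
        fr = np.array([1.0, 2.5, 2.5, 4, 5])
        vr = np.array([1.0, 2, 3, 4, 5])
        expected = np.corrcoef(fr, vr)[0, 1]
        rec = spearman_feature_volume(feature, volumes)
        assert rec.value == pytest.approx(expected, rel=1e-12)

    def test_constant_inputs_flagged_degenerate(self):
        rec = spearman_feature_volume([5, 5, 5, 5], [1, 2, 3, 4])
        assert rec.degenerate
        assert np.isnan(rec.value)

    def test_r_squared(self):
        rec = spearman_feature_volume([30, 20, 10], [1, 2, 3])
        assert rec.r_squared == pytest.approx(1.0)

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError):
            spearman_feature_volume([1, 2], [1, 2])


class TestRankSum:
    def test_separated_pairs_exact_third(self):
        rec = ranksum_disease_vs_control([1, 2], [3, 4])
        assert rec.value == pytest.approx(1 / 3)

    def test_identical_constant_samples_p_one(self):
        rec = ranksum_disease_vs_control([5, 5], [5, 5])
        assert rec.value == 1.0
        assert rec.degenerate

    def test_exact_branch_matches_permutation_enumeration(self, rng):
        """Tie-free samples with n1, n2 <= 5 reproduce full enumeration."""
        for n1, n2 in itertools.product(range(2, 6), range(2, 6)):
            for _ in range(3):
                pooled = rng.permutation(rng.uniform(0, 100, size=n1 + n2))
                x, y = pooled[:n1], pooled[n1:]
                rec = ranksum_disease_vs_control(x, y)
                assert rec.value == pytest.approx(
                    oracle_ranksum_p(x, y), rel=1e-12
                ), (n1, n2)

    def test_large_samples_use_corrected_normal_approximation(self, rng):
        x = rng.normal(0, 1, size=30)
        y = rng.normal(0.2, 1, size=28)
        rec = ranksum_disease_vs_control(x, y)
        assert 0 < rec.value <= 1
        # ties force the asymptotic branch even for small n
        rec_tied = ranksum_disease_vs_control([1, 2, 2], [2, 3, 4])
        assert 0 < rec_tied.value <= 1

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            ranksum_disease_vs_control([1], [2, 3])


def _ranksum_record(p, method="AR", param=50.0, seg="elliptical",
                    feature="glcm_Contrast", degenerate=False):
    return StatRecord(feature=feature, method=method, param=param,
                      segmentation=seg, kind="ranksum_p", value=p,
                      n_observations=10, degenerate=degenerate)


class TestSignificanceCounting:
    def test_all_below_alpha(self):
        recs = [_ranksum_record(0.01) for _ in range(240)]
        (summary,) = count_significant(recs)
        assert summary.n_tests == 240
        assert summary.n_significant == 240

    def test_boundary_p_is_not_significant(self):
        (summary,) = count_significant([_ranksum_record(0.05)])
        assert summary.n_significant == 0

    def test_degenerate_records_never_significant(self):
        recs = [_ranksum_record(0.001, degenerate=True),
                _ranksum_record(0.001)]
        (summary,) = count_significant(recs)
        assert summary.n_tests == 2 and summary.n_significant == 1

    def test_mixed_table_matches_recount(self, rng):
        ps = rng.uniform(0, 1, size=500)
        recs = [_ranksum_record(float(p)) for p in ps]
        (summary,) = count_significant(recs, alpha=0.05)
        assert summary.n_significant == int((ps < 0.05).sum())

    def test_grouping_by_method_param_segmentation(self):
        recs = [_ranksum_record(0.01, method="AR", param=50.0),
                _ranksum_record(0.01, method="LRR", param=64.0),
                _ranksum_record(0.5, method="LRR", param=64.0)]
        summaries = count_significant(recs)
        assert len(summaries) == 2
        by_method = {s.method: s for s in summaries}
        assert by_method["AR"].n_tests == 1
        assert by_method["LRR"].n_tests == 2
        assert by_method["LRR"].n_significant == 1


class TestCorrelationTable:
    def _records(self):
        recs = []
        groups = ["IS-path", "IS-ctrl", "MS-path", "MS-ctrl", "TU-path",
                  "TU-ctrl"]
        rng = np.random.default_rng(3)
        for feat in [f"f{i}" for i in range(40)]:
            for g in groups:
                for contrast in ("T1", "T2"):
                    recs.append(StatRecord(
                        feature=feat, group=g, contrast=contrast,
                        segmentation="elliptical", method="AR", param=50.0,
                        kind="spearman_rho",
                        value=float(rng.uniform(-1, 1)),
                        n_observations=20,
                    ))
        return recs

    def test_full_design_has_480_cells(self):
        table = correlation_matrix_table(self._records())
        assert table.shape == (40, 12)
        assert table.size == 480
        assert table.notna().all().all()

    def test_r_squared_values(self):
        recs = self._records()
        table = correlation_matrix_table(recs)
        r = recs[0]
        assert table.loc[r.feature, f"{r.group}_{r.contrast}"] == pytest.approx(
            r.value**2
        )

    def test_high_correlation_threshold(self):
        assert high_correlation_abs_r() == pytest.approx(np.sqrt(0.5))
        assert round(high_correlation_abs_r(), 2) == 0.71

    def test_mixed_cells_rejected(self):
        recs = self._records()
        recs[0].method = "LRR"
        recs[0].param = 64.0
        with pytest.raises(ValueError):
            correlation_matrix_table(recs)

    def test_degenerate_cells_emitted_as_nan(self):
        recs = self._records()
        recs[5].degenerate = True
        table = correlation_matrix_table(recs)
        r = recs[5]
        assert np.isnan(table.loc[r.feature, f"{r.group}_{r.contrast}"])


class TestVolumeNullUniformity:
    def test_spearman_pvalues_uniform_when_texture_volume_free(self):
        """With lesion texture independent of lesion size, pooled Spearman
        feature-volume p-values of the GLCM indices under fixed-bin-size
        discretization are close to uniform (Kolmogorov distance < 0.1)."""
        from mritexture.experiments import spearman_volume_null

        res = spearman_volume_null(master_seed=9, n_seeds=28)
        assert res["n_tests"] >= 1000
        assert res["ks_distance"] < 0.1
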