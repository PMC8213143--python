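"""Texture-index formulas: hand examples, degenerate fallbacks, oracles."""

import numpy as np
import pytest

from mritexture.discretization import discretize_ar, discretize_lar
from mritexture.features import (
    ALL_FEATURES,
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    extract_all,
    glcm_features,
    glrlm_features,
    glszm_features,
)
from mritexture.matrices import build_glcm, build_glrlm, build_glszm

from _oracles import (
    oracle_glcm,
    oracle_glcm_features,
    oracle_glrlm,
    oracle_glszm,
    oracle_rlm_features,
)
from conftest import dv_from_grid, random_level_grid


class TestRoster:
    def test_forty_features_in_three_families(self):
        assert len(GLCM_FEATURES) == 18
        assert len(GLRLM_FEATURES) == 11
        assert len(GLSZM_FEATURES) == 11
        assert len(ALL_FEATURES) == 40
        assert len(set(ALL_FEATURES)) == 40

    def test_extract_all_order_and_prefixes(self, rng):
        dv = dv_from_grid(random_level_grid(rng))
        feats = extract_all(dv)
        assert list(feats) == list(ALL_FEATURES)
        assert sum(k.startswith("glcm_") for k in feats) == 18
        assert sum(k.startswith("glrlm_") for k in feats) == 11
        assert sum(k.startswith("glszm_") for k in feats) == 11
        assert all(np.isfinite(v) for v in feats.values())


class TestGLCMHandValues:
    def test_three_entry_matrix(self):
        dv = dv_from_grid([[1, 1], [1, 2]])
        f = glcm_features(build_glcm(dv, directions=((0, 1),)))
        assert f["JMax"] == pytest.approx(0.5)
        assert f["Dissim"] == pytest.approx(0.5)
        assert f["Contrast"] == pytest.approx(0.5)

    def test_constant_voi_point_mass(self):
        dv = dv_from_grid(np.ones((3, 3, 3), dtype=int))
        f = glcm_features(build_glcm(dv))
        assert f["JMax"] == 1.0
        assert f["JEntropy"] == 0.0
        assert f["Dissim"] == 0.0
        assert f["Contrast"] == 0.0
        assert f["AngularSecondMoment"] == 1.0
        # degenerate fallbacks: zero-variance correlation, NormInvDiff = 1
        assert f["Correlation"] == 0.0
        assert f["NormInvDiff"] == 1.0

    def test_entropies_nonnegative(self, rng):
        for _ in range(10):
            f = glcm_features(build_glcm(dv_from_grid(random_level_grid(rng))))
            assert f["JEntropy"] >= 0
            assert f["DifferenceEntropy"] >= 0
            assert f["SumEntropy"] >= 0


class TestRunAndZonePercentages:
    def test_rp_from_hand_run_decomposition(self):
        dv = dv_from_grid([[1, 1, 1, 2]])
        f = glrlm_features(build_glrlm(dv, directions=((0, 1),)))
        assert f["RP"] == pytest.approx(2 / 4)

    def test_rp_constant_row(self):
        dv = dv_from_grid([[5, 5, 5, 5, 5, 5]])
        f = glrlm_features(build_glrlm(dv, directions=((0, 1),)))
        assert f["RP"] == pytest.approx(1 / 6)

    def test_rp_alternating_row_is_one(self):
        dv = dv_from_grid([[1, 2, 1, 2]])
        f = glrlm_features(build_glrlm(dv, directions=((0, 1),)))
        assert f["RP"] == pytest.approx(1.0)

    def test_zp_hand_example(self):
        dv = dv_from_grid([[1, 1], [2, 1]])
        f = glszm_features(build_glszm(dv))
        assert f["ZP"] == pytest.approx(2 / 4)

    def test_zp_constant_voi(self):
        dv = dv_from_grid(np.full((2, 2, 2), 3))
        f = glszm_features(build_glszm(dv))
        assert f["ZP"] == pytest.approx(1 / 8)

    def test_percentages_in_unit_interval(self, rng):
        for _ in range(10):
            dv = dv_from_grid(random_level_grid(rng))
            assert 0 < glrlm_features(build_glrlm(dv))["RP"] <= 1
            assert 0 < glszm_features(build_glszm(dv))["ZP"] <= 1


class TestOracleEquivalence:
    """All 40 formulas agree with naive loop evaluation to 1e-12 relative."""

    def _assert_close(self, mine, oracle):
        for name, v in oracle.items():
            m = mine[name]
            assert m == pytest.approx(v, rel=1e-12, abs=1e-12), name

    def test_glcm_features_random(self, rng):
        for _ in range(50):
            grid = random_level_grid(rng)
            mine = glcm_features(build_glcm(dv_from_grid(grid)))
            self._assert_close(mine, oracle_glcm_features(oracle_glcm(grid)))

    def test_glrlm_features_random(self, rng):
        for _ in range(50):
            grid = random_level_grid(rng)
            m = build_glrlm(dv_from_grid(grid))
            oracle = oracle_rlm_features(
                oracle_glrlm(grid), m.n_voxels, m.n_directions, "rlm"
            )
            self._assert_close(glrlm_features(m), oracle)

    def test_glszm_features_random(self, rng):
        for _ in range(50):
            grid = random_level_grid(rng)
            m = build_glszm(dv_from_grid(grid))
            oracle = oracle_rlm_features(
                oracle_glszm(grid), m.n_voxels, 1, "szm"
            )
            self._assert_close(glszm_features(m), oracle)

    def test_end_to_end_pipeline_matches_oracle(self, rng):
        """extract_all == naive matrices + naive formulas on random VOIs."""
        for _ in range(30):
            grid = random_level_grid(rng)
            feats = extract_all(dv_from_grid(grid))
            og = oracle_glcm_features(oracle_glcm(grid))
            orl = oracle_rlm_features(oracle_glrlm(grid), int((grid > 0).sum()),
                                      13 if grid.ndim == 3 else 4, "rlm")
            osz = oracle_rlm_features(oracle_glszm(grid), int((grid > 0).sum()),
                                      1, "szm")
            for name, v in {**{f"glcm_{k}": x for k, x in og.items()},
                            **{f"glrlm_{k}": x for k, x in orl.items()},
                            **{f"glszm_{k}": x for k, x in osz.items()}}.items():
                assert feats[name] == pytest.approx(v, rel=1e-12, abs=1e-12), name


class TestInvariances:
    def test_permutation_of_lattice_labels_irrelevant(self, rng):
        """Features depend only on geometry + levels, not voxel visit order."""
        grid = random_level_grid(rng, max_side=4)
        feats1 = extract_all(dv_from_grid(grid))
        feats2 = extract_all(dv_from_grid(np.ascontiguousarray(grid[::-1])))
        # mirroring the lattice preserves all pair/run/zone statistics
        for name in feats1:
            assert feats1[name] == pytest.approx(feats2[name], rel=1e-12)

    def test_translation_invariant_features_agree_between_ar_and_lar(self, rng):
        """With no intensity exactly on a bin edge, AR and LAR level arrays
        differ by the constant floor(i_min/B), so level-translation-invariant
        features (Contrast, Dissim, entropies) agree exactly."""
        B = 10.0
        x = np.sort(rng.uniform(0, 15, size=27)) + 0.01
        x = x - x.min() + 3 * B + 0.37  # anchored just above 3B, off-edge
        vol = x.reshape(3, 3, 3)
        mask = np.ones((3, 3, 3), dtype=bool)
        dv_ar = discretize_ar(vol[mask], B)
        dv_lar = discretize_lar(vol[mask], B)
        dv_ar.mask = mask
        dv_lar.mask = mask
        diff = dv_ar.grey_levels - dv_lar.grey_levels
        assert np.all(diff == diff[0])
        f_ar = glcm_features(build_glcm(dv_ar))
        f_lar = glcm_features(build_glcm(dv_lar))
        for name in ("Contrast", "Dissim", "JEntropy", "JVar"):
            assert f_ar[name] == pytest.approx(f_lar[name], rel=1e-12)
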