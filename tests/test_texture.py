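import itertools

import numpy as np
import pytest

from pettex import (
    DIRECTIONS,
    AR20,
    RR_SPEC,
    DegenerateTextureError,
    SUV,
    VOIMask,
    VolumeGrid,
    build_cm,
    build_grlm,
    build_gzlm,
    build_matrices,
    cm_indices,
    direction_set,
    extract_ti,
    grlm_indices,
    gzlm_indices,
    sphere_voi,
)
from pettex.resampling import ResampledVOI, ResamplingSpec

from _bruteforce import (
    bf_cm,
    bf_cm_indices,
    bf_directions,
    bf_grlm_indices,
    bf_gzlm_indices,
    bf_runs,
    bf_zones,
)


def rv_from(levels, mask, D=64):
    return ResampledVOI(
        levels[mask], ResamplingSpec("rr", levels=D), 0.0, 1.0
    )


def row_case():
    """The 1x1x3 row with levels [1, 1, 2] used as a hand oracle."""
    levels = np.array([[[1, 1, 2]]], dtype=np.int64)
    mask = np.ones((1, 1, 3), dtype=bool)
    return levels, mask


class TestDirections:
    def test_thirteen_sign_free_directions(self):
        dirs = direction_set()
        assert len(dirs) == 13
        as_set = set(dirs)
        assert len(as_set) == 13
        for d in dirs:
            assert tuple(-c for c in d) not in as_set
            assert max(abs(c) for c in d) == 1

    def test_matches_independent_enumeration(self):
        assert set(DIRECTIONS) == {tuple(d) for d in bf_directions()} or \
            {frozenset((d, tuple(-c for c in d))) for d in DIRECTIONS} == \
            {frozenset((d, tuple(-c for c in d))) for d in bf_directions()}


class TestCoOccurrence:
    def test_row_hand_enumeration(self):
        levels, mask = row_case()
        cms = build_cm(levels, mask)
        d_idx = DIRECTIONS.index((0, 0, 1))
        m = cms[d_idx]
        # symmetric counts {(1,1):2, (1,2):1, (2,1):1} -> probabilities
        assert m[0, 0] == pytest.approx(0.5)
        assert m[0, 1] == pytest.approx(0.25)
        assert m[1, 0] == pytest.approx(0.25)
        homo, ent, contr = cm_indices([m])
        assert homo == pytest.approx(0.75)
        assert ent == pytest.approx(1.5)
        assert contr == pytest.approx(0.5)

    def test_constant_voi_all_mass_on_diagonal(self):
        levels = np.full((3, 3, 3), 4, dtype=np.int64)
        mask = np.ones((3, 3, 3), dtype=bool)
        cms = build_cm(levels, mask)
        for m in cms:
            assert m is not None
            assert m[3, 3] == pytest.approx(1.0)
            assert m.sum() == pytest.approx(1.0)
        homo, ent, contr = cm_indices(cms)
        assert (homo, ent, contr) == pytest.approx((1.0, 0.0, 0.0))

    def test_single_voxel_is_degenerate(self):
        levels = np.array([[[3]]], dtype=np.int64)
        mask = np.ones((1, 1, 1), dtype=bool)
        cms = build_cm(levels, mask)
        assert all(m is None for m in cms)
        with pytest.raises(DegenerateTextureError):
            cm_indices(cms)

    def test_homogeneity_at_most_one(self, rng):
        for _ in range(10):
            levels = rng.integers(1, 5, size=(4, 4, 4))
            mask = np.ones((4, 4, 4), dtype=bool)
            homo, _, _ = cm_indices(build_cm(levels, mask))
            assert homo <= 1.0 + 1e-12


class TestRunLength:
    def test_row_hand_enumeration(self):
        levels, mask = row_case()
        grlms = build_grlm(levels, mask)
        d_idx = DIRECTIONS.index((0, 0, 1))
        g = g_row = grlms[d_idx]
        # runs {(level 1, len 2), (level 2, len 1)}
        assert g[0, 1] == 1 and g[1, 0] == 1 and g.sum() == 2
        sre, lre, rlnu = grlm_indices([g_row])
        assert sre == pytest.approx(0.625)
        assert lre == pytest.approx(2.5)
        assert rlnu == pytest.approx(1.0)

    def test_constant_row_single_run(self):
        n = 7
        levels = np.ones((1, 1, n), dtype=np.int64)
        mask = np.ones((1, 1, n), dtype=bool)
        grlms = build_grlm(levels, mask)
        along = grlms[DIRECTIONS.index((0, 0, 1))]
        assert along[0, n - 1] == 1 and along.sum() == 1
        sre, lre, _ = grlm_indices([along])
        assert sre == pytest.approx(1 / n**2)
        assert lre == pytest.approx(n**2)
        orthogonal = grlms[DIRECTIONS.index((1, 0, 0))]
        assert orthogonal[0, 0] == n and orthogonal.sum() == n

    def test_all_runs_length_one_closed_form(self):
        levels = np.indices((4, 4, 4)).sum(axis=0) % 2 + 1  # 3D checkerboard
        mask = np.ones((4, 4, 4), dtype=bool)
        axial = [build_grlm(levels, mask)[DIRECTIONS.index(d)]
                 for d in ((1, 0, 0), (0, 1, 0), (0, 0, 1))]
        for g in axial:
            h = g.sum()
            sre, lre, rlnu = grlm_indices([g])
            assert sre == 1.0 and lre == 1.0
            assert rlnu == pytest.approx(h)

    def test_run_mass_equals_voxel_count(self, rng):
        levels = rng.integers(1, 4, size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.7
        mask[2, 2, 2] = True
        for g in build_grlm(levels, mask):
            j = np.arange(1, g.shape[1] + 1)
            assert (g * j).sum() == mask.sum()


class TestZones:
    def test_row_hand_enumeration(self):
        levels, mask = row_case()
        z = build_gzlm(levels, mask)
        assert z[0, 1] == 1 and z[1, 0] == 1 and z.sum() == 2
        lgze, hgze = gzlm_indices(z)
        assert lgze == pytest.approx(0.625)
        assert hgze == pytest.approx(2.5)

    def test_constant_voi_single_zone(self):
        g = 5
        levels = np.full((3, 3, 3), g, dtype=np.int64)
        mask = np.ones((3, 3, 3), dtype=bool)
        z = build_gzlm(levels, mask)
        assert z.sum() == 1 and z[g - 1, 26] == 1
        lgze, hgze = gzlm_indices(z)
        assert lgze == pytest.approx(1 / g**2)
        assert hgze == pytest.approx(g**2)

    def test_checkerboard_two_diagonal_zones_under_26_connectivity(self):
        levels = (np.indices((4, 4, 4)).sum(axis=0) % 2 + 1).astype(np.int64)
        mask = np.ones((4, 4, 4), dtype=bool)
        z = build_gzlm(levels, mask, connectivity=26)
        assert z.sum() == 2  # each parity class is one diagonal-connected zone
        z6 = build_gzlm(levels, mask, connectivity=6)
        assert z6.sum() == 64  # under 6-connectivity every voxel is isolated

    def test_doubling_gray_levels_scales_hgze_by_four(self, rng):
        levels = rng.integers(1, 5, size=(4, 4, 4))
        mask = np.ones((4, 4, 4), dtype=bool)
        _, hgze1 = gzlm_indices(build_gzlm(levels, mask))
        _, hgze2 = gzlm_indices(build_gzlm(levels * 2, mask))
        assert hgze2 == pytest.approx(4 * hgze1)

    def test_zone_mass_conservation(self, rng):
        levels = rng.integers(1, 4, size=(5, 5, 5))
        mask = rng.random((5, 5, 5)) < 0.6
        mask[2, 2, 2] = True
        z = build_gzlm(levels, mask)
        j = np.arange(1, z.shape[1] + 1)
        assert (z * j).sum() == mask.sum()


class TestBruteForceEquivalence:
    """The vectorized engine must agree with explicit-loop oracles."""

    N_CASES = 60  # per-module check; the acceptance suite runs 200

    def test_matrices_and_indices_match_oracle(self, rng):
        for _ in range(self.N_CASES):
            levels = rng.integers(1, 6, size=(4, 4, 4))
            mask = rng.random((4, 4, 4)) < 0.7
            if mask.sum() < 2:
                mask[0, 0, 0] = mask[0, 0, 1] = True
            cms = build_cm(levels, mask)
            grlms = build_grlm(levels, mask)
            gz = build_gzlm(levels, mask)
            all_runs = []
            kept_cms = []
            for d_idx, d in enumerate(DIRECTIONS):
                prob = bf_cm(levels, mask, d)
                if not prob:
                    assert cms[d_idx] is None
                else:
                    m = cms[d_idx]
                    dense = {}
                    for i in range(m.shape[0]):
                        for j in range(m.shape[1]):
                            if m[i, j] > 0:
                                dense[(i + 1, j + 1)] = m[i, j]
                    assert set(dense) == set(prob)
                    for key in prob:
                        assert dense[key] == pytest.approx(prob[key], abs=1e-12)
                    kept_cms.append(m)
                runs = bf_runs(levels, mask, d)
                g = grlms[d_idx]
                counts = {}
                for lev, ln in runs:
                    counts[(lev, ln)] = counts.get((lev, ln), 0) + 1
                for (lev, ln), c in counts.items():
                    assert g[lev - 1, ln - 1] == c
                assert g.sum() == len(runs)
                all_runs.append(runs)
            # index-level agreement, direction-averaged
            homo, ent, contr = cm_indices(cms)
            bf_vals = [bf_cm_indices(bf_cm(levels, mask, d))
                       for d in DIRECTIONS if bf_cm(levels, mask, d)]
            assert homo == pytest.approx(np.mean([v[0] for v in bf_vals]), abs=1e-12)
            assert ent == pytest.approx(np.mean([v[1] for v in bf_vals]), abs=1e-12)
            assert contr == pytest.approx(np.mean([v[2] for v in bf_vals]), abs=1e-12)
            sre, lre, rlnu = grlm_indices(grlms)
            bf_rl = [bf_grlm_indices(r) for r in all_runs]
            assert sre == pytest.approx(np.mean([v[0] for v in bf_rl]), abs=1e-12)
            assert lre == pytest.approx(np.mean([v[1] for v in bf_rl]), abs=1e-12)
            assert rlnu == pytest.approx(np.mean([v[2] for v in bf_rl]), abs=1e-12)
            zones = bf_zones(levels, mask)
            zcounts = {}
            for g_, s_ in zones:
                zcounts[(g_, s_)] = zcounts.get((g_, s_), 0) + 1
            for (g_, s_), c in zcounts.items():
                assert gz[g_ - 1, s_ - 1] == c
            assert gz.sum() == len(zones)
            lgze, hgze = gzlm_indices(gz)
            bf_l, bf_h = bf_gzlm_indices(zones)
            assert lgze == pytest.approx(bf_l, abs=1e-12)
            assert hgze == pytest.approx(bf_h, abs=1e-12)


class TestLatticeSymmetry:
    def test_direction_averaged_indices_invariant_under_symmetries(self, rng):
        levels = rng.integers(1, 5, size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) < 0.8
        mask[1, 1, 1] = True
        ref_cm = cm_indices(build_cm(levels, mask))
        ref_rl = grlm_indices(build_grlm(levels, mask))
        for perm in itertools.permutations(range(3)):
            for flips in itertools.product([False, True], repeat=3):
                lv = np.transpose(levels, perm)
                mk = np.transpose(mask, perm)
                for ax, f in enumerate(flips):
                    if f:
                        lv = np.flip(lv, axis=ax)
                        mk = np.flip(mk, axis=ax)
                got_cm = cm_indices(build_cm(np.ascontiguousarray(lv),
                                             np.ascontiguousarray(mk)))
                got_rl = grlm_indices(build_grlm(np.ascontiguousarray(lv),
                                                 np.ascontiguousarray(mk)))
                assert got_cm == pytest.approx(ref_cm, abs=1e-10)
                assert got_rl == pytest.approx(ref_rl, abs=1e-10)


class TestExtractTi:
    def test_rr_and_ar_share_suvmax_and_mv(self, suv_cube):
        vol, mask = suv_cube
        rr = extract_ti(vol, mask, RR_SPEC)
        ar = extract_ti(vol, mask, AR20)
        assert rr.suvmax == ar.suvmax == vol.values[mask.mask].max()
        assert rr.mv == ar.mv
        assert rr.n_voxels == ar.n_voxels == mask.voxel_count

    def test_rr_invariant_ar_sensitive_to_intensity_scaling(self, suv_cube):
        vol, mask = suv_cube
        doubled = VolumeGrid(vol.values * 2, vol.spacing, unit=SUV)
        rr1, rr2 = extract_ti(vol, mask, RR_SPEC), extract_ti(doubled, mask, RR_SPEC)
        ar1, ar2 = extract_ti(vol, mask, AR20), extract_ti(doubled, mask, AR20)
        for name in ("homogeneity", "entropy", "contrast", "sre", "lre",
                     "rlnu", "lgze", "hgze"):
            assert getattr(rr1, name) == pytest.approx(getattr(rr2, name))
        assert ar2.suvmax == pytest.approx(2 * ar1.suvmax)
        assert ar1.entropy != pytest.approx(ar2.entropy)

    def test_sre_at_most_one_at_most_lre(self, rng):
        for _ in range(5):
            values = rng.gamma(3.0, 1.5, size=(6, 6, 6))
            vol = VolumeGrid(values, (4, 4, 4), unit=SUV)
            mask = sphere_voi(vol, (3, 3, 3), 5)
            ti = extract_ti(vol, mask, RR_SPEC)
            assert ti.sre <= 1.0 + 1e-12 <= ti.lre + 2e-12

    def test_matrix_bundle_consistency(self, suv_cube):
        vol, mask = suv_cube
        from pettex.resampling import resample

        rv = resample(vol.values[mask.mask], RR_SPEC)
        mats = build_matrices(rv, mask)
        assert mats.voxel_count == mask.voxel_count
        j = np.arange(1, mats.gzlm.shape[1] + 1)
        assert (mats.gzlm * j).sum() == mask.voxel_count
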