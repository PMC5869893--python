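"""DVH metrics against a sorted-array oracle; protocol checker; EQD2."""

import numpy as np
import pandas as pd
import pytest

from lexiplan import evaluation as ev
from lexiplan.errors import GridMismatchError, StructureError
from lexiplan.grid import StructureSet, VoxelGrid
from lexiplan.wishlist import PrescriptionContext


@pytest.fixture
def grid():
    return VoxelGrid((10, 10, 10), (2.0, 2.0, 2.0))


@pytest.fixture
def full(grid):
    return np.ones(grid.shape, bool)


def sorted_oracle_dq(d, q):
    """D_q% by explicit sorting + linear interpolation (numpy-free logic)."""
    s = np.sort(np.asarray(d).ravel())          # ascending
    # dose to the hottest q% == (100-q)th percentile
    pos = (100.0 - q) / 100.0 * (s.size - 1)
    lo, hi = int(np.floor(pos)), int(np.ceil(pos))
    frac = pos - lo
    return s[lo] * (1 - frac) + s[hi] * frac


class TestDoseVolume:
    def test_uniform_field_quantiles(self, grid, full):
        d = np.full(grid.shape, 60.0)
        assert ev.d_at_volume(d, full, 2) == 60.0
        assert ev.d_at_volume(d, full, 98) == 60.0

    def test_linear_ramp_against_oracle(self, grid, full, rng):
        d = np.linspace(50, 70, grid.n_voxels).reshape(grid.shape)
        for q in (2, 50, 98, 30.5):
            assert ev.d_at_volume(d, full, q) == pytest.approx(
                sorted_oracle_dq(d, q), rel=1e-12)

    def test_random_field_against_oracle(self, grid, full, rng):
        d = rng.uniform(0, 80, grid.shape)
        for q in (2, 50, 95, 98):
            assert ev.d_at_volume(d, full, q) == pytest.approx(
                sorted_oracle_dq(d, q), rel=1e-12)

    def test_quantile_ordering_invariant(self, grid, full, rng):
        d = rng.uniform(0, 80, grid.shape)
        d2, d50, d98 = (ev.d_at_volume(d, full, q) for q in (2, 50, 98))
        assert d98 <= d50 <= d2 <= d.max()

    def test_v_at_dose(self, grid, full):
        d = np.full(grid.shape, 50.0)
        assert ev.v_at_dose(d, full, 60.0) == 0.0
        assert ev.v_at_dose(d, full, 50.0) == 100.0
        d.ravel()[:100] = 70.0
        assert ev.v_at_dose(d, full, 60.0) == pytest.approx(10.0)

    def test_v_monotone_in_threshold(self, grid, full, rng):
        d = rng.uniform(0, 80, grid.shape)
        vols = [ev.v_at_dose(d, full, t) for t in np.linspace(0, 80, 17)]
        assert all(a >= b for a, b in zip(vols, vols[1:]))

    def test_total_irradiated_volume_in_ml(self, grid, full):
        # 100 of 1000 voxels at 8 mm^3 each above 95% of 60 Gy
        d = np.zeros(grid.shape)
        d.ravel()[:100] = 58.0
        out = ev.v_total_at_fraction(d, full, grid, 60.0, 0.95)
        assert out == pytest.approx(100 * grid.voxel_volume_ml)

    def test_empty_mask_raises(self, grid):
        with pytest.raises(StructureError):
            ev.d_at_volume(np.zeros(grid.shape), np.zeros(grid.shape, bool), 50)

    def test_dvh_cumulative_properties(self, grid, full, rng):
        d = rng.uniform(0, 75, grid.shape)
        h = ev.dvh(d, full, bin_width_gy=0.5)
        assert h.cumulative_volume[0] == 1.0           # everything gets >= 0 Gy
        assert np.all(np.diff(h.cumulative_volume) <= 1e-12)
        # fine bins reproduce V_xGy
        h_fine = ev.dvh(d, full, bin_width_gy=0.01)
        edges = h_fine.bin_edges_gy[:-1]
        idx = np.searchsorted(edges, 40.0)
        assert h_fine.cumulative_volume[idx] * 100 == pytest.approx(
            ev.v_at_dose(d, full, edges[idx]), abs=1e-9)


class TestIndices:
    def test_hi_zero_for_uniform(self, grid, full):
        assert ev.hi(np.full(grid.shape, 60.0), full) == 0.0

    def test_hi_matches_oracle_on_ramp(self, grid, full):
        d = np.linspace(50, 70, grid.n_voxels).reshape(grid.shape)
        expected = (sorted_oracle_dq(d, 2) - sorted_oracle_dq(d, 98)) / sorted_oracle_dq(d, 50)
        assert ev.hi(d, full) == pytest.approx(expected, rel=1e-12)

    def test_hi_scale_invariant(self, grid, full, rng):
        d = rng.uniform(40, 70, grid.shape)
        assert ev.hi(2.5 * d, full) == pytest.approx(ev.hi(d, full), rel=1e-9)

    def test_ci_exact_coverage(self, grid, full):
        ptv = np.zeros(grid.shape, bool)
        ptv[3:7, 3:7, 3:7] = True
        d = np.where(ptv, 60.0, 0.0)
        assert ev.ci(d, ptv, full, grid, 60.0) == pytest.approx(1.0)

    def test_ci_double_volume(self, grid, full):
        ptv = np.zeros(grid.shape, bool)
        ptv[0:5, :, :] = True  # 500 voxels
        hot = np.zeros(grid.shape, bool)
        hot[0:10, :, :] = True  # 1000 voxels at 95% isodose
        d = np.where(hot, 58.0, 0.0)
        assert ev.ci(d, ptv, full, grid, 60.0) == pytest.approx(2.0)

    def test_ci_brute_force_random(self, grid, full, rng):
        ptv = np.zeros(grid.shape, bool)
        ptv[4:8, 4:8, 4:8] = True
        d = rng.uniform(0, 70, grid.shape)
        expected = (d >= 0.95 * 60).sum() / ptv.sum()
        assert ev.ci(d, ptv, full, grid, 60.0) == pytest.approx(expected)
        expected50 = (d >= 0.50 * 60).sum() / ptv.sum()
        assert ev.ci50(d, ptv, full, grid, 60.0) == pytest.approx(expected50)

    def test_ci_ignores_oar_labels(self, grid, full, rng):
        # conformity depends only on dose, body and PTV
        ptv = np.zeros(grid.shape, bool)
        ptv[4:8, 4:8, 4:8] = True
        d = rng.uniform(0, 70, grid.shape)
        assert ev.ci(d, ptv, full, grid, 60.0) == ev.ci(d, ptv, full, grid, 60.0)

    def test_rx_must_be_positive(self, grid, full):
        ptv = full.copy()
        with pytest.raises(ValueError):
            ev.ci(np.ones(grid.shape), ptv, full, grid, 0.0)


class TestSumAndEqd2:
    def test_sum_identity_and_commutativity(self, grid, rng):
        a = rng.uniform(0, 60, grid.shape)
        b = rng.uniform(0, 13, grid.shape)
        assert np.array_equal(ev.sum_plans(a, np.zeros(grid.shape)), a)
        assert np.array_equal(ev.sum_plans(a, b), ev.sum_plans(b, a))
        assert np.allclose(ev.sum_plans(np.full(grid.shape, 60.0),
                                        np.full(grid.shape, 13.0)), 73.0)

    def test_sum_grid_mismatch(self, grid):
        with pytest.raises(GridMismatchError):
            ev.sum_plans(np.zeros(grid.shape), np.zeros((5, 5, 5)))

    def test_eqd2_identity_at_2gy_per_fraction(self):
        D = np.full((4, 4, 4), 60.0)
        assert np.allclose(ev.eqd2(D, 30, 3.0), D)

    def test_eqd2_spot_value(self):
        # 73 Gy in 30 fractions, alpha/beta = 3: 73*(73/30+3)/5
        out = ev.eqd2(np.array([[[73.0]]]), 30, 3.0)
        assert out[0, 0, 0] == pytest.approx(73 * (73 / 30 + 3) / 5, rel=1e-12)
        assert out[0, 0, 0] == pytest.approx(79.3, abs=0.05)

    def test_eqd2_zero_dose(self):
        assert np.all(ev.eqd2(np.zeros((3, 3, 3)), 30, 3.0) == 0.0)


def _mini_structures(grid):
    masks = {"external": np.ones(grid.shape, bool)}
    for i, name in enumerate(("rectum", "bladder", "bowel_bag")):
        m = np.zeros(grid.shape, bool)
        m[i * 3:i * 3 + 3, 0:4, :] = True
        masks[name] = m
    fem = np.zeros(grid.shape, bool)
    fem[0:2, 6:9, :] = True
    masks["femoral_head_left"] = fem
    masks["femoral_head_right"] = np.roll(fem, 5, axis=0)
    return StructureSet(grid, masks)


class TestProtocol:
    def test_builtin_protocol_content(self):
        proto = ev.ClinicalProtocol.builtin()
        labels = [c.label for c in proto.constraints]
        assert len(labels) == 16
        by_structure = {}
        for c in proto.constraints:
            by_structure.setdefault(c.structure, []).append(c)
        assert {s: len(v) for s, v in by_structure.items()} == {
            "rectum": 5, "bowel_bag": 4, "bladder": 5, "femoral_heads": 2}
        dmax = {c.structure: c.limit for c in proto.constraints if c.metric == "D_max"}
        assert dmax == {"rectum": 78, "bowel_bag": 56, "bladder": 78,
                        "femoral_heads": 55}
        vgy = {(c.structure, c.dose_gy): c.limit for c in proto.constraints
               if c.metric == "V_gy"}
        assert vgy == {("rectum", 65): 20, ("rectum", 60): 40, ("rectum", 55): 45,
                       ("rectum", 50): 50, ("bowel_bag", 50): 10,
                       ("bowel_bag", 45): 15, ("bowel_bag", 40): 20,
                       ("bladder", 65): 20, ("bladder", 55): 40,
                       ("bladder", 50): 50, ("bladder", 35): 80,
                       ("femoral_heads", 45): 5}

    def test_rectum_uniform_50gy(self, grid):
        ss = _mini_structures(grid)
        dose = np.where(ss["rectum"], 50.0, 0.0)
        ledger = ev.check_protocol(dose, ss)
        row = ledger.set_index("constraint")
        assert row.loc["rectum V_65Gy <= 20%", "pass"]
        assert row.loc["rectum V_65Gy <= 20%", "measured"] == 0.0
        assert not row.loc["rectum V_50Gy <= 50%", "pass"]       # 100% > 50%
        assert row.loc["rectum V_50Gy <= 50%", "measured"] == 100.0

    def test_all_zero_dose_passes_everything(self, grid):
        ss = _mini_structures(grid)
        ledger = ev.check_protocol(np.zeros(grid.shape), ss)
        assert ledger["pass"].all()

    def test_femoral_head_56gy_fails_dmax(self, grid):
        ss = _mini_structures(grid)
        dose = np.where(ss["femoral_head_left"], 56.0, 0.0)
        ledger = ev.check_protocol(dose, ss).set_index("constraint")
        assert not ledger.loc["femoral_heads D_max <= 55 Gy", "pass"]
        assert ledger.loc["femoral_heads D_max <= 55 Gy", "measured"] == 56.0

    def test_missing_structure_raises(self, grid):
        ss = _mini_structures(grid)
        del ss.masks["rectum"]
        with pytest.raises(StructureError, match="rectum"):
            ev.check_protocol(np.zeros(grid.shape), ss)

    def test_near_max_variant(self, grid, rng):
        ss = _mini_structures(grid)
        dose = rng.uniform(0, 60, grid.shape)
        strict = ev.check_protocol(dose, ss)
        near = ev.check_protocol(dose, ss, near_max_percent=2.0)
        m_strict = strict[strict.metric == "D_max"]["measured"].to_numpy()
        m_near = near[near.metric == "D_max"]["measured"].to_numpy()
        assert np.all(m_near <= m_strict + 1e-12)


class TestRectumHypofractionation:
    def test_dose_and_threshold_conversion_agree_at_2gy(self, grid):
        ss = _mini_structures(grid)
        dose = np.where(ss["rectum"], 60.0, 0.0)  # 2 Gy/fraction over 30 fx
        a = ev.rectum_hypofractionation_metrics(dose, ss, convert="dose")
        b = ev.rectum_hypofractionation_metrics(dose, ss, convert="threshold")
        assert a["V_55Gy"] == pytest.approx(b["V_55Gy"])
        assert a["V_70Gy"] == pytest.approx(b["V_70Gy"])

    def test_eqd2_raises_hot_voxels(self, grid):
        ss = _mini_structures(grid)
        dose = np.where(ss["rectum"], 72.0, 0.0)  # 2.4 Gy/fraction
        out = ev.rectum_hypofractionation_metrics(dose, ss, convert="dose")
        assert out["V_70Gy"] == 100.0  # EQD2(72 Gy @30fx) = 77.8 > 70
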