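"""Classic, bootstrap-CI and temperature-based aquagrams; WAMACS table."""

import numpy as np
import pandas as pd
import pytest

from aquaphot.aquagram import (
    aquagram_bootstrap_ci,
    classic_aquagram,
    fit_temperature_calibration,
    relative_wamacs_areas,
    temperature_aquagram,
)
from aquaphot.dataset import SpectraSet, WavelengthGrid, make_meta
from aquaphot.synthetic import (
    default_grid,
    default_model,
    simulate_reference_library,
    simulate_spectrum,
)
from aquaphot.wamacs import WAMACSTable, default_wamacs_table
from conftest import build_set


class TestWAMACSTable:
    def test_default_table_structure(self):
        t = default_wamacs_table()
        e = t.entries
        assert len(e) == 12
        widths = e["hi"] - e["lo"]
        assert ((widths >= 6) & (widths <= 20)).all()
        assert (e["lo"] >= 1300).all() and (e["hi"] <= 1600).all()
        assert (e["lo"].to_numpy()[1:] >= e["hi"].to_numpy()[:-1]).all()

    def test_region_constraints(self):
        e = default_wamacs_table().entries.set_index("label")
        assert e.loc[["C1", "C2", "C3"], "lo"].min() >= 1342
        assert e.loc[["C1", "C2", "C3"], "hi"].max() <= 1374
        assert e.loc[["C7", "C8"], "lo"].min() >= 1440
        assert e.loc[["C7", "C8"], "hi"].max() <= 1452
        assert e.loc[["C10", "C11", "C12"], "lo"].min() >= 1476
        assert e.loc[["C10", "C11", "C12"], "hi"].max() <= 1512

    def test_csv_round_trip(self, tmp_path):
        t = default_wamacs_table()
        t.to_csv(tmp_path / "w.csv")
        back = WAMACSTable.from_csv(tmp_path / "w.csv")
        pd.testing.assert_frame_equal(back.entries, t.entries)

    @pytest.mark.parametrize(
        "mutate,msg",
        [
            (lambda e: e.drop(index=0), "12 entries"),
            (lambda e: e.assign(hi=e["hi"] + 30), "6-20 nm"),
            (lambda e: e.assign(
                lo=np.where(e["label"] == "C1", e["lo"] - 6, e["lo"]),
                hi=np.where(e["label"] == "C1", e["hi"] - 6, e["hi"]),
            ), "1342"),
        ],
    )
    def test_structural_violations_rejected(self, mutate, msg):
        e = default_wamacs_table().entries
        with pytest.raises(ValueError, match=msg):
            WAMACSTable(mutate(e))


def mirror_set(n_per=6, delta=0.05, sigma=0.0, seed=0):
    """Two equal groups perturbed by ±delta at one wavelength."""
    rng = np.random.default_rng(seed)
    grid = WavelengthGrid.regular(1400.0, 1420.0, 1.0)
    base = 0.5 + 0.01 * np.sin(grid.values / 3.0)
    bump = np.zeros(len(grid))
    bump[10] = delta
    x = np.vstack(
        [base + bump + rng.normal(0, sigma, len(grid)) for _ in range(n_per)]
        + [base - bump + rng.normal(0, sigma, len(grid)) for _ in range(n_per)]
    )
    return build_set(x, grid=grid, groups=["plus"] * n_per + ["minus"] * n_per)


class TestClassicAquagram:
    def test_identical_spectra_rejected(self):
        s = build_set([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]],
                      groups=["a", "b"])
        with pytest.raises(ValueError, match="standard deviation"):
            classic_aquagram(s, axes=[1310.0], pretreatment="none")

    def test_mirror_groups_are_antisymmetric(self):
        s = mirror_set(sigma=1e-4)
        res = classic_aquagram(s, axes=[1410.0], pretreatment="snv")
        v = res.values[:, 0]
        assert abs(v[0] + v[1]) < 0.05 * abs(v[0])

    def test_count_weighted_mean_is_zero(self):
        rng = np.random.default_rng(1)
        grid = WavelengthGrid.regular(1400.0, 1409.0, 1.0)
        x = rng.normal(0.5, 0.05, size=(9, 10))
        s = build_set(x, grid=grid, groups=["a"] * 2 + ["b"] * 3 + ["c"] * 4)
        res = classic_aquagram(s, axes=[1402.0, 1405.0], pretreatment="snv")
        counts = np.array([2, 3, 4], dtype=float)
        wmean = (res.values * counts[:, None]).sum(axis=0) / counts.sum()
        np.testing.assert_allclose(wmean, 0.0, atol=1e-10)

    def test_invariant_to_spectrum_order_and_group_labels(self):
        s = mirror_set(sigma=1e-3)
        perm = np.random.default_rng(2).permutation(s.n_spectra)
        sp = SpectraSet(s.grid, s.intensities[perm],
                        s.meta.iloc[perm], s.unit)
        a = classic_aquagram(s, axes=[1405.0, 1410.0], pretreatment="msc")
        b = classic_aquagram(sp, axes=[1405.0, 1410.0], pretreatment="msc")
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)
        assert a.groups == b.groups

    def test_axes_default_to_wamacs_centers(self, grid601):
        model = default_model(noise_sd=1e-4, scatter_sd=0.0)
        rng = np.random.default_rng(3)
        rows = [simulate_spectrum(model, grid601, 28.0, c, 1, rng)
                for c in (0, 0, 50, 50)]
        s = SpectraSet(grid601, np.vstack(rows), make_meta(
            [{"sample_id": f"s{i}", "replicate": 1, "consecutive": 1,
              "group": g} for i, g in enumerate(["w", "w", "salt", "salt"])]
        ))
        res = classic_aquagram(s)
        assert res.axes == default_wamacs_table().labels
        assert res.values.shape == (2, 12)


class TestBootstrapCI:
    def test_seed_reproducibility_bitwise(self):
        s = mirror_set(sigma=0.01)
        kw = dict(axes=[1405.0, 1410.0], pretreatment="snv", B=200,
                  rng_seed=9)
        a = aquagram_bootstrap_ci(s, **kw)
        b = aquagram_bootstrap_ci(s, **kw)
        assert np.array_equal(a.lo95, b.lo95)
        assert np.array_equal(a.hi95, b.hi95)

    def test_ci_brackets_point_estimate(self):
        s = mirror_set(sigma=0.02, seed=4)
        res = aquagram_bootstrap_ci(s, axes=[1403.0, 1410.0, 1417.0],
                                    pretreatment="msc", B=300, rng_seed=1)
        assert np.all(res.lo95 <= res.values)
        assert np.all(res.values <= res.hi95)

    def test_msc_and_snv_paths_agree_with_point_values(self):
        s = mirror_set(sigma=0.01, seed=5)
        for pre in ("msc", "snv"):
            res = aquagram_bootstrap_ci(s, axes=[1410.0], pretreatment=pre,
                                        B=150, rng_seed=2)
            point = classic_aquagram(s, axes=[1410.0], pretreatment=pre)
            np.testing.assert_allclose(res.values, point.values, atol=1e-12)

    def test_single_spectrum_group_rejected(self):
        s = build_set([[1.0, 2.0], [1.1, 2.2], [0.9, 1.8]],
                      groups=["a", "a", "b"])
        with pytest.raises(ValueError, match="single spectrum"):
            aquagram_bootstrap_ci(s, axes=[1310.0], pretreatment="snv",
                                  B=100)

    def test_small_b_rejected(self):
        s = mirror_set()
        with pytest.raises(ValueError, match="B"):
            aquagram_bootstrap_ci(s, axes=[1410.0], B=50)


class TestRelativeAreas:
    def test_straight_line_spectrum_rejected(self, grid601):
        lam = grid601.values
        y = 0.001 * lam + 1.0  # equal to its own baseline
        with pytest.raises(ValueError, match="non-positive"):
            relative_wamacs_areas(y, default_wamacs_table(), grid601)

    def test_hand_trapezoid_on_triangle(self):
        """Symmetric triangle on a flat baseline: areas match a hand
        trapezoid computation."""
        grid = WavelengthGrid.regular(1300.0, 1600.0, 50.0)  # 7 points
        y = np.array([0.0, 1.0, 2.0, 3.0, 2.0, 1.0, 0.0])
        wam = default_wamacs_table()
        # baseline is zero; total area by trapezoid on the 7-point grid
        total = np.trapezoid(y, grid.values)
        areas = relative_wamacs_areas(y, wam, grid)
        for k, (lo, hi) in enumerate(wam.intervals()):
            m = (grid.values >= lo) & (grid.values <= hi)
            expected = (np.trapezoid(y[m], grid.values[m]) / total
                        if m.sum() >= 2 else 0.0)
            assert areas[k] == pytest.approx(expected, abs=1e-10)

    def test_disjoint_subset_areas_sum_below_one(self, grid601):
        model = default_model(noise_sd=0.0, scatter_sd=0.0)
        y = simulate_spectrum(model, grid601, 28.0, 0.0)
        areas = relative_wamacs_areas(y, default_wamacs_table(), grid601)
        assert areas.sum() <= 1.0 + 1e-12


@pytest.fixture(scope="module")
def calibration(grid601):
    model = default_model(noise_sd=0.0, scatter_sd=0.0,
                          consecutive_drift=0.0)
    library = simulate_reference_library(
        model, np.arange(20.0, 36.5, 1.0), replicates=1, grid=grid601
    )
    return fit_temperature_calibration(library, default_wamacs_table())


class TestTemperatureCalibration:
    def test_lattice_spans_reference_range(self, calibration):
        assert calibration.t_range == (20.0, 36.0)
        assert np.all(np.diff(calibration.lattice) > 0)

    def test_too_few_levels_rejected(self, grid601):
        model = default_model(noise_sd=0.0, scatter_sd=0.0)
        lib = simulate_reference_library(model, [20.0, 25.0, 30.0],
                                         grid=grid601)
        with pytest.raises(ValueError, match="insufficient temperature"):
            fit_temperature_calibration(lib, default_wamacs_table())

    def test_curve_tracks_generator_areas(self, calibration):
        """At the reference temperatures the loess curve reproduces the
        generating areas closely."""
        for i, t in enumerate(calibration.reference_temperatures):
            j = int(np.argmin(np.abs(calibration.lattice - t)))
            np.testing.assert_allclose(
                calibration.curves[:, j],
                calibration.reference_areas[i],
                atol=1e-3,
            )


class TestTemperatureAquagram:
    @staticmethod
    def _water_group(grid, model, t, n=3, label="x", rng=None):
        rows = [simulate_spectrum(model, grid, t, 0.0, 1, rng)
                for _ in range(n)]
        recs = [{"sample_id": f"{label}{i}", "replicate": 1,
                 "consecutive": 1, "group": label, "temperature": t}
                for i in range(n)]
        return np.vstack(rows), recs

    def test_heldout_temperature_recovered(self, calibration, grid601):
        model = default_model(noise_sd=0.0, scatter_sd=0.0,
                              consecutive_drift=0.0)
        t_star = 27.37
        rows, recs = self._water_group(grid601, model, t_star)
        s = SpectraSet(grid601, rows, make_meta(recs))
        res = temperature_aquagram(s, calibration, default_wamacs_table(),
                                   nominal_temperature=28.0)
        np.testing.assert_allclose(res.values, t_star, atol=0.1)

    def test_reference_level_self_consistency(self, calibration, grid601):
        model = default_model(noise_sd=0.0, scatter_sd=0.0,
                              consecutive_drift=0.0)
        rows, recs = self._water_group(grid601, model, 25.0)
        s = SpectraSet(grid601, rows, make_meta(recs))
        res = temperature_aquagram(s, calibration, default_wamacs_table())
        lattice_step = np.diff(calibration.lattice).max()
        np.testing.assert_allclose(res.values, 25.0, atol=lattice_step + 1e-9)

    def test_out_of_range_area_errors_and_clamps(self, calibration, grid601):
        model = default_model(noise_sd=0.0, scatter_sd=0.0,
                              consecutive_drift=0.0)
        rows, recs = self._water_group(grid601, model, 55.0, label="hot")
        s = SpectraSet(grid601, rows, make_meta(recs))
        wam = default_wamacs_table()
        with pytest.raises(ValueError, match="hot"):
            temperature_aquagram(s, calibration, wam)
        with pytest.warns(UserWarning, match="clamped"):
            res = temperature_aquagram(s, calibration, wam, clamp=True)
        assert np.all(res.values >= 20.0) and np.all(res.values <= 36.0)

    def test_ci_mode_brackets_and_reproduces(self, calibration, grid601):
        model = default_model(noise_sd=1e-4, scatter_sd=0.0,
                              consecutive_drift=0.0)
        rng = np.random.default_rng(6)
        rows_a, recs_a = self._water_group(grid601, model, 26.0, n=5,
                                           label="a", rng=rng)
        rows_b, recs_b = self._water_group(grid601, model, 30.0, n=5,
                                           label="b", rng=rng)
        s = SpectraSet(grid601, np.vstack([rows_a, rows_b]),
                       make_meta(recs_a + recs_b))
        wam = default_wamacs_table()
        kw = dict(with_ci=True, B=200, rng_seed=3, nominal_temperature=28.0)
        r1 = temperature_aquagram(s, calibration, wam, **kw)
        r2 = temperature_aquagram(s, calibration, wam, **kw)
        assert np.array_equal(r1.lo95, r2.lo95)
        assert np.all(r1.lo95 <= r1.values) and np.all(r1.values <= r1.hi95)
        # 4 °C apart with tiny noise: significant at every coordinate
        assert r1.significance["significant"].all()
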