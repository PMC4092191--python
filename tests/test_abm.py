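"""Unit and property tests for the agent-based wound-closure model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epirepair.abm import (
    ISOLATED,
    ModelParams,
    init_sheet,
    interaction_displacements,
    maybe_divide,
    migration_rate_series,
    pair_displacement,
    run_simulation,
    step,
    stretch_metric,
    stretch_metrics,
)
from epirepair.exceptions import (
    CoincidentCellsError,
    GeometryError,
    WindowError,
)

from conftest import S, make_free_sheet


def oracle_pair(d, p):
    """Independent piecewise evaluation of the pair interaction."""
    if d > p.d_max:
        return 0.0
    if d < p.d_rep:
        return p.k_rep * (p.d_rep - d)
    if d > p.d_att:
        return -p.k_att * (d - p.d_att)
    return 0.0


def oracle_displacements(positions, p):
    """Brute-force double loop over all pairs within the force cutoff."""
    n = len(positions)
    disp = np.zeros((n, 2))
    for i in range(n):
        for j in range(i + 1, n):
            dvec = positions[i] - positions[j]
            d = float(np.hypot(*dvec))
            if 0 < d <= p.d_max:
                f = oracle_pair(d, p)
                disp[i] += f * dvec / d
                disp[j] -= f * dvec / d
    return disp


class TestModelParams:
    def test_defaults_satisfy_radius_ordering(self):
        p = ModelParams()
        assert 0 < p.d_rep < p.cell_spacing < p.d_att < p.d_max <= p.d_sense

    @pytest.mark.parametrize(
        "bad",
        [
            {"d_rep": 7.0},                 # d_rep >= spacing
            {"d_att": 6.0},                 # d_att <= spacing
            {"d_max": 6.9},                 # d_max <= d_att
            {"p_div": 1.5},
            {"delay_steps": -1},
            {"motility_sigma": -0.1},
            {"d_sense": 5.0},               # smaller than d_max
            {"cell_spacing": -1.0},
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            ModelParams(**bad)


class TestInitSheet:
    def test_full_lattice_has_rows_times_cols_cells(self):
        sheet = init_sheet(10, 60, ModelParams(), gap_length=0.0)
        assert sheet.n_cells == 600
        assert not ((sheet.positions[:, 0] >= sheet.gap[0])
                    & (sheet.positions[:, 0] < sheet.gap[1])).any()

    def test_three_cell_diameter_ablation_removes_three_columns(self):
        # a ~20 µm ablation is three cell diameters: 3 columns x 10 rows
        sheet = init_sheet(10, 60, ModelParams(), gap_length=20.1)
        assert sheet.n_cells == 600 - 30

    def test_gap_spanning_sheet_is_rejected(self):
        p = ModelParams()
        with pytest.raises(GeometryError):
            init_sheet(10, 60, p, gap_length=59 * S)

    def test_anchored_margins(self):
        sheet = init_sheet(10, 60, ModelParams(), gap_length=0.0)
        x = sheet.positions[:, 0]
        assert (sheet.anchored == ((x <= 2 * S + 1e-9)
                                   | (x >= x.max() - 2 * S - 1e-9))).all()

    def test_anchored_cells_never_move(self):
        p = ModelParams(seed=0)
        sheet = init_sheet(6, 30, p, gap_length=20.1)
        frozen = sheet.positions[sheet.anchored].copy()
        rng = np.random.default_rng(0)
        for _ in range(20):
            step(sheet, p, rng)
        assert np.array_equal(sheet.positions[sheet.anchored], frozen)


class TestPairDisplacement:
    def test_comfort_zone_and_cutoff_are_force_free(self, passive_params):
        p = passive_params
        assert pair_displacement(p.cell_spacing, p) == 0.0
        assert pair_displacement(p.d_max + 1.0, p) == 0.0

    def test_continuity_at_zone_boundaries(self, passive_params):
        p = passive_params
        eps = 1e-9
        for d0 in (p.d_rep, p.d_att):
            lo = pair_displacement(d0 - eps, p)
            hi = pair_displacement(d0 + eps, p)
            assert abs(lo - hi) < 1e-6

    def test_coincident_cells_rejected(self, passive_params):
        with pytest.raises(CoincidentCellsError):
            pair_displacement(0.0, passive_params)

    def test_matches_independent_piecewise_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            s = rng.uniform(2.0, 12.0)
            p = ModelParams(
                cell_spacing=s,
                d_rep=rng.uniform(0.3, 0.95) * s,
                d_att=rng.uniform(1.02, 1.3) * s,
                d_max=rng.uniform(1.35, 1.9) * s,
                d_sense=2.0 * s,
                k_rep=rng.uniform(0.05, 0.6),
                k_att=rng.uniform(0.05, 0.6),
            )
            d = rng.uniform(1e-3, 2 * p.d_max)
            assert pair_displacement(d, p) == pytest.approx(
                oracle_pair(d, p), abs=1e-12
            )


class TestStep:
    def test_resting_lattice_is_a_fixed_point(self):
        # full calibrated interactions, motility off: no force anywhere
        p = ModelParams(motility_sigma=0.0)
        sheet = init_sheet(10, 40, p, gap_length=0.0)
        before = sheet.positions.copy()
        step(sheet, p, np.random.default_rng(0))
        assert np.allclose(sheet.positions, before, atol=1e-9 * S)

    def test_small_configurations_match_bruteforce_summation(
        self, passive_params
    ):
        rng = np.random.default_rng(7)
        for _ in range(50):
            n = rng.integers(2, 6)
            pos = rng.uniform(0, 3 * S, size=(n, 2))
            if np.min(
                np.linalg.norm(pos[None] - pos[:, None], axis=-1)
                + np.eye(n) * 1e6
            ) < 0.5:
                continue
            sheet = make_free_sheet(pos)
            expected = oracle_displacements(pos, passive_params)
            step(sheet, passive_params, rng)
            assert np.allclose(sheet.positions, pos + expected, atol=1e-9)

    def test_three_cells_in_compressed_line(self, passive_params):
        p = passive_params
        d = p.d_rep / 2
        pos = np.array([[0.0, 0.0], [d, 0.0], [2 * d, 0.0]])
        sheet = make_free_sheet(pos)
        step(sheet, p, np.random.default_rng(0))
        assert np.allclose(
            sheet.positions, pos + oracle_displacements(pos, p), atol=1e-9
        )

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.integers(0, 10_000))
    def test_centre_of_mass_invariant_without_anchors(self, seed):
        # pairwise interactions are equal and opposite
        p = ModelParams(motility_sigma=0.0, edge_speed=0.0, k_sub=0.0)
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0, 6 * S, size=(12, 2))
        if np.min(
            np.linalg.norm(pos[None] - pos[:, None], axis=-1)
            + np.eye(12) * 1e6
        ) < 0.5:
            return
        sheet = make_free_sheet(pos)
        com = sheet.positions.mean(axis=0)
        step(sheet, p, rng)
        assert np.allclose(sheet.positions.mean(axis=0), com,
                           atol=1e-9 * S)

    def test_gap_edge_columns_move_into_the_gap(self):
        # the active free-edge response drives both edges toward closure
        p = ModelParams(seed=3)
        sheet = init_sheet(10, 60, p, gap_length=90.0)
        c = 0.5 * sheet.axial_extent
        left = (sheet.positions[:, 0] < c) & (
            sheet.positions[:, 0] > c - 0.5 * 90 - 2 * S
        )
        right = (sheet.positions[:, 0] > c) & (
            sheet.positions[:, 0] < c + 0.5 * 90 + 2 * S
        )
        x0l = sheet.positions[left, 0].mean()
        x0r = sheet.positions[right, 0].mean()
        rng = np.random.default_rng(3)
        for _ in range(10):
            step(sheet, p, rng)
        assert sheet.positions[left, 0].mean() > x0l
        assert sheet.positions[right, 0].mean() < x0r


class TestStretchMetric:
    def test_single_neighbour_returns_its_distance(self, passive_params):
        sheet = make_free_sheet([[0.0, 0.0], [9.0, 0.0]])
        assert stretch_metric(sheet, passive_params, 0) == pytest.approx(9.0)

    def test_isolated_cell_sentinel(self, passive_params):
        sheet = make_free_sheet([[0.0, 0.0], [100.0, 0.0]])
        assert stretch_metric(sheet, passive_params, 0) == ISOLATED

    def test_interior_lattice_cell_between_pitch_and_diagonal(self):
        p = ModelParams()
        sheet = init_sheet(8, 20, p, gap_length=0.0)
        # pick the cell nearest the sheet centre
        c = np.array([0.5 * sheet.axial_extent, 0.5 * (8 - 1) * S])
        idx = int(np.argmin(np.linalg.norm(sheet.positions - c, axis=1)))
        m = stretch_metric(sheet, p, idx)
        assert S <= m <= np.sqrt(2) * S


class TestMaybeDivide:
    def _pair_params(self, **kw):
        # separation sensed but outside the force cutoff: statics are frozen
        return ModelParams(motility_sigma=0.0, edge_speed=0.0, k_sub=0.0,
                           p_div=1.0, div_margin=0.0, **kw)

    def test_forced_division_fires_the_step_after_the_delay(self):
        p = self._pair_params(delay_steps=3)
        sheet = make_free_sheet([[0.0, 0.0], [10.0, 0.0]])
        sheet.anchored[1] = True  # single dividing mother
        rng = np.random.default_rng(0)
        events = []
        for i in range(1, 6):
            sheet, ev = maybe_divide(sheet, p, rng, i)
            events += ev
        steps = [e[0] for e in events]
        assert steps[0] == p.delay_steps + 1
        assert len([s for s in steps if s == steps[0]]) == 1

    def test_run_resets_when_metric_drops(self):
        p = self._pair_params(delay_steps=5)
        sheet = make_free_sheet([[0.0, 0.0], [10.0, 0.0]])
        rng = np.random.default_rng(0)
        maybe_divide(sheet, p, rng, 1)
        assert (sheet.over_threshold_run == 1).all()
        sheet.positions[1, 0] = 6.7  # back to comfortable spacing
        maybe_divide(sheet, p, rng, 2)
        assert (sheet.over_threshold_run == 0).all()

    def test_division_count_is_binomial(self):
        # 500 isolated mother/partner pairs, all eligible, p_div = 0.3
        p = ModelParams(motility_sigma=0.0, edge_speed=0.0, k_sub=0.0,
                        p_div=0.3, delay_steps=0)
        pos = []
        for k in range(500):
            x = 3 * k * p.d_sense
            pos += [[x, 0.0], [x + 10.0, 0.0]]
        sheet = make_free_sheet(pos)
        rng = np.random.default_rng(123)
        sheet, events = maybe_divide(sheet, p, rng, 1)
        n, prob = 1000, 0.3
        sd = np.sqrt(n * prob * (1 - prob))
        assert abs(len(events) - n * prob) < 3 * sd

    def test_unablated_sheet_never_divides(self):
        p = ModelParams(seed=5, n_steps=300)
        result = run_simulation(p, rows=8, cols=40, gap_length=0.0,
                                record_positions=False)
        assert result.n_divisions == 0


class TestRunSimulation:
    def test_same_seed_is_bit_identical(self):
        p = ModelParams(seed=9, n_steps=120)
        a = run_simulation(p, rows=6, cols=30, gap_length=40.0)
        b = run_simulation(p, rows=6, cols=30, gap_length=40.0)
        assert np.array_equal(a.final_sheet.positions,
                              b.final_sheet.positions)
        assert np.array_equal(a.division_events, b.division_events)
        assert np.array_equal(a.edge_left, b.edge_left)

    def test_cells_divide_but_never_die(self, long_run):
        initial = init_sheet(10, 80, long_run.params, 90.0).n_cells
        assert long_run.final_sheet.n_cells == initial + long_run.n_divisions

    def test_divisions_occur_after_the_delay(self, long_run):
        assert long_run.n_divisions > 0
        assert (long_run.division_events[:, 0]
                > long_run.params.delay_steps).all()

    def test_long_gap_closes(self, long_run):
        gw = long_run.gap_width_series()
        assert gw[-1] < 0.1 * gw[0]

    def test_short_gap_produces_no_divisions(self, short_run):
        assert short_run.n_divisions == 0

    def test_edge_traces_monotone_after_smoothing(self, long_run):
        gw = long_run.gap_width_series()
        closed = int(np.flatnonzero(gw < 0.1 * gw[0])[0])
        n_bins = closed // 25
        smoothed = gw[: n_bins * 25].reshape(n_bins, 25).mean(axis=1)
        assert (np.diff(smoothed) < 0).all()


class TestMigrationRateSeries:
    def test_constant_advance_gives_constant_rate(self, long_run):
        res = long_run
        fake = res.__class__(
            params=res.params, rows=res.rows, cols=res.cols,
            gap_length=res.gap_length, gap=res.gap, positions=None,
            final_sheet=res.final_sheet, division_events=res.division_events,
            edge_steps=np.arange(101),
            edge_left=np.arange(101) * 0.5,
            edge_right=400 - np.arange(101) * 0.5,
        )
        series = migration_rate_series(fake, "left", bin_steps=10)
        assert np.allclose(series[:, 1], 0.5 / res.params.step_hours)
        series_r = migration_rate_series(fake, "right", bin_steps=10)
        assert np.allclose(series_r[:, 1], 0.5 / res.params.step_hours)

    def test_window_longer_than_trace_is_rejected(self, long_run):
        with pytest.raises(WindowError):
            migration_rate_series(long_run, "left",
                                  bin_steps=len(long_run.edge_left))
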