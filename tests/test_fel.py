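"""FEL estimation, convergence diagnostics, basins and frame assignment."""

import numpy as np
import pytest

from gqfold import (
    FreeEnergySurface,
    assign_frames,
    cv_coverage,
    estimate_fel,
    exchange_diagnostics,
    fel_rms_difference,
    identify_basins,
)
from gqfold.config import KB

KBT = KB * 300.0


def _surface_1d(values, mask=None):
    values = np.asarray(values, float)
    edges = np.arange(len(values) + 1, dtype=float)
    mask = np.ones_like(values, bool) if mask is None else np.asarray(mask, bool)
    return FreeEnergySurface(axes=("s",), edges=(edges,), values=values, mask=mask)


class TestEstimateFel:
    def test_uniform_counts_flat_surface(self):
        samples = np.repeat(np.arange(10) + 0.5, 50)
        f = estimate_fel(samples, bins=10, ranges=[(0, 10)], equilibration=0.0)
        assert np.allclose(f.values[f.mask], 0.0)

    def test_two_bin_hand_value(self):
        samples = np.concatenate([np.full(100, 0.25), np.full(37, 0.75)])
        f = estimate_fel(samples, bins=2, ranges=[(0, 1)], equilibration=0.0,
                         temperature=300.0)
        assert f.values[1] == pytest.approx(-KBT * np.log(0.37), rel=1e-9)

    def test_duplication_invariance(self):
        rng = np.random.default_rng(0)
        samples = rng.normal(0, 1, 2000)
        f1 = estimate_fel(samples, bins=15, ranges=[(-4, 4)], equilibration=0.0)
        f2 = estimate_fel(np.concatenate([samples, samples]), bins=15,
                          ranges=[(-4, 4)], equilibration=0.0)
        assert np.allclose(f1.values[f1.mask], f2.values[f2.mask])
        assert np.array_equal(f1.mask, f2.mask)

    def test_equilibration_discard(self):
        samples = np.concatenate([np.full(50, 9.5), np.full(50, 0.5)])
        f = estimate_fel(samples, bins=10, ranges=[(0, 10)], equilibration=0.5,
                         connected_support=False)
        assert f.mask[0] and not f.mask[9]

    def test_langevin_double_well_matches_analytic(self):
        # long unbiased run on U = h (x^2-1)^2; RMS error < 0.5 kBT on
        # supported bins
        from gqfold import make_analytic_landscape, run_langevin

        land = make_analytic_landscape("double_well", h=3.0)
        s = run_langevin(land, [1.0], 400_000, dt=2e-3, seed=3, sample_stride=4)
        f = estimate_fel(s[:, 0], bins=24, ranges=[(-1.8, 1.8)],
                         equilibration=0.1, min_count=40)
        centers = f.centers(0)[f.mask]
        analytic = np.array([land.energy([c]) for c in centers])
        analytic -= analytic.min()
        err = f.values[f.mask] - analytic
        err -= err.mean()
        assert np.sqrt(np.mean(err**2)) < 0.5 * KBT

    def test_empty_after_discard_rejected(self):
        with pytest.raises(ValueError):
            estimate_fel(np.array([]), bins=5)


class TestRmsDifference:
    def test_self_and_shift(self):
        rng = np.random.default_rng(1)
        s = rng.normal(0, 1, 3000)
        a = estimate_fel(s, bins=12, ranges=[(-4, 4)], equilibration=0.0)
        assert fel_rms_difference(a, a) == 0.0

    def test_halves_of_one_run_agree(self):
        from gqfold import make_analytic_landscape, run_langevin

        land = make_analytic_landscape("double_well", h=3.0)
        s = run_langevin(land, [1.0], 400_000, dt=2e-3, seed=9, sample_stride=4)[:, 0]
        half = len(s) // 2
        kw = dict(bins=20, ranges=[(-1.8, 1.8)], equilibration=0.0, min_count=25)
        a = estimate_fel(s[:half], **kw)
        b = estimate_fel(s[half:], **kw)
        assert fel_rms_difference(a, b) < 0.5 * KBT

    def test_mismatched_bins_rejected(self):
        a = _surface_1d([0, 1, 2])
        b = FreeEnergySurface(axes=("s",), edges=(np.arange(5.0),),
                              values=np.zeros(4), mask=np.ones(4, bool))
        with pytest.raises(ValueError):
            fel_rms_difference(a, b)


class TestExchangeDiagnostics:
    def test_zero_attempts_reported_missing(self):
        d = exchange_diagnostics([[]])
        r = d.replicas[0]
        assert r.n_attempts == 0 and r.mean_acceptance is None and r.r_squared is None

    def test_all_accepted_uniform_times(self):
        log = [(float(t), 1, True) for t in range(1, 101)]
        r = exchange_diagnostics([log]).replicas[0]
        assert r.mean_acceptance == 1.0
        assert r.r_squared == pytest.approx(1.0)

    def test_bernoulli_stream_recovers_rate(self):
        rng = np.random.default_rng(7)
        p = 0.3
        log = [(float(t), 1, bool(rng.random() < p)) for t in range(10_000)]
        r = exchange_diagnostics([log]).replicas[0]
        assert abs(r.mean_acceptance - p) <= 3 * np.sqrt(p * (1 - p) / 10_000)


class TestCvCoverage:
    def test_constant_trace(self):
        out = cv_coverage(np.full(100, 0.5), (0, 1), n_segments=20)
        assert out["covered_fraction"] == pytest.approx(1 / 20)
        assert out["traversals"] == 0

    def test_monotone_sweep(self):
        out = cv_coverage(np.linspace(0, 1, 200), (0, 1))
        assert out["covered_fraction"] == 1.0
        assert out["traversals"] == 1

    @pytest.mark.parametrize("k", [1, 3, 7])
    def test_triangle_wave(self, k):
        t = np.linspace(0, k, 1000 * k, endpoint=False)
        wave = 2 * np.abs(t % 1 - 0.5)  # starts at 1, dips to 0, back to 1
        out = cv_coverage(wave, (0, 1))
        assert out["traversals"] == 2 * k


class TestBasins:
    def test_single_bowl(self):
        f = _surface_1d((np.linspace(-1, 1, 21)) ** 2 * 10)
        assert identify_basins(f, min_barrier=0.5).n_basins == 1

    def test_double_well_split_and_merge(self):
        x = np.linspace(-1.5, 1.5, 31)
        f = _surface_1d(5.0 * (x**2 - 1) ** 2)
        assert identify_basins(f, min_barrier=2.0).n_basins == 2
        assert identify_basins(f, min_barrier=6.0).n_basins == 1

    def test_numbered_by_depth(self):
        x = np.linspace(-1.5, 1.5, 61)
        vals = 5.0 * (x**2 - 1) ** 2 + 1.5 * x  # left well deeper
        f = _surface_1d(vals)
        basins = identify_basins(f, min_barrier=1.0)
        assert basins.n_basins == 2
        assert basins.minima[0][1] < basins.minima[1][1]
        assert x[basins.minima[0][0][0]] < 0  # deeper minimum on the left

    def test_shift_invariance(self):
        x = np.linspace(-1.5, 1.5, 31)
        vals = 5.0 * (x**2 - 1) ** 2
        a = identify_basins(_surface_1d(vals), min_barrier=2.0)
        b = identify_basins(_surface_1d(vals + 7.0), min_barrier=2.0)
        assert np.array_equal(a.labels, b.labels)


class TestAssignFrames:
    def test_assignment_and_unassigned(self):
        x = np.linspace(-1.5, 1.5, 31)
        f = _surface_1d(5.0 * (x**2 - 1) ** 2)
        basins = identify_basins(f, min_barrier=2.0)
        centers = f.centers(0)
        left_min = centers[basins.minima[0][0][0]]
        labels = assign_frames(np.array([left_min, 99.0]), basins)
        assert labels[0] == 0 and labels[1] == -1

    def test_planted_boxes(self):
        rng = np.random.default_rng(0)
        # two gaussian clouds -> two basins; draws assigned to the right one
        s = np.concatenate([rng.normal(-1, 0.15, 2000), rng.normal(1, 0.15, 2000)])
        f = estimate_fel(s, bins=30, ranges=[(-2, 2)], equilibration=0.0, min_count=5)
        basins = identify_basins(f, min_barrier=1.0)
        assert basins.n_basins == 2
        test_points = np.array([-1.0, 1.0])
        lab = assign_frames(test_points, basins)
        assert lab[0] != lab[1] and -1 not in lab

    def test_population_recovery_within_multinomial_error(self):
        rng = np.random.default_rng(5)
        w = 0.7
        n = 4000
        s = np.where(rng.random(n) < w, rng.normal(-1, 0.12, n), rng.normal(1, 0.12, n))
        f = estimate_fel(s, bins=30, ranges=[(-2, 2)], equilibration=0.0, min_count=5)
        basins = identify_basins(f, min_barrier=1.0)
        lab = assign_frames(s, basins)
        frac = np.mean(lab == 0)
        assert abs(frac - w) <= 3 * np.sqrt(w * (1 - w) / n) + 0.01
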