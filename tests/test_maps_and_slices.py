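import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scotomap.field_geometry import FieldLocation, build_estimation_lattice, build_grid
from scotomap.maps_and_slices import (
    MlMapSettings,
    conventional_map,
    gaussian_kernel_weight,
    ml_threshold_map,
    slice_select,
    slice_sweep,
    weighted_ml_fit,
)
from scotomap.psychometrics import PsychometricParams, detection_probability


class TestConventionalMap:
    def test_sensitivity_is_negated_threshold(self):
        grid = build_grid(0, 1, 0, 1, 1.0)
        est = pd.DataFrame(
            dict(loc_id=[0, 1, 2, 3], threshold_log=[0.0, -0.3, np.log10(2.0), 0.1])
        )
        tmap = conventional_map(est, grid)
        assert tmap.sensitivity_log[0] == 0.0
        assert tmap.sensitivity_log[1] == pytest.approx(0.3)
        assert tmap.sensitivity_log[2] == pytest.approx(-0.301, abs=5e-4)

    def test_missing_locations_flagged_not_dropped(self):
        grid = build_grid(0, 1, 0, 1, 1.0)
        est = pd.DataFrame(dict(loc_id=[0, 2], threshold_log=[0.1, 0.2]))
        tmap = conventional_map(est, grid)
        assert list(tmap.fit_status) == ["ok", "missing", "ok", "missing"]
        assert np.isnan(tmap.threshold_log[1])

    def test_out_of_grid_loc_id_rejected(self):
        grid = build_grid(0, 1, 0, 1, 1.0)
        est = pd.DataFrame(dict(loc_id=[7], threshold_log=[0.1]))
        with pytest.raises(ValueError):
            conventional_map(est, grid)


class TestWeightedMlFit:
    def test_kernel_weight_values(self):
        assert gaussian_kernel_weight(0.0) == 1.0
        assert gaussian_kernel_weight(0.5, 0.5) == pytest.approx(np.exp(-0.5))
        assert gaussian_kernel_weight(0.5, 0.5) == pytest.approx(0.6065, abs=1e-4)

    def test_recovers_alpha_against_grid_search_oracle(self, rng):
        """Trials from Psi(alpha=0.1, beta=3.5), 6 contrasts x 20 reps at
        distance 0: the optimizer's alpha must agree with a brute-force grid
        search on the same weighted likelihood, and with the truth."""
        p = PsychometricParams(alpha=0.1, beta=3.5)
        cs = np.repeat(np.linspace(-0.3, 0.5, 6), 20)
        resp = (rng.random(cs.size) < detection_probability(p, cs)).astype(float)
        xy = np.zeros((cs.size, 2))
        fit = weighted_ml_fit(xy, cs, resp, FieldLocation(0, 0))
        assert fit.status == "ok"
        assert abs(fit.alpha - 0.1) <= 0.05

        # independent oracle: dense grid search over (alpha, beta)
        aa = np.linspace(-1.2, 0.9, 211)
        bb = np.linspace(0.5, 20, 79)
        best = (np.inf, None)
        for a in aa:
            t = 10.0 ** ((cs - a)[None, :] * bb[:, None])
            psi = 0.02 + 0.96 * (1 - 2.0 ** (-t))
            nll = -(resp * np.log(psi) + (1 - resp) * np.log(1 - psi)).sum(axis=1)
            j = int(np.argmin(nll))
            if nll[j] < best[0]:
                best = (nll[j], a)
        assert abs(fit.alpha - best[1]) <= 0.02

    def test_all_seen_neighborhood_pins_alpha_at_lower_bound(self):
        xy = np.zeros((10, 2))
        cs = np.full(10, 0.0)
        fit = weighted_ml_fit(xy, cs, np.ones(10), FieldLocation(0, 0))
        assert fit.status == "boundary"
        assert fit.alpha == pytest.approx(-1.2, abs=1e-3)

    def test_too_few_trials_undefined(self):
        fit = weighted_ml_fit(np.zeros((3, 2)), np.zeros(3), np.ones(3), FieldLocation(0, 0))
        assert fit.status == "insufficient" and np.isnan(fit.alpha)

    def test_trials_outside_radius_ignored(self):
        xy = np.array([[0, 0]] * 5 + [[3, 3]] * 5, dtype=float)
        cs = np.zeros(10)
        fit = weighted_ml_fit(xy, cs, np.ones(10), FieldLocation(0, 0))
        assert fit.n_trials == 5

    def test_invalid_kernel_rejected(self):
        with pytest.raises(ValueError):
            weighted_ml_fit(np.zeros((5, 2)), np.zeros(5), np.ones(5),
                            FieldLocation(0, 0), radius=-1)


class TestMlThresholdMap:
    def test_flat_observer_recovery(self, flat_trials):
        """On a spatially uniform observer the map's median absolute alpha
        error stays within 0.1 log units."""
        grid, trials = flat_trials
        lattice = build_estimation_lattice(grid, 0.5)
        tmap = ml_threshold_map(trials, lattice)
        ok = np.isfinite(tmap.threshold_log)
        assert ok.sum() > 0.9 * len(lattice)
        assert np.median(np.abs(tmap.threshold_log[ok] + 0.1)) <= 0.1

    def test_empty_trials_all_undefined(self):
        grid = build_grid(0, 1, 0, 1, 0.5)
        tmap = ml_threshold_map(pd.DataFrame(), grid)
        assert np.isnan(tmap.threshold_log).all()
        assert (tmap.fit_status == "insufficient").all()

    def test_map_equals_pointwise_fits(self, flat_trials):
        grid, trials = flat_trials
        lattice = build_grid(0.5, 2.5, 0.5, 2.5, 1.0)
        tmap = ml_threshold_map(trials, lattice)
        xy = trials[["inferred_x_deg", "inferred_y_deg"]].to_numpy()
        cs = trials["log_contrast"].to_numpy()
        rs = trials["seen"].to_numpy(dtype=float)
        for i, (x, y) in enumerate(lattice.locations):
            fit = weighted_ml_fit(xy, cs, rs, FieldLocation(x, y))
            if np.isnan(fit.alpha):
                assert np.isnan(tmap.threshold_log[i])
            else:
                assert tmap.threshold_log[i] == pytest.approx(fit.alpha, abs=1e-6)

    def test_map_frame_columns(self, flat_trials):
        grid, trials = flat_trials
        df = ml_threshold_map(trials, build_grid(1, 2, 1, 2, 1.0)).to_frame()
        assert list(df.columns) == [
            "point_id", "x_deg", "y_deg", "alpha_log", "beta",
            "sensitivity_log", "n_trials_in_radius", "fit_status",
        ]


def random_trial_table(rng, n=200):
    return pd.DataFrame(
        dict(
            log_contrast=rng.uniform(-0.9, 0.6, n),
            seen=rng.random(n) < 0.5,
            x_deg=rng.uniform(0, 5, n),
            y_deg=rng.uniform(0, 5, n),
        )
    )


class TestSliceDisplay:
    def test_hand_example(self):
        trials = pd.DataFrame(dict(log_contrast=[-0.10, 0.10, 0.02], seen=[True, False, True]))
        sel = slice_select(trials, 0.0)
        assert sel.trials["subset"].tolist() == [
            "crossover_seen", "crossover_notseen", "concordant",
        ]

    def test_threshold_below_all_contrasts(self):
        trials = pd.DataFrame(dict(log_contrast=[0.1, 0.2, 0.3], seen=[True, False, True]))
        sel = slice_select(trials, -1.0)
        assert len(sel.crossover_seen) == 0
        assert sel.crossover_notseen["log_contrast"].tolist() == [0.2]

    def test_boundary_is_inclusive_for_notseen(self):
        trials = pd.DataFrame(dict(log_contrast=[0.0], seen=[False]))
        assert slice_select(trials, 0.0).trials["subset"].tolist() == ["crossover_notseen"]

    def test_boundary_is_strict_for_seen(self):
        trials = pd.DataFrame(dict(log_contrast=[0.0], seen=[True]))
        assert slice_select(trials, 0.0).trials["subset"].tolist() == ["concordant"]

    @given(seed=st.integers(0, 1000), c0=st.floats(-0.6, 0.6))
    @settings(deadline=None, max_examples=50)
    def test_partition_law(self, seed, c0):
        """Crossover and concordant subsets are disjoint and exhaustive."""
        rng = np.random.default_rng(seed)
        trials = random_trial_table(rng)
        sel = slice_select(trials, c0)
        n = len(sel.crossover_seen) + len(sel.crossover_notseen) + len(sel.concordant)
        assert n == len(trials)

    def test_default_sweep_has_101_frames(self, rng):
        frames = slice_sweep(random_trial_table(rng))
        assert len(frames) == 101
        assert frames[0].display_threshold == pytest.approx(0.5)
        assert frames[-1].display_threshold == pytest.approx(-0.5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_sweep_monotonicity(self, seed):
        """As C0 falls, crossover-seen counts never grow and
        crossover-not-seen counts never shrink."""
        rng = np.random.default_rng(seed)
        frames = slice_sweep(random_trial_table(rng))
        seen_counts = [f.counts()["crossover_seen"] for f in frames]
        notseen_counts = [f.counts()["crossover_notseen"] for f in frames]
        assert all(b <= a for a, b in zip(seen_counts, seen_counts[1:]))
        assert all(b >= a for a, b in zip(notseen_counts, notseen_counts[1:]))

    def test_inconsistent_sweep_direction_rejected(self, rng):
        with pytest.raises(ValueError):
            slice_sweep(random_trial_table(rng), 0.5, -0.5, 0.01)
        with pytest.raises(ValueError):
            slice_sweep(random_trial_table(rng), 0.5, -0.5, 0.0)


class TestTwoContrastPrinciple:
    def test_slices_localize_a_step_scotoma(self):
        """With a 0.3 log-unit step scotoma and steep slopes, the crossover
        not-seen trials at a display threshold 0.3 above the normal
        threshold lie predominantly inside the scotoma, and the crossover
        seen trials at the normal threshold lie predominantly outside."""
        rng = np.random.default_rng(99)
        alpha_n = -0.35
        scotoma = lambda x, y: (x - 2.5) ** 2 + (y - 2.5) ** 2 <= 1.5**2
        rows = []
        for x in np.arange(0.25, 5.0, 0.25):
            for y in np.arange(0.25, 5.0, 0.25):
                a = alpha_n + (0.3 if scotoma(x, y) else 0.0)
                p = PsychometricParams(alpha=a, beta=10.0)
                for c in (alpha_n, alpha_n + 0.3):
                    rows.append(dict(
                        x_deg=x, y_deg=y, log_contrast=c,
                        seen=bool(rng.random() < detection_probability(p, c)),
                    ))
        trials = pd.DataFrame(rows)
        inside = scotoma(trials["x_deg"], trials["y_deg"])

        high = slice_select(trials, alpha_n + 0.3)
        ns = high.trials["subset"] == "crossover_notseen"
        assert inside[ns].mean() >= 0.8  # not-seen crossover sits in the scotoma

        low = slice_select(trials, alpha_n + 0.01)
        s = low.trials["subset"] == "crossover_seen"
        assert (~inside[s]).mean() >= 0.8  # seen crossover sits in normal retina
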