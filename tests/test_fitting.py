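"""Objective function, trust-region fits, and the promoter Hill fit."""

import numpy as np
import pytest

from hisicc import (FlaskDataset, NoiseSpec, generate_flasks,
                    generate_promoter_grid, hill_fit, objective, simulate)
from hisicc.fitting import apply_theta, default_bounds, fit_parameters

from conftest import NO_NOISE


class TestObjective:
    def test_zero_at_generating_parameters(self, ta1415, noiseless_flasks_1415):
        assert objective(ta1415, noiseless_flasks_1415) == pytest.approx(
            0.0, abs=1e-8)

    def test_direct_summation_on_offset_data(self, ta1415, noiseless_flasks_1415):
        # shift each channel by known offsets: expected V accumulates
        # (offset / max)^2 term by term, summed here independently
        shifted, expected = [], 0.0
        rng = np.random.default_rng(0)
        for f in noiseless_flasks_1415:
            d_od = rng.uniform(-0.05, 0.05, f.times.size)
            d_ipa = rng.uniform(-0.5, 0.5, f.times.size)
            data = f.data.copy()
            data["od600"] = data["od600"] + d_od
            data["ipa_mM"] = data["ipa_mM"] + d_ipa
            for k in range(f.times.size):
                expected += (d_od[k] / data["od600"].max()) ** 2
                expected += (d_ipa[k] / data["ipa_mM"].max()) ** 2
            shifted.append(FlaskDataset(f.flask_id, f.condition, data))
        assert objective(ta1415, shifted) == pytest.approx(expected, rel=1e-5)

    def test_invariant_to_channel_unit_rescaling(self, ta1415):
        flasks = generate_flasks(ta1415, n_replicates=1, seed=4)
        v = objective(ta1415, flasks)
        # expressing cell density in different units scales the data and the
        # observation gain together; the per-flask normalization cancels it
        scaled = [FlaskDataset(f.flask_id, f.condition,
                               f.data.assign(od600=f.data["od600"] * 7.0))
                  for f in flasks]
        model = ta1415.with_shared(N_m=ta1415.shared.N_m * 7.0)
        assert objective(model, scaled) == pytest.approx(v, rel=1e-10)

    def test_zero_channel_maximum_rejected(self, ta1415, noiseless_flasks_1415):
        f = noiseless_flasks_1415[0]
        dead = FlaskDataset(f.flask_id, f.condition,
                            f.data.assign(ipa_mM=0.0))
        with pytest.raises(ValueError, match="maximum"):
            objective(ta1415, [dead])


class TestFitParameters:
    def test_quick_noiseless_recovery_of_growth_parameters(
            self, ta1415, noiseless_flasks_1415):
        free = ("k1", "k2", "N_m")
        truth = {k: getattr(ta1415.shared, k) for k in free}
        start = {k: v * 1.15 for k, v in truth.items()}
        fit = fit_parameters(noiseless_flasks_1415, ta1415, free=free,
                             start=start, n_starts=1)
        assert fit.success
        for k, v in truth.items():
            assert fit.theta[k] == pytest.approx(v, rel=1e-4)
        assert fit.cost == pytest.approx(0.0, abs=1e-8)
        assert set(fit.per_flask) == {f.flask_id for f in noiseless_flasks_1415}

    def test_start_outside_bounds_is_projected(self, ta1415,
                                               noiseless_flasks_1415):
        fit = fit_parameters(noiseless_flasks_1415, ta1415, free=("k1",),
                             start={"k1": 1e6}, n_starts=1, max_nfev=3)
        lo, hi = default_bounds(ta1415)["k1"]
        assert lo <= fit.theta["k1"] <= hi

    def test_apply_theta_touches_only_named_parameters(self, ta2445):
        model = apply_theta(ta2445, {"k1": 0.3, "d_A": 0.2})
        assert model.shared.k1 == 0.3
        assert model.quorum.d_A == 0.2
        assert model.shared.k2 == ta2445.shared.k2
        assert model.quorum.K_A == ta2445.quorum.K_A


class TestHillFit:
    def test_noiseless_round_trip(self, ta2445):
        q = ta2445.quorum
        ds = generate_promoter_grid(q, seed=0)
        fit = hill_fit(ds)
        assert fit.K_A == pytest.approx(q.K_A, rel=1e-5)
        assert fit.K_u == pytest.approx(q.K_u, rel=1e-5)
        assert fit.n_A == pytest.approx(q.n_A, rel=1e-5)
        assert fit.n_u == pytest.approx(q.n_u, rel=1e-5)
        assert fit.amplitude == pytest.approx(1.0, rel=1e-5)

    def test_amplitude_separates_from_shape(self, ta2445):
        q = ta2445.quorum
        ds = generate_promoter_grid(q, seed=0)
        half = ds.data.assign(response=ds.data["response"] * 0.5)
        fit = hill_fit(type(ds)(data=half))
        assert fit.amplitude == pytest.approx(0.5, rel=1e-5)
        assert fit.K_A == pytest.approx(q.K_A, rel=1e-4)
        assert fit.n_u == pytest.approx(q.n_u, rel=1e-4)

    def test_noisy_recovery_within_ten_percent(self, ta2445):
        q = ta2445.quorum
        for seed in range(10):
            ds = generate_promoter_grid(q, noise_cv=0.05, seed=seed)
            fit = hill_fit(ds)
            for name in ("K_A", "K_u", "n_A", "n_u"):
                assert getattr(fit, name) == pytest.approx(
                    getattr(q, name), rel=0.10), f"{name} seed {seed}"

    def test_single_level_grid_unidentifiable(self, ta2445):
        q = ta2445.quorum
        ds = generate_promoter_grid(q, ahl_levels=[q.K_A],
                                    iptg_levels=q.K_u * np.logspace(-1, 1, 5))
        with pytest.raises(ValueError, match="unidentifiable"):
            hill_fit(ds)

    def test_updates_quorum_parameters(self, ta2445):
        fit = hill_fit(generate_promoter_grid(ta2445.quorum, seed=0))
        q2 = fit.update_quorum(ta2445.quorum)
        assert q2.k_A == ta2445.quorum.k_A      # production rate untouched
        assert q2.K_A == fit.K_A
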