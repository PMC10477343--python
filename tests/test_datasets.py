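"""Synthetic flask and promoter-grid generators."""

import numpy as np
import pandas as pd
import pytest

from hisicc import (InputCondition, NoiseSpec, generate_flasks,
                    generate_promoter_grid, load_flasks, save_flasks,
                    simulate)
from hisicc.datasets import (default_measurement_grid, flasks_to_frame,
                             load_promoter, save_promoter)

from conftest import NO_NOISE


class TestGenerateFlasks:
    def test_design_structure(self, ta1415):
        flasks = generate_flasks(ta1415, seed=0)
        assert len(flasks) == 15    # 5 input conditions x 3 flasks
        values = sorted({f.condition.value for f in flasks})
        assert values == [0.0, 6.0, 9.0, 12.0, 15.0]
        for f in flasks:
            assert f.times[0] == 0.0 and f.times[-1] == ta1415.duration
            assert (f.od600 >= 0).all() and (f.ipa >= 0).all()

    def test_ta2445_design_structure(self, ta2445):
        flasks = generate_flasks(ta2445, seed=0)
        assert len(flasks) == 15
        assert sorted({f.condition.value for f in flasks}) == [
            0.01, 0.03, 0.05, 0.1, 1.0]

    def test_zero_noise_reproduces_model_observations(self, ta1415):
        flasks = generate_flasks(ta1415, n_replicates=1, noise=NO_NOISE, seed=0)
        for f in flasks:
            traj = simulate(ta1415, f.condition, times=f.times)
            # generated records clip at 0, so integrator-level negative
            # residue (~1e-21) is absorbed by the absolute tolerance
            np.testing.assert_allclose(f.od600, traj.od600, rtol=1e-12,
                                       atol=1e-15)
            np.testing.assert_allclose(f.ipa, traj.ipa_mM, rtol=1e-12,
                                       atol=1e-15)

    def test_same_seed_same_data(self, ta1415):
        a = generate_flasks(ta1415, seed=11)
        b = generate_flasks(ta1415, seed=11)
        for fa, fb in zip(a, b):
            pd.testing.assert_frame_equal(fa.data, fb.data)
        c = generate_flasks(ta1415, seed=12)
        assert not np.allclose(a[0].od600, c[0].od600)

    def test_empirical_cv_matches_specification(self, ta1415):
        # regenerate one flask many times; OD600 CV at the endpoint, where
        # the signal dwarfs the additive floor, should approach 5%
        cond = [InputCondition("TA1415", t_add=9.0)]
        noise = NoiseSpec(cv_od600=0.05, cv_ipa=0.05,
                          floor_od600=0.0, floor_ipa=0.0)
        vals = []
        rng = np.random.default_rng(3)
        flasks = generate_flasks(ta1415, inputs=cond, n_replicates=1000,
                                 noise=noise, rng=rng,
                                 times=np.array([0.0, 69.0]))
        vals = np.array([f.od600[-1] for f in flasks])
        assert vals.std() / vals.mean() == pytest.approx(0.05, rel=0.12)

    def test_invalid_replicates_rejected(self, ta1415):
        with pytest.raises(ValueError):
            generate_flasks(ta1415, n_replicates=0, seed=0)
        with pytest.raises(ValueError):
            NoiseSpec(cv_od600=-0.1)

    def test_measurement_grid_covers_endpoints(self):
        grid = default_measurement_grid(69.0)
        assert grid[0] == 0.0 and grid[-1] == 69.0
        assert np.allclose(np.diff(grid)[:-1], 3.0)


class TestPromoterGrid:
    def test_noiseless_value_at_dissociation_constants(self, ta2445):
        q = ta2445.quorum
        ds = generate_promoter_grid(q, ahl_levels=[q.K_A], iptg_levels=[q.K_u])
        assert ds.data["response"].iloc[0] == pytest.approx(0.25)

    def test_zero_ahl_row_is_zero(self, ta2445):
        ds = generate_promoter_grid(ta2445.quorum, ahl_levels=[0.0, 1.0],
                                    iptg_levels=[0.01, 0.1])
        zero_rows = ds.data[ds.data["ahl_nM"] == 0.0]
        assert (zero_rows["response"] == 0.0).all()

    def test_default_grid_spans_two_decades(self, ta2445):
        q = ta2445.quorum
        ds = generate_promoter_grid(q, seed=0)
        a = ds.data["ahl_nM"]
        u = ds.data["iptg_mM"]
        assert a.min() < 0.1 * q.K_A and a.max() > 10 * q.K_A
        assert u.min() < 0.1 * q.K_u and u.max() > 10 * q.K_u

    def test_seeded_noise_reproducible(self, ta2445):
        a = generate_promoter_grid(ta2445.quorum, noise_cv=0.05, seed=5)
        b = generate_promoter_grid(ta2445.quorum, noise_cv=0.05, seed=5)
        pd.testing.assert_frame_equal(a.data, b.data)


class TestCsvRoundTrip:
    def test_flasks(self, ta1415, tmp_path):
        flasks = generate_flasks(ta1415, seed=2)
        path = tmp_path / "flasks.csv"
        save_flasks(flasks, path)
        back = load_flasks(path)
        assert [f.flask_id for f in back] == [f.flask_id for f in flasks]
        for fa, fb in zip(flasks, back):
            assert fa.condition == fb.condition
            np.testing.assert_allclose(fa.od600, fb.od600)

    def test_frame_schema(self, ta1415):
        df = flasks_to_frame(generate_flasks(ta1415, seed=2))
        assert list(df.columns) == ["flask_id", "strain", "input_value",
                                    "time_h", "od600", "ipa_mM"]

    def test_promoter(self, ta2445, tmp_path):
        ds = generate_promoter_grid(ta2445.quorum, noise_cv=0.05, seed=1)
        path = tmp_path / "promoter.csv"
        save_promoter(ds, path)
        pd.testing.assert_frame_equal(load_promoter(path).data, ds.data)
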