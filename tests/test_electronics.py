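import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from ircmech import electronics as el
from ircmech import synthetic as syn
from ircmech.exceptions import ValidationError
from ircmech.io_formats import StationaryPoint


class TestPercentEvolution:
    def test_no_progress(self):
        assert el.percent_evolution(1.0, 1.0, 0.0) == pytest.approx(0.0)

    def test_complete_progress(self):
        assert el.percent_evolution(1.0, 0.0, 0.0) == pytest.approx(100.0)

    def test_sixty_percent_late(self):
        value = el.percent_evolution(1.0, 0.4, 0.0)
        assert value == pytest.approx(60.0)
        ev = el.BondEvolution("C1-H5", 1.0, 0.4, 0.0, value)
        assert ev.timing == "late"

    def test_early_flag(self):
        ev = el.BondEvolution("b", 1.0, 0.7, 0.0, el.percent_evolution(1.0, 0.7, 0.0))
        assert ev.percent_evolution == pytest.approx(30.0)
        assert ev.timing == "early"

    def test_undefined_when_endpoints_equal(self):
        with pytest.raises(ValidationError):
            el.percent_evolution(0.5, 0.4, 0.5)

    def test_overshoot_allowed_not_clamped(self, caplog):
        with caplog.at_level("WARNING"):
            value = el.percent_evolution(1.0, -0.1, 0.0)
        assert value == pytest.approx(110.0)
        assert any("overshoot" in r.message for r in caplog.records)

    @given(
        b_r=hst.floats(-2, 2),
        b_ts=hst.floats(-2, 2),
        b_i=hst.floats(-2, 2),
        a=hst.floats(0.1, 5.0),
        b=hst.floats(-3, 3),
        neg=hst.booleans(),
    )
    @settings(max_examples=100, deadline=None)
    def test_affine_invariance(self, b_r, b_ts, b_i, a, b, neg):
        if abs(b_i - b_r) < 1e-6:
            return
        if neg:
            a = -a
        base = el.percent_evolution(b_r, b_ts, b_i)
        scaled = el.percent_evolution(a * b_r + b, a * b_ts + b, a * b_i + b)
        assert scaled == pytest.approx(base, rel=1e-6, abs=1e-6)


class TestSynchronicity:
    def test_equal_evolutions_sy_one(self):
        assert el.synchronicity([60.0, 60.0]).synchronicity == pytest.approx(1.0)

    def test_hand_oracle_60_40(self):
        # mean 50, sum|dev|/mean = 0.4, /(2n-2) = 0.2 -> Sy = 0.8
        assert el.synchronicity([60.0, 40.0]).synchronicity == pytest.approx(0.8)

    def test_hand_oracle_100_0(self):
        assert el.synchronicity([100.0, 0.0]).synchronicity == pytest.approx(0.0)

    def test_single_input_rejected(self):
        with pytest.raises(ValidationError):
            el.synchronicity([60.0])

    def test_zero_mean_rejected(self):
        with pytest.raises(ValidationError):
            el.synchronicity([50.0, -50.0])

    def test_negative_sy_warned_not_clipped(self, caplog):
        # overshoot evolutions can push Sy below zero; report as-is
        with caplog.at_level("WARNING"):
            result = el.synchronicity([150.0, -50.0])
        assert result.synchronicity == pytest.approx(-1.0)
        assert any("asynchrony" in r.message for r in caplog.records)

    @given(
        values=hst.lists(hst.floats(1.0, 99.0), min_size=2, max_size=6),
        seed=hst.integers(0, 100),
    )
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance_and_bound(self, values, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(values)
        rng.shuffle(shuffled)
        a = el.synchronicity(values).synchronicity
        b = el.synchronicity(shuffled).synchronicity
        assert a == pytest.approx(b, abs=1e-9)
        assert a <= 1.0 + 1e-12

    @given(values=hst.lists(hst.floats(1.0, 99.0), min_size=2, max_size=6))
    @settings(max_examples=60, deadline=None)
    def test_sy_is_one_iff_all_equal(self, values):
        result = el.synchronicity(values)
        if max(values) - min(values) < 1e-9:
            assert result.synchronicity == pytest.approx(1.0)
        else:
            assert result.synchronicity < 1.0


class TestStationaryEvolutions:
    def test_matches_ground_truth(self, aromatic_data):
        spec, _, truth = aromatic_data
        pts = syn.make_stationary_points(spec)
        result = el.stationary_evolutions(pts, ["C1-H5", "H5-O6"])
        for ev in result.evolutions:
            assert ev.percent_evolution == pytest.approx(
                truth.percent_evolution[ev.bond], abs=1e-9
            )
        assert result.synchronicity == pytest.approx(truth.synchronicity, abs=1e-9)

    def test_identical_sigmoids_sy_one(self):
        spec = syn.SyntheticSpec(
            wbi_break=syn.LogisticParams(-0.2, 0.3),
            wbi_form=syn.LogisticParams(-0.2, 0.3),
        )
        pts = syn.make_stationary_points(spec)
        result = el.stationary_evolutions(pts, ["C1-H5", "H5-O6"])
        assert result.synchronicity == pytest.approx(1.0, abs=1e-9)

    def test_single_bond_rejected(self, aromatic_spec):
        pts = syn.make_stationary_points(aromatic_spec)
        with pytest.raises(ValidationError):
            el.stationary_evolutions(pts, ["C1-H5"])

    def test_missing_role_named(self, aromatic_spec):
        pts = [p for p in syn.make_stationary_points(aromatic_spec) if p.role != "intermediate"]
        with pytest.raises(ValidationError, match="intermediate"):
            el.stationary_evolutions(pts, ["C1-H5", "H5-O6"])

    def test_missing_bond_named(self, aromatic_spec):
        pts = syn.make_stationary_points(aromatic_spec)
        with pytest.raises(ValidationError, match="C4-N3"):
            el.stationary_evolutions(pts, ["C1-H5", "N3-C4"])

    def test_bond_labels_order_normalized(self, aromatic_spec):
        pts = syn.make_stationary_points(aromatic_spec)
        a = el.stationary_evolutions(pts, ["C1-H5", "H5-O6"])
        b = el.stationary_evolutions(pts, ["H5-C1", "O6-H5"])
        assert a.synchronicity == pytest.approx(b.synchronicity, abs=1e-12)


class TestChannelSeries:
    def test_constant_channel_min_equals_max(self):
        from ircmech.io_formats import IRCProfile

        prof = IRCProfile(
            xi=[-1, 0, 1], energy=[0, 1, 0], charges={"C1": [0.5, 0.5, 0.5]}
        )
        s = el.charge_series(prof, "C1").summary()
        assert s["min"] == s["max"]

    def test_charge_dip_location(self):
        spec = syn.SyntheticSpec(charge_center=0.2)
        profile, truth = syn.make_profile(spec)
        series = el.charge_series(profile, "C1")
        step = profile.xi[1] - profile.xi[0]
        assert abs(series.argmin_xi() - 0.2) <= step + 1e-12

    def test_dipole_directions(self, aromatic_data, aliphatic_data):
        aro = el.dipole_series(aromatic_data[1])
        ali = el.dipole_series(aliphatic_data[1])
        assert aro.values[-1] < aro.values[0]
        assert ali.values[-1] > ali.values[0]

    def test_missing_channel_errors(self, gaussian_data):
        _, profile, _ = gaussian_data
        with pytest.raises(ValidationError):
            el.charge_series(profile, "Zz1")
        with pytest.raises(ValidationError):
            el.wbi_series(profile, "N3-C4")
        from ircmech.io_formats import IRCProfile

        bare = IRCProfile(xi=profile.xi, energy=profile.energy)
        with pytest.raises(ValidationError):
            el.dipole_series(bare)

    def test_wbi_series_label_normalization(self, aromatic_data):
        _, profile, _ = aromatic_data
        a = el.wbi_series(profile, "C1-H5")
        b = el.wbi_series(profile, "H5-C1")
        np.testing.assert_array_equal(a.values, b.values)


class TestWbiEvolutionCurve:
    def test_identical_logistics_zero_deviation(self):
        spec = syn.SyntheticSpec(
            wbi_break=syn.LogisticParams(-0.2, 0.3),
            wbi_form=syn.LogisticParams(-0.2, 0.3),
        )
        profile, _ = syn.make_profile(spec)
        curve = el.wbi_evolution_curve(profile, "C1-H5", "H5-O6")
        assert curve.deviation == pytest.approx(0.0, abs=1e-9)

    def test_offset_midpoints_lagging_sign(self):
        spec = syn.SyntheticSpec(
            wbi_break=syn.LogisticParams(-0.15, 0.35),
            wbi_form=syn.LogisticParams(0.15, 0.35),  # forming lags by 0.3
        )
        profile, _ = syn.make_profile(spec)
        curve = el.wbi_evolution_curve(profile, "C1-H5", "H5-O6")
        assert curve.deviation < -1e-3

    def test_flat_channel_rejected(self):
        from ircmech.io_formats import IRCProfile

        n = 21
        xi = np.linspace(-2, 2, n)
        prof = IRCProfile(
            xi=xi,
            energy=np.exp(-(xi**2)),
            wbi={"C1-H5": np.ones(n), "H5-O6": 1 / (1 + np.exp(-xi))},
        )
        with pytest.raises(ValidationError, match="flat"):
            el.wbi_evolution_curve(prof, "C1-H5", "H5-O6")

    def test_wbi_less_asynchronous_than_lengths(self, aliphatic_spec):
        from ircmech import structure as st

        profile, _ = syn.make_profile(aliphatic_spec)
        geoms = syn.make_trajectory(aliphatic_spec)
        wbi_curve = el.wbi_evolution_curve(profile, "C1-H5", "H5-O6")
        len_curve = st.length_evolution_curve(
            st.distance_series(geoms, "C1", "H5"),
            st.distance_series(geoms, "H5", "O6"),
        )
        assert wbi_curve.max_abs_deviation < len_curve.max_abs_deviation
        assert len_curve.deviation < 0  # below the diagonal


class TestAromaticAliphaticContrast:
    def test_aliphatic_percent_evolution_higher(self, aromatic_spec, aliphatic_spec):
        results = {}
        for spec in (aromatic_spec, aliphatic_spec):
            pts = syn.make_stationary_points(spec)
            results[spec.name] = el.stationary_evolutions(pts, ["C1-H5", "H5-O6"])
        assert (
            results["aliphatic_like"].mean_evolution
            > results["aromatic_like"].mean_evolution
        )
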