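"""Phantom generator: forward model, noise, determinism, built-in scenarios."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import nanofret as nf
from nanofret.calibration import ratio_from_integrity
from nanofret.synthetic import (
    ConstantConcentration,
    Ellipse,
    ExponentialDecay,
    LogisticSchedule,
    Rect,
    RegionSpec,
    SaturatingUptake,
    Scenario,
    ScenarioError,
    builtin_scenarios,
    expected_signal,
    generate_calibration_plate,
    generate_frame,
    generate_timeseries,
)

CAL = nf.DEFAULT_CALIBRATION


def simple_region(integrity=100.0, brightness=1000.0, fret=True):
    sched = LogisticSchedule(a1=integrity, a2=integrity * 0.999, x0=8.0, p=2.0)
    return RegionSpec(
        name="liver",
        footprint=Ellipse(center=(10, 10), radii=(5, 5)),
        integrity=sched,
        concentration=ConstantConcentration(1.0),
        brightness=brightness,
        fret=fret,
    )


class TestExpectedSignal:
    def test_full_integrity_split(self):
        region = RegionSpec(
            name="liver",
            footprint=Ellipse((10, 10), (5, 5)),
            integrity=LogisticSchedule(100, 100, 8, 2),  # pinned at 100%
            concentration=ConstantConcentration(1.0),
            brightness=1000.0,
        )
        d, a = expected_signal(region, 1.0, CAL)
        assert a == pytest.approx(865.905, abs=0.01)
        assert d == pytest.approx(134.095, abs=0.01)

    def test_zero_integrity_split(self):
        region = RegionSpec(
            name="liver",
            footprint=Ellipse((10, 10), (5, 5)),
            integrity=LogisticSchedule(0, 0, 8, 2),
            concentration=ConstantConcentration(1.0),
            brightness=1000.0,
        )
        d, a = expected_signal(region, 1.0, CAL)
        assert a == pytest.approx(271.12, abs=0.01)
        assert d == pytest.approx(728.88, abs=0.01)

    def test_no_carrier_no_signal(self):
        region = simple_region(brightness=0.0)
        assert expected_signal(region, 1.0, CAL) == (0.0, 0.0)

    def test_donor_only_routes_everything_to_donor(self):
        d, a = expected_signal(simple_region(fret=False), 2.0, CAL)
        assert a == 0.0
        assert d == pytest.approx(1000.0)

    @given(
        t=st.floats(0.01, 48),
        x0=st.floats(1, 20),
        p=st.floats(0.5, 4),
        half=st.floats(0.5, 10),
        brightness=st.floats(10, 5000),
    )
    @settings(max_examples=60, derandomize=True)
    def test_channel_sum_conserves_total_signal(self, t, x0, p, half, brightness):
        region = RegionSpec(
            name="tumor",
            footprint=Rect((0, 4), (0, 4)),
            integrity=LogisticSchedule(100, 0, x0, p),
            concentration=ExponentialDecay(half),
            brightness=brightness,
        )
        d, a = expected_signal(region, t, CAL)
        total = brightness * region.concentration(t)
        assert d + a == pytest.approx(total, rel=1e-12)
        assert d >= 0 and a >= 0


class TestSchedules:
    def test_through_point_matches_independent_root(self):
        # frozen from a brentq root-finding oracle over the same endpoint equations
        liver = LogisticSchedule.through_point(66.0, 6.0, x0=8.2)
        tumor = LogisticSchedule.through_point(77.0, 2.0, x0=4.4)
        assert liver.p == pytest.approx(2.123392993003766, abs=1e-12)
        assert tumor.p == pytest.approx(1.532500381969026, abs=1e-12)
        assert liver(6.0) == pytest.approx(66.0, abs=1e-9)
        assert tumor(2.0) == pytest.approx(77.0, abs=1e-9)

    def test_through_point_rejects_inconsistent_endpoint(self):
        with pytest.raises(ScenarioError):
            LogisticSchedule.through_point(120.0, 6.0, x0=8.2)

    def test_concentration_invariants(self):
        with pytest.raises(ScenarioError):
            ExponentialDecay(half_time_h=0)
        with pytest.raises(ScenarioError):
            SaturatingUptake(rise_time_h=-1)
        with pytest.raises(ScenarioError):
            ConstantConcentration(-0.5)


@pytest.fixture(scope="module")
def scenario():
    return builtin_scenarios(seed=11)["healthy"]


class TestFrames:

    def test_pre_injection_frame_is_background_only(self, scenario):
        frame = generate_frame(scenario, 0.0, nf.ACCEPTOR)
        # shot noise on a mean-4 background: region means stay near 4 everywhere
        for mask in scenario.region_masks().values():
            assert abs(frame.data[mask].mean() - scenario.background_acceptor) < 1.0

    def test_pre_injection_independent_of_schedules(self, scenario):
        slower = dataclasses.replace(
            scenario,
            regions=tuple(
                dataclasses.replace(r, concentration=ConstantConcentration(0.7))
                for r in scenario.regions
            ),
        )
        f1 = generate_frame(scenario, 0.0, nf.DONOR)
        f2 = generate_frame(slower, 0.0, nf.DONOR)
        assert np.array_equal(f1.data, f2.data)

    def test_fixed_seed_bit_identical(self, scenario):
        f1 = generate_frame(scenario, 6.0, nf.DONOR)
        f2 = generate_frame(scenario, 6.0, nf.DONOR)
        assert np.array_equal(f1.data, f2.data)

    def test_channels_and_times_use_distinct_streams(self, scenario):
        assert not np.array_equal(
            generate_frame(scenario, 6.0, nf.DONOR).data,
            generate_frame(scenario, 6.0, nf.ACCEPTOR).data,
        )
        assert not np.array_equal(
            generate_frame(scenario, 3.0, nf.DONOR).data,
            generate_frame(scenario, 6.0, nf.DONOR).data,
        )

    def test_unknown_channel_rejected(self, scenario):
        with pytest.raises(ScenarioError, match="channel"):
            generate_frame(scenario, 6.0, "teal")

    def test_early_tail_vein_ratio_near_full_integrity(self, scenario):
        donor = generate_frame(scenario, 0.25, nf.DONOR)
        acceptor = generate_frame(scenario, 0.25, nf.ACCEPTOR)
        mask = scenario.region_masks()["tail_vein"]
        d = donor.data[mask].mean() - scenario.background_donor
        a = acceptor.data[mask].mean() - scenario.background_acceptor
        expected = ratio_from_integrity(CAL, scenario.regions[0].integrity(0.25))
        assert a / (a + d) == pytest.approx(expected, abs=0.01)

    def test_noise_off_yields_exact_expected_counts(self, scenario):
        quiet = dataclasses.replace(scenario, noise=nf.NoiseModel.off())
        frame = generate_frame(quiet, 6.0, nf.ACCEPTOR)
        assert frame.data.dtype == np.float32
        mask = quiet.region_masks()["liver"]
        _, a = expected_signal(quiet.regions[1], 6.0, CAL)
        assert frame.data[mask].mean() == pytest.approx(a + quiet.background_acceptor, rel=1e-6)


class TestTimeseries:
    def test_file_census_and_reload(self, tmp_path):
        scenario = dataclasses.replace(
            builtin_scenarios(seed=5)["healthy"], times=(0.0, 1.0, 2.0, 3.0, 6.0, 24.0)
        )
        manifest = generate_timeseries(scenario, tmp_path / "run")
        tiffs = sorted(p.name for p in (tmp_path / "run").glob("*.tif"))
        assert len(tiffs) == 13  # 6 times x 2 channels + ROI mask
        assert (tmp_path / "run" / "manifest.json").exists()
        back = nf.read_manifest(tmp_path / "run" / "manifest.json")
        assert back.scenario == "healthy"
        assert back.times == list(scenario.times)
        assert back.seed == 5
        rois = back.load_rois()
        assert set(rois.names.values()) == {"tail_vein", "liver", "body"}

    def test_deleting_frame_breaks_loading_with_name(self, tmp_path):
        scenario = dataclasses.replace(
            builtin_scenarios(seed=5)["healthy"], times=(0.0, 1.0)
        )
        manifest = generate_timeseries(scenario, tmp_path / "run")
        victim = manifest.frame_path(manifest.find(1.0, nf.DONOR))
        victim.unlink()
        with pytest.raises(nf.image_io.ImageIOError, match=victim.name):
            manifest.load_frame(1.0, nf.DONOR)

    def test_scenario_json_round_trip(self, tmp_path):
        scenario = builtin_scenarios(seed=9)["tumor_bearing"]
        path = tmp_path / "scenario.json"
        scenario.to_json(path)
        assert Scenario.from_json(path) == scenario


class TestCalibrationPlate:
    def test_noiseless_plate_hits_law_exactly(self):
        series = generate_calibration_plate(CAL, levels=(0, 100), sigma=0.0)
        ratios = series.data.groupby("integrity_percent")["ratio"].first()
        assert ratios[0] == pytest.approx(0.27112, abs=1e-9)
        assert ratios[100] == pytest.approx(0.8659053635, abs=1e-9)
        assert len(series.data) == 6  # triplicate

    def test_seeded_plate_reproducible(self):
        s1 = generate_calibration_plate(CAL, sigma=0.005, seed=3)
        s2 = generate_calibration_plate(CAL, sigma=0.005, seed=3)
        assert np.array_equal(s1.data["ratio"], s2.data["ratio"])

    def test_out_of_range_level_rejected(self):
        with pytest.raises(nf.calibration.CalibrationError):
            generate_calibration_plate(CAL, levels=(0, 150), sigma=0.0)


class TestBuiltinScenarios:
    def test_schedules_encode_observed_endpoints(self):
        s = builtin_scenarios(seed=0)
        by_name = {r.name: r for r in s["healthy"].regions}
        assert by_name["liver"].integrity(6.0) == pytest.approx(66.0, abs=1e-9)
        assert by_name["tail_vein"].integrity(6.0) == pytest.approx(93.0, abs=1e-9)
        t = {r.name: r for r in s["tumor_bearing"].regions}
        assert t["tumor"].integrity(2.0) == pytest.approx(77.0, abs=1e-9)
        assert t["tumor"].integrity(6.0) == pytest.approx(38.336, abs=0.01)  # within 40 +/- 4
        assert t["tail_vein"].integrity(6.0) == pytest.approx(71.0, abs=1e-9)
        assert by_name["tail_vein"].concentration.half_time_h == 3.0

    def test_donor_only_acceptor_frames_are_background(self):
        scenario = builtin_scenarios(seed=2)["donor_only"]
        frame = generate_frame(scenario, 2.0, nf.ACCEPTOR)
        assert abs(frame.data.mean() - scenario.background_acceptor) < 1.0

    def test_region_masks_disjoint(self):
        for scenario in builtin_scenarios(seed=0).values():
            masks = list(scenario.region_masks().values())
            stacked = np.sum(masks, axis=0)
            assert stacked.max() == 1

    def test_overlapping_regions_rejected(self):
        with pytest.raises(ScenarioError, match="disjoint"):
            Scenario(
                name="bad",
                regions=(
                    RegionSpec(name="liver", footprint=Ellipse((10, 10), (5, 5))),
                    RegionSpec(name="tumor", footprint=Ellipse((12, 12), (5, 5))),
                ),
                shape=(32, 32),
            )

    def test_times_must_start_at_zero(self):
        with pytest.raises(ScenarioError, match="pre-injection"):
            dataclasses.replace(builtin_scenarios(seed=0)["healthy"], times=(1.0, 2.0))
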