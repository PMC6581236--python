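import json

import numpy as np
import pandas as pd
import pytest

from pairflight import kinematics as kin, trackgeo as tg
from pairflight import io as pfio
from pairflight.synthio import (
    build_scenario,
    emit_dataset,
    kappa_from_accuracy,
    make_birds,
    mean_cos_vonmises,
    simulate_accel,
    simulate_flight_summaries,
    simulate_track,
    simulate_wingbeat_rows,
    two_segment_wave,
)
from pairflight.synthio.config import (
    FlightPlan,
    PopulationConfig,
    ScenarioConfig,
    SimConfig,
    TruthRecord,
)

CALM = SimConfig(gps_noise_sd_m=0.0)


class TestMakeBirds:
    def test_population_moments(self):
        birds = make_birds(20, seed=0)
        freqs = np.array([b.solo_freq_hz for b in birds])
        assert len(birds) == 20
        assert abs(freqs.mean() - 5.48) < 3 * 0.19 / np.sqrt(20)

    def test_degenerate_sds(self):
        pop = PopulationConfig(freq_sd_hz=0.0, tarsus_sd_mm=0.0, mass_sd_g=0.0)
        (bird,) = make_birds(1, seed=3, pop=pop)
        assert bird.solo_freq_hz == 5.48
        assert bird.tarsus_mm == pop.tarsus_mean_mm
        assert bird.mass_g == pop.mass_mean_g

    def test_seed_determinism(self):
        assert make_birds(10, seed=7) == make_birds(10, seed=7)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_birds(0, seed=1)
        with pytest.raises(ValueError):
            PopulationConfig(freq_sd_hz=-0.1)


class TestBesselCalibration:
    @pytest.mark.parametrize("target", [0.1, 0.3, 0.5, 0.7, 0.86, 0.92, 0.99])
    def test_mean_cosine_matches_target(self, target, rng):
        kappa = kappa_from_accuracy(target)
        draws = rng.vonmises(0.0, kappa, 10_000)
        assert abs(np.mean(np.cos(draws)) - target) < 0.01

    def test_inverse_consistency(self):
        for a in (0.2, 0.6, 0.95):
            assert mean_cos_vonmises(kappa_from_accuracy(a)) == pytest.approx(a, abs=1e-8)

    def test_out_of_range_error(self):
        for bad in (0.0, 1.0, 1.2, -0.3):
            with pytest.raises(ValueError):
                kappa_from_accuracy(bad)


def solo_plan(i=0, **kw):
    return FlightPlan(flight_id=f"S{i}", phase=1, condition="solo", bird_ids=("B01",), **kw)


def pair_plan(i=0, **kw):
    return FlightPlan(
        flight_id=f"P{i}", phase=2, condition="pair", bird_ids=("B01", "B02"),
        pair_id="B01-B02", **kw
    )


class TestSimulateTrack:
    def test_near_unit_accuracy_is_straight(self):
        truth = TruthRecord(accuracy_solo=0.9999)
        birds = make_birds(2, 1)
        trk = simulate_track(solo_plan(), birds, truth, seed=0, cfg=CALM)["B01"]
        assert tg.route_accuracy(trk, CALM.loft_latlon) == pytest.approx(1.0, abs=1e-3)

    def test_monte_carlo_calibration(self):
        # mean over many flights matches the Bessel-ratio calibration target
        truth = TruthRecord(accuracy_solo=0.86)
        birds = make_birds(2, 1)
        accs = [
            tg.route_accuracy(
                simulate_track(solo_plan(i), birds, truth, seed=i, cfg=CALM)["B01"],
                CALM.loft_latlon,
            )
            for i in range(200)
        ]
        assert abs(np.mean(accs) - 0.86) < 0.01

    def test_paired_spacing_contract(self):
        truth = TruthRecord()
        birds = make_birds(2, 1)
        close_fracs, fronts = [], []
        for i in range(10):
            trks = simulate_track(pair_plan(i), birds, truth, seed=i, cfg=CALM)
            ctx = tg.pair_spacing_and_masks(trks["B01"], trks["B02"])
            close_fracs.append(np.mean(ctx.spacing_m < 50.0))
            fronts.append(ctx.front_fraction)
        assert np.mean(close_fracs) >= 0.8
        assert np.mean(fronts) > 0.9  # first-listed bird leads consistently

    def test_seed_determinism(self):
        truth = TruthRecord()
        birds = make_birds(2, 1)
        a = simulate_track(solo_plan(), birds, truth, seed=5)["B01"]
        b = simulate_track(solo_plan(), birds, truth, seed=5)["B01"]
        assert np.array_equal(a.lat, b.lat) and np.array_equal(a.lon, b.lon)


class TestSimulateAccel:
    def test_solo_round_trip(self):
        truth = TruthRecord(residual_sd_hz=0.0, pp_accel_g=2.5)
        birds = make_birds(1, 1, PopulationConfig(freq_sd_hz=0.0))
        tr = simulate_accel(solo_plan(), birds, truth, seed=0)["B01"]
        wb = kin.dorsal_pipeline(tr)
        assert wb.freq_hz.median() == pytest.approx(5.48, abs=0.01)
        assert wb.pp_accel_g.median() == pytest.approx(2.5, abs=0.1)

    def test_pair_frequency_shift(self):
        truth = TruthRecord(
            delta0_hz=1.0, spacing_slope_hz_per_m=0.0, residual_sd_hz=0.0
        )
        birds = make_birds(2, 1, PopulationConfig(freq_sd_hz=0.0, tarsus_sd_mm=0.0))
        solo = simulate_accel(solo_plan(), birds, truth, seed=0)["B01"]
        pair = simulate_accel(pair_plan(), birds, truth, seed=0)["B01"]
        f_solo = kin.dorsal_pipeline(solo).freq_hz.median()
        f_pair = kin.dorsal_pipeline(pair).freq_hz.median()
        assert f_pair - f_solo == pytest.approx(1.0, abs=0.02)

    def test_pair_shortens_upstroke_only(self):
        truth = TruthRecord(
            delta0_hz=1.0, spacing_slope_hz_per_m=0.0, residual_sd_hz=0.0
        )
        birds = make_birds(2, 1, PopulationConfig(freq_sd_hz=0.0, tarsus_sd_mm=0.0))
        solo = kin.dorsal_pipeline(simulate_accel(solo_plan(), birds, truth, seed=0)["B01"])
        pair = kin.dorsal_pipeline(simulate_accel(pair_plan(), birds, truth, seed=0)["B01"])
        assert pair.down_ms.median() == pytest.approx(solo.down_ms.median(), abs=1.5)
        assert pair.up_ms.median() < solo.up_ms.median() - 20.0

    def test_sinusoid_mode_harmonic_displacement(self):
        truth = TruthRecord(residual_sd_hz=0.0, pp_accel_g=2.5)
        birds = make_birds(1, 1, PopulationConfig(freq_sd_hz=0.0))
        cfg = SimConfig(waveform="sinusoid")
        tr = simulate_accel(solo_plan(), birds, truth, seed=0, cfg=cfg)["B01"]
        wb = kin.dorsal_pipeline(tr)
        expected = 2.5 * 9.80665 / (2 * np.pi * 5.48) ** 2 * 1000.0
        assert wb.pp_disp_mm.median() == pytest.approx(expected, abs=0.5)

    def test_non_positive_frequency_error(self):
        truth = TruthRecord(delta0_hz=-10.0, residual_sd_hz=0.0)
        birds = make_birds(2, 1)
        with pytest.raises(ValueError):
            simulate_accel(pair_plan(), birds, truth, seed=0)

    def test_waveform_segments_sum_to_period(self):
        wave = two_segment_wave(10.0, 5.48, 2.5, 0.0487, 200.0)
        # max at every cycle start; exactly one min per cycle
        period = 1.0 / 5.48
        t = np.arange(len(wave)) / 200.0
        cyc = np.floor(t / period).astype(int)
        for c in range(1, 5):
            seg = wave[cyc == c]
            assert np.sum(np.diff(np.sign(np.diff(seg))) != 0) <= 2


class TestSummaries:
    def test_flight_summary_moments(self):
        birds = make_birds(10, 2)
        truth = TruthRecord(delta0_hz=1.0, residual_sd_hz=0.05)
        df = simulate_flight_summaries(birds, truth, n_solo=6, n_pair=6, seed=3)
        assert len(df) == 10 * 12
        solo = df[df.is_pair == 0].median_freq_hz.mean()
        pair = df[df.is_pair == 1].median_freq_hz.mean()
        assert pair - solo == pytest.approx(1.0, abs=0.1)

    def test_wingbeat_rows_shape(self):
        rows = simulate_wingbeat_rows(
            n_pair_flights=5, n_solo_flights=5, beats_per_flight=20, seed=1
        )
        assert len(rows) == 200
        assert (rows.loc[rows.is_pair == 0, "spacing_m"] == 0).all()


class TestEmitDataset:
    @pytest.fixture
    def tiny(self, tmp_path):
        scenario = ScenarioConfig(n_birds=2, flights_per_phase=1)
        truth = TruthRecord()
        birds, plans = build_scenario(scenario, truth, seed=4)
        cfg = SimConfig(accel_duration_s=5.0)
        tracks = {p.flight_id: simulate_track(p, birds, truth, 4, cfg) for p in plans}
        traces = {p.flight_id: simulate_accel(p, birds, truth, 4, cfg) for p in plans}
        return birds, plans, tracks, traces, truth, tmp_path

    def test_round_trip(self, tiny):
        birds, plans, tracks, traces, truth, tmp = tiny
        paths = emit_dataset(plans, tracks, traces, birds, truth, tmp / "d")
        bdf = pfio.read_birds(paths["birds"])
        assert list(bdf.bird_id) == [b.bird_id for b in birds]
        flights = pfio.read_flights(paths["flights"])
        weather = pfio.read_weather(paths["weather"])
        assert pfio.frame_to_plans(flights, weather) == plans
        gps = pfio.read_gps(paths["gps"])
        rebuilt = pfio.gps_frame_to_tracks(gps)
        key = (plans[0].flight_id, plans[0].bird_ids[0])
        assert np.allclose(rebuilt[key].lat, tracks[plans[0].flight_id][plans[0].bird_ids[0]].lat)
        truth_doc = json.loads(paths["truth"].read_text())
        assert truth_doc["delta0_hz"] == truth.delta0_hz

    def test_empty_plans_schema_valid(self, tmp_path):
        birds = make_birds(2, 1)
        paths = emit_dataset([], {}, {}, birds, TruthRecord(), tmp_path / "e")
        gps = pfio.read_gps(paths["gps"])
        assert gps.empty and list(gps.columns) == pfio.SCHEMAS["gps.csv"]

    def test_byte_identical_reruns(self, tiny, tmp_path):
        birds, plans, tracks, traces, truth, tmp = tiny
        p1 = emit_dataset(plans, tracks, traces, birds, truth, tmp_path / "a")
        p2 = emit_dataset(plans, tracks, traces, birds, truth, tmp_path / "b")
        for k in p1:
            assert p1[k].read_bytes() == p2[k].read_bytes()

    def test_id_mismatch_error(self, tiny):
        birds, plans, tracks, traces, truth, tmp = tiny
        bad = dict(tracks)
        bad["NOPE"] = list(tracks.values())[0]
        with pytest.raises(ValueError, match="NOPE"):
            emit_dataset(plans, bad, traces, birds, truth, tmp / "x")


class TestScenario:
    def test_four_phase_design(self):
        birds, plans = build_scenario(ScenarioConfig(n_birds=4, flights_per_phase=2), seed=0)
        phases = pd.Series([p.phase for p in plans]).value_counts().to_dict()
        assert phases[1] == phases[4] == 8  # per-bird solo releases
        assert phases[2] == phases[3] == 4  # pair releases (two birds each)
        for p in plans:
            assert (p.condition == "pair") == (len(p.bird_ids) == 2)

    def test_similar_vs_different_pairing(self):
        birds, plans = build_scenario(ScenarioConfig(n_birds=6, flights_per_phase=1), seed=0)
        tarsus = {b.bird_id: b.tarsus_mm for b in birds}
        gaps = {2: [], 3: []}
        for p in plans:
            if p.condition == "pair":
                a, b = p.bird_ids
                gaps[p.phase].append(abs(tarsus[a] - tarsus[b]))
        assert np.mean(gaps[2]) < np.mean(gaps[3])
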