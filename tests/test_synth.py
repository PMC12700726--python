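"""Ground-truth generators: determinism, planted structure, range contracts."""

import numpy as np
import pytest
from scipy import stats

from nocturne.acoustics import band_limit, compute_power_spectrogram
from nocturne.social import dai_matrix, davids_score, kinship_counts
from nocturne.synth import (
    SimulationConfig,
    gen_behaviors,
    gen_counts_and_attributes,
    gen_night_audio,
    gen_social,
    gen_weather,
    planted_aci,
)


@pytest.fixture(scope="module")
def cfg():
    return SimulationConfig.desk_scale()


class TestDeterminism:
    def test_audio_identical_for_same_seed(self, cfg):
        a = gen_night_audio(cfg, 5)
        b = gen_night_audio(cfg, 5)
        assert np.array_equal(a.waveform, b.waveform)
        assert a.calls.equals(b.calls)

    def test_audio_differs_across_seeds(self, cfg):
        assert not np.array_equal(
            gen_night_audio(cfg, 5).waveform, gen_night_audio(cfg, 6).waveform
        )

    def test_weather_social_counts_reproducible(self, cfg):
        w1, _ = gen_weather(cfg, 3, 50)
        w2, _ = gen_weather(cfg, 3, 50)
        assert w1.equals(w2)
        s1, s2 = gen_social(cfg, 4), gen_social(cfg, 4)
        assert np.array_equal(s1.wins, s2.wins)
        assert np.array_equal(s1.proximity.dyad_seconds, s2.proximity.dyad_seconds)
        c1, _ = gen_counts_and_attributes(cfg, 7)
        c2, _ = gen_counts_and_attributes(cfg, 7)
        assert c1.equals(c2)


class TestNightAudio:
    def test_call_energy_localized_when_noise_free(self, cfg):
        quiet = cfg.replace(
            {"audio": {"noise_floor": 0.0, "wind_noise_coef": 0.0},
             "hourly_rate": [4, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]}
        )
        night = gen_night_audio(quiet, 123)
        assert len(night.calls) >= 1
        active = np.flatnonzero(np.abs(night.waveform) > 0)
        assert active.size > 0
        dur = int(quiet["audio"]["call"]["duration_s"] * night.sample_rate)
        spans = [(s, s + dur) for s in night.calls["sample"]]
        assert all(any(lo <= i <= hi for lo, hi in spans) for i in active)

    def test_doubling_rates_roughly_doubles_calls(self, cfg):
        rates = np.array(cfg["hourly_rate"], dtype=float)
        doubled = cfg.replace({"hourly_rate": (2 * rates).tolist()})
        n1 = np.mean([len(gen_night_audio(cfg, 100 + s).calls) for s in range(5)])
        n2 = np.mean([len(gen_night_audio(doubled, 200 + s).calls) for s in range(5)])
        mu = rates.sum()
        sigma = np.sqrt(2 * mu / 5)
        assert abs(n2 - 2 * n1) < 3 * sigma + 3 * np.sqrt(mu / 5)

    def test_call_energy_sits_in_harmonic_band(self, cfg):
        quiet = cfg.replace(
            {"audio": {"noise_floor": 0.0},
             "hourly_rate": [5, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]}
        )
        night = gen_night_audio(quiet, 3)
        spec = compute_power_spectrogram(night.waveform[: night.sample_rate * 30],
                                         night.sample_rate, 256, 128)
        f0 = quiet["audio"]["call"]["fundamental_hz"]
        in_band = band_limit(spec, f0 - 200, f0 + 200).power.sum()
        out_band = band_limit(spec, 2800, 3300).power.sum()
        assert in_band > out_band

    def test_silent_profile_gives_empty_log(self, cfg):
        silent = cfg.replace({"hourly_rate": [0] * 13})
        night = gen_night_audio(silent, 9)
        assert len(night.calls) == 0


class TestSocialGenerator:
    def test_planted_hierarchy_recovered_by_davids_score(self, cfg):
        ok = 0
        for seed in range(10):
            soc = gen_social(cfg, seed, n_individuals=10)
            ds = davids_score(soc.wins, ids=soc.ids).ds
            rho = stats.spearmanr(np.arange(10), -ds).statistic
            ok += rho > 0.9
        assert ok >= 9

    def test_within_family_association_exceeds_between(self, cfg):
        soc = gen_social(cfg, 2)
        m = dai_matrix(soc.proximity).values
        fam_of = {ind: k for k, fam in enumerate(soc.families) for ind in fam}
        within, between = [], []
        for i, a in enumerate(soc.ids):
            for j in range(i + 1, len(soc.ids)):
                (within if fam_of[a] == fam_of[soc.ids[j]] else between).append(m[i, j])
        assert np.mean(within) > np.mean(between)

    def test_pedigree_kinship_counts(self, cfg):
        soc = gen_social(cfg, 1, n_individuals=3)  # one family: mother + 2 offspring
        counts = kinship_counts(soc.pedigree, soc.ids)
        assert counts == {soc.ids[0]: 2, soc.ids[1]: 2, soc.ids[2]: 2}


class TestCountsGenerator:
    def test_zero_betas_zero_sd_gives_iid_poisson(self, cfg):
        null = {"rank": 0.0, "sex": 0.0, "age": 0.0, "centrality": 0.0,
                "relatives": 0.0, "intercept": 2.0}
        data, _ = gen_counts_and_attributes(cfg, 3, n_individuals=200, n_periods=5,
                                            betas=null, random_sd=0.0)
        counts = data["count"].to_numpy()
        lam = np.exp(2.0)
        assert counts.mean() == pytest.approx(lam, abs=3 * np.sqrt(lam / counts.size))
        assert counts.var() == pytest.approx(lam, rel=0.15)

    def test_sex_effect_matches_rate_ratio(self, cfg):
        b = {"rank": 0.0, "age": 0.0, "centrality": 0.0, "relatives": 0.0,
             "sex": -1.909, "intercept": 4.0}
        data, _ = gen_counts_and_attributes(cfg, 8, n_individuals=600, n_periods=2,
                                            betas=b, random_sd=0.0)
        means = data.groupby("sex")["count"].mean()
        ratio = means["female"] / means["male"]
        assert ratio == pytest.approx(np.exp(-1.909), rel=0.1)

    def test_random_intercept_creates_overdispersion(self, cfg):
        data, _ = gen_counts_and_attributes(
            cfg, 9, n_individuals=100, n_periods=30,
            betas={"rank": 0, "sex": 0, "age": 0, "centrality": 0, "relatives": 0,
                   "intercept": 3.0},
            random_sd=1.0,
        )
        per_ind = data.groupby("id")["count"].mean()
        assert per_ind.var() > per_ind.mean()  # far beyond Poisson at sd=1


class TestWeatherGenerator:
    def test_range_contracts(self, cfg):
        w, _ = gen_weather(cfg, 4, 500)
        assert w["humidity"].between(0, 100).all()
        assert w["wind_direction"].between(0, 360, inclusive="left").all()
        assert (w["precipitation"] >= 0).all()
        assert (w["surface_radiation"] >= 0).all()

    def test_ar1_autocorrelation_near_phi(self, cfg):
        w, _ = gen_weather(cfg, 6, 500)
        x = w["temperature"].to_numpy()
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert r1 == pytest.approx(0.8, abs=0.1)

    def test_planted_aci_couples_to_meridional_wind(self, cfg):
        w, truth = gen_weather(cfg, 7, 400)
        aci = planted_aci(w, truth, 8, noise_sd=0.0)
        residual = aci - truth.interaction_effect(w["temperature"], w["humidity"])
        expected = truth.base + truth.meridional_effect(w["meridional_wind"])
        assert np.allclose(residual, expected)

    def test_null_aci_is_uncorrelated_noise(self, cfg):
        w, _ = gen_weather(cfg, 10, 300)
        aci = planted_aci(w, None, 11)
        rho = stats.spearmanr(w["meridional_wind"], aci).statistic
        assert abs(rho) < 0.2


@pytest.fixture(scope="module")
def behavior_frames():
    bcfg = SimulationConfig.desk_scale()
    night = gen_night_audio(bcfg, 31)
    log = gen_behaviors(bcfg, night.calls, 32)
    return night, log


class TestBehaviorGenerator:
    def test_times_fall_within_context_window(self, behavior_frames):
        night, log = behavior_frames
        call_times = night.calls["time"].to_numpy()
        for t in log["time"]:
            nearest = min(abs((t - ct) / np.timedelta64(1, "s")) for ct in call_times)
            assert nearest <= 10.0

    def test_category_mix_shifts_across_night(self, behavior_frames):
        from nocturne.events import classify_behavior

        _, log = behavior_frames
        log = log.assign(
            hour=[t.hour for t in log["time"]],
            category=[classify_behavior(b) for b in log["behavior"]],
        )
        early = log[log["hour"] == 18]
        late = log[log["hour"].isin([21, 22])]
        agg_early = (early["category"] == "aggression").mean()
        agg_late = (late["category"] == "aggression").mean()
        soc_early = (early["category"] == "social").mean()
        soc_late = (late["category"] == "social").mean()
        assert agg_early > agg_late
        assert soc_late > soc_early
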