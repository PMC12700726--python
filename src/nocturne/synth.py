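"""Synthetic night-monitoring data with known ground truth.

Every input the pipeline consumes can be generated here: night
soundscapes with planted harmonic-stack calls over wind-dependent noise,
call and behavior logs, proximity / agonistic / pedigree records with a
planted linear hierarchy and kin clusters, per-individual attributes and
counts drawn from the forward count model, and autocorrelated hourly
weather with planted weather-to-ACI coupling functions.  All defaults
live in ``config/defaults.yaml`` and every generator is a pure function
of its seed.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from importlib import resources
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .events import BEHAVIOR_CATEGORIES, night_hours
from .social import ProximityData

__all__ = [
    "SimulationConfig",
    "NightAudio",
    "SocialData",
    "WeatherTruth",
    "gen_night_audio",
    "gen_behaviors",
    "gen_social",
    "gen_counts_and_attributes",
    "gen_weather",
    "planted_aci",
    "write_wav",
]

_BY_CATEGORY: dict[str, list[str]] = {}
for _name, _cat in BEHAVIOR_CATEGORIES.items():
    _BY_CATEGORY.setdefault(_cat, []).append(_name)


def _load_defaults() -> dict[str, Any]:
    ref = resources.files("nocturne").joinpath("config", "defaults.yaml")
    return yaml.safe_load(ref.read_text())


@dataclass
class SimulationConfig:
    """Generator settings; defaults come from the packaged YAML file."""

    params: dict[str, Any] = field(default_factory=_load_defaults)

    @classmethod
    def default(cls) -> "SimulationConfig":
        return cls()

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        base = _load_defaults()
        override = yaml.safe_load(Path(path).read_text()) or {}
        _deep_update(base, override)
        return cls(params=base)

    @classmethod
    def desk_scale(cls) -> "SimulationConfig":
        """A reduced problem size for desk runs and the test suite.

        Audio at 8 kHz with 90-s hour-blocks and 30-s ACI windows; the
        planted hourly call counts, ethogram mix, model coefficients and
        weather parameters are unchanged.
        """
        cfg = cls()
        cfg = cfg.replace(
            {
                "audio": {
                    "sample_rate": 8000,
                    "seconds_per_hour": 90,
                    "aci_window_s": 30,
                    # keep the frame's time span (~21 ms) and hop ratio
                    "frame_length": 256,
                    "hop": 128,
                }
            }
        )
        return cfg

    def replace(self, override: dict[str, Any]) -> "SimulationConfig":
        params = copy.deepcopy(self.params)
        _deep_update(params, override)
        return SimulationConfig(params=params)

    def __getitem__(self, key: str) -> Any:
        return self.params[key]

    @property
    def hours(self) -> list[int]:
        return night_hours(self.params["night_start"], self.params["night_end"])


def _deep_update(base: dict, override: dict) -> None:
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


# --------------------------------------------------------------------- audio


@dataclass
class NightAudio:
    waveform: np.ndarray
    sample_rate: int
    start_time: datetime
    seconds_per_hour: float
    calls: pd.DataFrame          # columns: time (datetime), hour, sample
    hourly_rate: list[float]     # planted expectation per hour-block
    wind_speed_by_hour: np.ndarray


def _call_template(sr: int, f0: float, n_harmonics: int, dur_s: float,
                   amplitude: float, pulse_rate_hz: float = 12.0,
                   pulse_duty: float = 0.5) -> np.ndarray:
    # pulsed harmonic stack: macaque-like calls are amplitude-modulated,
    # and the pulsing is what drives frame-to-frame spectral change
    n = max(int(dur_s * sr), 8)
    t = np.arange(n) / sr
    env = np.hanning(n)
    if pulse_rate_hz > 0:
        phase = (t * pulse_rate_hz) % 1.0
        env = env * (phase < pulse_duty)
    wave = np.zeros(n)
    for k in range(1, n_harmonics + 1):
        if k * f0 >= sr / 2:
            break
        wave += np.sin(2 * np.pi * k * f0 * t) / k
    wave /= np.max(np.abs(wave))
    return amplitude * env * wave


def gen_night_audio(
    cfg: SimulationConfig,
    seed: int,
    night_date: date = date(2023, 11, 1),
    weather: pd.DataFrame | None = None,
) -> NightAudio:
    """Synthesize one night of audio plus its ground-truth call log.

    Call times follow an inhomogeneous Poisson process with the planted
    per-hour expectations; each call is a harmonic stack added to
    Gaussian noise whose level scales with surface wind speed (taken
    from ``weather`` when supplied, else zero wind).  Each simulated
    hour-block occupies ``seconds_per_hour`` seconds of audio but keeps
    the full-hour expected call count, so hourly statistics stay at
    study magnitude at any audio scale.
    """
    rng = np.random.default_rng(seed)
    audio = cfg["audio"]
    sr = int(audio["sample_rate"])
    sph = float(audio["seconds_per_hour"])
    hours = cfg.hours
    rates = list(cfg["hourly_rate"])
    if len(rates) != len(hours):
        raise ValueError("hourly_rate length must match the night window")

    if weather is not None and "surface_wind_speed" in weather:
        wind = np.asarray(weather["surface_wind_speed"], dtype=float)[: len(hours)]
        if wind.size < len(hours):
            wind = np.resize(wind, len(hours))
    else:
        wind = np.zeros(len(hours))

    n_block = int(sph * sr)
    template = _call_template(
        sr,
        float(audio["call"]["fundamental_hz"]),
        int(audio["call"]["n_harmonics"]),
        float(audio["call"]["duration_s"]),
        float(audio["call"]["amplitude"]),
        float(audio["call"].get("pulse_rate_hz", 12.0)),
        float(audio["call"].get("pulse_duty", 0.5)),
    )
    start_dt = datetime.combine(night_date, time(hour=hours[0]))
    wave = np.empty(n_block * len(hours))
    call_rows = []
    for bi, (h, rate) in enumerate(zip(hours, rates)):
        sigma = float(audio["noise_floor"]) + float(audio["wind_noise_coef"]) * wind[bi]
        block = rng.normal(0.0, sigma, n_block)
        n_calls = rng.poisson(rate)
        offsets = np.sort(rng.uniform(0, sph, n_calls))
        for off in offsets:
            s0 = int(off * sr)
            s1 = min(s0 + template.size, n_block)
            block[s0:s1] += template[: s1 - s0]
            frac_h = off / sph  # position within the (full) hour
            t = start_dt + timedelta(hours=bi + frac_h)
            call_rows.append({"time": t, "hour": h, "sample": bi * n_block + s0})
        wave[bi * n_block : (bi + 1) * n_block] = block
    calls = pd.DataFrame(call_rows, columns=["time", "hour", "sample"])
    return NightAudio(
        waveform=np.clip(wave, -1.0, 1.0),
        sample_rate=sr,
        start_time=start_dt,
        seconds_per_hour=sph,
        calls=calls,
        hourly_rate=rates,
        wind_speed_by_hour=wind,
    )


def write_wav(path: str | Path, waveform: np.ndarray, sample_rate: int) -> None:
    """Write a mono float waveform as 16-bit PCM."""
    from scipy.io import wavfile

    pcm = np.clip(waveform, -1.0, 1.0)
    wavfile.write(str(path), int(sample_rate), (pcm * 32767).astype(np.int16))


# ---------------------------------------------------------------- behaviors


def gen_behaviors(cfg: SimulationConfig, calls: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Behavior-log rows around each call, with an hour-dependent mix.

    The category mix is aggression-heavy near the configured aggression
    peak (18:00) and social-heavy near the social peak (21:00-22:00);
    sleep-related behaviors rise through the late night.  Times fall
    within 10 s of the call.
    """
    rng = np.random.default_rng(seed)
    bc = cfg["behavior_context"]
    gain = float(bc["mix_gain"])
    width = float(bc["mix_width_h"])
    rows = []
    for _, call in calls.iterrows():
        h = call["hour"]
        night_h = (h - cfg.params["night_start"]) % 24
        agg_d = _hour_dist(h, float(bc["aggression_peak_hour"]))
        soc_d = _hour_dist(h, float(bc["social_peak_hour"]))
        weights = np.array(
            [
                1.0 + gain * np.exp(-0.5 * (agg_d / width) ** 2),  # aggression
                1.0 + gain * np.exp(-0.5 * (soc_d / width) ** 2),  # social
                0.5 + 0.3 * night_h,                               # sleep, rises late
                1.0,                                               # other
            ]
        )
        weights /= weights.sum()
        n = rng.poisson(float(bc["mean_context_behaviors"]))
        for _ in range(n):
            cat = ("aggression", "social", "sleep", "other")[
                rng.choice(4, p=weights)
            ]
            name = _BY_CATEGORY[cat][rng.integers(len(_BY_CATEGORY[cat]))]
            dt = call["time"] + timedelta(seconds=float(rng.uniform(-10, 10)))
            rows.append(
                {"time": dt, "individual_id": f"M{rng.integers(1, 25):02d}",
                 "behavior": name}
            )
    return pd.DataFrame(rows, columns=["time", "individual_id", "behavior"])


def _hour_dist(h: float, peak: float) -> float:
    d = abs(h - peak) % 24
    return min(d, 24 - d)


# ------------------------------------------------------------------- social


@dataclass
class SocialData:
    ids: list[str]
    proximity: ProximityData
    wins: np.ndarray
    pedigree: list[tuple[str, str]]
    true_order: list[str]        # dominance order, highest first
    families: list[list[str]]


def gen_social(cfg: SimulationConfig, seed: int, n_individuals: int | None = None) -> SocialData:
    """Proximity, agonistic and pedigree records with planted structure.

    A linear hierarchy (higher-ranked individual wins each bout with
    probability ``win_prob``), kin clusters with elevated co-proximity,
    and a pedigree of one mother per family.
    """
    rng = np.random.default_rng(seed)
    sc = cfg["social"]
    n = int(n_individuals or cfg.params["n_individuals"])
    if n < 3:
        raise ValueError("need at least 3 individuals")
    ids = [f"M{i + 1:02d}" for i in range(n)]

    # agonistic bouts
    wins = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            n_int = rng.poisson(float(sc["interactions_per_dyad"]))
            wi = rng.binomial(n_int, float(sc["win_prob"]))  # i outranks j
            wins[i, j], wins[j, i] = wi, n_int - wi

    # kin clusters and pedigree
    fam_size = int(sc["family_size"])
    families = [ids[k : k + fam_size] for k in range(0, n, fam_size)]
    pedigree = [(fam[0], child) for fam in families if len(fam) > 1 for child in fam[1:]]
    fam_of = {ind: fi for fi, fam in enumerate(families) for ind in fam}

    dyad = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mean = (
                float(sc["within_kin_seconds"])
                if fam_of[ids[i]] == fam_of[ids[j]]
                else float(sc["between_kin_seconds"])
            )
            dyad[i, j] = dyad[j, i] = rng.gamma(shape=4.0, scale=mean / 4.0)
    focal = np.full(n, float(sc["focal_seconds"]))
    prox = ProximityData(ids=ids, dyad_seconds=dyad, focal_seconds=focal)
    return SocialData(
        ids=ids, proximity=prox, wins=wins, pedigree=pedigree,
        true_order=list(ids), families=families,
    )


# ------------------------------------------------------- counts & attributes


def gen_counts_and_attributes(
    cfg: SimulationConfig,
    seed: int,
    n_individuals: int | None = None,
    n_periods: int | None = None,
    betas: dict[str, float] | None = None,
    random_sd: float | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-individual attributes and counts from the forward count model.

    Attributes are drawn independently (sex Bernoulli(1/2) with female
    coded 1; age uniform over 4-15 y; centrality Beta(2,2); relatives
    Poisson(2); rank score standard-normal-ish), continuous attributes
    are z-scored, and counts per observation period follow
    Poisson(exp(b0 + X beta + b_id)) with a normal random intercept per
    individual.  Returns the long table (one row per individual-period)
    and the betas used, on the z-scale shared with the fitting stage.
    """
    rng = np.random.default_rng(seed)
    n = int(n_individuals or cfg.params["n_individuals"])
    m = int(n_periods or cfg.params["n_nights"])
    b = dict(cfg["glmm"]["betas"])
    if betas is not None:
        b.update(betas)
    sd_id = float(cfg["glmm"]["random_sd"] if random_sd is None else random_sd)

    sex = rng.integers(0, 2, n)  # 1 = female
    age = rng.uniform(4.0, 15.0, n)
    centrality = rng.beta(2.0, 2.0, n)
    relatives = rng.poisson(2.0, n)
    rank = rng.normal(0.0, 2.0, n)

    def z(v: np.ndarray) -> np.ndarray:
        sd = v.std(ddof=0)
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v, dtype=float)

    eta_ind = (
        b["intercept"]
        + b["sex"] * sex
        + b["age"] * z(age)
        + b["centrality"] * z(centrality)
        + b["relatives"] * z(relatives.astype(float))
        + b["rank"] * z(rank)
        + rng.normal(0.0, sd_id, n)
    )
    rows = []
    for i in range(n):
        lam = np.exp(eta_ind[i])
        counts = rng.poisson(lam, m)
        for t in range(m):
            rows.append(
                {
                    "id": f"M{i + 1:02d}",
                    "period": t,
                    "sex": "female" if sex[i] else "male",
                    "age": age[i],
                    "centrality": centrality[i],
                    "relatives": int(relatives[i]),
                    "rank": rank[i],
                    "count": int(counts[t]),
                }
            )
    return pd.DataFrame(rows), b


# ------------------------------------------------------------------ weather


@dataclass
class WeatherTruth:
    """Planted weather-to-ACI coupling, evaluable for recovery scoring."""

    base: float
    meridional_amp: float
    meridional_center: float
    meridional_width: float
    temp_humidity_coef: float
    temp_mean: float
    temp_sd: float
    hum_mean: float
    hum_sd: float
    noise_sd: float

    def meridional_effect(self, mw: np.ndarray) -> np.ndarray:
        mw = np.asarray(mw, dtype=float)
        return self.meridional_amp * np.exp(
            -0.5 * ((mw - self.meridional_center) / self.meridional_width) ** 2
        )

    def interaction_effect(self, temp: np.ndarray, hum: np.ndarray) -> np.ndarray:
        tz = (np.asarray(temp, dtype=float) - self.temp_mean) / self.temp_sd
        hz = (np.asarray(hum, dtype=float) - self.hum_mean) / self.hum_sd
        return self.temp_humidity_coef * tz * hz


def gen_weather(
    cfg: SimulationConfig, seed: int, n_hours: int
) -> tuple[pd.DataFrame, WeatherTruth]:
    """Autocorrelated hourly weather series plus the planted coupling.

    Each variable follows an AR(1) process (lag-1 coefficient from the
    config); humidity is clipped to [0, 100], precipitation is a
    thresholded transform that is zero most hours, wind speed/direction
    derive from the zonal and meridional components (direction is the
    bearing the wind blows from, in [0, 360)).
    """
    if n_hours < 1:
        raise ValueError("need at least one hour")
    rng = np.random.default_rng(seed)
    w = cfg["weather"]
    phi = float(w["ar1"])

    def ar1(n: int) -> np.ndarray:
        x = np.empty(n)
        x[0] = rng.normal()
        innov = rng.normal(size=n - 1) * np.sqrt(1 - phi**2)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + innov[t - 1]
        return x

    temp = w["temperature"]["mean"] + w["temperature"]["sd"] * ar1(n_hours)
    hum = np.clip(w["humidity"]["mean"] + w["humidity"]["sd"] * ar1(n_hours), 0.0, 100.0)
    precip = np.maximum(
        0.0, w["precipitation"]["scale"] * (ar1(n_hours) - w["precipitation"]["threshold"])
    )
    zonal = w["wind_sd"] * ar1(n_hours)
    meridional = w["wind_sd"] * ar1(n_hours)
    speed = np.hypot(zonal, meridional)
    direction = np.degrees(np.arctan2(-zonal, -meridional)) % 360.0
    radiation = w["radiation_scale"] * np.abs(ar1(n_hours))

    start = datetime(2023, 11, 1, 17, 0)
    frame = pd.DataFrame(
        {
            "hour": [start + timedelta(hours=i) for i in range(n_hours)],
            "temperature": temp,
            "humidity": hum,
            "precipitation": precip,
            "zonal_wind": zonal,
            "meridional_wind": meridional,
            "surface_wind_speed": speed,
            "wind_direction": direction,
            "surface_radiation": radiation,
        }
    )
    c = cfg["coupling"]
    truth = WeatherTruth(
        base=float(c["base"]),
        meridional_amp=float(c["meridional_amp"]),
        meridional_center=float(c["meridional_center"]),
        meridional_width=float(c["meridional_width"]),
        temp_humidity_coef=float(c["temp_humidity_coef"]),
        temp_mean=float(w["temperature"]["mean"]),
        temp_sd=float(w["temperature"]["sd"]),
        hum_mean=float(w["humidity"]["mean"]),
        hum_sd=float(w["humidity"]["sd"]),
        noise_sd=float(c["noise_sd"]),
    )
    return frame, truth


def planted_aci(
    weather: pd.DataFrame,
    truth: WeatherTruth | None,
    seed: int,
    noise_sd: float | None = None,
) -> np.ndarray:
    """Hourly ACI driven by the planted coupling (or pure noise).

    With ``truth=None`` the series is Gaussian noise around the default
    base level — the null condition for selection-procedure checks.
    """
    rng = np.random.default_rng(seed)
    n = len(weather)
    if truth is None:
        sd = 0.3 if noise_sd is None else noise_sd
        return 5.0 + rng.normal(0.0, sd, n)
    sd = truth.noise_sd if noise_sd is None else noise_sd
    return (
        truth.base
        + truth.meridional_effect(weather["meridional_wind"])
        + truth.interaction_effect(weather["temperature"], weather["humidity"])
        + rng.normal(0.0, sd, n)
    )
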