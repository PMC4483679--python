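"""Synthetic study worlds with known ground truth.

The real study materials — region-level daily cardiovascular death counts, a
national weather-station network and census factor tables — are restricted,
so this module generates a stand-in world in which every downstream stage
has a recoverable truth:

* a station network with seasonal-sinusoid weather (daily mean/max/min
  temperature and relative humidity),
* per-region daily death counts drawn from the same Poisson hinge model the
  analysis stage fits (seasonal temperature, day-of-week factors, a smooth
  humidity term, and cold/heat effects beyond the 10th/90th temperature
  percentiles), and
* a region factor table sampled from a small known Bayesian network over the
  ten socioeconomic/demographic factors plus binary cold/heat risk labels,
  with continuous factor values drawn within per-state intervals so the
  discretization stage has real work to do.

All randomness flows from a single integer seed, forked per sub-generator by
documented stream labels, so e.g. adding stations does not perturb the
mortality draws.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bn, gam
from .exposure import Grid, RegionMask

__all__ = [
    "WorldConfig",
    "HumidityEffect",
    "FactorSample",
    "InvalidConfigError",
    "GenerationError",
    "generate_stations",
    "generate_region_weather",
    "generate_mortality",
    "generate_factor_table",
    "default_truth_model",
    "region_box_masks",
    "write_world",
]

DAYS_PER_YEAR = 365.25
EXTENT = {"lon_min": 100.0, "lon_max": 110.0, "lat_min": 22.0, "lat_max": 32.0}

FACTOR_NAMES = [
    "hospital_beds", "edu_years", "pct_uneducated", "pct_women", "pct_urban",
    "pct_65plus", "pct_agriculture", "pct_industry", "pct_service",
    "climatic_zone",
]


class InvalidConfigError(ValueError):
    pass


class GenerationError(RuntimeError):
    pass


@dataclass(frozen=True)
class HumidityEffect:
    """Smooth log-rate bump in humidity: amplitude * exp(-((rh-center)/width)^2).

    The default is a mild effect (3% peak rate change) centered at
    comfortable humidity, enough to exercise the humidity spline without
    dominating the temperature signal.
    """

    amplitude: float = 0.03
    center: float = 70.0
    width: float = 15.0

    def __call__(self, rh: np.ndarray) -> np.ndarray:
        return self.amplitude * np.exp(-(((np.asarray(rh, float) - self.center)
                                          / self.width) ** 2))


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of a synthetic study world.

    The temperature-effect slopes are per-degC log-rate increases beyond the
    thresholds; the defaults (``ln 1.01`` cold, ``ln 1.10`` heat) mirror the
    1%- and 10%-per-degC orders of magnitude of the two risk thresholds.
    ``temperature_exposure`` selects what the effect multiplies: ``"lagged"``
    (default) applies it to the same stratified-lag hinge exposures the
    analysis model estimates — cold to the mean of the three stratum hinges,
    so a sustained 1 degC exceedance raises log-rate by ``beta_cold_true`` —
    while ``"current"`` applies it to the current day's hinge.
    """

    n_regions: int = 26
    n_stations: int = 20
    n_days: int = 1461  # four years
    seed: int = 0
    beta_cold_true: float = float(np.log(1.01))
    beta_heat_true: float = float(np.log(1.10))
    baseline_rate: float = 5.0
    mean_temp: float = 18.0
    seasonal_amp_temp: float = 10.0
    temp_noise_sd: float = 2.0
    station_offset_sd: float = 1.5
    diurnal_half_range: float = 4.0
    diurnal_noise_sd: float = 2.5
    rh_mean: float = 70.0
    rh_amp: float = 15.0
    rh_noise_sd: float = 5.0
    dow_effects: tuple = (1.00, 0.98, 0.97, 0.98, 0.99, 1.03, 1.05)  # Mon..Sun
    humidity_effect: HumidityEffect | None = HumidityEffect()
    seasonal_confounder_amp: float = 0.0  # optional baseline sinusoid, off by default
    temperature_exposure: str = "lagged"  # or "current"
    start_date: str = "2008-01-01"
    true_dag: tuple = ()   # () -> default truth network
    true_cpts: dict | None = None

    def __post_init__(self):
        if self.n_stations < 1 or self.n_regions < 1:
            raise InvalidConfigError("n_stations and n_regions must be >= 1")
        if self.n_days < 365:
            raise InvalidConfigError("need at least one year of days (n_days >= 365)")
        if self.baseline_rate <= 0:
            raise InvalidConfigError("baseline_rate must be > 0")
        if len(self.dow_effects) != 7 or any(f <= 0 for f in self.dow_effects):
            raise InvalidConfigError("dow_effects must be 7 positive factors")
        if self.temperature_exposure not in ("lagged", "current"):
            raise InvalidConfigError("temperature_exposure must be 'lagged' or 'current'")


def _rng(seed: int, label: str) -> np.random.Generator:
    """Named sub-stream of the run's seed (stable label hash)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


def _dates(cfg: WorldConfig) -> pd.DatetimeIndex:
    return pd.date_range(cfg.start_date, periods=cfg.n_days, freq="D")


def _season(day_index: np.ndarray) -> np.ndarray:
    # peak mid-year: northern-hemisphere summer for a Jan 1 start
    return np.sin(2.0 * np.pi * (day_index - 81.0) / DAYS_PER_YEAR)


# ---------------------------------------------------------------------------
# weather


def generate_stations(cfg: WorldConfig) -> pd.DataFrame:
    """Station network with seasonal-sinusoid weather.

    Returns a long-format DataFrame (station, lon, lat, date, tmean, tmax,
    tmin, rh). Coordinates are uniform over the configured extent; each
    station's daily mean temperature is
    ``mean_temp + seasonal_amp * sin(...) + station offset + noise``, the
    max/min are the mean plus/minus positive half-ranges, and humidity is
    seasonal (drier in the cold season) and clipped to [0, 100].
    """
    rng = _rng(cfg.seed, "stations")
    lon = rng.uniform(EXTENT["lon_min"], EXTENT["lon_max"], cfg.n_stations)
    lat = rng.uniform(EXTENT["lat_min"], EXTENT["lat_max"], cfg.n_stations)
    offsets = rng.normal(0.0, cfg.station_offset_sd, cfg.n_stations)
    dates = _dates(cfg)
    day = np.arange(cfg.n_days, dtype=float)
    season = _season(day)

    frames = []
    for s in range(cfg.n_stations):
        tmean = (cfg.mean_temp + cfg.seasonal_amp_temp * season + offsets[s]
                 + rng.normal(0.0, cfg.temp_noise_sd, cfg.n_days))
        up = np.abs(rng.normal(cfg.diurnal_half_range, cfg.diurnal_noise_sd,
                                cfg.n_days)) + 0.1
        dn = np.abs(rng.normal(cfg.diurnal_half_range, cfg.diurnal_noise_sd,
                                cfg.n_days)) + 0.1
        rh = np.clip(cfg.rh_mean + cfg.rh_amp * season
                     + rng.normal(0.0, cfg.rh_noise_sd, cfg.n_days), 0.0, 100.0)
        frames.append(pd.DataFrame({
            "station": f"S{s:03d}", "lon": lon[s], "lat": lat[s], "date": dates,
            "tmean": tmean, "tmax": tmean + up, "tmin": tmean - dn, "rh": rh,
        }))
    return pd.concat(frames, ignore_index=True)


def generate_region_weather(cfg: WorldConfig, region_id: str = "R00") -> pd.DataFrame:
    """One region's daily weather series directly (no station network).

    Convenience path for parameter-recovery studies of the regression
    stage; statistically matches what the station network plus
    interpolation would deliver for a single region.
    """
    rng = _rng(cfg.seed, f"weather:{region_id}")
    day = np.arange(cfg.n_days, dtype=float)
    season = _season(day)
    tmean = (cfg.mean_temp + cfg.seasonal_amp_temp * season
             + rng.normal(0.0, cfg.temp_noise_sd, cfg.n_days))
    up = np.abs(rng.normal(cfg.diurnal_half_range, cfg.diurnal_noise_sd,
                            cfg.n_days)) + 0.1
    dn = np.abs(rng.normal(cfg.diurnal_half_range, cfg.diurnal_noise_sd,
                            cfg.n_days)) + 0.1
    rh = np.clip(cfg.rh_mean + cfg.rh_amp * season
                 + rng.normal(0.0, cfg.rh_noise_sd, cfg.n_days), 0.0, 100.0)
    return pd.DataFrame({
        "region_id": region_id, "date": _dates(cfg), "tmean": tmean,
        "tmax": tmean + up, "tmin": tmean - dn, "rh": rh,
    })


# ---------------------------------------------------------------------------
# mortality


def _effect_exposures(exposure: pd.DataFrame, cfg: WorldConfig,
                      thresholds: gam.TemperatureThresholds):
    """Cold and heat exposure vectors the true effects multiply."""
    T = exposure["tmean"].to_numpy(dtype=float)
    if cfg.temperature_exposure == "current":
        cold = np.maximum(thresholds.tau_low - T, 0.0)
        heat = np.maximum(T - thresholds.tau_high, 0.0)
        return cold, heat
    lags = gam.build_lag_features(exposure)
    # first 14 days have no lag history: their hinge exposure is zero
    strata = np.nan_to_num(np.column_stack(
        [lags[f"T_{k}"].to_numpy() for k in ("1_3", "4_8", "9_14")]),
        nan=np.inf)  # +inf temperature -> zero cold hinge
    cold = np.maximum(thresholds.tau_low - strata, 0.0).mean(axis=1)
    heat = np.nan_to_num(np.maximum(
        lags["T_1_3"].to_numpy() - thresholds.tau_high, 0.0))
    return cold, heat


def generate_mortality(exposure: pd.DataFrame, cfg: WorldConfig,
                       beta_cold: float | None = None,
                       beta_heat: float | None = None,
                       rng_label: str | None = None) -> pd.DataFrame:
    """Draw daily death counts for one region's exposure series.

    ``deaths ~ Poisson(mu_t)`` with
    ``log mu_t = log(baseline) + beta_cold * cold_t + beta_heat * heat_t
    + log(dow factor) + humidity term [+ optional seasonal confounder]``,
    where the exposures are threshold exceedances (see
    :class:`WorldConfig.temperature_exposure`) and the thresholds are the
    exposure series' own 10th/90th ``tmean`` percentiles.
    """
    exposure = gam.validate_series(exposure, require_deaths=False)
    beta_cold = cfg.beta_cold_true if beta_cold is None else beta_cold
    beta_heat = cfg.beta_heat_true if beta_heat is None else beta_heat
    thresholds = gam.temperature_thresholds(exposure)
    cold, heat = _effect_exposures(exposure, cfg, thresholds)

    log_mu = np.full(len(exposure), np.log(cfg.baseline_rate))
    log_mu += beta_cold * cold + beta_heat * heat
    dow = exposure["date"].dt.dayofweek.to_numpy()
    log_mu += np.log(np.asarray(cfg.dow_effects))[dow]
    if cfg.humidity_effect is not None:
        log_mu += cfg.humidity_effect(exposure["rh"].to_numpy())
    if cfg.seasonal_confounder_amp:
        day = np.arange(len(exposure), dtype=float)
        log_mu += cfg.seasonal_confounder_amp * _season(day)

    # 43.7 is where the Poisson sampler's mean stops being representable
    if np.abs(log_mu).max() > 50 or log_mu.max() > 43.0:
        t = int(np.abs(log_mu).argmax())
        raise GenerationError(
            f"log-rate overflow (|log mu|={np.abs(log_mu).max():.1f} on "
            f"{exposure['date'].iloc[t].date()}): check baseline_rate / "
            f"beta_cold_true / beta_heat_true against the exposure range")

    region = str(exposure["region_id"].iloc[0]) if "region_id" in exposure else "R00"
    rng = _rng(cfg.seed, rng_label or f"mortality:{region}")
    out = exposure.copy()
    out["deaths"] = rng.poisson(np.exp(log_mu)).astype(int)
    return out


# ---------------------------------------------------------------------------
# factor table


#: continuous value interval per factor state; numeric ranges loosely follow
#: the printed census summaries so discretized output looks familiar
STATE_INTERVALS: dict[str, dict[str, tuple[float, float]]] = {
    "hospital_beds": {"low": (4.95, 30.71), "high": (30.71, 109.38)},
    "edu_years": {"low": (5.18, 5.25), "high": (5.25, 12.31)},
    "pct_uneducated": {"low": (2.0, 10.0), "high": (10.0, 35.0)},
    "pct_women": {"low": (46.66, 50.08), "high": (50.08, 50.94)},
    "pct_urban": {"low": (10.0, 35.0), "high": (35.0, 90.0)},
    "pct_65plus": {"low": (3.49, 5.65), "high": (5.65, 12.68)},
    "pct_agriculture": {"low": (10.0, 40.0), "high": (40.0, 80.0)},
    "pct_industry": {"low": (1.02, 6.36), "middle": (6.36, 23.14),
                     "high": (23.14, 51.24)},
    "pct_service": {"low": (5.0, 20.0), "high": (20.0, 60.0)},
}

RISK_STATES = ["low_risk", "high_risk"]


def default_truth_model() -> bn.BnModel:
    """The default ground-truth network over the ten factors plus binary
    cold/heat risk labels.

    Urbanization drives the economic block (education, hospital beds,
    occupation mix); the risk labels depend on the same direct parents the
    study reports (cold: education, %65+, %women; heat: hospital beds,
    %industry, %women), with probabilities oriented the same way (e.g. fewer
    hospital beds -> higher heat risk) and overall high-risk rates near the
    study's 9/26 (cold) and 7/26 (heat).
    """
    states = {
        "pct_urban": ["low", "high"],
        "edu_years": ["low", "high"],
        "pct_uneducated": ["low", "high"],
        "pct_65plus": ["low", "high"],
        "pct_women": ["low", "high"],
        "hospital_beds": ["low", "high"],
        "pct_agriculture": ["low", "high"],
        "pct_industry": ["low", "middle", "high"],
        "pct_service": ["low", "high"],
        "climatic_zone": ["subtropical", "temperate", "plateau"],
        "cold_risk": RISK_STATES,
        "heat_risk": RISK_STATES,
    }
    edges = [
        ("pct_urban", "edu_years"), ("edu_years", "pct_uneducated"),
        ("pct_urban", "hospital_beds"), ("pct_urban", "pct_agriculture"),
        ("pct_urban", "pct_industry"), ("pct_urban", "pct_service"),
        ("edu_years", "cold_risk"), ("pct_65plus", "cold_risk"),
        ("pct_women", "cold_risk"),
        ("hospital_beds", "heat_risk"), ("pct_industry", "heat_risk"),
        ("pct_women", "heat_risk"),
    ]
    dag = bn.Dag(states, edges)

    def t(rows):
        return np.array(rows, dtype=float)

    cpts = {
        "pct_urban": bn.Cpt("pct_urban", (), t([[0.5, 0.5]])),
        "edu_years": bn.Cpt("edu_years", ("pct_urban",),
                            t([[0.7, 0.3], [0.2, 0.8]])),
        "pct_uneducated": bn.Cpt("pct_uneducated", ("edu_years",),
                                 t([[0.3, 0.7], [0.85, 0.15]])),
        "pct_65plus": bn.Cpt("pct_65plus", (), t([[0.5, 0.5]])),
        "pct_women": bn.Cpt("pct_women", (), t([[0.5, 0.5]])),
        "hospital_beds": bn.Cpt("hospital_beds", ("pct_urban",),
                                t([[0.7, 0.3], [0.25, 0.75]])),
        "pct_agriculture": bn.Cpt("pct_agriculture", ("pct_urban",),
                                  t([[0.2, 0.8], [0.8, 0.2]])),
        "pct_industry": bn.Cpt("pct_industry", ("pct_urban",),
                               t([[0.5, 0.3, 0.2], [0.2, 0.3, 0.5]])),
        "pct_service": bn.Cpt("pct_service", ("pct_urban",),
                              t([[0.7, 0.3], [0.3, 0.7]])),
        "climatic_zone": bn.Cpt("climatic_zone", (), t([[0.5, 0.3, 0.2]])),
        # parents sorted: (edu_years, pct_65plus, pct_women); P(high_risk)
        # falls with education, %65+ and %women, as in the cold network
        "cold_risk": bn.Cpt("cold_risk", ("edu_years", "pct_65plus", "pct_women"),
                            t([[0.25, 0.75], [0.45, 0.55], [0.60, 0.40], [0.75, 0.25],
                               [0.50, 0.50], [0.65, 0.35], [0.80, 0.20], [0.92, 0.08]])),
        # parents sorted: (hospital_beds, pct_industry, pct_women); high risk
        # with few beds, low %industry, more women, as in the heat network
        "heat_risk": bn.Cpt("heat_risk", ("hospital_beds", "pct_industry", "pct_women"),
                            t([[0.30, 0.70], [0.20, 0.80], [0.70, 0.30], [0.60, 0.40],
                               [0.55, 0.45], [0.45, 0.55], [0.70, 0.30], [0.60, 0.40],
                               [0.92, 0.08], [0.85, 0.15], [0.85, 0.15], [0.75, 0.25]])),
    }
    return bn.BnModel(dag, cpts)


def truth_model_from_config(cfg: WorldConfig) -> bn.BnModel:
    if not cfg.true_dag and cfg.true_cpts is None:
        return default_truth_model()
    if cfg.true_cpts is None:
        raise InvalidConfigError("true_dag given without true_cpts")
    states = {n: list(c["states"]) for n, c in cfg.true_cpts.items()}
    dag = bn.Dag(states, [tuple(e) for e in cfg.true_dag])
    cpts = {}
    for n, c in cfg.true_cpts.items():
        table = np.asarray(c["table"], dtype=float)
        if not np.allclose(table.sum(axis=1), 1.0, atol=1e-9):
            raise InvalidConfigError(f"CPT rows for {n!r} do not sum to 1")
        cpts[n] = bn.Cpt(n, dag.parents(n), table)
    return bn.BnModel(dag, cpts)


@dataclass
class FactorSample:
    """Sampled region factors: discrete states, continuous values, and the
    true risk labels, plus the truth network they came from."""

    discrete: pd.DataFrame     # region_id + factor states + risk labels
    continuous: pd.DataFrame   # region_id + continuous factor values
    labels: pd.DataFrame       # region_id, cold_risk, heat_risk
    model: bn.BnModel


def generate_factor_table(cfg: WorldConfig,
                          model: bn.BnModel | None = None) -> FactorSample:
    """One ancestral-order sample per region from the truth network.

    The network yields discrete factor states and the binary risk labels;
    each continuous factor value is then drawn uniformly within its state's
    interval, so supervised discretization can rediscover the state
    boundaries. The categorical climatic zone passes through unchanged.
    """
    model = model or truth_model_from_config(cfg)
    rng = _rng(cfg.seed, "factors")
    disc = bn.sample(model, cfg.n_regions, rng)
    disc.insert(0, "region_id", [f"R{i:02d}" for i in range(cfg.n_regions)])

    cont = pd.DataFrame({"region_id": disc["region_id"]})
    for factor in FACTOR_NAMES:
        if factor == "climatic_zone":
            cont[factor] = disc[factor].to_numpy()
            continue
        if factor not in disc.columns:
            continue
        lo_hi = disc[factor].map(STATE_INTERVALS[factor])
        a = np.array([iv[0] for iv in lo_hi])
        b = np.array([iv[1] for iv in lo_hi])
        cont[factor] = rng.uniform(a, b)

    label_cols = [c for c in ("cold_risk", "heat_risk") if c in disc.columns]
    labels = disc[["region_id", *label_cols]].copy()
    return FactorSample(discrete=disc, continuous=cont, labels=labels, model=model)


# ---------------------------------------------------------------------------
# region geometry and file output


def region_box_masks(cfg: WorldConfig, grid: Grid) -> list[RegionMask]:
    """Tile the extent into ``n_regions`` rectangular regions (row-major
    boxes on the grid). Plumbing: real administrative polygons are replaced
    by boxes of roughly equal area."""
    n_side = int(np.ceil(np.sqrt(cfg.n_regions)))
    cols_per = max(1, grid.n_cols // n_side)
    rows_per = max(1, grid.n_rows // n_side)
    masks = []
    for r in range(cfg.n_regions):
        bi, bj = divmod(r, n_side)
        c0, r0 = bj * cols_per, bi * rows_per
        cells = {(c, w) for c in range(c0, min(c0 + cols_per, grid.n_cols))
                 for w in range(r0, min(r0 + rows_per, grid.n_rows))}
        if not cells:
            raise InvalidConfigError(
                f"grid too coarse to host {cfg.n_regions} regions")
        masks.append(RegionMask(f"R{r:02d}", frozenset(cells)))
    return masks


def write_world(outdir, cfg: WorldConfig, stations: pd.DataFrame,
                region_series: pd.DataFrame, factors: FactorSample) -> dict:
    """Write the CSV schemas the pipeline reads plus a ground-truth JSON."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "stations": outdir / "stations.csv",
        "region_series": outdir / "region_series.csv",
        "factors": outdir / "factors.csv",
        "factors_discrete": outdir / "factors_discrete.csv",
        "truth": outdir / "truth.json",
    }
    stations.to_csv(paths["stations"], index=False)
    region_series.to_csv(paths["region_series"], index=False)
    factors.continuous.to_csv(paths["factors"], index=False)
    factors.discrete.to_csv(paths["factors_discrete"], index=False)
    truth = {
        "beta_cold_true": cfg.beta_cold_true,
        "beta_heat_true": cfg.beta_heat_true,
        "baseline_rate": cfg.baseline_rate,
        "dow_effects": list(cfg.dow_effects),
        "dag_edges": factors.model.dag.edges,
        "cpts": {n: {"parents": list(c.parents), "table": c.table.tolist()}
                 for n, c in factors.model.cpts.items()},
        "labels": factors.labels.to_dict(orient="list"),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2))
    return {k: str(v) for k, v in paths.items()}
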