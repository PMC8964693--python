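"""Synthetic reef thermal regimes, breeding designs and survival outcomes.

The generator emulates the study system end to end with known ground truth:
five source reefs with distinct thermal regimes spanning a warm far-northern
to cooler central gradient, the full 5 × 5 = 25 ordered egg × sperm cross
design, well-level larval counts (20 larvae per well) under a control and an
elevated temperature, and individual juvenile alive/dead outcomes across four
symbiont treatments in replicated tanks. Heat-treatment survival probability
is a known smooth function of ONE environmental metric of the maternal reef,
so that model-recovery tests have an exact truth to compare against.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .series import SSTSeries
from .metrics import FEATURES, PROFILE_COLUMNS, feature_frame

logger = logging.getLogger(__name__)

__all__ = [
    "ReefScenario",
    "CrossDesign",
    "TrueResponse",
    "ReplicationLayout",
    "gen_reef_sst",
    "gen_cross_design",
    "gen_survival",
    "tank_layout",
    "default_scenarios",
    "default_reef_profiles",
    "default_true_response",
    "write_survival_csv",
    "read_survival_csv",
]

#: Survival-table column schema shared with the ingest side.
SURVIVAL_COLUMNS = (
    "stage", "cross_id", "maternal_reef", "paternal_reef", "symbiont",
    "temperature", "tank", "plate", "well",
    "initial_count", "final_count", "status", "censored", "time",
)

JUVENILE_SYMBIONTS = ("C1", "D1a", "SED", "SS1")


@dataclass
class ReefScenario:
    """Parametric thermal regime for one synthetic reef.

    The daily mean follows an annual cosine peaking at ``warmest_doy``
    (default mid-February, Southern Hemisphere summer) plus Gaussian noise;
    the daily min/max sit symmetrically ``daily_range`` apart around the
    mean. Heat anomalies are planted as whole ISO weeks (chosen distinct
    across years where possible) offset upward by ``anomaly_magnitude``.
    """

    reef_id: str
    latitude: float  # degrees south, positive southward
    annual_mean: float  # °C
    seasonal_amplitude: float = 0.0  # °C
    daily_range: float = 0.0  # °C
    noise_sd: float = 0.0  # °C
    anomaly_weeks_per_year: int | tuple = 0
    anomaly_magnitude: float = 0.0  # °C
    years: tuple = (2013, 2019)  # half-open [start, end)
    seed: int = 0
    warmest_doy: int = 45  # mid-February
    longitude: float = float("nan")

    def __post_init__(self) -> None:
        for name in ("daily_range", "noise_sd", "anomaly_magnitude"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["years"] = list(self.years)
        if not isinstance(self.anomaly_weeks_per_year, int):
            d["anomaly_weeks_per_year"] = list(self.anomaly_weeks_per_year)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ReefScenario":
        d = dict(d)
        d["years"] = tuple(d.get("years", (2013, 2019)))
        aw = d.get("anomaly_weeks_per_year", 0)
        if isinstance(aw, list):
            d["anomaly_weeks_per_year"] = tuple(aw)
        return cls(**d)


@dataclass(frozen=True)
class CrossDesign:
    """One egg-pool × sperm-pool cross; purebred when both reefs coincide."""

    maternal_reef: str
    paternal_reef: str

    @property
    def cross_id(self) -> str:
        return f"{self.maternal_reef}x{self.paternal_reef}"

    @property
    def is_purebred(self) -> bool:
        return self.maternal_reef == self.paternal_reef


@dataclass
class TrueResponse:
    """Ground-truth heat-survival response for the generator.

    Survival probability is a polynomial in one maternal-reef metric
    (``coefficients`` in ascending powers), passed through either an
    identity link clipped to [0, 1] or a logistic link. ``residual_sd``
    adds probability-scale noise per experimental unit.
    """

    driver_metric: str = "TSA_DHW_stdev"
    coefficients: tuple = (0.332, 1.08, -0.45)
    link: str = "identity"
    residual_sd: float = 0.0

    def survival_prob(self, x) -> np.ndarray:
        x = np.asarray(x, float)
        y = np.polynomial.polynomial.polyval(x, np.asarray(self.coefficients, float))
        if self.link == "logit":
            p = 1.0 / (1.0 + np.exp(-y))
        elif self.link == "identity":
            p = y
            n_out = int(np.sum((y < 0) | (y > 1)))
            if n_out:
                logger.warning(
                    "TrueResponse: %d probabilities outside [0, 1] clipped", n_out)
        else:
            raise ValueError(f"unknown link {self.link!r}")
        return np.clip(p, 0.0, 1.0)


@dataclass
class ReplicationLayout:
    """Replicate structure of the breeding experiment.

    Defaults mirror the experimental setup: 20 larvae per floating net-well
    with six replicate wells per cross and temperature; settled juveniles in
    three wells per six-well plate, plates floated in three replicate tanks
    per symbiont × temperature treatment; 56 h larval and 58 d juvenile
    exposures; alive/dead coded 2/1.
    """

    larvae_per_well: int = 20
    wells_per_cross: int = 6
    tanks_per_treatment: int = 3
    plates_per_tank: int = 1
    wells_per_plate: int = 3
    juveniles_per_well: int = 5
    control_temp: float = 27.0
    heat_temp_larva: float = 35.5
    heat_temp_juvenile: float = 32.0
    larval_duration_days: float = 56.0 / 24.0
    juvenile_duration_days: float = 58.0
    control_p_larva: float = 0.96
    control_p_juvenile: float = 0.85
    censor_fraction: float = 0.0
    tank_effect_sd: float = 0.0  # probability-scale tank-level random effect


def gen_reef_sst(scenario: ReefScenario) -> SSTSeries:
    """Generate a daily SST series (mean/min/max) for one scenario.

    Bit-identical under a fixed scenario seed. The planted ISO anomaly weeks
    are recorded in ``series.attrs['anomaly_weeks']`` (year → week numbers).
    """
    y0, y1 = int(scenario.years[0]), int(scenario.years[1])
    if y1 - y0 < 2:
        raise ValueError(f"years {scenario.years} must span >= 2 full years")
    rng = np.random.default_rng(scenario.seed)
    dates = pd.date_range(f"{y0}-01-01", f"{y1 - 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy()
    mean = (scenario.annual_mean
            + scenario.seasonal_amplitude
            * np.cos(2 * np.pi * (doy - scenario.warmest_doy) / 365.25))
    if scenario.noise_sd > 0:
        mean = mean + rng.normal(0.0, scenario.noise_sd, size=mean.size)

    # Plant anomalies on whole ISO weeks, distinct across years while the
    # pool lasts, so weekly aggregation and yearly anomaly counts see them
    # exactly. Weeks 2..51 avoid year-boundary ISO weeks.
    iso = dates.isocalendar()
    iso_year = iso["year"].to_numpy()
    iso_week = iso["week"].to_numpy()
    per_year = scenario.anomaly_weeks_per_year
    years = list(range(y0, y1))
    counts = ([int(per_year)] * len(years) if isinstance(per_year, (int, np.integer))
              else [int(c) for c in per_year])
    if len(counts) != len(years):
        raise ValueError("anomaly_weeks_per_year sequence must have one entry per year")
    pool = list(range(2, 52))
    planted: dict[int, list[int]] = {}
    for year, k in zip(years, counts):
        if k > len(pool):
            pool = list(range(2, 52))  # pool exhausted: allow reuse
        chosen = sorted(rng.choice(pool, size=k, replace=False).tolist()) if k else []
        pool = [w for w in pool if w not in chosen]
        planted[year] = chosen
        if chosen and scenario.anomaly_magnitude > 0:
            mask = (iso_year == year) & np.isin(iso_week, chosen)
            mean[mask] += scenario.anomaly_magnitude

    half = scenario.daily_range / 2.0
    df = pd.DataFrame(
        {"sst_mean": mean, "sst_min": mean - half, "sst_max": mean + half},
        index=dates,
    )
    attrs = {
        "anomaly_weeks": planted,
        "latitude": scenario.latitude,
        "longitude": scenario.longitude,
    }
    return SSTSeries(scenario.reef_id, df, cadence="daily", attrs=attrs)


def gen_cross_design(reef_ids: list[str]) -> list[CrossDesign]:
    """All ordered maternal × paternal combinations over the given reefs."""
    ids = list(reef_ids)
    if len(ids) < 2:
        raise ValueError("need at least 2 distinct reef ids")
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate reef ids in {ids}")
    return [CrossDesign(m, p) for m in ids for p in ids]


def tank_layout(symbionts: tuple = JUVENILE_SYMBIONTS,
                temperatures: tuple = (27.0, 32.0),
                tanks_per_treatment: int = 3) -> pd.DataFrame:
    """Replicate-tank layout: one row per physical tank.

    The default four symbiont treatments × two temperatures × three
    replicate tanks give 24 tanks.
    """
    rows = [
        {"tank": f"{s}-{t:g}C-t{i + 1}", "symbiont": s, "temperature": t}
        for s in symbionts for t in temperatures for i in range(tanks_per_treatment)
    ]
    return pd.DataFrame(rows)


def _resolve_env(env) -> pd.DataFrame:
    if isinstance(env, pd.DataFrame):
        if "reef_id" in env.columns or "lat" in env.columns:
            return feature_frame(env)
        return env
    raise TypeError("env must be a profile table or feature frame DataFrame")


def gen_survival(design: list[CrossDesign], env: pd.DataFrame, truth: TrueResponse,
                 layout: ReplicationLayout | None = None, seed: int = 0,
                 stages: tuple = ("larva", "juvenile")) -> pd.DataFrame:
    """Draw a survival table for the full design with known truth.

    Larval rows are per-well binomial counts out of ``larvae_per_well``;
    juvenile rows are one Bernoulli outcome per individual (status 2 = alive,
    1 = dead). Heat-treatment survival probability is ``truth`` evaluated at
    the MATERNAL reef's driver metric; the control temperature uses the
    layout's stage-specific high constant. Dead individuals receive a
    uniform event time within the exposure; an optional fraction is censored
    at a uniform time instead.
    """
    lay = layout or ReplicationLayout()
    features = _resolve_env(env)
    maternal = {d.maternal_reef for d in design}
    missing = maternal - set(features.index.astype(str))
    if missing:
        raise ValueError(f"env table is missing maternal reefs: {sorted(missing)}")
    if truth.driver_metric not in features.columns:
        raise ValueError(f"truth driver {truth.driver_metric!r} is not an env metric column")

    rng = np.random.default_rng(seed)
    rows: list[dict] = []

    def unit_p(base: float) -> float:
        if truth.residual_sd > 0:
            base = base + rng.normal(0.0, truth.residual_sd)
        return float(np.clip(base, 0.0, 1.0))

    for cross in design:
        x = float(features.loc[cross.maternal_reef, truth.driver_metric])
        p_heat = float(truth.survival_prob(x))
        if "larva" in stages:
            for temp, base in ((lay.control_temp, lay.control_p_larva),
                               (lay.heat_temp_larva, p_heat)):
                for w in range(lay.wells_per_cross):
                    final = int(rng.binomial(lay.larvae_per_well, unit_p(base)))
                    rows.append({
                        "stage": "larva", "cross_id": cross.cross_id,
                        "maternal_reef": cross.maternal_reef,
                        "paternal_reef": cross.paternal_reef,
                        "symbiont": "Apo", "temperature": temp,
                        "tank": "larval", "plate": "", "well": f"w{w + 1}",
                        "initial_count": lay.larvae_per_well, "final_count": final,
                        "status": np.nan, "censored": False,
                        "time": lay.larval_duration_days,
                    })
        if "juvenile" in stages:
            for symbiont in JUVENILE_SYMBIONTS:
                for temp, base in ((lay.control_temp, lay.control_p_juvenile),
                                   (lay.heat_temp_juvenile, p_heat)):
                    for t in range(lay.tanks_per_treatment):
                        tank = f"{symbiont}-{temp:g}C-t{t + 1}"
                        tank_base = base
                        if lay.tank_effect_sd > 0:
                            tank_base = float(np.clip(
                                base + rng.normal(0.0, lay.tank_effect_sd),
                                0.0, 1.0))
                        for pl in range(lay.plates_per_tank):
                            for w in range(lay.wells_per_plate):
                                for _ in range(lay.juveniles_per_well):
                                    p = unit_p(tank_base)
                                    alive = bool(rng.random() < p)
                                    censored = bool(rng.random() < lay.censor_fraction)
                                    if censored:
                                        time = float(rng.uniform(0, lay.juvenile_duration_days))
                                        status = 2
                                    elif alive:
                                        time = lay.juvenile_duration_days
                                        status = 2
                                    else:
                                        time = float(rng.uniform(0, lay.juvenile_duration_days))
                                        status = 1
                                    rows.append({
                                        "stage": "juvenile", "cross_id": cross.cross_id,
                                        "maternal_reef": cross.maternal_reef,
                                        "paternal_reef": cross.paternal_reef,
                                        "symbiont": symbiont, "temperature": temp,
                                        "tank": tank, "plate": f"p{pl + 1}",
                                        "well": f"w{w + 1}",
                                        "initial_count": np.nan, "final_count": np.nan,
                                        "status": status, "censored": censored,
                                        "time": time,
                                    })
    return pd.DataFrame(rows, columns=list(SURVIVAL_COLUMNS))


# ---------------------------------------------------------------------------
# Default study conditions.


def default_scenarios() -> list[ReefScenario]:
    """Five reef scenarios emulating a warm far-northern to cooler central
    gradient: three warm low-latitude reefs and two cooler higher-latitude
    reefs, with distinct seasonal amplitudes, daily ranges and anomaly
    schedules."""
    rows = [
        # reef, latS, lonE, mean, amp, dtr, noise, anom wk/yr (2013..2018), anom °C, seed
        ("CU", 13.0, 143.5, 28.6, 2.2, 1.10, 0.30, (3, 1, 2, 6, 0, 2), 1.8, 101),
        ("BK", 14.2, 144.6, 27.9, 2.5, 0.85, 0.30, (4, 2, 3, 7, 1, 3), 1.7, 102),
        ("LS", 15.6, 145.3, 27.4, 2.7, 0.65, 0.30, (1, 0, 1, 2, 0, 1), 1.6, 103),
        ("DR", 17.3, 146.4, 26.8, 3.0, 0.50, 0.30, (0, 1, 0, 2, 0, 1), 1.5, 104),
        ("SB", 18.8, 147.6, 26.3, 3.2, 0.35, 0.30, (2, 4, 0, 5, 1, 2), 2.0, 105),
    ]
    return [
        ReefScenario(reef_id=r, latitude=la, longitude=lo, annual_mean=m,
                     seasonal_amplitude=a, daily_range=d, noise_sd=n,
                     anomaly_weeks_per_year=aw, anomaly_magnitude=am,
                     years=(2013, 2019), seed=s)
        for (r, la, lo, m, a, d, n, aw, am, s) in rows
    ]


def default_reef_profiles() -> pd.DataFrame:
    """Fixed seven-metric profiles for the five synthetic source reefs.

    Values sit in realistic ranges for the system. Six of the metrics follow
    a common latitudinal thermal gradient (collinear, as on real reefs);
    the anomaly-dispersion driver TSA_DHW_stdev varies independently of that
    gradient, and its reef-grouping splits never coincide with gradient
    splits — so a survival response driven by it is identifiable against
    the correlated background.
    """
    rows = [
        # reef  latS   lonE   pre    post  stdev  dtr   ssta  tsa
        ("CU", 13.0, 143.5, 28.6, 28.8, 1.90, 1.10, 3.5, 0.65),
        ("BK", 14.2, 144.6, 27.9, 28.1, 2.15, 0.85, 2.8, 2.00),
        ("LS", 15.6, 145.3, 27.4, 27.6, 2.35, 0.65, 2.3, 1.10),
        ("DR", 17.3, 146.4, 26.8, 27.0, 2.60, 0.50, 1.9, 0.20),
        ("SB", 18.8, 147.6, 26.3, 26.5, 2.80, 0.35, 1.5, 1.55),
    ]
    return pd.DataFrame(rows, columns=list(PROFILE_COLUMNS))


def default_true_response() -> TrueResponse:
    """Unimodal heat-survival truth: a clipped quadratic in TSA_DHW_stdev
    peaking at 0.98 survival at 1.2 °C-weeks (0.332 + 1.08 x − 0.45 x²)."""
    return TrueResponse(driver_metric="TSA_DHW_stdev",
                        coefficients=(0.332, 1.08, -0.45),
                        link="identity", residual_sd=0.02)


def write_survival_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_survival_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_scenarios_json(scenarios: list[ReefScenario], path) -> None:
    with open(path, "w") as fh:
        json.dump([s.to_dict() for s in scenarios], fh, indent=2)


def read_scenarios_json(path) -> list[ReefScenario]:
    """Read a scenario list from JSON or YAML (by file extension)."""
    with open(path) as fh:
        if str(path).endswith((".yaml", ".yml")):
            import yaml
            payload = yaml.safe_load(fh)
        else:
            payload = json.load(fh)
    return [ReefScenario.from_dict(d) for d in payload]
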