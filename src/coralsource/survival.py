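"""Larval and juvenile survival summaries and pairwise comparisons.

Larval survival is summarized per cross × temperature as the mean of per-well
percentages (100 × final/initial) with the standard error over wells.
Juvenile survival follows the product-limit bookkeeping of the source
experiment: the reported percentage is the number of individuals alive at the
final timepoint divided by all individuals at risk — the experiment's
"n.event / (n.event + n.censor)" convention, in which *alive* individuals are
the tabulated events. On ingest, alive/dead is accepted either as the 2/1
status coding or as a boolean, and is normalized internally.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .metrics import experiment_dhw

__all__ = [
    "normalize_survival_table",
    "larval_percent_survival",
    "juvenile_percent_survival",
    "KMCurve",
    "km_curve",
    "pairwise_wilcoxon",
    "tolerance_boost",
    "choose_final_timepoint",
    "load_survival_table",
]


def normalize_survival_table(table: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with an ``alive`` boolean resolved from status codes.

    ``status`` may be 2/1 (alive/dead), "alive"/"dead", or boolean. Larval
    rows (count data) keep ``alive`` as NA.
    """
    df = table.copy()
    if "alive" in df.columns and df["alive"].notna().any():
        df["alive"] = df["alive"].astype("boolean")
        return df
    alive = pd.Series(pd.NA, index=df.index, dtype="boolean")
    if "status" in df.columns:
        s = df["status"]
        numeric = pd.to_numeric(s, errors="coerce")
        alive[numeric.notna()] = numeric[numeric.notna()] == 2
        text = s.astype(str).str.lower()
        alive[text.isin(["alive", "dead"])] = text == "alive"
    df["alive"] = alive
    return df


def _group(df: pd.DataFrame, by) -> "pd.core.groupby.DataFrameGroupBy":
    keys = [k for k in by if k in df.columns]
    if not keys:
        raise ValueError(f"none of the grouping keys {by} are present")
    return df.groupby(keys, sort=False, dropna=False)


def larval_percent_survival(table: pd.DataFrame,
                            by=("cross_id", "temperature")) -> pd.DataFrame:
    """Mean per-well percent survival and its SE, per group.

    Per-well percent is 100 × final_count / initial_count; the group mean is
    averaged over wells and the SE is the sample stdev over wells divided by
    √n_wells.
    """
    df = table[table["stage"] == "larva"].copy()
    if df.empty:
        raise ValueError("no larval rows in table")
    if df["initial_count"].isna().any():
        raise ValueError("larval rows with missing initial_count")
    df["pct"] = 100.0 * df["final_count"] / df["initial_count"]
    out = []
    for keys, sub in _group(df, by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        pct = sub["pct"].to_numpy(float)
        se = float(np.std(pct, ddof=1) / np.sqrt(pct.size)) if pct.size > 1 else 0.0
        out.append(dict(zip([k for k in by if k in df.columns], keys))
                   | {"percent": float(pct.mean()), "se": se, "n_units": int(pct.size)})
    return pd.DataFrame(out)


def juvenile_percent_survival(table: pd.DataFrame,
                              by=("cross_id", "symbiont", "temperature"),
                              drop_censored: bool = False) -> pd.DataFrame:
    """Percent of individuals alive at the final timepoint, per group.

    Follows the experiment's inverted event convention: percent =
    100 × n_alive / n_at_risk. Censored individuals count toward the
    denominator unless ``drop_censored``. SE is the binomial approximation
    100 × √(p(1−p)/n).
    """
    df = normalize_survival_table(table[table["stage"] == "juvenile"])
    if df.empty:
        raise ValueError("no juvenile rows in table")
    if drop_censored and "censored" in df.columns:
        df = df[~df["censored"].astype(bool)]
    out = []
    for keys, sub in _group(df, by):
        keys = keys if isinstance(keys, tuple) else (keys,)
        alive = sub["alive"]
        n = int(alive.notna().sum())
        if n == 0:
            warnings.warn(f"group {keys} has no resolvable outcomes; dropped", stacklevel=2)
            continue
        p = float(alive.sum()) / n
        out.append(dict(zip([k for k in by if k in df.columns], keys))
                   | {"percent": 100.0 * p,
                      "se": 100.0 * float(np.sqrt(p * (1 - p) / n)),
                      "n_units": n})
    return pd.DataFrame(out)


@dataclass
class KMCurve:
    """Product-limit survival curve: right-continuous, non-increasing."""

    timeline: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        idx = np.searchsorted(self.timeline, t, side="right") - 1
        return float(self.survival[idx]) if idx >= 0 else 1.0

    __call__ = at


def km_curve(times, death_flags) -> KMCurve:
    """Kaplan–Meier product-limit estimate.

    ``death_flags`` True marks an observed death; False marks censoring.
    With no censoring the estimate equals the empirical survival fraction at
    each event time.
    """
    times = np.asarray(times, float)
    if (times < 0).any():
        raise ValueError("negative event times")
    events = np.asarray(death_flags, bool)
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return KMCurve(timeline=sf.index.to_numpy(float),
                   survival=sf.iloc[:, 0].to_numpy(float))


def pairwise_wilcoxon(groups: dict, adjust: str = "bonferroni",
                      exact_max_n: int = 12) -> pd.DataFrame:
    """Two-sided rank-sum tests for every pair of groups.

    Uses the exact null distribution when both samples are small
    (≤ ``exact_max_n``) and tie-free, otherwise the normal approximation
    with tie correction. Bonferroni adjustment multiplies each p by the
    number of pairs, capped at 1. A pair where both groups are a single
    repeated value is degenerate: p is reported as 1 and flagged.
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    for name in names:
        if len(np.asarray(groups[name])) < 1:
            raise ValueError(f"group {name!r} is empty")
    rows = []
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    for a, b in pairs:
        x, y = np.asarray(groups[a], float), np.asarray(groups[b], float)
        pooled = np.concatenate([x, y])
        degenerate = np.unique(pooled).size == 1
        if degenerate:
            stat, p = np.nan, 1.0
        else:
            has_ties = np.unique(pooled).size < pooled.size
            method = ("exact" if (not has_ties and max(x.size, y.size) <= exact_max_n)
                      else "asymptotic")
            res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"group1": a, "group2": b, "statistic": stat,
                     "p": p, "degenerate": degenerate})
    df = pd.DataFrame(rows)
    if adjust == "bonferroni":
        df["p_adj"] = np.minimum(1.0, df["p"] * m)
    elif adjust in (None, "none"):
        df["p_adj"] = df["p"]
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def tolerance_boost(summary_heat: pd.DataFrame, reef_mmm: dict,
                    treatment_temp: float, duration_days: float,
                    survival_threshold: float = 50.0,
                    reef_col: str = "maternal_reef") -> pd.DataFrame:
    """Thermal-tolerance boost per reef implied by heat-treatment survivors.

    For reefs whose offspring groups exceed ``survival_threshold`` percent
    survival at the elevated treatment, the boost is the exposure temperature
    minus the reef's expected summertime maximum (its MMM), also expressed in
    degree heating weeks via the linear experiment-dose convention.
    """
    if not reef_mmm:
        raise ValueError("reef_mmm climatology mapping is empty")
    rows = []
    for reef, sub in summary_heat.groupby(reef_col, sort=False):
        if reef not in reef_mmm:
            raise ValueError(f"no climatology (MMM) for reef {reef!r}")
        mmm = float(reef_mmm[reef])
        qualifies = bool((sub["percent"] > survival_threshold).any())
        rows.append({
            reef_col: reef,
            "qualifies": qualifies,
            "boost_c": treatment_temp - mmm if qualifies else np.nan,
            "boost_dhw": (experiment_dhw(treatment_temp, mmm, duration_days)
                          if qualifies else np.nan),
        })
    return pd.DataFrame(rows)


def choose_final_timepoint(table: pd.DataFrame, elevated_temp: float,
                           cross_fraction: float = 0.5,
                           survival_cutoff: float = 50.0) -> float:
    """Pick the scoring timepoint for longitudinal larval counts.

    Returns the earliest observed time at which at least ``cross_fraction``
    of the crosses have dropped to or below ``survival_cutoff`` percent
    survival in the elevated treatment; if no time qualifies, the last
    observed time. One documented operationalization of "the time needed for
    50% of the crosses to reach 50% survival" — the selection rule on new
    data is inherently a judgement call.
    """
    df = table[(table["stage"] == "larva") & (table["temperature"] == elevated_temp)].copy()
    if df.empty:
        raise ValueError("no elevated-temperature larval rows")
    df["pct"] = 100.0 * df["final_count"] / df["initial_count"]
    per = df.groupby(["time", "cross_id"], sort=True)["pct"].mean().reset_index()
    for t, sub in per.groupby("time", sort=True):
        frac = float((sub["pct"] <= survival_cutoff).mean())
        if frac >= cross_fraction:
            return float(t)
    return float(per["time"].max())


#: Column mapping from the deposited source-data layout to the internal schema.
DEFAULT_COLUMN_MAP = {
    "stage": "stage",
    "cross_id": "cross_id",
    "maternal_reef": "maternal_reef",
    "paternal_reef": "paternal_reef",
    "symbiont": "symbiont",
    "temperature": "temperature",
    "tank": "tank",
    "plate": "plate",
    "well": "well",
    "initial_count": "initial_count",
    "final_count": "final_count",
    "status": "status",
    "censored": "censored",
    "time": "time",
}


def load_survival_table(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a survival CSV, renaming columns per ``column_map``.

    ``column_map`` maps internal names to the file's column names, so
    externally deposited layouts can be ingested by configuration alone.
    Missing optional columns are filled with defaults; ``status``-coded
    outcomes (2 = alive, 1 = dead) are normalized to an ``alive`` boolean.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path)
    df = pd.DataFrame(index=raw.index)
    for internal, external in cmap.items():
        if external in raw.columns:
            df[internal] = raw[external]
    for col, default in (("symbiont", "Apo"), ("censored", False),
                         ("plate", ""), ("well", ""), ("tank", "")):
        if col not in df.columns:
            df[col] = default
    return normalize_survival_table(df)
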