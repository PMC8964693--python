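"""Intrinsic-resistance models: partial dependence → polynomial → envelope.

A fitted boosted ensemble is reduced to one marginal-effect (partial
dependence) curve per predictor; a low-order polynomial (degree 3–5) is fit
to that curve — the "intrinsic resistance" equation; solving the polynomial
against a survival threshold (default 90 %) yields the environmental
envelope: the feature intervals, within the observed range only, where
predicted survival under heat stress meets the threshold. The polynomial's
maximum over the range gives the survival optimum and its environmental
value.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PartialDependenceCurve",
    "PartialDependenceSurface",
    "partial_dependence",
    "partial_dependence_2d",
    "IntrinsicResistance",
    "IntrinsicResistanceResults",
    "solve_envelope",
    "find_optimum",
    "interval_jaccard",
]

_IMAG_TOL = 1e-8


@dataclass
class PartialDependenceCurve:
    """Marginal effect of one feature: grid values and averaged predictions."""

    feature: str
    grid: np.ndarray  # strictly increasing
    values: np.ndarray  # predicted survival (%) per grid point
    constant_feature: bool = False

    @property
    def n_grid(self) -> int:
        return self.grid.size


@dataclass
class PartialDependenceSurface:
    features: tuple
    grid_x: np.ndarray
    grid_y: np.ndarray
    values: np.ndarray  # shape (len(grid_x), len(grid_y))


def _grid_for(col: np.ndarray, n_grid: int):
    obs = col[~np.isnan(col)]
    if obs.size == 0:
        raise ValueError("feature has no observed values")
    lo, hi = float(obs.min()), float(obs.max())
    if lo == hi:
        return np.array([lo]), True
    return np.linspace(lo, hi, n_grid), False


def partial_dependence(results, X: pd.DataFrame, feature: str,
                       n_grid: int = 100) -> PartialDependenceCurve:
    """Partial dependence of the model on ``feature``.

    For each grid value g spanning the observed feature range,
    ``pd(g) = mean over rows of predict(row with feature := g)`` — the plain
    row × grid average, with no shortcut approximations.
    """
    if feature not in results.feature_names:
        raise KeyError(f"feature {feature!r} not in model")
    M = results._matrix(X)
    j = results.feature_names.index(feature)
    grid, constant = _grid_for(M[:, j], n_grid)
    if constant:
        warnings.warn(f"feature {feature!r} is constant; single-point curve",
                      stacklevel=2)
    values = np.empty(grid.size)
    W = M.copy()
    for i, g in enumerate(grid):
        W[:, j] = g
        values[i] = float(np.mean(results.predict(W)))
    return PartialDependenceCurve(feature=feature, grid=grid, values=values,
                                  constant_feature=constant)


def partial_dependence_2d(results, X: pd.DataFrame, feature_pair,
                          n_grid: int = 25) -> PartialDependenceSurface:
    """Joint marginal effect over a 2-D grid of two features."""
    f1, f2 = feature_pair
    for f in (f1, f2):
        if f not in results.feature_names:
            raise KeyError(f"feature {f!r} not in model")
    M = results._matrix(X)
    j1 = results.feature_names.index(f1)
    j2 = results.feature_names.index(f2)
    gx, _ = _grid_for(M[:, j1], n_grid)
    gy, _ = _grid_for(M[:, j2], n_grid)
    Z = np.empty((gx.size, gy.size))
    W = M.copy()
    for a, u in enumerate(gx):
        W[:, j1] = u
        for b, v in enumerate(gy):
            W[:, j2] = v
            Z[a, b] = float(np.mean(results.predict(W)))
    return PartialDependenceSurface(features=(f1, f2), grid_x=gx, grid_y=gy,
                                    values=Z)


# ---------------------------------------------------------------------------
# Polynomial fitting and envelope solving.


def _polyval(coeffs, x):
    return np.polynomial.polynomial.polyval(np.asarray(x, float),
                                            np.asarray(coeffs, float))


def _real_roots(coeffs) -> np.ndarray:
    """Real roots of an ascending-coefficient polynomial.

    Computed as eigenvalues of the companion matrix; imaginary parts below
    1e-8 are treated as numerical noise.
    """
    c = np.trim_zeros(np.asarray(coeffs, float), "b")
    if c.size <= 1:
        return np.array([])
    roots = np.polynomial.polynomial.polyroots(c)
    return np.sort(roots[np.abs(roots.imag) < _IMAG_TOL].real)


def solve_envelope(coeffs, threshold: float, xrange) -> list[tuple]:
    """Closed intervals within ``xrange`` where the polynomial ≥ threshold.

    Real roots of p(x) − threshold partition the range; each cell is kept or
    dropped by the polynomial's sign at its midpoint. The envelope never
    extends beyond the given range. An empty list is a valid result.
    """
    lo, hi = float(xrange[0]), float(xrange[1])
    if not (np.isfinite(lo) and np.isfinite(hi)) or hi < lo:
        raise ValueError(f"invalid range {xrange}")
    shifted = np.asarray(coeffs, float).copy()
    shifted[0] -= threshold
    roots = _real_roots(shifted)
    bounds = np.unique(np.concatenate([[lo, hi], roots[(roots > lo) & (roots < hi)]]))
    intervals = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if _polyval(coeffs, 0.5 * (a + b)) >= threshold:
            if intervals and intervals[-1][1] == a:
                intervals[-1] = (intervals[-1][0], float(b))
            else:
                intervals.append((float(a), float(b)))
    return intervals


def find_optimum(coeffs, xrange) -> tuple:
    """Global maximum of the polynomial over the closed range.

    Candidates are the real stationary points inside the range plus both
    endpoints; returns ``(x*, p(x*))``.
    """
    lo, hi = float(xrange[0]), float(xrange[1])
    deriv = np.polynomial.polynomial.polyder(np.asarray(coeffs, float))
    stationary = _real_roots(deriv)
    cand = np.concatenate([[lo, hi], stationary[(stationary >= lo) & (stationary <= hi)]])
    vals = _polyval(coeffs, cand)
    i = int(np.argmax(vals))
    return float(cand[i]), float(vals[i])


def interval_jaccard(a: list[tuple], b: list[tuple]) -> float:
    """Jaccard similarity of two unions of closed intervals (by length)."""

    def _measure(intervals):
        return sum(hi - lo for lo, hi in intervals)

    inter = []
    for la, ha in a:
        for lb, hb in b:
            lo, hi = max(la, lb), min(ha, hb)
            if hi > lo:
                inter.append((lo, hi))
    ai, bi, ii = _measure(a), _measure(b), _measure(inter)
    union = ai + bi - ii
    return ii / union if union > 0 else (1.0 if ai == bi == 0 else 0.0)


class IntrinsicResistance:
    """Polynomial intrinsic-resistance model over a partial-dependence curve.

    Candidate degrees 3–5 are each fit by least squares on the grid; the
    selected degree is the smallest whose R² comes within ``r2_tolerance``
    of the best candidate's — preferring the simplest equation that explains
    the curve essentially as well.
    """

    def __init__(self, curve: PartialDependenceCurve,
                 degrees: tuple = (3, 4, 5), threshold: float = 90.0,
                 r2_tolerance: float = 0.005):
        self.curve = curve
        self.degrees = tuple(sorted(degrees))
        self.threshold = float(threshold)
        self.r2_tolerance = float(r2_tolerance)

    def fit(self) -> "IntrinsicResistanceResults":
        g, v = self.curve.grid, self.curve.values
        xrange = (float(g.min()), float(g.max())) if g.size else (np.nan, np.nan)
        sst = float(np.sum((v - v.mean()) ** 2)) if v.size else 0.0
        if v.size < 2 or sst <= 1e-12 * max(1.0, float(np.abs(v).max())):
            # Degenerate flat curve: constant model, flagged.
            const = float(v.mean()) if v.size else np.nan
            envelope = ([(xrange[0], xrange[1])]
                        if v.size and const >= self.threshold and g.size > 1 else [])
            return IntrinsicResistanceResults(
                feature=self.curve.feature, degree=0, coefficients=(const,),
                r2=np.nan, optimum_x=float(g[0]) if g.size else np.nan,
                optimum_survival=const, envelope=envelope,
                threshold=self.threshold, feature_range=xrange,
                flagged="constant partial dependence", curve=self.curve)
        fits = {}
        for deg in self.degrees:
            if g.size < deg + 2:
                continue
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                coeffs = np.polynomial.polynomial.polyfit(g, v, deg)
                rank_deficient = any("conditioned" in str(w.message).lower()
                                     or "rank" in str(w.message).lower()
                                     for w in caught)
            if rank_deficient:
                continue
            resid = v - _polyval(coeffs, g)
            fits[deg] = (tuple(float(c) for c in coeffs),
                         1.0 - float(np.sum(resid ** 2)) / sst)
        flag = None
        if not fits:
            # Fall back to the highest feasible degree below the candidates.
            deg = max(1, min(self.degrees[0] - 1, g.size - 2))
            coeffs = np.polynomial.polynomial.polyfit(g, v, deg)
            resid = v - _polyval(coeffs, g)
            fits[deg] = (tuple(float(c) for c in coeffs),
                         1.0 - float(np.sum(resid ** 2)) / sst)
            flag = f"degree reduced to {deg} (too few points or rank-deficient fit)"
        best_r2 = max(r2 for _, r2 in fits.values())
        degree = min(d for d, (_, r2) in fits.items()
                     if r2 >= best_r2 - self.r2_tolerance)
        coeffs, r2 = fits[degree]
        opt_x, opt_p = find_optimum(coeffs, xrange)
        envelope = solve_envelope(coeffs, self.threshold, xrange)
        return IntrinsicResistanceResults(
            feature=self.curve.feature, degree=degree, coefficients=coeffs,
            r2=r2, optimum_x=opt_x, optimum_survival=opt_p,
            envelope=envelope, threshold=self.threshold,
            feature_range=xrange, flagged=flag, curve=self.curve)


@dataclass
class IntrinsicResistanceResults:
    """Fitted intrinsic-resistance equation with optimum and envelope."""

    feature: str
    degree: int
    coefficients: tuple  # ascending powers
    r2: float
    optimum_x: float
    optimum_survival: float
    envelope: list  # list of (lo, hi) closed intervals
    threshold: float
    feature_range: tuple
    flagged: str | None = None
    curve: PartialDependenceCurve | None = field(default=None, repr=False)

    def predict(self, x) -> np.ndarray:
        return _polyval(self.coefficients, x)

    def contains(self, x) -> np.ndarray:
        """Whether feature values fall inside the envelope (closed bounds)."""
        x = np.asarray(x, float)
        out = np.zeros(x.shape, bool)
        for lo, hi in self.envelope:
            out |= (x >= lo) & (x <= hi)
        return out

    def summary(self) -> str:
        terms = " + ".join(f"{c:.6g}·x^{i}" if i else f"{c:.6g}"
                           for i, c in enumerate(self.coefficients))
        lines = [
            f"Intrinsic resistance model — {self.feature}",
            "=" * 54,
            f"Polynomial degree:   {self.degree}",
            f"p(x) = {terms}",
            f"Fit R2 on PD grid:   {self.r2:.4f}" if np.isfinite(self.r2)
            else "Fit R2 on PD grid:   n/a",
            f"Optimum:             {self.optimum_survival:.2f}% at "
            f"{self.feature} = {self.optimum_x:.4g}",
            f"Envelope (>= {self.threshold:g}%): "
            + (", ".join(f"[{lo:.4g}, {hi:.4g}]" for lo, hi in self.envelope)
               or "empty"),
        ]
        if self.flagged:
            lines.append(f"Flag: {self.flagged}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature, "degree": self.degree,
            "coefficients": list(self.coefficients), "r2": self.r2,
            "optimum_x": self.optimum_x,
            "optimum_survival": self.optimum_survival,
            "envelope": [list(iv) for iv in self.envelope],
            "threshold": self.threshold,
            "feature_range": list(self.feature_range),
            "flagged": self.flagged,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "IntrinsicResistanceResults":
        return cls(feature=d["feature"], degree=d["degree"],
                   coefficients=tuple(d["coefficients"]), r2=d["r2"],
                   optimum_x=d["optimum_x"],
                   optimum_survival=d["optimum_survival"],
                   envelope=[tuple(iv) for iv in d["envelope"]],
                   threshold=d["threshold"],
                   feature_range=tuple(d["feature_range"]),
                   flagged=d.get("flagged"))

    @classmethod
    def from_json(cls, path) -> "IntrinsicResistanceResults":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))
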