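"""Stochastic gradient-boosted regression trees for heat-stress survival.

The model regresses an offspring survival response (per-well larval percent
survival, or individual juvenile survival scored 0/100) on the seven
environmental predictors of the maternal reef. It follows the classic
stochastic gradient boosting recipe for squared-error loss: initialize at the
response mean, then repeatedly fit a small least-squares regression tree to
the current residuals of a random subsample of rows (drawn without
replacement at ``bag_fraction``), and add it scaled by the shrinkage
(learning rate).

Conventions follow the R ``gbm`` lineage rather than depth-limited CART:

* ``interaction_depth`` is the maximum number of *splits* per tree, grown
  best-first by squared-error reduction — not a tree height;
* missing feature values are routed by majority direction at each split
  (the child holding more observed rows), with no surrogate splits;
* relative influence of a predictor is its summed squared-error reduction
  over every split in the ensemble, normalized to 100 % (a split-count
  variant is available as an alternative).

A single seed drives bagging, fold assignment and grid search through
independently derived streams, so each component is reproducible in
isolation.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, asdict, field, replace

import numpy as np
import pandas as pd

from .metrics import feature_frame

__all__ = [
    "GBMParams",
    "BoostedSurvival",
    "BoostedSurvivalResults",
    "CVResult",
    "TuneResult",
    "derive_seed",
]

_GAIN_EPS = 1e-12


def derive_seed(seed: int, label: str) -> int:
    """Deterministic child seed (< 2^31) for a named component stream."""
    salt = int.from_bytes(label.encode(), "little") % (2**31 - 1)
    ss = np.random.SeedSequence([int(seed) % (2**31), salt])
    return int(ss.generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class GBMParams:
    """Boosting hyperparameters.

    Defaults follow common practice for small ecological datasets: 500 trees
    of up to five splits, shrinkage 0.1, at least 10 observations per node,
    and 50 % bagging.
    """

    n_trees: int = 500
    shrinkage: float = 0.1
    interaction_depth: int = 5
    min_obs_in_node: int = 10
    bag_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")
        if not (0 < self.shrinkage <= 1):
            raise ValueError("shrinkage must be in (0, 1]")
        if self.interaction_depth < 1:
            raise ValueError("interaction_depth must be >= 1")
        if self.min_obs_in_node < 1:
            raise ValueError("min_obs_in_node must be >= 1")
        if not (0 < self.bag_fraction <= 1):
            raise ValueError("bag_fraction must be in (0, 1]")


# ---------------------------------------------------------------------------
# Single-tree machinery.


def _best_split(X: np.ndarray, r: np.ndarray, idx: np.ndarray, min_obs: int,
                features: np.ndarray):
    """Best squared-error-reduction split over the given rows and features.

    Returns ``(gain, feature, threshold, missing_left)`` or ``None``. The
    gain is computed on non-missing rows; missing rows are routed to the
    majority child and count toward the child-size constraint.
    """
    best = None
    for j in features:
        x = X[idx, j]
        miss = np.isnan(x)
        xo = x[~miss]
        if xo.size < 2:
            continue
        ro = r[idx][~miss]
        n_miss = int(miss.sum())
        order = np.argsort(xo, kind="stable")
        xs, rs = xo[order], ro[order]
        if xs[0] == xs[-1]:
            continue
        csum = np.cumsum(rs)
        total = csum[-1]
        n = xs.size
        nL = np.arange(1, n)
        nR = n - nL
        sL = csum[:-1]
        sR = total - sL
        miss_left = nL >= nR
        nL_eff = nL + np.where(miss_left, n_miss, 0)
        nR_eff = nR + np.where(miss_left, 0, n_miss)
        valid = (xs[1:] > xs[:-1]) & (nL_eff >= min_obs) & (nR_eff >= min_obs)
        if not valid.any():
            continue
        gain = sL * sL / nL + sR * sR / nR - total * total / n
        gain[~valid] = -np.inf
        i = int(np.argmax(gain))
        if gain[i] <= _GAIN_EPS:
            continue
        if best is None or gain[i] > best[0]:
            thr = 0.5 * (xs[i] + xs[i + 1])
            best = (float(gain[i]), int(j), thr, bool(miss_left[i]))
    return best


def _partition(X: np.ndarray, idx: np.ndarray, feature: int, threshold: float,
               missing_left: bool):
    x = X[idx, feature]
    miss = np.isnan(x)
    go_left = np.where(miss, missing_left, x <= threshold)
    return idx[go_left], idx[~go_left]


def _fit_tree(X: np.ndarray, r: np.ndarray, max_splits: int, min_obs: int,
              feature_subsample: np.ndarray | None = None) -> dict:
    """Grow one least-squares tree best-first, up to ``max_splits`` splits.

    Leaves predict the mean residual of all rows routed to them (including
    majority-routed missing rows). All-constant features yield a single-leaf
    tree, never an error.
    """
    n, p = X.shape
    features = (np.arange(p) if feature_subsample is None
                else np.asarray(feature_subsample, int))
    idx0 = np.arange(n)
    root = {"value": float(r.mean()), "n": int(n)}
    if max_splits < 1 or n < 2 * min_obs:
        return root
    frontier = []  # (candidate, node, idx)
    cand = _best_split(X, r, idx0, min_obs, features)
    if cand is not None:
        frontier.append((cand, root, idx0))
    splits = 0
    while frontier and splits < max_splits:
        k = max(range(len(frontier)), key=lambda i: frontier[i][0][0])
        (gain, j, thr, miss_left), node, idx = frontier.pop(k)
        left_idx, right_idx = _partition(X, idx, j, thr, miss_left)
        node.pop("value", None)
        node.update({
            "feature": j, "threshold": float(thr), "gain": float(gain),
            "missing_left": miss_left,
            "left": {"value": float(r[left_idx].mean()), "n": int(left_idx.size)},
            "right": {"value": float(r[right_idx].mean()), "n": int(right_idx.size)},
        })
        splits += 1
        for child, cidx in ((node["left"], left_idx), (node["right"], right_idx)):
            if cidx.size >= 2 * min_obs:
                cand = _best_split(X, r, cidx, min_obs, features)
                if cand is not None:
                    frontier.append((cand, child, cidx))
    return root


def _predict_tree(tree: dict, X: np.ndarray) -> np.ndarray:
    out = np.empty(X.shape[0])
    stack = [(tree, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        if "feature" not in node:
            out[idx] = node["value"]
            continue
        x = X[idx, node["feature"]]
        miss = np.isnan(x)
        go_left = np.where(miss, node["missing_left"], x <= node["threshold"])
        stack.append((node["left"], idx[go_left]))
        stack.append((node["right"], idx[~go_left]))
    return out


def _walk_splits(tree: dict):
    stack = [tree]
    while stack:
        node = stack.pop()
        if "feature" in node:
            yield node["feature"], node["gain"]
            stack.append(node["left"])
            stack.append(node["right"])


# ---------------------------------------------------------------------------
# Model / results objects.


class BoostedSurvival:
    """Boosted-trees survival model (statsmodels-style model object).

    Parameters
    ----------
    endog : array-like
        Survival response per observation unit (percent scale 0–100 for
        larval wells; 0/100 for individual juveniles).
    exog : pandas.DataFrame
        Feature matrix; columns are predictor names, NaN allowed.
    groups : array-like, optional
        Maternal reef id per row, used by grouped validation.
    """

    def __init__(self, endog, exog: pd.DataFrame, groups=None):
        endog = np.asarray(endog, float)
        if np.isnan(endog).any():
            raise ValueError("endog contains missing values")
        if not isinstance(exog, pd.DataFrame):
            exog = pd.DataFrame(np.asarray(exog, float))
        if len(exog) != endog.size:
            raise ValueError("endog and exog lengths differ")
        self.endog = endog
        self.exog = exog.reset_index(drop=True)
        self.feature_names = [str(c) for c in exog.columns]
        self.groups = (np.asarray(groups).astype(str)
                       if groups is not None else None)
        self._X = self.exog.to_numpy(float)

    @classmethod
    def from_survival_table(cls, table: pd.DataFrame, env: pd.DataFrame,
                            stage: str, symbiont: str | None = None,
                            cross_type: str | None = None,
                            temperature: float | None = None) -> "BoostedSurvival":
        """Build the model matrix from a survival table and reef profiles.

        Observation units are replicate larval wells or single juveniles.
        Features are the seven metrics of the MATERNAL reef. ``temperature``
        defaults to the elevated treatment (the highest temperature present
        for the stage); ``cross_type`` may restrict to "purebred" or
        "hybrid" crosses.
        """
        from .survival import normalize_survival_table

        df = table[table["stage"] == stage].copy()
        if symbiont is not None:
            df = df[df["symbiont"] == symbiont]
        if cross_type == "purebred":
            df = df[df["maternal_reef"] == df["paternal_reef"]]
        elif cross_type == "hybrid":
            df = df[df["maternal_reef"] != df["paternal_reef"]]
        elif cross_type is not None:
            raise ValueError(f"unknown cross_type {cross_type!r}")
        if temperature is None:
            temperature = float(df["temperature"].max())
        df = df[df["temperature"] == temperature]
        if df.empty:
            raise ValueError("no rows left after filtering the survival table")
        if stage == "larva":
            y = 100.0 * df["final_count"].to_numpy(float) / df["initial_count"].to_numpy(float)
        elif stage == "juvenile":
            df = normalize_survival_table(df)
            y = 100.0 * df["alive"].astype(float).to_numpy()
        else:
            raise ValueError(f"unknown stage {stage!r}")
        feats = feature_frame(env)
        X = feats.loc[df["maternal_reef"].astype(str)].reset_index(drop=True)
        return cls(y, X, groups=df["maternal_reef"].to_numpy())

    # -- fitting ----------------------------------------------------------

    def fit(self, params: GBMParams | None = None, **kwargs) -> "BoostedSurvivalResults":
        """Fit the boosted ensemble; returns a results object."""
        if params is None:
            params = GBMParams(**kwargs)
        elif kwargs:
            params = replace(params, **kwargs)
        n = self.endog.size
        if n < params.min_obs_in_node:
            raise ValueError("fewer rows than min_obs_in_node")
        rng = np.random.default_rng(derive_seed(params.seed, "bagging"))
        y = self.endog
        F = np.full(n, y.mean())
        trees: list[dict] = []
        train_curve: list[float] = []
        bag_size = max(1, int(round(params.bag_fraction * n)))
        for _ in range(params.n_trees):
            bag = (np.arange(n) if params.bag_fraction >= 1.0
                   else np.sort(rng.choice(n, size=bag_size, replace=False)))
            tree = _fit_tree(self._X[bag], (y - F)[bag],
                             params.interaction_depth, params.min_obs_in_node)
            F = F + params.shrinkage * _predict_tree(tree, self._X)
            trees.append(tree)
            train_curve.append(float(np.mean((y - F) ** 2)))
        return BoostedSurvivalResults(self, params, float(y.mean()), trees,
                                      np.asarray(train_curve))

    # -- validation -------------------------------------------------------

    def _folds(self, scheme: str, k: int, repeats: int, seed: int):
        """Yield (repeat, fold, train_idx, test_idx) index tuples."""
        n = self.endog.size
        if scheme == "loo":
            scheme, k, repeats = "kfold", n, 1
        if scheme == "kfold":
            repeats = 1
        rng = np.random.default_rng(derive_seed(seed, f"folds-{scheme}"))
        if scheme in ("kfold", "repeated_kfold"):
            if k > n:
                raise ValueError(f"k={k} exceeds the {n} available rows")
            for rep in range(repeats):
                perm = rng.permutation(n)
                for fold, test in enumerate(np.array_split(perm, k)):
                    train = np.setdiff1d(perm, test)
                    yield rep, fold, train, np.sort(test)
        elif scheme == "bootstrap":
            for rep in range(repeats):
                train = np.sort(rng.choice(n, size=n, replace=True))
                test = np.setdiff1d(np.arange(n), train)
                if test.size == 0:
                    continue
                yield rep, 0, train, test
        else:
            raise ValueError(f"unknown CV scheme {scheme!r}")

    def cross_validate(self, params: GBMParams | None = None,
                       scheme: str = "repeated_kfold", k: int = 10,
                       repeats: int = 10, seed: int | None = None) -> "CVResult":
        """Out-of-sample R² under a chosen resampling scheme.

        Per-fold R² (1 − SSE/SST about the held-out mean) is reported where a
        fold holds at least two rows; the headline ``r2`` pools every
        held-out (observation, prediction) pair, which stays well defined for
        leave-one-out.
        """
        params = params or GBMParams()
        seed = params.seed if seed is None else seed
        rows = []
        ys, preds = [], []
        for rep, fold, train, test in self._folds(scheme, k, repeats, seed):
            sub = BoostedSurvival(self.endog[train], self.exog.iloc[train],
                                  None if self.groups is None else self.groups[train])
            fit_seed = derive_seed(seed, f"fit-{scheme}-{rep}-{fold}")
            res = sub.fit(replace(params, seed=fit_seed))
            pred = res.predict(self.exog.iloc[test])
            yt = self.endog[test]
            ys.append(yt)
            preds.append(pred)
            sse = float(np.sum((yt - pred) ** 2))
            sst = float(np.sum((yt - yt.mean()) ** 2))
            rows.append({
                "repeat": rep, "fold": fold, "n_test": int(test.size),
                "rmse": float(np.sqrt(sse / test.size)),
                "r2": 1.0 - sse / sst if test.size > 1 and sst > 0 else np.nan,
            })
        y_all = np.concatenate(ys)
        p_all = np.concatenate(preds)
        sse = float(np.sum((y_all - p_all) ** 2))
        sst = float(np.sum((y_all - y_all.mean()) ** 2))
        return CVResult(scheme=scheme, scores=pd.DataFrame(rows),
                        r2=1.0 - sse / sst,
                        rmse=float(np.sqrt(sse / y_all.size)))

    def tune(self, grid, scheme: str = "repeated_kfold", k: int = 10,
             repeats: int = 3, seed: int = 0) -> "TuneResult":
        """Exhaustive grid search minimizing pooled CV RMSE.

        ``grid`` is either an iterable of :class:`GBMParams` or a dict of
        parameter-name → list of values. Every combination is evaluated on
        the same derived fold stream; ties keep the earliest grid entry.
        Training-loss curves per combination are returned as diagnostics.
        """
        combos = self._expand_grid(grid)
        if not combos:
            raise ValueError("empty hyperparameter grid")
        records, curves = [], []
        best_i = None
        best_rmse = np.inf
        for i, params in enumerate(combos):
            cv = self.cross_validate(params, scheme=scheme, k=k,
                                     repeats=repeats, seed=seed)
            full = self.fit(replace(params, seed=derive_seed(seed, f"diag-{i}")))
            curves.append(full.train_curve)
            records.append({"combo": i, **asdict(params),
                            "cv_rmse": cv.rmse, "cv_r2": cv.r2})
            if cv.rmse < best_rmse:
                best_rmse, best_i = cv.rmse, i
        return TuneResult(best_params=combos[best_i],
                          table=pd.DataFrame(records),
                          train_curves=curves)

    @staticmethod
    def _expand_grid(grid) -> list[GBMParams]:
        if isinstance(grid, dict):
            keys = list(grid)
            return [GBMParams(**dict(zip(keys, vals)))
                    for vals in itertools.product(*(grid[k] for k in keys))]
        return list(grid)

    def leave_one_reef_out(self, reef_id: str | None = None,
                           params: GBMParams | None = None):
        """Hold out every row whose maternal reef matches ``reef_id``.

        With ``reef_id=None``, runs the exclusion for each reef in turn and
        returns a dict reef → (results, prediction table).
        """
        if self.groups is None:
            raise ValueError("model was built without reef groups")
        reefs = pd.unique(self.groups)
        if reefs.size < 2:
            raise ValueError("need at least 2 reefs for leave-one-reef-out")
        if reef_id is None:
            return {r: self.leave_one_reef_out(r, params) for r in reefs}
        if reef_id not in set(reefs):
            raise ValueError(f"unknown reef {reef_id!r}")
        held = self.groups == str(reef_id)
        train = np.flatnonzero(~held)
        test = np.flatnonzero(held)
        sub = BoostedSurvival(self.endog[train], self.exog.iloc[train],
                              self.groups[train])
        res = sub.fit(params or GBMParams())
        pred = res.predict(self.exog.iloc[test])
        table = pd.DataFrame({"row": test, "reef": reef_id,
                              "observed": self.endog[test], "predicted": pred})
        return res, table


@dataclass
class CVResult:
    scheme: str
    scores: pd.DataFrame
    r2: float  # pooled over all held-out pairs
    rmse: float

    @property
    def mean_fold_r2(self) -> float:
        vals = self.scores["r2"].dropna()
        return float(vals.mean()) if len(vals) else self.r2


@dataclass
class TuneResult:
    best_params: GBMParams
    table: pd.DataFrame
    train_curves: list = field(default_factory=list)


class BoostedSurvivalResults:
    """Fitted boosted ensemble with influence and dependence diagnostics."""

    def __init__(self, model: BoostedSurvival | None, params: GBMParams,
                 initial_value: float, trees: list[dict],
                 train_curve: np.ndarray, feature_names: list[str] | None = None):
        self.model = model
        self.params = params
        self.initial_value = initial_value
        self.trees = trees
        self.train_curve = np.asarray(train_curve, float)
        self.feature_names = (list(model.feature_names) if model is not None
                              else list(feature_names or []))

    # -- prediction -------------------------------------------------------

    def _matrix(self, X) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [f for f in self.feature_names if f not in X.columns]
            if missing:
                raise KeyError(f"features absent from input: {missing}")
            return X[self.feature_names].to_numpy(float)
        X = np.asarray(X, float)
        if X.ndim != 2 or X.shape[1] != len(self.feature_names):
            raise ValueError("feature matrix has wrong shape")
        return X

    def predict(self, X) -> np.ndarray:
        """Ensemble prediction: initial value plus shrunken tree sum."""
        M = self._matrix(X)
        out = np.full(M.shape[0], self.initial_value)
        for tree in self.trees:
            out += self.params.shrinkage * _predict_tree(tree, M)
        return out

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict(self.model.exog)

    @property
    def training_r2(self) -> float:
        y = self.model.endog
        sse = float(np.sum((y - self.fittedvalues) ** 2))
        sst = float(np.sum((y - y.mean()) ** 2))
        return 1.0 - sse / sst if sst > 0 else np.nan

    # -- diagnostics ------------------------------------------------------

    def relative_influence(self, method: str = "sse") -> pd.Series:
        """Per-feature relative influence, summing to 100 %.

        ``sse``: summed squared-error reduction over all splits (primary).
        ``splits``: share of split counts (alternative, cruder).
        """
        acc = np.zeros(len(self.feature_names))
        for tree in self.trees:
            for j, gain in _walk_splits(tree):
                acc[j] += gain if method == "sse" else 1.0
        total = acc.sum()
        if total <= 0:
            warnings.warn("model has no splits; influence undefined (zeros)",
                          stacklevel=2)
            return pd.Series(acc, index=self.feature_names)
        return pd.Series(100.0 * acc / total, index=self.feature_names)

    def partial_dependence(self, feature: str, X=None, n_grid: int = 100):
        from .resistance import partial_dependence
        X = self.model.exog if X is None else X
        return partial_dependence(self, X, feature, n_grid=n_grid)

    def partial_dependence_2d(self, feature_pair, X=None, n_grid: int = 25):
        from .resistance import partial_dependence_2d
        X = self.model.exog if X is None else X
        return partial_dependence_2d(self, X, feature_pair, n_grid=n_grid)

    def summary(self) -> str:
        lines = [
            "Boosted survival model",
            "=" * 54,
            f"Observations:        {self.model.endog.size if self.model else 'n/a'}",
            f"Trees:               {len(self.trees)}",
            f"Shrinkage:           {self.params.shrinkage}",
            f"Interaction depth:   {self.params.interaction_depth}",
            f"Min obs per node:    {self.params.min_obs_in_node}",
            f"Bag fraction:        {self.params.bag_fraction}",
        ]
        if self.model is not None:
            lines.append(f"Training R2:         {self.training_r2:.4f}")
        lines.append("-" * 54)
        lines.append("Relative influence (% of squared-error reduction)")
        infl = self.relative_influence().sort_values(ascending=False)
        for name, val in infl.items():
            lines.append(f"  {name:<18s} {val:6.2f}")
        return "\n".join(lines)

    # -- serialization ----------------------------------------------------

    def to_json(self, path) -> None:
        payload = {
            "params": asdict(self.params),
            "initial_value": self.initial_value,
            "feature_names": self.feature_names,
            "train_curve": self.train_curve.tolist(),
            "trees": self.trees,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "BoostedSurvivalResults":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(model=None, params=GBMParams(**payload["params"]),
                   initial_value=payload["initial_value"],
                   trees=payload["trees"],
                   train_curve=np.asarray(payload["train_curve"]),
                   feature_names=payload["feature_names"])
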