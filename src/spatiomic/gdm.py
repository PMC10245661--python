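"""Generalized dissimilarity modelling of community turnover.

A GDM regresses pairwise compositional dissimilarity d_ij in [0, 1) on
monotone transforms of predictor differences:

    d_ij = 1 - exp(-eta),   eta = alpha + sum_p |f_p(x_pi) - f_p(x_pj)|

where each f_p is a non-negative combination of monotone I-spline basis
functions (default 3, knots at the predictor's min/median/max), so every
fitted turnover curve is non-decreasing.  Coefficients are found by
minimizing the binomial-type deviance

    D = sum_ij 2 [ y ln(y/mu) + (1-y) ln((1-y)/(1-mu)) ]

under alpha, beta >= 0 (0*ln 0 = 0).  Percent deviance explained is
100 (D_null - D_model) / D_null.

Predictors come in two kinds: *site* predictors measured per sample
(soil chemistry, plant traits, weather), entering as |f(x_i) - f(x_j)|,
and *pair* predictors that are already pairwise distances (geographic
distance in meters, temporal distance in days), entering as f(d_ij).

On top of the fit the module provides permutation variable importance
with backward selection, deviance partitioning over predictor groups by
inclusion-exclusion, and bootstrap uncertainty bands for the fitted
splines (refits with a fraction of samples withheld).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.optimize import minimize, nnls
from sklearn.base import BaseEstimator

__all__ = [
    "ISplineBasis",
    "GdmData",
    "GDM",
    "fit_gdm",
    "build_pair_table",
    "variable_importance",
    "backward_select",
    "partition_deviance",
    "bootstrap_splines",
]

_EPS = 1e-9
_MU_CLIP = 1e-10


# ---------------------------------------------------------------------------
# I-spline basis
# ---------------------------------------------------------------------------

class ISplineBasis:
    """Monotone I-spline basis (integrated degree-1 M-splines).

    ``n_basis`` knots are placed at evenly spaced quantiles of the
    observed values (for the default 3: min, median, max).  Each basis
    function rises monotonically from 0 (at or below the first knot) to
    1 (at or above the last).
    """

    def __init__(self, values, n_basis: int = 3):
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if v.size == 0:
            raise ValueError("no finite values to place spline knots")
        q = np.quantile(v, np.linspace(0, 1, n_basis))
        self.degenerate = q[-1] - q[0] <= 0
        if not self.degenerate:
            # nudge interior knots off the boundaries if quantiles collide
            span = q[-1] - q[0]
            for i in range(1, n_basis - 1):
                if q[i] <= q[i - 1]:
                    q[i] = q[i - 1] + span * 1e-6 * i
            q = np.minimum(q, q[-1])
            for i in range(n_basis - 2, 0, -1):
                if q[i] >= q[i + 1]:
                    q[i] = q[i + 1] - span * 1e-6 * (n_basis - 1 - i)
        self.knots = q
        self.n_basis = n_basis
        if not self.degenerate:
            t = np.concatenate([[q[0]], q, [q[-1]]])
            deg = 1
            self._splines = []
            for j in range(n_basis):
                c = np.zeros(n_basis)
                c[j] = 1.0
                b = BSpline(t, c, deg, extrapolate=False)
                integral = (t[j + deg + 1] - t[j]) / (deg + 1)
                self._splines.append((b.antiderivative(), integral))

    def transform(self, x) -> np.ndarray:
        """Evaluate all basis functions at x; shape (len(x), n_basis)."""
        x = np.asarray(x, dtype=float)
        out = np.zeros((x.size, self.n_basis))
        if self.degenerate:
            return out
        lo, hi = self.knots[0], self.knots[-1]
        xc = np.clip(x, lo, hi)
        for j, (anti, integral) in enumerate(self._splines):
            vals = anti(xc)
            vals = np.where(np.isnan(vals), 0.0, vals)
            out[:, j] = vals / integral
        out[x >= hi] = np.maximum(out[x >= hi], 0.0)
        # above the last knot every basis function has saturated at 1
        out[x > hi] = 1.0
        return np.clip(out, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Data container
# ---------------------------------------------------------------------------

@dataclass
class GdmData:
    """Samples, observed dissimilarities, and predictors for a GDM fit.

    ``site_predictors`` is a DataFrame indexed by sample id (one value
    per sample); ``pair_predictors`` maps a name to a square symmetric
    matrix aligned with ``ids``.
    """

    ids: list[str]
    dissimilarity: np.ndarray
    site_predictors: pd.DataFrame | None = None
    pair_predictors: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.ids)
        self.dissimilarity = np.asarray(self.dissimilarity, dtype=float)
        if self.dissimilarity.shape != (n, n):
            raise ValueError("dissimilarity matrix does not match ids")
        if self.site_predictors is not None:
            self.site_predictors = self.site_predictors.loc[self.ids]
            bad = self.site_predictors.columns[
                ~np.isfinite(self.site_predictors).all(axis=0)
            ].tolist()
            if bad:
                raise ValueError(f"non-finite predictor values in: {bad}")

    @classmethod
    def from_distance_matrix(cls, dm, site_predictors=None, pair_predictors=None):
        pp = {}
        for name, m in (pair_predictors or {}).items():
            data = m.data if hasattr(m, "data") else np.asarray(m, dtype=float)
            pp[name] = data
        return cls(list(dm.ids), np.asarray(dm.data, dtype=float), site_predictors, pp)

    @property
    def predictor_names(self) -> list[str]:
        names = list(self.pair_predictors)
        if self.site_predictors is not None:
            names += list(self.site_predictors.columns)
        return names

    def kind(self, name: str) -> str:
        if name in self.pair_predictors:
            return "pair"
        if self.site_predictors is not None and name in self.site_predictors.columns:
            return "site"
        raise KeyError(f"unknown predictor {name!r}")

    def values(self, name: str) -> np.ndarray:
        """Pooled values of a predictor (for knot placement)."""
        if self.kind(name) == "site":
            return self.site_predictors[name].to_numpy(dtype=float)
        m = self.pair_predictors[name]
        iu = np.triu_indices(len(self.ids), 1)
        return m[iu]

    def subset(self, index: np.ndarray) -> "GdmData":
        ids = [self.ids[i] for i in index]
        sp = self.site_predictors.iloc[index] if self.site_predictors is not None else None
        pp = {k: v[np.ix_(index, index)] for k, v in self.pair_predictors.items()}
        return GdmData(ids, self.dissimilarity[np.ix_(index, index)], sp, pp)

    def permute_predictor(self, name: str, perm: np.ndarray) -> "GdmData":
        """Return a copy with predictor ``name`` permuted across samples."""
        if self.kind(name) == "site":
            sp = self.site_predictors.copy()
            sp[name] = sp[name].to_numpy()[perm]
            return GdmData(self.ids, self.dissimilarity, sp, dict(self.pair_predictors))
        pp = dict(self.pair_predictors)
        pp[name] = pp[name][np.ix_(perm, perm)]
        return GdmData(self.ids, self.dissimilarity, self.site_predictors, pp)

    def to_pair_table(self, predictors: list[str] | None = None) -> pd.DataFrame:
        """Long-format table of all unordered pairs (the SitePairTable)."""
        predictors = predictors or self.predictor_names
        n = len(self.ids)
        iu, ju = np.triu_indices(n, 1)
        out = {
            "i": [self.ids[a] for a in iu],
            "j": [self.ids[b] for b in ju],
            "distance": self.dissimilarity[iu, ju],
        }
        for p in predictors:
            if self.kind(p) == "pair":
                out[p] = self.pair_predictors[p][iu, ju]
            else:
                v = self.site_predictors[p].to_numpy(dtype=float)
                out[f"{p}_i"] = v[iu]
                out[f"{p}_j"] = v[ju]
        return pd.DataFrame(out)


def build_pair_table(
    dm,
    site_predictors: pd.DataFrame | None = None,
    pair_predictors: dict | None = None,
    include_samples: list[str] | None = None,
) -> pd.DataFrame:
    """All unordered sample pairs with endpoint predictor values.

    ``include_samples`` restricts the table to a sample subset (e.g.
    soil samples from root-sampling dates only); pairs touching excluded
    samples are dropped.
    """
    data = GdmData.from_distance_matrix(dm, site_predictors, pair_predictors)
    if include_samples is not None:
        keep = set(include_samples)
        idx = np.array([i for i, s in enumerate(data.ids) if s in keep])
        if idx.size == 0:
            raise ValueError("no samples left after restriction")
        data = data.subset(idx)
    return data.to_pair_table()


def data_from_pair_table(table: pd.DataFrame) -> GdmData:
    """Reconstruct a :class:`GdmData` from a long-format pair table."""
    ids = list(pd.unique(pd.concat([table["i"], table["j"]], ignore_index=True)))
    pos = {s: k for k, s in enumerate(ids)}
    n = len(ids)
    d = np.zeros((n, n))
    ii = table["i"].map(pos).to_numpy()
    jj = table["j"].map(pos).to_numpy()
    d[ii, jj] = table["distance"].to_numpy(dtype=float)
    d[jj, ii] = d[ii, jj]
    site_cols = sorted({c[:-2] for c in table.columns if c.endswith("_i")})
    pair_cols = [
        c for c in table.columns if c not in ("i", "j", "distance")
        and not (c.endswith("_i") or c.endswith("_j"))
    ]
    sp = None
    if site_cols:
        vals = {c: np.full(n, np.nan) for c in site_cols}
        for c in site_cols:
            vals[c][ii] = table[f"{c}_i"].to_numpy(dtype=float)
            vals[c][jj] = table[f"{c}_j"].to_numpy(dtype=float)
        sp = pd.DataFrame(vals, index=ids)
    pp = {}
    for c in pair_cols:
        m = np.zeros((n, n))
        m[ii, jj] = table[c].to_numpy(dtype=float)
        m[jj, ii] = m[ii, jj]
        pp[c] = m
    return GdmData(ids, d, sp, pp)


# ---------------------------------------------------------------------------
# Deviance
# ---------------------------------------------------------------------------

def binomial_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    """Sum of 2[y ln(y/mu) + (1-y) ln((1-y)/(1-mu))] with 0 ln 0 = 0."""
    y = np.clip(y, 0.0, 1.0 - _EPS)
    mu = np.clip(mu, _MU_CLIP, 1.0 - _MU_CLIP)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(y > 0, y * np.log(y / mu), 0.0)
        t2 = np.where(y < 1, (1 - y) * np.log((1 - y) / (1 - mu)), 0.0)
    return float(2.0 * np.sum(t1 + t2))


# ---------------------------------------------------------------------------
# The model
# ---------------------------------------------------------------------------

class GDM(BaseEstimator):
    """Generalized dissimilarity model (scikit-learn style estimator).

    Parameters
    ----------
    n_basis : int
        I-spline basis functions per predictor (knots at evenly spaced
        quantiles; 3 = min/median/max).
    max_iter : int
        L-BFGS-B iteration cap.

    Attributes (after :meth:`fit`)
    ------------------------------
    intercept_ : float           non-negative intercept alpha
    coefs_ : dict[str, ndarray]  non-negative basis coefficients per predictor
    bases_ : dict[str, ISplineBasis]
    deviance_ : float            fitted model deviance
    null_deviance_ : float
    deviance_explained_ : float  percent, 100 (D0 - D) / D0
    predictors_ : list[str]
    """

    def __init__(self, n_basis: int = 3, max_iter: int = 1000):
        self.n_basis = n_basis
        self.max_iter = max_iter

    # -- feature construction ------------------------------------------------
    def _features(self, data: GdmData, predictors, bases) -> np.ndarray:
        n = len(data.ids)
        iu, ju = np.triu_indices(n, 1)
        cols = []
        for p in predictors:
            basis = bases[p]
            if data.kind(p) == "pair":
                cols.append(basis.transform(data.pair_predictors[p][iu, ju]))
            else:
                v = data.site_predictors[p].to_numpy(dtype=float)
                t = basis.transform(v)
                cols.append(np.abs(t[iu] - t[ju]))
        if not cols:
            return np.zeros((iu.size, 0))
        return np.hstack(cols)

    def fit(self, data: GdmData, predictors: list[str] | None = None,
            bases: dict | None = None) -> "GDM":
        """Fit on all unordered pairs of ``data``.

        ``bases`` pins pre-built spline bases (used by the bootstrap so
        refits stay on the full-data knots).
        """
        predictors = list(predictors if predictors is not None else data.predictor_names)
        n = len(data.ids)
        iu, ju = np.triu_indices(n, 1)
        if iu.size < 10:
            raise ValueError("need at least 10 pairs to fit a GDM")
        y = data.dissimilarity[iu, ju]
        if bases is None:
            bases = {p: ISplineBasis(data.values(p), self.n_basis) for p in predictors}
        F = self._features(data, predictors, bases)
        A = np.hstack([np.ones((len(y), 1)), F])
        yc = np.clip(y, 0.0, 1.0 - _EPS)

        def objective(theta):
            eta = A @ theta
            mu = 1.0 - np.exp(-eta)
            mu_c = np.clip(mu, _MU_CLIP, 1.0 - _MU_CLIP)
            dev = binomial_deviance(yc, mu_c)
            # dD/deta = 2[(1 - y) - y (1 - mu)/mu]
            g = 2.0 * ((1.0 - yc) - yc * (1.0 - mu_c) / mu_c)
            return dev, A.T @ g

        bounds = [(0.0, None)] * A.shape[1]
        starts = []
        # warm start: non-negative least squares on the link scale
        eta_obs = -np.log(1.0 - yc)
        try:
            w, _ = nnls(A, eta_obs)
            starts.append(w)
        except Exception:
            pass
        cold = np.zeros(A.shape[1])
        cold[0] = max(-np.log(max(1.0 - yc.mean(), _MU_CLIP)), 0.0)
        starts.append(cold)

        best = None
        for x0 in starts:
            res = minimize(
                objective, x0, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": self.max_iter, "ftol": 1e-12, "gtol": 1e-10},
            )
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise RuntimeError(f"GDM optimizer failed: {best}")

        theta = best.x
        self.predictors_ = predictors
        self.bases_ = bases
        self.intercept_ = float(theta[0])
        self.coefs_ = {}
        k = 1
        for p in predictors:
            nb = bases[p].n_basis
            self.coefs_[p] = theta[k:k + nb].copy()
            k += nb
        self.deviance_ = float(best.fun)
        mu0 = np.full_like(yc, np.clip(yc.mean(), _MU_CLIP, 1 - _MU_CLIP))
        self.null_deviance_ = binomial_deviance(yc, mu0)
        if self.null_deviance_ > 0:
            self.deviance_explained_ = float(
                100.0 * (self.null_deviance_ - self.deviance_) / self.null_deviance_
            )
        else:
            self.deviance_explained_ = 0.0
        # numerical floor: an all-zero-beta fit explains exactly nothing
        if all(np.all(c == 0) for c in self.coefs_.values()):
            self.deviance_explained_ = max(self.deviance_explained_, 0.0)
        return self

    def predict(self, data: GdmData) -> np.ndarray:
        """Predicted dissimilarity for all unordered pairs of ``data``."""
        F = self._features(data, self.predictors_, self.bases_)
        beta = np.concatenate([self.coefs_[p] for p in self.predictors_]) if self.predictors_ else np.zeros(0)
        eta = self.intercept_ + (F @ beta if F.size else 0.0)
        return 1.0 - np.exp(-eta)

    def spline(self, predictor: str, grid: np.ndarray) -> np.ndarray:
        """Partial turnover function f_p evaluated on a grid."""
        basis = self.bases_[predictor]
        return basis.transform(grid) @ self.coefs_[predictor]

    def coefficient_sum(self, predictor: str) -> float:
        return float(np.sum(self.coefs_[predictor]))


def fit_gdm(data, predictors: list[str] | None = None, n_basis: int = 3) -> GDM:
    """Convenience wrapper: fit a GDM on a :class:`GdmData` or pair table."""
    if isinstance(data, pd.DataFrame):
        data = data_from_pair_table(data)
    return GDM(n_basis=n_basis).fit(data, predictors)


# ---------------------------------------------------------------------------
# Variable importance and backward selection
# ---------------------------------------------------------------------------

def variable_importance(
    data: GdmData,
    predictors: list[str] | None = None,
    n_perm: int = 100,
    seed: int = 0,
    n_basis: int = 3,
) -> pd.DataFrame:
    """Permutation importance of each predictor in the full model.

    Importance = mean decrease in percent deviance explained when the
    predictor's sample values are permuted (the model is refit each
    time), in percentage points, so a sole predictor's importance equals
    the model's full deviance explained; p-value = proportion of
    permutations whose deviance explained is >= the observed model's.
    """
    predictors = list(predictors if predictors is not None else data.predictor_names)
    rng = np.random.default_rng(seed)
    full = GDM(n_basis=n_basis).fit(data, predictors)
    rows = []
    n = len(data.ids)
    for p in predictors:
        drops = []
        geq = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            data_p = data.permute_predictor(p, perm)
            m = GDM(n_basis=n_basis).fit(data_p, predictors)
            drops.append(full.deviance_explained_ - m.deviance_explained_)
            if m.deviance_explained_ >= full.deviance_explained_ - 1e-12:
                geq += 1
        rows.append(
            dict(
                predictor=p,
                importance=float(np.mean(drops)),
                p_value=geq / n_perm,
                coefficient_sum=full.coefficient_sum(p),
            )
        )
    out = pd.DataFrame(rows).set_index("predictor")
    out.attrs["deviance_explained"] = full.deviance_explained_
    return out


def backward_select(
    data: GdmData,
    predictors: list[str] | None = None,
    n_perm: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    n_basis: int = 3,
) -> tuple[GDM, pd.DataFrame]:
    """Backward elimination on permutation importance.

    While any retained predictor is non-significant at ``alpha``, the
    least-important non-significant one is dropped (ties broken by
    smaller coefficient sum, then name) and the model refit.  Returns
    the final model and the last importance table.
    """
    predictors = list(predictors if predictors is not None else data.predictor_names)
    rng = np.random.default_rng(seed)
    imp = None
    while predictors:
        imp = variable_importance(
            data, predictors, n_perm=n_perm,
            seed=int(rng.integers(2**31 - 1)), n_basis=n_basis,
        )
        nonsig = imp[imp["p_value"] > alpha]
        if nonsig.empty:
            break
        victim = (
            nonsig.reset_index()
            .sort_values(["importance", "coefficient_sum", "predictor"])
            .iloc[0]["predictor"]
        )
        predictors.remove(victim)
    if not predictors:
        warnings.warn("all predictors eliminated; returning null model", stacklevel=2)
    model = GDM(n_basis=n_basis).fit(data, predictors)
    return model, imp if imp is not None else pd.DataFrame()


# ---------------------------------------------------------------------------
# Deviance partitioning
# ---------------------------------------------------------------------------

def solve_inclusion_exclusion(explained: dict[frozenset, float]) -> dict[frozenset, float]:
    """Venn-region values from deviance explained by every group subset.

    ``explained[T]`` is the deviance explained by fitting the union of
    groups in T; the returned ``v[S]`` is the deviance attributable to
    exactly the groups in S, satisfying R(T) = sum of v(S) over regions
    S that intersect T.  Negative shared components are legitimate and
    returned unchanged.
    """
    subsets = list(explained)
    A = np.zeros((len(subsets), len(subsets)))
    b = np.zeros(len(subsets))
    for r, t in enumerate(subsets):
        b[r] = explained[t]
        for c, s in enumerate(subsets):
            if s & t:
                A[r, c] = 1.0
    v = np.linalg.solve(A, b)
    return dict(zip(subsets, v))

def partition_deviance(
    data: GdmData,
    groups: dict[str, list[str]],
    n_basis: int = 3,
) -> pd.DataFrame:
    """Unique and shared deviance fractions over predictor groups.

    GDMs are fit on every non-empty subset of groups; region values of
    the Venn/Euler decomposition are recovered by solving the
    inclusion-exclusion system.  Negative shared components are reported
    as computed, never clipped.  Region fractions sum to the full
    model's deviance explained.
    """
    names = list(groups)
    if not names:
        raise ValueError("no groups given")
    for g, preds in groups.items():
        if not preds:
            raise ValueError(f"group {g!r} is empty")
    k = len(names)
    subsets = []
    for mask in range(1, 2**k):
        subsets.append(frozenset(names[i] for i in range(k) if mask >> i & 1))
    explained = {}
    for s in subsets:
        preds = sorted({p for g in s for p in groups[g]})
        try:
            explained[s] = GDM(n_basis=n_basis).fit(data, preds).deviance_explained_
        except Exception as exc:  # noqa: BLE001
            raise RuntimeError(f"subset fit failed for groups {sorted(s)}: {exc}") from exc
    regions = solve_inclusion_exclusion(explained)
    rows = [
        {"region": "&".join(sorted(s)), "n_groups": len(s), "deviance_fraction": float(val)}
        for s, val in regions.items()
    ]
    out = pd.DataFrame(rows).sort_values(["n_groups", "region"]).reset_index(drop=True)
    out.attrs["total_deviance_explained"] = explained[frozenset(names)]
    return out


# ---------------------------------------------------------------------------
# Bootstrap spline uncertainty
# ---------------------------------------------------------------------------

def bootstrap_splines(
    data: GdmData,
    model: GDM,
    withhold: float = 0.30,
    n_boot: int = 100,
    seed: int = 0,
    grid_size: int = 50,
) -> dict[str, pd.DataFrame]:
    """95% pointwise bands for each fitted spline by sample withholding.

    Each iteration refits the model (same predictors, same knots) on a
    random subset with ``withhold`` of the samples removed; bands are
    the 2.5/97.5 percentiles of the refit splines on a predictor grid.
    Errors if more than 20% of refits fail.
    """
    rng = np.random.default_rng(seed)
    n = len(data.ids)
    keep_n = max(int(round((1.0 - withhold) * n)), 3)
    grids = {}
    for p in model.predictors_:
        knots = model.bases_[p].knots
        grids[p] = np.linspace(knots[0], knots[-1], grid_size)
    curves = {p: [] for p in model.predictors_}
    failures = 0
    for _ in range(n_boot):
        idx = np.sort(rng.choice(n, size=keep_n, replace=False))
        try:
            sub = data.subset(idx)
            m = GDM(n_basis=model.n_basis).fit(sub, model.predictors_, bases=model.bases_)
        except Exception:  # noqa: BLE001
            failures += 1
            continue
        for p in model.predictors_:
            curves[p].append(m.spline(p, grids[p]))
    if failures > 0.2 * n_boot:
        raise RuntimeError(f"{failures}/{n_boot} bootstrap refits failed")
    out = {}
    for p in model.predictors_:
        arr = np.asarray(curves[p])
        out[p] = pd.DataFrame(
            {
                "grid": grids[p],
                "fit": model.spline(p, grids[p]),
                "lo": np.percentile(arr, 2.5, axis=0),
                "hi": np.percentile(arr, 97.5, axis=0),
            }
        )
    return out
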