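"""Distance-based multivariate ANOVA for nested split-plot designs.

Implements PERMANOVA on a Gower-centered distance matrix with:

* type III (marginal) sums of squares via projector differences, with
  fixed factors encoded by sum-to-zero contrasts so main effects remain
  estimable in the presence of their interactions;
* nested random factors (e.g. plot nested within site x N) whose degrees
  of freedom fall out of rank differences of the model projectors;
* pseudo-F ratios formed against the error stratum appropriate to each
  term (whole-plot fixed effects over the nested plot mean square, the
  plot term over the residual mean square);
* permutation p-values by Freedman-Lane permutation of reduced-model
  residuals, with whole-plot terms permuted at the level of their
  exchangeable units (rigid block exchange of equal-sized plots);
* omega-squared effect sizes;
* beta dispersion (distance to group spatial median in principal
  coordinate space with negative-eigenvalue correction) and its
  permutation F-test.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = [
    "Term",
    "DesignSpec",
    "mle_design",
    "lux_arbor_design",
    "one_factor_design",
    "permanova",
    "omega_squared",
    "beta_dispersion",
    "BetaDispersionResult",
]

_RANK_TOL = 1e-9


# ---------------------------------------------------------------------------
# Design specification
# ---------------------------------------------------------------------------

@dataclass
class Term:
    """One model term.

    Parameters
    ----------
    name : str
    columns : list of str
        Metadata columns whose combination defines the factor levels.
        Interactions list all parent columns.
    denominator : str
        Name of the term providing the error mean square, or "residual".
    random : bool
        Random (nested) terms are encoded as raw cell dummies and
        adjusted for all fixed terms; fixed terms use sum-to-zero
        contrasts and marginal (type III) adjustment against each other.
    permute_blocks : list of str or None
        Columns defining the exchangeable units for this term's
        permutation test.  Whole blocks are exchanged rigidly; ``None``
        means free permutation of samples.
    """

    name: str
    columns: list[str]
    denominator: str = "residual"
    random: bool = False
    permute_blocks: list[str] | None = None


@dataclass
class DesignSpec:
    terms: list[Term] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [t.name for t in self.terms]
        if len(set(names)) != len(names):
            raise ValueError("duplicate term names in design")
        for t in self.terms:
            if t.denominator != "residual" and t.denominator not in names:
                raise ValueError(
                    f"term {t.name!r} uses unknown denominator {t.denominator!r}"
                )

    @property
    def fixed_terms(self) -> list[Term]:
        return [t for t in self.terms if not t.random]

    @property
    def random_terms(self) -> list[Term]:
        return [t for t in self.terms if t.random]


def mle_design() -> DesignSpec:
    """Regional design: site, N addition, their interaction, plot(site x N).

    Whole-plot fixed effects are tested over the plot-within-site-x-N mean
    square with plot-level restricted permutations; the plot term is
    tested over the residual.
    """
    blocks = ["plot", "n_treatment"]
    return DesignSpec(
        terms=[
            Term("Site", ["site"], denominator="Plot(Site*N)", permute_blocks=blocks),
            Term("N add", ["n_treatment"], denominator="Plot(Site*N)", permute_blocks=blocks),
            Term("Site*N add", ["site", "n_treatment"], denominator="Plot(Site*N)", permute_blocks=blocks),
            Term("Plot(Site*N)", ["plot", "n_treatment"], denominator="residual", random=True),
        ]
    )


def lux_arbor_design() -> DesignSpec:
    """Growing-season design: collection date, N addition, interaction, plot(N)."""
    blocks = ["plot", "n_treatment"]
    return DesignSpec(
        terms=[
            Term("Collection Date", ["collection_date"], denominator="Plot(Date*N)", permute_blocks=blocks),
            Term("N add", ["n_treatment"], denominator="Plot(Date*N)", permute_blocks=blocks),
            Term("Date*N add", ["collection_date", "n_treatment"], denominator="Plot(Date*N)", permute_blocks=blocks),
            Term("Plot(Date*N)", ["plot", "n_treatment"], denominator="residual", random=True),
        ]
    )


def one_factor_design(column: str, name: str | None = None) -> DesignSpec:
    return DesignSpec(terms=[Term(name or column, [column])])


# ---------------------------------------------------------------------------
# Encoding and projectors
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    """Gower-centered inner product matrix G = -1/2 J D2 J."""
    a = -0.5 * d**2
    n = a.shape[0]
    row = a.mean(axis=1, keepdims=True)
    col = a.mean(axis=0, keepdims=True)
    return a - row - col + a.mean()


def _sum_to_zero(levels: pd.Series) -> np.ndarray:
    """Sum-to-zero contrast columns for a factor (k levels -> k-1 columns)."""
    cats = sorted(pd.unique(levels), key=str)
    k = len(cats)
    if k < 2:
        return np.zeros((len(levels), 0))
    idx = {c: i for i, c in enumerate(cats)}
    out = np.zeros((len(levels), k - 1))
    for r, v in enumerate(levels):
        i = idx[v]
        if i < k - 1:
            out[r, i] = 1.0
        else:
            out[r, :] = -1.0
    return out


def _interaction(cols: list[np.ndarray]) -> np.ndarray:
    out = cols[0]
    for c in cols[1:]:
        out = np.einsum("ij,ik->ijk", out, c).reshape(len(out), -1)
    return out


def _encode_term(term: Term, meta: pd.DataFrame) -> np.ndarray:
    if term.random:
        combo = meta[term.columns].astype(str).agg("|".join, axis=1)
        cats = sorted(pd.unique(combo))
        idx = {c: i for i, c in enumerate(cats)}
        out = np.zeros((len(meta), len(cats)))
        for r, v in enumerate(combo):
            out[r, idx[v]] = 1.0
        return out
    mats = [_sum_to_zero(meta[c].astype(str)) for c in term.columns]
    if len(mats) == 1:
        return mats[0]
    return _interaction(mats)


def _projector(X: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(X) and its rank."""
    if X.shape[1] == 0:
        return np.zeros((X.shape[0], X.shape[0])), 0
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    r = int(np.sum(s > _RANK_TOL * max(X.shape) * (s[0] if len(s) else 1.0)))
    ur = u[:, :r]
    return ur @ ur.T, r


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def permanova(
    dm: DistanceMatrix,
    meta: pd.DataFrame,
    design: DesignSpec,
    n_perm: int = 999,
    seed: int = 0,
    enumerate_all: bool = False,
) -> pd.DataFrame:
    """Nested split-plot PERMANOVA table.

    Parameters
    ----------
    dm : skbio.DistanceMatrix
    meta : DataFrame indexed by sample_id covering all dm ids.
    design : DesignSpec
    n_perm : int
        Monte-Carlo permutations; p = (b + 1) / (n_perm + 1).  ``0``
        skips the permutation test (p-values NaN).
    enumerate_all : bool
        Enumerate all n! sample relabelings instead of sampling
        (free-permutation terms only; small n).  p = b_all / n!.

    Returns
    -------
    DataFrame with rows per term plus "Residual" and "Total", columns
    ``df, SS, MS, pseudo_F, R2, omega2, p_perm``.
    """
    ids = list(dm.ids)
    missing = [s for s in ids if s not in meta.index]
    if missing:
        raise ValueError(f"samples missing from metadata: {missing}")
    meta = meta.loc[ids]
    n = len(ids)
    G = _gower_center(dm.data)
    ss_total = float(np.trace(G))
    rng = np.random.default_rng(seed)

    ones = np.ones((n, 1))
    fixed = design.fixed_terms
    random = design.random_terms
    enc = {t.name: _encode_term(t, meta) for t in design.terms}

    X_fixed = np.hstack([ones] + [enc[t.name] for t in fixed])
    H_fixed, r_fixed = _projector(X_fixed)
    X_all = np.hstack([X_fixed] + [enc[t.name] for t in random])
    H_all, r_all = _projector(X_all)

    # marginal (type III) projectors: full fixed model minus one fixed term
    H_drop: dict[str, tuple[np.ndarray, int]] = {}
    for t in fixed:
        X_r = np.hstack([ones] + [enc[u.name] for u in fixed if u.name != t.name])
        H_drop[t.name] = _projector(X_r)
    # random terms adjusted for the fixed model (plus preceding random terms)
    prev = [X_fixed]
    H_before_random: dict[str, tuple[np.ndarray, int]] = {}
    H_with_random: dict[str, tuple[np.ndarray, int]] = {}
    for t in random:
        Xb = np.hstack(prev)
        H_before_random[t.name] = _projector(Xb)
        prev.append(enc[t.name])
        H_with_random[t.name] = _projector(np.hstack(prev))

    def term_ss(g: np.ndarray) -> dict[str, float]:
        trf = float(np.einsum("ij,ji->", H_fixed, g))
        out = {}
        for t in fixed:
            Hd, _ = H_drop[t.name]
            out[t.name] = trf - float(np.einsum("ij,ji->", Hd, g))
        for t in random:
            Hb, _ = H_before_random[t.name]
            Hw, _ = H_with_random[t.name]
            out[t.name] = float(np.einsum("ij,ji->", Hw - Hb, g))
        out["residual"] = float(np.trace(g)) - float(np.einsum("ij,ji->", H_all, g))
        return out

    # degrees of freedom by rank differences
    df = {}
    for t in fixed:
        _, r_drop = H_drop[t.name]
        df[t.name] = r_fixed - r_drop
        if df[t.name] == 0:
            raise ValueError(
                f"term {t.name!r} is completely aliased with the other terms "
                "(singular design)"
            )
    for t in random:
        df[t.name] = H_with_random[t.name][1] - H_before_random[t.name][1]
        if df[t.name] == 0:
            raise ValueError(f"random term {t.name!r} contributes no degrees of freedom")
    df["residual"] = n - r_all
    if df["residual"] <= 0:
        raise ValueError("saturated design: no residual degrees of freedom")

    obs = term_ss(G)

    def f_stat(ss: dict[str, float], term: Term) -> float:
        num = ss[term.name] / df[term.name]
        den = ss[term.denominator] / df[term.denominator]
        return num / den if den > 0 else np.nan

    table_rows = {}
    for t in design.terms:
        ss, d = obs[t.name], df[t.name]
        ms = ss / d
        den_ms = obs[t.denominator] / df[t.denominator]
        f = f_stat(obs, t)
        r2 = ss / ss_total
        om2 = omega_squared(ss, d, den_ms, ss_total)
        table_rows[t.name] = dict(df=d, SS=ss, MS=ms, pseudo_F=f, R2=r2, omega2=om2)

    # permutation p-values: Freedman-Lane residual permutation per term
    pvals = {t.name: np.nan for t in design.terms}
    if n_perm > 0 or enumerate_all:
        for t in design.terms:
            # Reduced model: the other fixed terms.  Random terms are left
            # out so the error-stratum variation survives residualization
            # (it forms the permutation-distribution denominator).
            X_r = np.hstack(
                [ones] + [enc[u.name] for u in fixed if u.name != t.name]
            )
            H_r, _ = _projector(X_r)
            R = np.eye(n) - H_r
            G_res = R @ G @ R
            f_obs = f_stat(obs, t)
            perms = _permutation_indices(
                meta, t.permute_blocks, n_perm, rng, enumerate_all
            )
            exceed = 0
            total = 0
            for p in perms:
                gp = G_res[np.ix_(p, p)]
                f_p = f_stat(term_ss(gp), t)
                if np.isnan(f_p):
                    continue
                total += 1
                if f_p >= f_obs - 1e-12:
                    exceed += 1
            if enumerate_all:
                pvals[t.name] = exceed / total
            else:
                pvals[t.name] = (exceed + 1) / (total + 1)

    rows = []
    for t in design.terms:
        r = table_rows[t.name]
        rows.append(
            dict(term=t.name, p_perm=pvals[t.name], **r)
        )
    rows.append(
        dict(
            term="Residual", df=df["residual"], SS=obs["residual"],
            MS=obs["residual"] / df["residual"], pseudo_F=np.nan, R2=obs["residual"] / ss_total,
            omega2=np.nan, p_perm=np.nan,
        )
    )
    rows.append(
        dict(term="Total", df=n - 1, SS=ss_total, MS=np.nan, pseudo_F=np.nan,
             R2=1.0, omega2=np.nan, p_perm=np.nan)
    )
    out = pd.DataFrame(rows).set_index("term")
    return out[["df", "SS", "MS", "pseudo_F", "R2", "omega2", "p_perm"]]


def _permutation_indices(meta, block_cols, n_perm, rng, enumerate_all):
    n = len(meta)
    if enumerate_all:
        if block_cols is not None:
            raise ValueError("exhaustive enumeration supported for free permutation only")
        return (np.array(p) for p in itertools.permutations(range(n)))
    if block_cols is None:
        return (rng.permutation(n) for _ in range(n_perm))
    combo = meta[block_cols].astype(str).agg("|".join, axis=1).to_numpy()
    blocks = [np.nonzero(combo == c)[0] for c in pd.unique(combo)]
    sizes = {len(b) for b in blocks}
    if len(sizes) > 1:
        warnings.warn(
            "unequal permutation-block sizes; falling back to free permutation",
            stacklevel=2,
        )
        return (rng.permutation(n) for _ in range(n_perm))

    def gen():
        for _ in range(n_perm):
            order = rng.permutation(len(blocks))
            p = np.empty(n, dtype=int)
            for slot, src in zip(blocks, (blocks[o] for o in order)):
                p[slot] = src
            yield p

    return gen()


def omega_squared(ss_effect: float, df_effect: int, ms_denom: float, ss_total: float) -> float:
    """Bias-adjusted effect size for a distance-based ANOVA term.

    omega^2 = (SS_effect - df_effect * MS_denom) / (SS_total + MS_denom).
    May be negative (reported as computed).
    """
    if df_effect <= 0:
        raise ValueError("df_effect must be positive")
    denom = ss_total + ms_denom
    if denom <= 0:
        raise ValueError("SS_total + MS_denom must be positive")
    return (ss_effect - df_effect * ms_denom) / denom


# ---------------------------------------------------------------------------
# Beta dispersion
# ---------------------------------------------------------------------------

@dataclass
class BetaDispersionResult:
    distances: pd.Series           # per-sample distance to group spatial median
    group_means: pd.Series
    f_stat: float
    p_perm: float
    excluded: list[str]            # groups of size 1 (excluded with warning)


def _geometric_median(points: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    """Weiszfeld iteration for the spatial median."""
    if points.shape[0] == 1 or points.shape[1] == 0:
        return points.mean(axis=0)
    y = points.mean(axis=0)
    for _ in range(max_iter):
        d = np.linalg.norm(points - y, axis=1)
        at_point = d < 1e-12
        if at_point.any():
            d = np.where(at_point, 1e-12, d)
        w = 1.0 / d
        y_new = (points * w[:, None]).sum(axis=0) / w.sum()
        if np.linalg.norm(y_new - y) < tol:
            return y_new
        y = y_new
    return y


def beta_dispersion(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> BetaDispersionResult:
    """Per-sample distance to the group spatial median, with permutation F-test.

    Samples are embedded by principal coordinates of the Gower matrix;
    axes with negative eigenvalues contribute *imaginary* coordinates
    whose squared distances are subtracted (negatives truncated at 0).
    The group centre is the spatial median, computed separately on the
    real and imaginary subspaces.
    """
    ids = list(dm.ids)
    groups = groups.loc[ids]
    counts = groups.value_counts()
    excluded = [g for g, c in counts.items() if c < 2]
    if len(counts) - len(excluded) < 2:
        raise ValueError("need at least 2 groups with at least 2 members")
    if excluded:
        warnings.warn(f"groups of size 1 excluded: {excluded}", stacklevel=2)
        keep = ~groups.isin(excluded)
        dm = dm.filter([s for s, k in zip(ids, keep) if k])
        ids = list(dm.ids)
        groups = groups.loc[ids]

    G = _gower_center(dm.data)
    eigval, eigvec = np.linalg.eigh((G + G.T) / 2)
    scale = max(abs(eigval).max(), 1.0)
    pos = eigval > 1e-10 * scale
    neg = eigval < -1e-10 * scale
    real = eigvec[:, pos] * np.sqrt(eigval[pos])
    imag = eigvec[:, neg] * np.sqrt(-eigval[neg])

    dist = np.empty(len(ids))
    for g in pd.unique(groups):
        m = (groups == g).to_numpy()
        med_r = _geometric_median(real[m])
        med_i = _geometric_median(imag[m]) if imag.shape[1] else np.zeros(0)
        d2 = np.sum((real[m] - med_r) ** 2, axis=1)
        if imag.shape[1]:
            d2 = d2 - np.sum((imag[m] - med_i) ** 2, axis=1)
        clipped = d2 < 0
        if clipped.any():
            warnings.warn(
                f"{int(clipped.sum())} squared distances truncated at 0 "
                "(negative-eigenvalue correction)",
                stacklevel=2,
            )
        dist[m] = np.sqrt(np.clip(d2, 0.0, None))

    labels = groups.to_numpy()

    def anova_f(d: np.ndarray) -> float:
        grand = d.mean()
        ss_b = 0.0
        ss_w = 0.0
        k = 0
        for g in pd.unique(labels):
            m = labels == g
            k += 1
            ss_b += m.sum() * (d[m].mean() - grand) ** 2
            ss_w += np.sum((d[m] - d[m].mean()) ** 2)
        df_b, df_w = k - 1, len(d) - k
        if ss_w <= 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / df_b) / (ss_w / df_w)

    f_obs = anova_f(dist)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if anova_f(dist[rng.permutation(len(dist))]) >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1) if n_perm > 0 else np.nan

    dist_s = pd.Series(dist, index=ids, name="dispersion")
    means = dist_s.groupby(groups).mean()
    return BetaDispersionResult(dist_s, means, f_obs, p, excluded)
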