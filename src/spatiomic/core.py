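"""Core-microbiome selection and neutral community model fitting.

The persistent "core" community is the prefix of an abundance-occupancy
ranking of taxa whose members contribute materially to between-sample
Bray-Curtis dissimilarity:

1. taxa are ranked by the mean of (i) their mean per-group occupancy
   (groups = sites or collection dates) and (ii) their replicate
   consistency (the share of groups in which they appear in every
   replicate), ties broken by mean relative abundance then taxon id;
2. the cumulative contribution of the top-i taxa to mean pairwise
   Bray-Curtis is computed with the full-table denominator fixed, so
   contributions are additive and the curve is monotone, reaching 1 at
   full richness;
3. the core is the ranking prefix up to the *last* rank whose inclusion
   increased the curve by at least 5% relative to the previous value.

The Sloan neutral model predicts a taxon's occupancy from its mean
relative abundance p under drift plus immigration at rate m in
communities of N reads:

    occupancy(p) = 1 - BetaCDF(1/N; N m p, N m (1 - p))

m is fit by least squares over taxa; taxa are classified above / within
/ below the 95% (Wilson) band around the prediction.

The module also computes root-vs-soil differential family abundances
(log2 ratio of median proportions, Wilcoxon rank-sum, BH FDR) and
collapses multi-guild fungal annotations into grouped guild labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .community import OtuTable

__all__ = [
    "occupancy_abundance",
    "rank_taxa",
    "bc_contribution_curve",
    "select_core",
    "CoreResult",
    "SloanNeutralModel",
    "fit_neutral",
    "threshold_scan",
    "differential_family_abundance",
    "group_guilds",
]


# ---------------------------------------------------------------------------
# Occupancy-abundance statistics and ranking
# ---------------------------------------------------------------------------

def occupancy_abundance(
    table: OtuTable,
    meta: pd.DataFrame,
    group_by: str,
    replicate_by: list[str] | None = None,
) -> pd.DataFrame:
    """Per-taxon occupancy and abundance statistics.

    Parameters
    ----------
    group_by : str
        Metadata column defining groups (``site`` or ``collection_date``).
    replicate_by : list of str, optional
        Columns defining replicate cells within groups (default: the
        group itself, i.e. consistency = detected in every sample of a
        group).

    Returns
    -------
    DataFrame indexed by taxon_id with columns ``occupancy``,
    ``mean_rel_abund``, ``mean_group_occupancy``,
    ``replicate_consistency`` and per-group occupancy columns
    ``occ@<group>``.
    """
    meta = meta.loc[table.sample_ids]
    groups = meta[group_by]
    if groups.isna().any():
        raise ValueError(f"missing values in grouping column {group_by!r}")
    present = table.counts > 0
    rel = table.relative_abundance()
    out = pd.DataFrame(index=pd.Index(table.taxon_ids, name="taxon_id"))
    out["occupancy"] = present.mean(axis=0)
    out["mean_rel_abund"] = rel.mean(axis=0)
    group_occ = {}
    for g in pd.unique(groups):
        m = (groups == g).to_numpy()
        if m.sum() == 0:
            raise ValueError(f"empty group {g!r}")
        group_occ[g] = present[m].mean(axis=0)
        out[f"occ@{g}"] = group_occ[g]
    out["mean_group_occupancy"] = np.mean(list(group_occ.values()), axis=0)
    # replicate consistency: share of groups where detected in all replicates
    full = np.zeros((len(pd.unique(groups)), table.n_taxa), dtype=bool)
    for k, g in enumerate(pd.unique(groups)):
        m = (groups == g).to_numpy()
        full[k] = present[m].all(axis=0)
    out["replicate_consistency"] = full.mean(axis=0)
    return out


def rank_taxa(stats_df: pd.DataFrame) -> pd.DataFrame:
    """Rank taxa by the abundance-occupancy index.

    rank_index = mean(mean per-group occupancy, replicate consistency),
    descending; ties broken by mean relative abundance (descending),
    then taxon id (ascending).  The returned frame is sorted with a
    ``rank`` column (1 = first).
    """
    if stats_df.empty:
        raise ValueError("empty occupancy-abundance table")
    out = stats_df.copy()
    out["rank_index"] = (out["mean_group_occupancy"] + out["replicate_consistency"]) / 2.0
    out = (
        out.reset_index()
        .sort_values(
            ["rank_index", "mean_rel_abund", "taxon_id"],
            ascending=[False, False, True],
            kind="stable",
        )
        .set_index("taxon_id")
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# Bray-Curtis contribution curve and core selection
# ---------------------------------------------------------------------------

@dataclass
class CoreResult:
    ranking: list[str]
    bc_contribution: np.ndarray     # cumulative fraction of mean BC, per prefix
    threshold_index: int | None = None
    core_taxa: list[str] = field(default_factory=list)
    richness_share: float | None = None   # core taxa / all taxa
    read_share: float | None = None       # core reads / all reads


def bc_contribution_curve(table: OtuTable, ranking: list[str]) -> CoreResult:
    """Cumulative Bray-Curtis contribution of ranked taxon prefixes.

    The partial Bray-Curtis of a prefix keeps the *full-table*
    denominator sum(x_i + x_j), so per-taxon contributions accumulate to
    the complete Bray-Curtis and the curve is monotone non-decreasing,
    reaching exactly 1 at full richness.
    """
    if set(ranking) != set(table.taxon_ids):
        raise ValueError("ranking must cover exactly the table's taxa")
    x = table.counts.astype(float)
    n = table.n_samples
    iu, ju = np.triu_indices(n, 1)
    denom = x.sum(axis=1)[iu] + x.sum(axis=1)[ju]
    if np.any(denom == 0):
        raise ValueError("pair of all-zero samples")
    idx = {t: k for k, t in enumerate(table.taxon_ids)}
    numer = np.zeros(len(iu))
    mean_partial = np.empty(len(ranking))
    for r, t in enumerate(ranking):
        col = x[:, idx[t]]
        numer += np.abs(col[iu] - col[ju])
        mean_partial[r] = np.mean(numer / denom)
    full = mean_partial[-1]
    if full == 0:
        raise ValueError("all samples identical: mean Bray-Curtis is zero")
    return CoreResult(list(ranking), mean_partial / full)


def select_core(
    curve: CoreResult,
    table: OtuTable,
    threshold: float = 0.05,
    mode: str = "relative",
) -> CoreResult:
    """Apply the "last 5% increase" rule to the contribution curve.

    The threshold index is the largest prefix size i >= 2 whose
    inclusion increased the curve by at least ``threshold``
    (``mode="relative"``: (c_i - c_{i-1}) / c_{i-1}; ``mode="absolute"``:
    c_i - c_{i-1}).  The core is the ranking prefix up to that index;
    a single-taxon core (with a warning) if no step qualifies.
    """
    c = curve.bc_contribution
    if mode == "relative":
        steps = np.where(c[:-1] > 0, np.diff(c) / c[:-1], np.inf)
    elif mode == "absolute":
        steps = np.diff(c)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    qualifying = np.nonzero(steps >= threshold)[0]
    if qualifying.size:
        thr_idx = int(qualifying[-1]) + 2  # prefix size (1-based rank)
    else:
        warnings.warn("no step meets the threshold; core = first-ranked taxon", stacklevel=2)
        thr_idx = 1
    core = curve.ranking[:thr_idx]
    core_set = set(core)
    cols = [k for k, t in enumerate(table.taxon_ids) if t in core_set]
    read_share = float(table.counts[:, cols].sum() / table.counts.sum())
    return CoreResult(
        ranking=curve.ranking,
        bc_contribution=curve.bc_contribution,
        threshold_index=thr_idx,
        core_taxa=core,
        richness_share=thr_idx / len(curve.ranking),
        read_share=read_share,
    )


# ---------------------------------------------------------------------------
# Sloan neutral model
# ---------------------------------------------------------------------------

class SloanNeutralModel:
    """Neutral community model: occupancy from mean relative abundance.

    Parameters
    ----------
    N : int
        Community size in reads per sample (the rarefaction depth).

    Attributes (after :meth:`fit`)
    ------------------------------
    m_ : float            migration probability in (0, 1]
    r2_ : float           1 - SSE/SST of occupancy predictions
    table_ : DataFrame    per-taxon observed/predicted occupancy, Wilson
                          95% CI, and class in {below, neutral, above}
    converged_ : bool
    """

    def __init__(self, N: int = 10_000):
        self.N = N

    def predict_occupancy(self, mean_rel_abund, m: float | None = None) -> np.ndarray:
        p = np.asarray(mean_rel_abund, dtype=float)
        m = self.m_ if m is None else m
        d = 1.0 / self.N
        a = self.N * m * p
        b = self.N * m * (1.0 - p)
        return 1.0 - stats.beta.cdf(d, np.maximum(a, 1e-12), np.maximum(b, 1e-12))

    def fit(self, mean_rel_abund, occupancy, n_samples: int) -> "SloanNeutralModel":
        p = np.asarray(mean_rel_abund, dtype=float)
        occ = np.asarray(occupancy, dtype=float)
        if p.size < 10:
            raise ValueError("need at least 10 taxa to fit the neutral model")

        def sse(m):
            return float(np.sum((occ - self.predict_occupancy(p, m)) ** 2))

        res = minimize_scalar(sse, bounds=(1e-6, 1.0), method="bounded",
                              options={"xatol": 1e-10})
        m = float(res.x)
        if not (0.0 < m <= 1.0) or not np.isfinite(res.fun):
            raise RuntimeError("neutral-model optimizer left (0, 1]")
        self.m_ = m
        pred = self.predict_occupancy(p)
        sst = float(np.sum((occ - occ.mean()) ** 2))
        if sst <= 0:
            self.r2_ = np.nan
            warnings.warn("degenerate occupancy variance; R^2 undefined", stacklevel=2)
        else:
            self.r2_ = 1.0 - float(res.fun) / sst
        self.converged_ = True
        from statsmodels.stats.proportion import proportion_confint

        lo, hi = proportion_confint(
            np.round(pred * n_samples), n_samples, alpha=0.05, method="wilson"
        )
        cls = np.where(occ > hi, "above", np.where(occ < lo, "below", "neutral"))
        self.table_ = pd.DataFrame(
            {
                "mean_rel_abund": p,
                "occupancy": occ,
                "predicted_occupancy": pred,
                "ci_lo": lo,
                "ci_hi": hi,
                "neutral_class": cls,
            }
        )
        return self

    @property
    def failed_(self) -> bool:
        """The fit is reported as a failure when R^2 <= 0 or undefined."""
        return (not getattr(self, "converged_", False)) or not np.isfinite(self.r2_) or self.r2_ <= 0


def fit_neutral(stats_df: pd.DataFrame, N: int = 10_000, n_samples: int | None = None) -> SloanNeutralModel:
    """Fit the Sloan model to an occupancy-abundance table."""
    if n_samples is None:
        raise ValueError("n_samples (realized sample count) is required")
    model = SloanNeutralModel(N=N).fit(
        stats_df["mean_rel_abund"].to_numpy(),
        stats_df["occupancy"].to_numpy(),
        n_samples,
    )
    model.table_.index = stats_df.index
    return model


def threshold_scan(
    table: OtuTable,
    curve: CoreResult,
    stats_df: pd.DataFrame,
    thresholds=np.round(np.arange(0.01, 0.21, 0.01), 2),
    N: int = 10_000,
) -> pd.DataFrame:
    """Core size, read share, and neutral-model fit across BC thresholds.

    Exports the information used to choose the Bray-Curtis step
    threshold; the choice itself stays in configuration.
    """
    rows = []
    n_samples = table.n_samples
    for thr in thresholds:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = select_core(curve, table, threshold=float(thr))
            core = set(res.core_taxa)
            sub = stats_df.loc[[t for t in stats_df.index if t in core]]
            r2 = np.nan
            if len(sub) >= 10:
                try:
                    r2 = fit_neutral(sub, N=N, n_samples=n_samples).r2_
                except RuntimeError:
                    pass
        rows.append(
            dict(
                threshold=float(thr),
                core_richness=len(core),
                richness_share=res.richness_share,
                read_share=res.read_share,
                neutral_r2=r2,
            )
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Differential family abundance
# ---------------------------------------------------------------------------

def differential_family_abundance(
    root: OtuTable,
    soil: OtuTable,
    annotations: pd.DataFrame,
    family_column: str = "family",
    pseudo_n: int = 10_000,
) -> pd.DataFrame:
    """Root-vs-soil differential abundance per family.

    For each family with at least one annotated taxon: per-sample summed
    proportions in each niche, log2 ratio of the niche medians (a
    pseudo-proportion of 1/(2*pseudo_n) is added to both medians when
    either is zero, flagged in the output), a two-sided Wilcoxon
    rank-sum test across samples, and Benjamini-Hochberg FDR.
    """
    fam = annotations[family_column].dropna()
    rows = []
    for family in sorted(pd.unique(fam)):
        taxa = set(fam.index[fam == family])
        r_cols = [k for k, t in enumerate(root.taxon_ids) if t in taxa]
        s_cols = [k for k, t in enumerate(soil.taxon_ids) if t in taxa]
        r_prop = root.relative_abundance()[:, r_cols].sum(axis=1) if r_cols else np.zeros(root.n_samples)
        s_prop = soil.relative_abundance()[:, s_cols].sum(axis=1) if s_cols else np.zeros(soil.n_samples)
        if r_prop.sum() == 0 and s_prop.sum() == 0:
            continue  # family absent from both niches
        med_r, med_s = float(np.median(r_prop)), float(np.median(s_prop))
        pseudo = med_r == 0 or med_s == 0
        eps = 1.0 / (2 * pseudo_n)
        if pseudo:
            med_r, med_s = med_r + eps, med_s + eps
        log2_ratio = float(np.log2(med_r / med_s))
        if np.all(r_prop == r_prop[0]) and np.all(s_prop == s_prop[0]) and r_prop[0] == s_prop[0]:
            pval = 1.0
        else:
            method = "exact" if max(len(r_prop), len(s_prop)) <= 25 else "asymptotic"
            pval = float(
                stats.mannwhitneyu(r_prop, s_prop, alternative="two-sided", method=method).pvalue
            )
        rows.append(
            dict(
                family=family,
                n_taxa=len(taxa),
                median_root=float(np.median(root.relative_abundance()[:, r_cols].sum(axis=1)) if r_cols else 0.0),
                median_soil=float(np.median(soil.relative_abundance()[:, s_cols].sum(axis=1)) if s_cols else 0.0),
                log2_ratio=log2_ratio,
                pseudo_count_used=pseudo,
                p_value=pval,
            )
        )
    out = pd.DataFrame(rows)
    if not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out.set_index("family") if not out.empty else out


# ---------------------------------------------------------------------------
# Guild grouping
# ---------------------------------------------------------------------------

_ACCEPTED_CONFIDENCE = {"probable", "highly probable"}


def group_guilds(
    annotations: pd.DataFrame,
    guild_map: pd.DataFrame,
    guild_column: str = "guild_label",
    confidence_column: str = "guild_confidence",
) -> pd.DataFrame:
    """Collapse multi-guild labels to grouped categories.

    ``guild_map`` maps raw guild labels to grouped ones (symbiotroph /
    pathogen / saprotroph style categories).  Classifications below
    "Probable" confidence are dropped (guild cleared); empty guilds
    become "unknown"; unmapped multi-guild labels are retained verbatim
    with a warning.
    """
    mapping = dict(zip(guild_map["guild_label"], guild_map["guild_group"]))
    out = annotations.copy()
    groups = []
    unmapped = set()
    for _, row in out.iterrows():
        label = row.get(guild_column)
        conf = str(row.get(confidence_column, "")).strip().lower()
        if label is None or (isinstance(label, float) and np.isnan(label)) or str(label).strip() == "":
            groups.append("unknown")
            continue
        if conf and conf not in _ACCEPTED_CONFIDENCE:
            groups.append("unknown")
            continue
        label = str(label)
        if label in mapping:
            groups.append(mapping[label])
        elif "-" in label or "," in label:
            unmapped.add(label)
            groups.append(label)
        else:
            groups.append(label)
    if unmapped:
        warnings.warn(f"unmapped multi-guild labels kept verbatim: {sorted(unmapped)}", stacklevel=2)
    out["guild_group"] = groups
    return out
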