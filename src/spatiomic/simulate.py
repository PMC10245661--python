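"""Synthetic community generator emulating the field study's design.

Two sampling scaffolds are supported:

* ``mle`` — the regional design: 5 sites, 4 plots each (one site with 3,
  its first block decommissioned), 2 N-treatment subplots per plot,
  3 cores per subplot, one July collection date, for both niches
  (root and soil): 114 samples per niche.
* ``lux_arbor`` — the single-site growing season: 4 plots x 2 subplots
  x 3 cores per collection date (24 samples per niche per date), with
  15 biweekly soil dates and 6 root dates placed on every second soil
  date so each root date has a soil collection exactly 14 days earlier.

Communities are generated from a log-normal baseline abundance pool.
Taxa are partitioned into:

* *core* taxa — high baseline abundance, present in every sample;
* *neutral* taxa — per-sample relative abundances drawn from the Sloan
  process (Beta(N m p, N m (1-p)) for a community of N reads with
  migration rate m), then binomial read counts;
* *structured* taxa — multiplicative log-scale effects: per-site
  offsets ~ Normal(0, site_sigma^2), smooth seasonal curves scaled by
  date_amplitude, a spatially autocorrelated Gaussian field with
  exponential covariance of range spatial_range, and an N-addition
  shift on a random 10% of taxa.

Root samples are a convex mixture of the realized soil community of the
same subplot lagged by ``root_lag_days`` (weight 0.7) and root-specific
taxa (weight 0.3), so a two-week lead of soil over root composition is
present by construction when the lag is on.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .community import OtuTable

__all__ = ["SimulationConfig", "GroundTruth", "simulate_design", "simulate_community"]

_MLE_PLOTS = {"S1": 4, "S2": 4, "S3": 3, "S4": 4, "S5": 4}
_PLOT_SIZE = 19.5  # m, square plot edge
_SITE_SPACING = 50_000.0  # m between site origins
_PLOT_SPACING = 50.0  # m between plot origins within a site


@dataclass
class SimulationConfig:
    """Study-design and effect-size parameters for the generator.

    Effect sizes are on the natural-log abundance scale; fractions
    partition the taxon pool and must sum to at most 1.
    """

    design: str = "mle"            # {"mle", "lux_arbor"}
    depth: int = 10_000            # reads per sample (rarefaction depth)
    n_taxa: int = 400
    site_sigma: float = 1.0        # sd of per-site log-abundance offsets
    date_amplitude: float = 0.5    # seasonal log-abundance amplitude
    spatial_range: float = 50.0    # m, exponential covariance range
    spatial_sigma: float = 0.5     # sd of the spatial log-abundance field
    n_effect: float = 0.2          # log-abundance shift under N addition
    n_effect_taxa_fraction: float = 0.10
    core_fraction: float = 0.05
    core_abundance_boost: float = 20.0
    neutral_fraction: float = 0.30
    m: float = 0.1                 # Sloan migration rate for neutral taxa
    root_lag_days: int = 14
    root_soil_weight: float = 0.7  # lagged-soil weight in the root mixture
    seed: int = 0

    def __post_init__(self) -> None:
        if self.design not in ("mle", "lux_arbor"):
            raise ValueError(f"unknown design {self.design!r}")
        if not (0 <= self.core_fraction <= 1 and 0 <= self.neutral_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if self.core_fraction + self.neutral_fraction > 1:
            raise ValueError("core_fraction + neutral_fraction must be <= 1")
        for name in ("site_sigma", "date_amplitude", "spatial_range",
                     "spatial_sigma", "n_effect"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0 < self.m <= 1):
            raise ValueError("m must be in (0, 1]")


@dataclass
class GroundTruth:
    membership: pd.Series        # taxon -> {"core", "neutral", "structured"}
    m: float
    n_effect_taxa: list[str]
    site_offsets: pd.DataFrame | None = None
    seasonal_phase: pd.Series | None = None
    config: SimulationConfig | None = None


def _soil_dates() -> list[_dt.date]:
    start = _dt.date(2018, 3, 19)
    return [start + _dt.timedelta(days=14 * k) for k in range(15)]


def _root_dates() -> list[_dt.date]:
    dates = _soil_dates()
    return [dates[k] for k in range(4, 15, 2)]


def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata scaffold for the configured design (both niches)."""
    rng = np.random.default_rng(config.seed)
    rows = []
    if config.design == "mle":
        sites = list(_MLE_PLOTS)
        date = _dt.date(2018, 7, 30)
        niche_dates = {"soil": [date], "root": [date]}
    else:
        sites = ["LUX"]
        niche_dates = {"soil": _soil_dates(), "root": _root_dates()}

    # fixed core sampling points per subplot, shared between dates and niches
    # (roots taken adjacent to the soil core, as in the field protocol)
    points: dict[tuple, np.ndarray] = {}
    for si, site in enumerate(sites):
        n_plots = _MLE_PLOTS[site] if config.design == "mle" else 4
        for p in range(1, n_plots + 1):
            origin = np.array([si * _SITE_SPACING + (p - 1) * _PLOT_SPACING, si * _SITE_SPACING])
            for trt_i, trt in enumerate(("control", "N")):
                # N and control split-plots are the two halves of the plot
                half = np.array([trt_i * _PLOT_SIZE / 2, 0.0])
                xy = origin + half + rng.uniform(
                    [0, 0], [_PLOT_SIZE / 2, _PLOT_SIZE], size=(3, 2)
                )
                points[(site, p, trt)] = xy

    for niche, dates in niche_dates.items():
        for site in sites:
            n_plots = _MLE_PLOTS[site] if config.design == "mle" else 4
            for p in range(1, n_plots + 1):
                plot = f"{site}P{p}"
                for trt in ("control", "N"):
                    subplot = f"{plot}-{trt}"
                    xy = points[(site, p, trt)]
                    for date in dates:
                        for c in range(3):
                            sid = f"{niche}_{plot}_{trt}_{date.isoformat()}_c{c + 1}"
                            rows.append(
                                dict(
                                    sample_id=sid, niche=niche, site=site, plot=plot,
                                    subplot=subplot, n_treatment=trt,
                                    collection_date=date,
                                    easting=xy[c, 0], northing=xy[c, 1],
                                )
                            )
    meta = pd.DataFrame(rows).set_index("sample_id")
    return meta


def simulate_community(
    config: SimulationConfig, meta: pd.DataFrame
) -> tuple[OtuTable, GroundTruth]:
    """Generate an OTU table (all samples in ``meta``) with known truth."""
    rng = np.random.default_rng(config.seed + 1)
    T = config.n_taxa
    taxa = [f"OTU{t + 1:04d}" for t in range(T)]
    n_core = int(round(config.core_fraction * T))
    n_neutral = int(round(config.neutral_fraction * T))
    membership = np.array(
        ["core"] * n_core + ["neutral"] * n_neutral + ["structured"] * (T - n_core - n_neutral)
    )
    base = rng.lognormal(mean=0.0, sigma=1.5, size=T)
    base[membership == "core"] *= config.core_abundance_boost
    struct = membership == "structured"

    sites = sorted(pd.unique(meta["site"]))
    site_off = np.zeros((len(sites), T))
    site_off[:, struct] = rng.normal(0.0, config.site_sigma, size=(len(sites), struct.sum()))
    phase = rng.uniform(0, 365, size=T)
    n_taxa_mask = np.zeros(T, dtype=bool)
    candidates = np.nonzero(struct)[0]
    if candidates.size:
        chosen = rng.choice(
            candidates,
            size=max(int(round(config.n_effect_taxa_fraction * T)), 1) if config.n_effect > 0 else 0,
            replace=False,
        ) if config.n_effect > 0 else []
        n_taxa_mask[list(chosen)] = True

    soil_meta = meta[meta["niche"] == "soil"]
    root_meta = meta[meta["niche"] == "root"]
    order = list(soil_meta.index) + list(root_meta.index)

    # spatially autocorrelated field over soil samples (shared Cholesky)
    ns = len(soil_meta)
    field_vals = np.zeros((ns, T))
    if config.spatial_sigma > 0 and config.spatial_range > 0 and struct.any():
        xy = soil_meta[["easting", "northing"]].to_numpy(float)
        d = np.linalg.norm(xy[:, None, :] - xy[None, :, :], axis=-1)
        cov = config.spatial_sigma**2 * np.exp(-d / config.spatial_range)
        cov[np.diag_indices(ns)] += 1e-8
        L = np.linalg.cholesky(cov)
        field_vals[:, struct] = L @ rng.standard_normal((ns, struct.sum()))

    site_idx = {s: i for i, s in enumerate(sites)}
    counts = np.zeros((len(order), T), dtype=np.int64)
    soil_weights = {}
    Nm = config.depth * config.m
    for r, sid in enumerate(soil_meta.index):
        m = soil_meta.loc[sid]
        logw = np.log(base)
        logw[struct] += site_off[site_idx[m["site"]], struct]
        doy = m["collection_date"].timetuple().tm_yday
        logw[struct] += config.date_amplitude * np.sin(
            2 * np.pi * (doy - phase[struct]) / 365.0
        )
        logw[struct] += field_vals[r, struct]
        if m["n_treatment"] == "N":
            logw[n_taxa_mask] += config.n_effect
        w = np.exp(logw - logw.max())
        counts[r] = _draw_counts(rng, w, membership, base, Nm, config.depth)
        soil_weights[sid] = counts[r] / config.depth

    # roots: convex mixture of lagged subplot soil and root-specific taxa
    root_specific = np.zeros(T)
    if len(root_meta):
        spec_taxa = rng.choice(T, size=max(T // 10, 1), replace=False)
        root_specific[spec_taxa] = rng.lognormal(0.0, 1.0, size=len(spec_taxa))
        root_specific /= root_specific.sum()
    for r, sid in enumerate(root_meta.index, start=ns):
        m = root_meta.loc[sid]
        target = m["collection_date"] - _dt.timedelta(days=config.root_lag_days)
        cell = soil_meta[
            (soil_meta["plot"] == m["plot"]) & (soil_meta["subplot"] == m["subplot"])
        ]
        lagged = cell[cell["collection_date"] == target]
        if len(lagged) == 0:  # no collection at the lag (e.g. single-date design)
            lagged = cell[cell["collection_date"] == m["collection_date"]]
        soil_comp = np.mean([soil_weights[s] for s in lagged.index], axis=0)
        mix = config.root_soil_weight * soil_comp + (1 - config.root_soil_weight) * root_specific
        counts[r] = rng.multinomial(config.depth, mix / mix.sum())

    table = OtuTable(order, taxa, counts)
    truth = GroundTruth(
        membership=pd.Series(membership, index=taxa, name="membership"),
        m=config.m,
        n_effect_taxa=[taxa[i] for i in np.nonzero(n_taxa_mask)[0]],
        site_offsets=pd.DataFrame(site_off, index=sites, columns=taxa),
        seasonal_phase=pd.Series(phase, index=taxa),
        config=config,
    )
    return table, truth


def _draw_counts(rng, w, membership, base, Nm, depth):
    """One sample's counts: Sloan draws for neutral taxa, multinomial rest."""
    neutral = membership == "neutral"
    out = np.zeros(len(w), dtype=np.int64)
    if neutral.any():
        p_bar = base[neutral] / base.sum()
        a = np.maximum(Nm * p_bar, 1e-9)
        b = np.maximum(Nm * (1.0 - p_bar), 1e-9)
        rel = rng.beta(a, b)
        out[neutral] = rng.binomial(depth, rel)
    others = ~neutral
    rest = depth - int(out.sum())
    if rest < 0:
        # trim overshoot without bias: subsample the neutral reads
        out[neutral] = rng.multivariate_hypergeometric(out[neutral], depth)
        rest = 0
    if others.any():
        if rest > 0:
            ww = w[others]
            out[others] = rng.multinomial(rest, ww / ww.sum())
    elif rest > 0:  # all-neutral community: top up proportionally
        p_bar = base / base.sum()
        out += rng.multinomial(rest, p_bar / p_bar.sum())
    return out
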