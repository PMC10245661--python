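"""End-to-end orchestration of the regional and growing-season analyses.

Each run executes the stage modules in order (rarefaction, Bray-Curtis,
nested PERMANOVA, beta dispersion, ordination concordance, generalized
dissimilarity models with deviance partitioning, core-community
selection, and — for the growing season — the lagged root-soil
similarity comparison), communicating through files in the output
directory so any stage can be re-run and audited independently.  A JSON
manifest records inputs, seeds, configuration hash, and package version
for bit-identical re-runs.

Runs can consume real tables from disk or generate a fully synthetic
bundle (two domains, bacteria-like and fungi-like, over the same design)
from :mod:`spatiomic.simulate`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .community import OtuTable, rarefy, alpha_diversity_frame, write_otu_table, write_metadata
from .core import (
    bc_contribution_curve,
    fit_neutral,
    occupancy_abundance,
    rank_taxa,
    select_core,
)
from .distances import bray_curtis, geo_distance, lagged_similarity, similarity_frame, time_distance, write_distance_matrix
from .gdm import GdmData, backward_select, partition_deviance
from .ordination import ordinate, protest
from .permanova import beta_dispersion, lux_arbor_design, mle_design, permanova
from .simulate import SimulationConfig, simulate_community, simulate_design

__all__ = ["RunConfig", "run_regional", "run_growing_season"]


@dataclass
class RunConfig:
    out_dir: str
    simulation: SimulationConfig | None = None
    tables: dict | None = None        # domain -> OtuTable (or paths preloaded by CLI)
    metadata: pd.DataFrame | None = None
    depth: int = 10_000
    n_perm: int = 999
    varimp_n_perm: int = 100
    core_threshold: float = 0.05
    gdm_n_basis: int = 3
    ordination_method: str = "nmds"
    seed: int = 0
    outlier_samples: list[str] = field(default_factory=list)
    restrict_soil_to_root_dates: bool = True
    stages: dict = field(default_factory=dict)  # stage name -> bool toggle

    def enabled(self, stage: str) -> bool:
        return self.stages.get(stage, True)


def _prepare(config: RunConfig, design: str):
    """Load or simulate the two-domain table bundle and metadata."""
    if config.tables is not None and config.metadata is not None:
        return config.tables, config.metadata
    sim = config.simulation or SimulationConfig(design=design, seed=config.seed)
    if sim.design != design:
        raise ValueError(f"simulation design {sim.design!r} does not match run {design!r}")
    meta = simulate_design(sim)
    tables = {}
    for k, domain in enumerate(("bacteria", "fungi")):
        cfg = SimulationConfig(**{**asdict(sim), "seed": sim.seed + 1000 * (k + 1)})
        tables[domain], _ = simulate_community(cfg, meta)
    return tables, meta


def _synthetic_predictors(meta: pd.DataFrame, seed: int) -> pd.DataFrame:
    """Site-, date-, and plot-structured environmental covariates.

    Stand-ins for the measured soil, meteorological, and plant
    predictors, synthetic by construction: soil pH varies by site, soil
    moisture follows the season, subplot yield varies by plot.
    """
    rng = np.random.default_rng(seed)
    sites = sorted(pd.unique(meta["site"]))
    site_ph = {s: 5.5 + 0.4 * i + rng.normal(0, 0.05) for i, s in enumerate(sites)}
    plots = sorted(pd.unique(meta["plot"]))
    plot_yield = {p: rng.lognormal(0, 0.3) for p in plots}
    doy = np.array([d.timetuple().tm_yday for d in meta["collection_date"]])
    out = pd.DataFrame(
        {
            "soil_ph": [site_ph[s] for s in meta["site"]] + rng.normal(0, 0.05, len(meta)),
            "soil_moisture": 0.25 + 0.1 * np.sin(2 * np.pi * (doy - 90) / 365.0)
            + rng.normal(0, 0.01, len(meta)),
            "plant_yield": [plot_yield[p] for p in meta["plot"]] + rng.normal(0, 0.05, len(meta)),
        },
        index=meta.index,
    )
    return out


def _hash_config(config: RunConfig) -> str:
    def default(o):
        if isinstance(o, (pd.DataFrame, OtuTable)):
            return "<data>"
        if hasattr(o, "__dict__"):
            return o.__dict__
        return str(o)

    blob = json.dumps(asdict(config) if config.tables is None else {"inline": True},
                      default=default, sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _analyze_community(
    name: str,
    table: OtuTable,
    meta: pd.DataFrame,
    design_spec,
    group_col: str,
    config: RunConfig,
    out: Path,
    pair_predictors: dict,
    site_predictors: pd.DataFrame,
    groups: dict,
) -> dict:
    """Shared per-community stage chain; returns summary dict."""
    summary: dict = {"name": name, "n_samples": table.n_samples}
    dm = bray_curtis(table)
    write_distance_matrix(dm, out / f"{name}_braycurtis.tsv")
    m = meta.loc[table.sample_ids]

    if config.enabled("permanova"):
        tab = permanova(dm, m, design_spec, n_perm=config.n_perm, seed=config.seed)
        tab.to_csv(out / f"{name}_permanova.tsv", sep="\t")
        summary["permanova"] = {
            t: {"omega2": float(tab.loc[t, "omega2"]), "p": float(tab.loc[t, "p_perm"])}
            for t in tab.index[:-2]
        }
    if config.enabled("dispersion"):
        disp = beta_dispersion(dm, m[group_col], n_perm=config.n_perm, seed=config.seed)
        disp.distances.to_csv(out / f"{name}_dispersion.tsv", sep="\t")
        summary["dispersion"] = {"F": disp.f_stat, "p": disp.p_perm}
    if config.enabled("gdm"):
        data = GdmData.from_distance_matrix(
            dm,
            site_predictors=site_predictors.loc[table.sample_ids],
            pair_predictors={k: v.filter(table.sample_ids) for k, v in pair_predictors.items()},
        )
        model, imp = backward_select(
            data, n_perm=config.varimp_n_perm, seed=config.seed,
            n_basis=config.gdm_n_basis,
        )
        if imp is not None and len(imp):
            imp.to_csv(out / f"{name}_gdm_importance.tsv", sep="\t")
        part = partition_deviance(data, groups, n_basis=config.gdm_n_basis)
        part.to_csv(out / f"{name}_gdm_partition.tsv", sep="\t", index=False)
        summary["gdm"] = {
            "deviance_explained": model.deviance_explained_,
            "retained": model.predictors_,
            "partition_total": part.attrs["total_deviance_explained"],
        }
    if config.enabled("core"):
        stats_df = occupancy_abundance(table, m, group_by=group_col)
        ranked = rank_taxa(stats_df)
        curve = bc_contribution_curve(table, list(ranked.index))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            core = select_core(curve, table, threshold=config.core_threshold)
            ranked.to_csv(out / f"{name}_ranked_taxa.tsv", sep="\t")
            pd.DataFrame(
                {"rank": np.arange(1, len(curve.bc_contribution) + 1),
                 "bc_contribution": curve.bc_contribution}
            ).to_csv(out / f"{name}_bc_curve.tsv", sep="\t", index=False)
            neutral = None
            try:
                neutral = fit_neutral(stats_df, N=config.depth, n_samples=table.n_samples)
                neutral.table_.to_csv(out / f"{name}_neutral_fit.tsv", sep="\t")
            except (RuntimeError, ValueError):
                pass
        summary["core"] = {
            "core_richness": len(core.core_taxa),
            "richness_share": core.richness_share,
            "read_share": core.read_share,
            "neutral_m": getattr(neutral, "m_", None),
            "neutral_r2": getattr(neutral, "r2_", None),
            "neutral_failed": neutral.failed_ if neutral is not None else True,
        }
    return summary


def _run(config: RunConfig, design: str) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables, meta = _prepare(config, design)
    if config.outlier_samples:
        tables = {d: t.drop_samples([s for s in config.outlier_samples if s in t.sample_ids])
                  for d, t in tables.items()}
    write_metadata(meta, out / "metadata.tsv")
    preds = _synthetic_predictors(meta, config.seed + 77)
    design_spec = mle_design() if design == "mle" else lux_arbor_design()
    group_col = "site" if design == "mle" else "collection_date"

    manifest = {
        "version": __version__,
        "design": design,
        "seed": config.seed,
        "depth": config.depth,
        "n_perm": config.n_perm,
        "config_hash": _hash_config(config),
        "stages": {},
    }
    summaries = {}
    ordinations = {}
    for domain, table in tables.items():
        rare, dropped = rarefy(table, config.depth, seed=config.seed)
        if dropped:
            pd.Series(dropped).to_csv(out / f"{domain}_dropped_samples.tsv", sep="\t", index=False)
        write_otu_table(rare, out / f"{domain}_rarefied.tsv")
        alpha_diversity_frame(rare).to_csv(out / f"{domain}_alpha.tsv", sep="\t")
        for niche in ("root", "soil"):
            ids = [s for s in rare.sample_ids if meta.loc[s, "niche"] == niche]
            if not ids:
                raise RuntimeError(f"stage input: no {niche} samples for {domain}")
            sub = rare.select_samples(ids)
            m = meta.loc[ids]
            pair_preds = {"geographic_m": geo_distance(m)}
            groups = {"spatial": ["geographic_m"], "soil": ["soil_ph"],
                      "MET": ["soil_moisture"], "plant": ["plant_yield"]}
            if design == "lux_arbor":
                pair_preds["temporal_days"] = time_distance(m)
                groups["temporal"] = ["temporal_days"]
                if niche == "soil" and config.restrict_soil_to_root_dates:
                    root_dates = set(
                        meta.loc[meta["niche"] == "root", "collection_date"]
                    )
                    ids = [s for s in ids if meta.loc[s, "collection_date"] in root_dates]
                    sub = rare.select_samples(ids)
                    m = meta.loc[ids]
                    pair_preds = {"geographic_m": geo_distance(m),
                                  "temporal_days": time_distance(m)}
            name = f"{domain}_{niche}"
            summaries[name] = _analyze_community(
                name, sub, meta, design_spec, group_col, config, out,
                pair_preds, preds, groups,
            )
            if config.enabled("protest"):
                ordinations[name] = ordinate(
                    bray_curtis(sub), seed=config.seed,
                    method=config.ordination_method,
                )
        if design == "lux_arbor" and config.enabled("lagged_similarity"):
            root_ids = [s for s in rare.sample_ids if meta.loc[s, "niche"] == "root"]
            soil_ids = [s for s in rare.sample_ids if meta.loc[s, "niche"] == "soil"]
            recs = lagged_similarity(
                rare.select_samples(root_ids), rare.select_samples(soil_ids), meta
            )
            df = similarity_frame(recs)
            df.to_csv(out / f"{domain}_lagged_similarity.tsv", sep="\t", index=False)
            ok = df[~df["missing"]]
            summaries[f"{domain}_lagged"] = {
                "mean_same_day": float(ok[ok.soil_reference == "same_day"].similarity.mean()),
                "mean_two_week_prior": float(
                    ok[ok.soil_reference == "two_week_prior"].similarity.mean()
                ),
            }

    if config.enabled("protest"):
        for niche in ("root", "soil"):
            a, b = f"bacteria_{niche}", f"fungi_{niche}"
            if a in ordinations and b in ordinations:
                res = protest(ordinations[a], ordinations[b],
                              n_perm=config.n_perm, seed=config.seed)
                res.residuals.to_csv(out / f"protest_{niche}_residuals.tsv", sep="\t")
                summaries[f"protest_{niche}"] = {
                    "m2": res.m2, "t": res.t_stat, "p": res.p_perm,
                }

    manifest["stages"] = summaries
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def run_regional(config: RunConfig) -> dict:
    """Regional (five-site, single-date) analysis bundle."""
    return _run(config, "mle")


def run_growing_season(config: RunConfig) -> dict:
    """Single-site growing-season analysis bundle."""
    return _run(config, "lux_arbor")
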