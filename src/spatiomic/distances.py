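"""Pairwise community, spatial, and temporal distances.

Bray-Curtis dissimilarity between rarefied count profiles, Euclidean
geographic distance on UTM coordinates, calendar-day temporal distance,
and the lagged root-vs-soil similarity comparison (root communities
against soil communities collected the same day or a fixed number of days
earlier).

Distance matrices are :class:`skbio.DistanceMatrix` objects throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .community import OtuTable

__all__ = [
    "bray_curtis",
    "geo_distance",
    "time_distance",
    "lagged_similarity",
    "PairedSimilarityRecord",
    "write_distance_matrix",
    "read_distance_matrix",
]


def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d_ij = sum|x_i - x_j| / sum(x_i + x_j).

    Computed on the counts as given (rarefied counts recommended; at equal
    depth this equals the relative-abundance version).
    """
    x = table.counts.astype(float)
    d = pdist(x, metric="braycurtis")
    return DistanceMatrix(squareform(d), ids=table.sample_ids)


def geo_distance(meta: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance in meters on (easting, northing) UTM coordinates."""
    missing = meta.index[
        ~np.isfinite(meta["easting"]) | ~np.isfinite(meta["northing"])
    ].tolist()
    if missing:
        raise ValueError(f"samples with missing coordinates: {missing}")
    xy = meta[["easting", "northing"]].to_numpy(dtype=float)
    return DistanceMatrix(squareform(pdist(xy)), ids=list(meta.index))


def time_distance(meta: pd.DataFrame) -> DistanceMatrix:
    """|date_i - date_j| in whole days."""
    days = np.array(
        [d.toordinal() for d in meta["collection_date"]], dtype=float
    ).reshape(-1, 1)
    return DistanceMatrix(squareform(pdist(days, metric="cityblock")), ids=list(meta.index))


@dataclass
class PairedSimilarityRecord:
    """Similarity (1 - Bray-Curtis) of one root sample to its soil reference."""

    root_sample_id: str
    soil_reference: str  # "same_day" or "two_week_prior"
    similarity: float | None
    collection_date: object
    plot: str
    subplot: str
    n_treatment: str
    missing: bool = False
    subplot_mean: bool = False  # two_week_prior records average over the subplot


def _bc_pair(x: np.ndarray, y: np.ndarray) -> float:
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValueError("Bray-Curtis undefined for a pair of all-zero samples")
    return float(np.sum(np.abs(x - y)) / denom)


def lagged_similarity(
    root: OtuTable,
    soil: OtuTable,
    meta: pd.DataFrame,
    lag_days: int = 14,
    tolerance_days: int = 4,
) -> list[PairedSimilarityRecord]:
    """Similarity of each root sample to soil sampled same-day or ``lag_days`` earlier.

    Same-day records pair each root sample with its spatially paired soil
    core (the nearest soil core of the same subplot on the same date).
    Lagged records use the *mean* similarity between the root sample and
    all soil samples of the same subplot collected ``lag_days`` earlier;
    the soil collection nearest to (root date - lag_days) within
    ``tolerance_days`` is used.  Records with no qualifying soil
    collection are flagged missing, never fabricated.
    """
    shared = [t for t in root.taxon_ids if t in set(soil.taxon_ids)]
    if len(shared) != root.n_taxa or len(shared) != soil.n_taxa:
        root = _subset_taxa(root, shared)
        soil = _subset_taxa(soil, shared)
    soil_meta = meta.loc[[s for s in soil.sample_ids]]
    soil_idx = {s: i for i, s in enumerate(soil.sample_ids)}
    records: list[PairedSimilarityRecord] = []
    for ri, rid in enumerate(root.sample_ids):
        m = meta.loc[rid]
        rdate = m["collection_date"]
        cell = (m["plot"], m["subplot"])
        in_cell = soil_meta[
            (soil_meta["plot"] == cell[0]) & (soil_meta["subplot"] == cell[1])
        ]

        # same-day: spatially paired soil core = nearest by coordinates
        same_day = in_cell[in_cell["collection_date"] == rdate]
        if len(same_day) == 0:
            records.append(
                PairedSimilarityRecord(rid, "same_day", None, rdate, *cell, m["n_treatment"], missing=True)
            )
        else:
            dx = same_day["easting"].to_numpy(float) - float(m["easting"])
            dy = same_day["northing"].to_numpy(float) - float(m["northing"])
            sid = same_day.index[int(np.argmin(np.hypot(dx, dy)))]
            bc = _bc_pair(root.counts[ri].astype(float), soil.counts[soil_idx[sid]].astype(float))
            records.append(
                PairedSimilarityRecord(rid, "same_day", 1.0 - bc, rdate, *cell, m["n_treatment"])
            )

        # lagged: mean similarity over all subplot soils collected lag_days earlier
        target = rdate.toordinal() - lag_days
        offsets = np.array([abs(d.toordinal() - target) for d in in_cell["collection_date"]])
        if len(offsets) == 0 or offsets.min() > tolerance_days:
            records.append(
                PairedSimilarityRecord(
                    rid, "two_week_prior", None, rdate, *cell, m["n_treatment"],
                    missing=True, subplot_mean=True,
                )
            )
            continue
        best = in_cell["collection_date"].iloc[int(np.argmin(offsets))]
        lagged = in_cell[in_cell["collection_date"] == best]
        sims = [
            1.0 - _bc_pair(root.counts[ri].astype(float), soil.counts[soil_idx[s]].astype(float))
            for s in lagged.index
        ]
        records.append(
            PairedSimilarityRecord(
                rid, "two_week_prior", float(np.mean(sims)), rdate, *cell,
                m["n_treatment"], subplot_mean=True,
            )
        )
    return records


def _subset_taxa(table: OtuTable, taxa: list[str]) -> OtuTable:
    idx = {t: i for i, t in enumerate(table.taxon_ids)}
    cols = [idx[t] for t in taxa]
    return OtuTable(list(table.sample_ids), list(taxa), table.counts[:, cols])


def similarity_frame(records: list[PairedSimilarityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "root_sample_id": [r.root_sample_id for r in records],
            "soil_reference": [r.soil_reference for r in records],
            "similarity": [r.similarity for r in records],
            "collection_date": [r.collection_date for r in records],
            "plot": [r.plot for r in records],
            "subplot": [r.subplot for r in records],
            "n_treatment": [r.n_treatment for r in records],
            "missing": [r.missing for r in records],
        }
    )


def write_distance_matrix(dm: DistanceMatrix, path, long_format: bool = False) -> None:
    if long_format:
        rows = []
        for i, a in enumerate(dm.ids):
            for j in range(i + 1, len(dm.ids)):
                rows.append((a, dm.ids[j], dm.data[i, j]))
        pd.DataFrame(rows, columns=["i", "j", "value"]).to_csv(path, sep="\t", index=False)
    else:
        pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
            path, sep="\t", index_label="id"
        )


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])
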