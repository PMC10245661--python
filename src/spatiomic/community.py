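"""OTU tables, sample metadata, and sample-level summaries.

This module holds the containers every downstream stage consumes: an
integer count matrix of samples x taxa (:class:`OtuTable`), the per-sample
design metadata (site / plot / subplot / N treatment / niche / date / UTM
coordinates), and taxonomy/guild annotations.  It also implements the
sample-level preprocessing steps of the analysis: rarefaction to a common
read depth, alpha diversity (richness and inverse Simpson), and the
extreme-value covariate filter used to clean environmental predictors.

File formats are plain TSV (taxa as columns, header row of taxon ids) and
a minimal BIOM 2.1 (HDF5) profile written through h5py.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "AlphaDiversity",
    "read_otu_table",
    "write_otu_table",
    "read_metadata",
    "write_metadata",
    "read_annotations",
    "rarefy",
    "alpha_diversity",
    "flag_extreme",
]

METADATA_COLUMNS = [
    "sample_id",
    "niche",
    "site",
    "plot",
    "subplot",
    "n_treatment",
    "collection_date",
    "easting",
    "northing",
]


class ValidationError(ValueError):
    """A table or metadata file violated a structural invariant."""


@dataclass
class OtuTable:
    """Samples x taxa count matrix with aligned identifiers.

    Parameters
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per matrix row.
    taxon_ids : list of str
        Unique taxon (OTU) identifiers, one per matrix column.
    counts : ndarray of shape (n_samples, n_taxa)
        Non-negative integer read counts.

    Notes
    -----
    Taxa whose total count is zero are *flagged* (``empty_taxa``) rather
    than dropped, so matrices stay alignable across niches after
    rarefaction.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    empty_taxa: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()
        totals = self.counts.sum(axis=0)
        self.empty_taxa = [t for t, s in zip(self.taxon_ids, totals) if s == 0]

    def validate(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = _first_duplicate(self.sample_ids)
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            dup = _first_duplicate(self.taxon_ids)
            raise ValidationError(f"duplicate taxon id: {dup!r}")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValidationError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ValidationError("counts must be numeric")
        if np.any(~np.isfinite(self.counts.astype(float))):
            raise ValidationError("counts contain non-finite values")
        if np.any(self.counts < 0):
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if np.any(self.counts != np.round(self.counts)):
            i, j = np.argwhere(self.counts != np.round(self.counts))[0]
            raise ValidationError(
                f"non-integer count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        self.counts = self.counts.astype(np.int64)
        row_sums = self.counts.sum(axis=1)
        if np.any(row_sums == 0):
            empty = [s for s, r in zip(self.sample_ids, row_sums) if r == 0]
            raise ValidationError(f"samples with zero total reads: {empty}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalized counts (per-sample relative abundances)."""
        return self.counts / self.counts.sum(axis=1, keepdims=True)

    def select_samples(self, ids) -> "OtuTable":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in idx]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        rows = [idx[s] for s in ids]
        return OtuTable(list(ids), list(self.taxon_ids), self.counts[rows])

    def drop_samples(self, ids) -> "OtuTable":
        """Remove samples by explicit id list (e.g. manually flagged outliers)."""
        drop = set(ids)
        keep = [s for s in self.sample_ids if s not in drop]
        return self.select_samples(keep)


def _first_duplicate(items):
    seen = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_otu_table(path, format: str = "tsv", orientation: str = "samples") -> OtuTable:
    """Read an OTU count table.

    Parameters
    ----------
    path : str or Path
    format : {"tsv", "biom"}
        TSV has a header row of taxon ids and the first column of sample ids
        (``orientation="samples"``) or the transpose (``orientation="taxa"``).
        BIOM is the 2.1 HDF5 profile.
    orientation : {"samples", "taxa"}
        Which axis the TSV rows represent; output is always samples x taxa.
    """
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if orientation == "taxa":
            df = df.T
        elif orientation != "samples":
            raise ValueError(f"unknown orientation {orientation!r}")
        bad = df.columns[~df.apply(lambda c: pd.to_numeric(c, errors="coerce").notna().all())]
        if len(bad):
            raise ValidationError(f"non-numeric cells in columns: {list(bad)}")
        return OtuTable(
            [str(s) for s in df.index],
            [str(t) for t in df.columns],
            df.to_numpy(),
        )
    if format == "biom":
        return _read_biom(path)
    raise ValueError(f"unknown format {format!r}")


def write_otu_table(table: OtuTable, path, format: str = "tsv") -> None:
    if format == "tsv":
        table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")
    elif format == "biom":
        _write_biom(table, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _read_biom(path) -> OtuTable:
    # Minimal BIOM 2.1 (HDF5) profile: CSR counts stored observation-major.
    import h5py

    with h5py.File(path, "r") as f:
        obs_ids = [x.decode() for x in f["observation/ids"][:]]
        samp_ids = [x.decode() for x in f["sample/ids"][:]]
        data = f["observation/matrix/data"][:]
        indices = f["observation/matrix/indices"][:]
        indptr = f["observation/matrix/indptr"][:]
    from scipy.sparse import csr_matrix

    mat = csr_matrix((data, indices, indptr), shape=(len(obs_ids), len(samp_ids)))
    return OtuTable(samp_ids, obs_ids, np.asarray(mat.T.todense()))


def _write_biom(table: OtuTable, path) -> None:
    import h5py
    from scipy.sparse import csr_matrix

    mat = csr_matrix(table.counts.T)  # observations (taxa) x samples
    with h5py.File(path, "w") as f:
        f.attrs["id"] = "No Table ID"
        f.attrs["type"] = "OTU table"
        f.attrs["format-url"] = "http://biom-format.org"
        f.attrs["format-version"] = (2, 1)
        f.attrs["generated-by"] = "spatiomic"
        f.attrs["creation-date"] = _dt.datetime.now().isoformat()
        f.attrs["shape"] = mat.shape
        f.attrs["nnz"] = mat.nnz
        str_t = h5py.string_dtype()
        f.create_dataset("observation/ids", data=np.array(table.taxon_ids, dtype=str_t))
        f.create_dataset("sample/ids", data=np.array(table.sample_ids, dtype=str_t))
        f.create_dataset("observation/matrix/data", data=mat.data.astype(float))
        f.create_dataset("observation/matrix/indices", data=mat.indices.astype(np.int64))
        f.create_dataset("observation/matrix/indptr", data=mat.indptr.astype(np.int64))
        # sample-major copy, as required by the 2.1 profile
        cs = mat.T.tocsr()
        f.create_dataset("sample/matrix/data", data=cs.data.astype(float))
        f.create_dataset("sample/matrix/indices", data=cs.indices.astype(np.int64))
        f.create_dataset("sample/matrix/indptr", data=cs.indptr.astype(np.int64))
        for grp in ("observation", "sample"):
            f.create_group(f"{grp}/metadata")
            f.create_group(f"{grp}/group-metadata")


def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata TSV with the mandated column names.

    Returns a DataFrame indexed by ``sample_id``; ``collection_date`` is
    parsed from ISO-8601 into ``datetime.date`` objects.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing columns: {missing}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"duplicate sample_id in metadata: {dup!r}")
    df = df.set_index("sample_id")
    df["collection_date"] = [
        _dt.date.fromisoformat(d) for d in df["collection_date"]
    ]
    for col in ("easting", "northing"):
        df[col] = pd.to_numeric(df[col])
        if not np.all(np.isfinite(df[col])):
            bad = df.index[~np.isfinite(df[col])].tolist()
            raise ValidationError(f"non-finite {col} for samples: {bad}")
    bad_niche = set(df["niche"]) - {"root", "soil"}
    if bad_niche:
        raise ValidationError(f"unknown niche values: {sorted(bad_niche)}")
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    out = meta.copy()
    out["collection_date"] = [d.isoformat() for d in out["collection_date"]]
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_annotations(path) -> pd.DataFrame:
    """Read taxonomy / guild annotation TSV, indexed by taxon_id."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "taxon_id" not in df.columns:
        raise ValidationError("annotation file missing 'taxon_id' column")
    if df["taxon_id"].duplicated().any():
        raise ValidationError("duplicate taxon_id in annotations")
    return df.set_index("taxon_id")


# ---------------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int) -> tuple[OtuTable, list[str]]:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples whose total read count falls below ``depth`` are removed and
    reported; one seeded generator governs all samples so results are
    reproducible.  Taxa that become all-zero are retained in the matrix
    (flagged via ``empty_taxa``) to keep tables alignable.

    Returns
    -------
    (rarefied_table, dropped_sample_ids)
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    keep = totals >= depth
    dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
    if not keep.any():
        raise ValueError(f"all {table.n_samples} samples have fewer than {depth} reads")
    out = np.zeros((int(keep.sum()), table.n_taxa), dtype=np.int64)
    row = 0
    for i in np.nonzero(keep)[0]:
        counts = table.counts[i]
        if totals[i] == depth:
            out[row] = counts
        else:
            # multivariate hypergeometric = subsample reads without replacement
            out[row] = rng.multivariate_hypergeometric(counts, depth)
        row += 1
    kept_ids = [s for s, k in zip(table.sample_ids, keep) if k]
    return OtuTable(kept_ids, list(table.taxon_ids), out), dropped


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

@dataclass
class AlphaDiversity:
    sample_id: str
    richness: int
    inverse_simpson: float


def alpha_diversity(table: OtuTable) -> list[AlphaDiversity]:
    """Richness (# taxa with count > 0) and inverse Simpson 1 / sum(p_i^2)."""
    rel = table.relative_abundance()
    out = []
    for sid, row in zip(table.sample_ids, rel):
        richness = int(np.count_nonzero(row))
        inv_simpson = 1.0 / float(np.sum(row**2))
        out.append(AlphaDiversity(sid, richness, inv_simpson))
    return out


def alpha_diversity_frame(table: OtuTable) -> pd.DataFrame:
    recs = alpha_diversity(table)
    return pd.DataFrame(
        {
            "richness": [r.richness for r in recs],
            "inverse_simpson": [r.inverse_simpson for r in recs],
        },
        index=[r.sample_id for r in recs],
    ).rename_axis("sample_id")


# ---------------------------------------------------------------------------
# Extreme-value covariate filter
# ---------------------------------------------------------------------------

def flag_extreme(values, k: float = 3.0) -> np.ndarray:
    """Flag values outside ``[Q1 - k*IQR, Q3 + k*IQR]`` (default k = 3).

    Quartiles use linear interpolation between order statistics.  Missing
    (NaN) values are never flagged.  Requires at least 4 finite values.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() == 0:
        raise ValueError("all values are missing")
    if finite.sum() < 4:
        raise ValueError("need at least 4 finite values to estimate quartiles")
    q1, q3 = np.percentile(x[finite], [25, 75], method="linear")
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    mask = np.zeros(x.shape, dtype=bool)
    mask[finite] = (x[finite] < lo) | (x[finite] > hi)
    return mask
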