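"""Ordination and Procrustes/PROTEST concordance between communities.

Non-metric multidimensional scaling (stress majorization with multiple
random restarts, via scikit-learn) or metric principal coordinates embed
a distance matrix in k dimensions.  PROTEST superimposes one ordination
onto another (translation + uniform scale + orthogonal rotation chosen to
minimize the sum of squared deviations m2) and assesses concordance by
permuting sample identities.

The fit is asymmetric: the second configuration is rotated onto the
first (here: fungal onto bacterial), and m2 is normalized by the target
configuration's sum of squares so it lies in [0, 1].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

__all__ = ["OrdinationResult", "ProcrustesResult", "ordinate", "pcoa_embed", "protest"]


@dataclass
class OrdinationResult:
    ids: list[str]
    configuration: np.ndarray  # n x k, centered at the origin
    stress: float | None       # Kruskal stress-1 (None for metric embedding)
    method: str
    seed: int | None = None


@dataclass
class ProcrustesResult:
    m2: float                  # sum of squared deviations, target-normalized
    t_stat: float              # sqrt(1 - m2)
    p_perm: float
    residuals: pd.Series       # per-sample residual lengths; sum(r^2) = m2
    rotation: np.ndarray
    scale: float
    translation: np.ndarray


def ordinate(
    dm: DistanceMatrix,
    k: int = 2,
    seed: int = 0,
    n_restarts: int = 20,
    method: str = "nmds",
    max_iter: int = 300,
    eps: float = 1e-6,
) -> OrdinationResult:
    """Embed a distance matrix in k dimensions.

    ``method="nmds"`` runs non-metric MDS with ``n_restarts`` random
    starts and returns the lowest-stress configuration (Kruskal
    stress-1); ``method="pcoa"`` is the metric principal-coordinate
    fallback.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if method == "pcoa":
        return pcoa_embed(dm, k)
    if method != "nmds":
        raise ValueError(f"unknown ordination method {method!r}")
    from sklearn.manifold import MDS

    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_restarts,
        max_iter=max_iter,
        eps=eps,
        random_state=seed,
        normalized_stress=True,
    )
    config = mds.fit_transform(dm.data)
    if not np.all(np.isfinite(config)):
        raise RuntimeError(f"NMDS failed to converge; stress trace: {mds.stress_}")
    config = config - config.mean(axis=0)
    return OrdinationResult(list(dm.ids), config, float(mds.stress_), "nmds", seed)


def pcoa_embed(dm: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Metric principal coordinates (top-k positive eigenvalue axes)."""
    a = -0.5 * dm.data**2
    n = a.shape[0]
    g = a - a.mean(axis=1, keepdims=True) - a.mean(axis=0, keepdims=True) + a.mean()
    eigval, eigvec = np.linalg.eigh((g + g.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.clip(eigval[:k], 0.0, None)
    config = eigvec[:, :k] * np.sqrt(pos)
    config = config - config.mean(axis=0)
    return OrdinationResult(list(dm.ids), config, None, "pcoa")


def _procrustes_m2(x: np.ndarray, y: np.ndarray):
    """Fit y onto x; return (m2, rotation, scale, translation, residual matrix).

    x is normalized to unit sum of squares so m2 is in [0, 1] and the
    per-sample squared residuals sum to m2.
    """
    mx, my = x.mean(axis=0), y.mean(axis=0)
    xc, yc = x - mx, y - my
    norm_x = np.sqrt(np.sum(xc**2))
    norm_y = np.sqrt(np.sum(yc**2))
    if norm_x == 0 or norm_y == 0:
        raise ValueError("degenerate (zero-variance) configuration")
    xc = xc / norm_x
    u, s, vt = np.linalg.svd(xc.T @ yc)
    rot = vt.T @ u.T           # y @ rot approximates xc
    scale = s.sum() / norm_y**2
    yhat = scale * yc @ rot
    resid = xc - yhat
    m2 = float(np.sum(resid**2))
    return m2, rot, scale, mx - my, resid


def protest(
    x: OrdinationResult,
    y: OrdinationResult,
    n_perm: int = 999,
    seed: int = 0,
    enumerate_all: bool = False,
) -> ProcrustesResult:
    """Procrustes superimposition of y onto x with a permutation test.

    Significance: sample identities of y are permuted ``n_perm`` times
    and p = (#{m2* <= m2} + 1) / (n_perm + 1).  With ``enumerate_all``
    every permutation of the rows of y is evaluated (small n only) and
    p = b / n!.
    """
    shared = [s for s in x.ids if s in set(y.ids)]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 shared samples, got {len(shared)}")
    xi = {s: i for i, s in enumerate(x.ids)}
    yi = {s: i for i, s in enumerate(y.ids)}
    xc = x.configuration[[xi[s] for s in shared]]
    yc = y.configuration[[yi[s] for s in shared]]

    m2, rot, scale, trans, resid = _procrustes_m2(xc, yc)
    resid_len = np.linalg.norm(resid, axis=1)

    n = len(shared)
    if enumerate_all:
        exceed = 0
        total = 0
        for p in itertools.permutations(range(n)):
            m2_p, *_ = _procrustes_m2(xc, yc[list(p)])
            total += 1
            if m2_p <= m2 + 1e-12:
                exceed += 1
        p_val = exceed / total
    elif n_perm > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_perm):
            m2_p, *_ = _procrustes_m2(xc, yc[rng.permutation(n)])
            if m2_p <= m2 + 1e-12:
                exceed += 1
        p_val = (exceed + 1) / (n_perm + 1)
    else:
        p_val = np.nan

    return ProcrustesResult(
        m2=m2,
        t_stat=float(np.sqrt(max(0.0, 1.0 - m2))),
        p_perm=p_val,
        residuals=pd.Series(resid_len, index=shared, name="procrustes_residual"),
        rotation=rot,
        scale=scale,
        translation=trans,
    )
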