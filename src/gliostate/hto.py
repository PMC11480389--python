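"""Hashtag-oligo (HTO) demultiplexing.

Hashed samples are demultiplexed in four steps: (1) CLR-normalize the raw
tag counts per tag across cells; (2) k-means cluster the CLR profiles
(k = n_tags + 1 by default, the extra cluster absorbing negatives); (3) for
each tag, fit a negative binomial to the RAW counts of the background
cells — every cell outside the cluster with the highest mean CLR for that
tag, with far outliers excluded — by the method of moments, and set the
positivity threshold at a high quantile (default 0.99) of the fitted
distribution; (4) call each cell by
its positive-tag count: exactly one positive tag = singlet, two or more =
doublet, none = negative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.cluster import KMeans

from gliostate.io import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class HTOCall:
    calls: pd.DataFrame  # index barcode; columns label, n_positive, positive_tags
    thresholds: pd.Series  # per tag


def clr_normalize(h: CountMatrix) -> pd.DataFrame:
    """Centered log-ratio transform per tag across cells.

    clr(x_i) = ln(x_i + 1) - mean_j ln(x_j + 1), computed within each tag.
    Rows (tags) of the result sum to zero across cells.
    """
    x = np.log(np.asarray(h.counts.todense(), dtype=float) + 1.0)
    x -= x.mean(axis=1, keepdims=True)
    return pd.DataFrame(x, index=h.genes, columns=h.cells)


def cluster_cells(clr: pd.DataFrame, k: int | None = None, seed: int = 0) -> pd.Series:
    """Seeded k-means on CLR profiles (cells as observations).

    k defaults to n_tags + 1. Ten k-means++ restarts; best inertia kept.
    """
    if k is None:
        k = len(clr.index) + 1
    if k < 2:
        raise ValueError("k must be >= 2")
    if clr.shape[1] < k:
        raise ValueError(f"fewer cells ({clr.shape[1]}) than clusters ({k})")
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(clr.to_numpy().T)
    return pd.Series(labels, index=clr.columns, name="cluster")


def fit_background_thresholds(
    h: CountMatrix,
    clusters: pd.Series,
    quantile_q: float = 0.99,
    background: str = "complement_top",
    outlier_mads: float = 10.0,
    min_background: int = 100,
) -> pd.Series:
    """Per-tag positivity thresholds from negative-binomial background fits.

    For each tag, the background cells are every cell outside the cluster
    with the highest mean CLR for that tag (default; pooling across the
    other clusters keeps the fit representative of the full staining-depth
    range). ``background="lowest_cluster"`` instead uses the cluster with
    the lowest mean CLR for the tag, pooling further low-CLR clusters
    until at least ``min_background`` cells are available (a tiny leftover
    cluster alone gives an unusable fit).
    A negative binomial is fit to the background raw
    counts by the method of moments (size = m^2/(v - m), floored at 1e-8);
    the threshold is the ``quantile_q`` quantile of the fitted
    distribution. If the background is underdispersed (v <= m) a Poisson
    quantile is used instead (logged). Background counts further than
    ``outlier_mads`` scaled MADs above the median are excluded before the
    fit: a handful of mis-clustered doublets carrying signal-level counts
    would otherwise dominate the variance estimate, while a cut this far
    out leaves the genuine background essentially untouched.
    """
    if background not in ("lowest_cluster", "complement_top"):
        raise ValueError(f"unknown background strategy {background!r}")
    clr = clr_normalize(h)
    clusters = pd.Series(clusters).reindex(clr.columns)
    raw = np.asarray(h.counts.todense(), dtype=float)
    thresholds = {}
    for t, tag in enumerate(h.genes):
        by_cluster = clr.iloc[t].groupby(clusters).mean()
        if background == "lowest_cluster":
            take: list = []
            n_taken = 0
            for cl in by_cluster.sort_values().index:
                take.append(cl)
                n_taken += int((clusters == cl).sum())
                if n_taken >= min(min_background, h.n_cells):
                    break
            bg = raw[t, clusters.isin(take).to_numpy()]
        else:
            bg = raw[t, (clusters != by_cluster.idxmax()).to_numpy()]
        if bg.size == 0:
            raise ValueError(f"tag {tag}: empty background cell set")
        if outlier_mads > 0:
            med = np.median(bg)
            mad = 1.4826 * np.median(np.abs(bg - med))
            bg = bg[bg <= med + outlier_mads * (mad + 1.0)]
        m, v = bg.mean(), bg.var()
        if m == 0:
            thresholds[tag] = 0.0
        elif v <= m:
            logger.info("tag %s background underdispersed (v=%.2f <= m=%.2f); Poisson fallback", tag, v, m)
            thresholds[tag] = float(scipy.stats.poisson.ppf(quantile_q, m))
        else:
            size = max(m * m / (v - m), 1e-8)
            p = size / (size + m)
            thresholds[tag] = float(scipy.stats.nbinom.ppf(quantile_q, size, p))
    return pd.Series(thresholds, name="threshold")


def call_cells(h: CountMatrix, thresholds: pd.Series) -> HTOCall:
    """Classify each cell by its positive tags (raw count > tag threshold).

    Exactly one positive tag -> singlet:<tag>; two or more -> doublet;
    none -> negative.
    """
    missing = [t for t in h.genes if t not in thresholds.index]
    if missing:
        raise ValueError(f"missing thresholds for tags {missing}")
    raw = np.asarray(h.counts.todense(), dtype=float)
    thr = thresholds.reindex(h.genes).to_numpy()
    positive = raw > thr[:, None]
    n_pos = positive.sum(axis=0)

    tags = np.array(h.genes, dtype=object)
    labels = np.empty(h.n_cells, dtype=object)
    pos_tags = []
    for c in range(h.n_cells):
        pt = tags[positive[:, c]]
        pos_tags.append(",".join(pt))
        if n_pos[c] == 1:
            labels[c] = f"singlet:{pt[0]}"
        elif n_pos[c] >= 2:
            labels[c] = "doublet"
        else:
            labels[c] = "negative"
    calls = pd.DataFrame(
        {"label": labels, "n_positive": n_pos, "positive_tags": pos_tags},
        index=pd.Index(h.cells, name="barcode"),
    )
    return HTOCall(calls=calls, thresholds=thresholds.reindex(h.genes))


def demux(h: CountMatrix, k: int | None = None, quantile_q: float = 0.99, seed: int = 0) -> HTOCall:
    """CLR -> k-means -> NB thresholds -> calls, in one pass."""
    clr = clr_normalize(h)
    clusters = cluster_cells(clr, k=k, seed=seed)
    thresholds = fit_background_thresholds(h, clusters, quantile_q=quantile_q)
    return call_cells(h, thresholds)
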