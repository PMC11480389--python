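"""Matched-subsample differential expression and signature derivation.

Two conditions are compared only after being matched on both cell number
(the larger condition is subsampled without replacement to the smaller's
cell count) and sequencing depth (the deeper condition's counts are
binomially thinned so the average number of molecules per cell is equal).
Counts are then normalized by median-scaled library-size factors and each
gene is tested with a two-sided, tie-corrected Mann-Whitney U test; p
values are Benjamini-Hochberg adjusted across all tested genes.

Consistent up/down signatures are derived from four pairwise comparisons
(two biological replicates per model, crossed): a gene enters the up list
when log2FC > 1 and FDR < 0.05 in at least three of the four comparisons,
and symmetrically for the down list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats
from statsmodels.stats.multitest import multipletests

from gliostate.io import CountMatrix

logger = logging.getLogger(__name__)

DEPTH_TOLERANCE = 0.01


@dataclass
class MatchedPair:
    a: CountMatrix
    b: CountMatrix
    cells_dropped_a: int
    cells_dropped_b: int
    thinning_p: float
    thinned: str  # "a", "b" or "none"
    seed: int

    def __post_init__(self) -> None:
        if self.a.n_cells != self.b.n_cells:
            raise ValueError("matched pair must have equal cell counts")
        avg_a = self.a.cell_totals().mean()
        avg_b = self.b.cell_totals().mean()
        rel = abs(avg_a - avg_b) / max(avg_a, avg_b)
        if rel >= DEPTH_TOLERANCE:
            raise ValueError(
                f"average molecules per cell differ by {rel:.2%} (>= {DEPTH_TOLERANCE:.0%}): "
                f"{avg_a:.1f} vs {avg_b:.1f}"
            )


@dataclass
class DerivedSignature:
    up: list[str]
    down: list[str]
    support_up: pd.Series
    support_down: pd.Series


def _thin(m: CountMatrix, p_keep: float, rng: np.random.Generator) -> CountMatrix:
    """Binomial thinning: keep each molecule independently with probability p_keep."""
    coo = sp.coo_matrix(m.counts)
    data = rng.binomial(coo.data.astype(np.int64), p_keep)
    thinned = sp.coo_matrix((data, (coo.row, coo.col)), shape=coo.shape)
    thinned.eliminate_zeros()
    return CountMatrix(genes=list(m.genes), cells=list(m.cells), counts=sp.csr_matrix(thinned), cell_meta=m.cell_meta)


def match_subsample(a: CountMatrix, b: CountMatrix, seed: int = 0) -> MatchedPair:
    """Match two conditions on cell count and average molecules per cell.

    The larger condition's cells are subsampled without replacement to the
    smaller's count; then the deeper condition's count entries are thinned
    binomially with p = shallow_average / deep_average. Already-matched
    pairs pass through unchanged (idempotent).
    """
    if a.n_cells == 0 or b.n_cells == 0:
        raise ValueError("cannot match a zero-cell condition")
    if a.genes != b.genes:
        raise ValueError("conditions must share a gene universe")
    rng = np.random.default_rng(seed)

    n = min(a.n_cells, b.n_cells)
    dropped_a = a.n_cells - n
    dropped_b = b.n_cells - n
    if dropped_a:
        a = a.subset_cells(np.sort(rng.choice(a.n_cells, size=n, replace=False)))
    if dropped_b:
        b = b.subset_cells(np.sort(rng.choice(b.n_cells, size=n, replace=False)))

    avg_a = a.cell_totals().mean()
    avg_b = b.cell_totals().mean()
    thinned = "none"
    p_keep = 1.0
    if avg_a > avg_b:
        p_keep = avg_b / avg_a
        if p_keep < 1.0:
            a = _thin(a, p_keep, rng)
            thinned = "a"
    elif avg_b > avg_a:
        p_keep = avg_a / avg_b
        if p_keep < 1.0:
            b = _thin(b, p_keep, rng)
            thinned = "b"
    logger.info(
        "matched %d cells/condition; dropped %d/%d; thinned %s with p=%.4f",
        n, dropped_a, dropped_b, thinned, p_keep,
    )
    return MatchedPair(a=a, b=b, cells_dropped_a=dropped_a, cells_dropped_b=dropped_b,
                       thinning_p=p_keep, thinned=thinned, seed=seed)


def normalize_counts(m: CountMatrix) -> pd.DataFrame:
    """Median-scaled library-size normalization (genes x cells).

    Per-cell size factor = cell total / median cell total; normalized value
    = count / size factor. Zero-total cells are removed with a warning.
    """
    totals = m.cell_totals().astype(float)
    if totals.sum() == 0:
        raise ValueError("all-zero count matrix cannot be normalized")
    keep = totals > 0
    if not keep.all():
        logger.warning("removing %d zero-total cells before normalization", (~keep).sum())
        m = m.subset_cells(keep)
        totals = totals[keep]
    sf = totals / np.median(totals)
    x = np.asarray(m.counts.todense(), dtype=float) / sf
    return pd.DataFrame(x, index=m.genes, columns=m.cells)


def mwu_de(
    pair: MatchedPair,
    pseudocount: float = 0.1,
    method: str = "asymptotic",
) -> pd.DataFrame:
    """Per-gene two-sided Mann-Whitney U test between matched conditions.

    Values are median-scaled normalized counts. Genes with zero counts in
    both conditions are excluded (logged). log2FC = log2((mean_A + eps) /
    (mean_B + eps)); q is the Benjamini-Hochberg adjustment over all tested
    genes. ``method`` is passed to scipy ("asymptotic" = tie-corrected
    normal approximation with continuity correction; "exact" for tiny n).
    """
    if pair.a.n_cells < 2 or pair.b.n_cells < 2:
        raise ValueError("need >= 2 cells per condition")
    xa = normalize_counts(pair.a)
    xb = normalize_counts(pair.b)
    va, vb = xa.to_numpy(), xb.to_numpy()

    detected = (va.sum(axis=1) + vb.sum(axis=1)) > 0
    n_dropped = int((~detected).sum())
    if n_dropped:
        logger.info("excluding %d genes with zero counts in both conditions", n_dropped)
    va, vb = va[detected], vb[detected]
    genes = [g for g, d in zip(pair.a.genes, detected) if d]

    res = scipy.stats.mannwhitneyu(va, vb, axis=1, alternative="two-sided", method=method)
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), 1.0, p)  # all-tied genes: no evidence
    u = np.asarray(res.statistic, dtype=float)
    q = multipletests(p, method="fdr_bh")[1]

    mean_a = va.mean(axis=1)
    mean_b = vb.mean(axis=1)
    lfc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    return pd.DataFrame(
        {"log2fc": lfc, "u_stat": u, "p": p, "q": q, "mean_a": mean_a, "mean_b": mean_b},
        index=pd.Index(genes, name="gene"),
    )


def derive_consistent_signature(
    tables: list[pd.DataFrame],
    lfc_thresh: float = 1.0,
    q_thresh: float = 0.05,
    min_support: int = 3,
) -> DerivedSignature:
    """Consistency-rule signature over multiple pairwise comparisons.

    A gene enters the up list when (log2FC > lfc_thresh and q < q_thresh)
    in at least ``min_support`` of the supplied tables, and the down list
    symmetrically with log2FC < -lfc_thresh. A gene qualifying for both
    lists (possible with mixed directions across tables) is excluded and
    logged. Tables with differing gene universes are intersected with a
    warning.
    """
    if len(tables) < min_support:
        raise ValueError(f"need >= {min_support} tables, got {len(tables)}")
    common = tables[0].index
    for t in tables[1:]:
        common = common.intersection(t.index)
    if any(len(t) != len(common) for t in tables):
        logger.warning("tables disagree on gene universe; intersected to %d genes", len(common))

    support_up = pd.Series(0, index=common, dtype=int)
    support_down = pd.Series(0, index=common, dtype=int)
    for t in tables:
        t = t.loc[common]
        sig = t["q"] < q_thresh
        support_up += ((t["log2fc"] > lfc_thresh) & sig).astype(int)
        support_down += ((t["log2fc"] < -lfc_thresh) & sig).astype(int)

    up_mask = support_up >= min_support
    down_mask = support_down >= min_support
    conflict = up_mask & down_mask
    if conflict.any():
        logger.warning("%d genes met both up and down rules; excluded", conflict.sum())
        up_mask &= ~conflict
        down_mask &= ~conflict
    return DerivedSignature(
        up=list(common[up_mask]),
        down=list(common[down_mask]),
        support_up=support_up,
        support_down=support_down,
    )
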