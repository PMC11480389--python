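"""Preranked gene-set enrichment analysis.

Genes are ranked by a signed metric — either the log2 fold change of a
differential-expression table or sign(log2FC) * (-log10 q) — and each gene
set is tested with the weighted Kolmogorov-Smirnov running-sum statistic:
the running sum gains |metric|^weight (normalized over hits) at each set
member and loses 1/(n_genes - set_size) at each non-member; the enrichment
score (ES) is the extremum of largest magnitude. Significance comes from a
gene-set permutation null: random same-size sets drawn from the ranked
universe. NES divides ES by the mean |null ES| of matching sign; the FDR is
the standard positive/negative-pool ratio of null to observed NES tail
fractions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gliostate.io import GeneSetCollection

logger = logging.getLogger(__name__)

Q_FLOOR = 1e-300


@dataclass
class RankedList:
    genes: list[str]
    metric: np.ndarray  # descending
    mode: str

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.metric):
            raise ValueError("genes and metric lengths differ")
        if not np.all(np.isfinite(self.metric)):
            raise ValueError("ranking metric must be finite")


def rank_genes(table: pd.DataFrame, mode: str = "log2fc") -> RankedList:
    """Build a ranked gene list from a differential-expression table.

    mode="log2fc" ranks by the log2 fold change; mode="signed_logq" by
    sign(log2FC) * (-log10 q), with q floored at 1e-300. Ties are broken by
    gene identifier so the order is deterministic.
    """
    if table.empty:
        raise ValueError("empty differential-expression table")
    if mode == "log2fc":
        metric = table["log2fc"].astype(float)
    elif mode == "signed_logq":
        q = np.maximum(table["q"].astype(float), Q_FLOOR)
        metric = np.sign(table["log2fc"]) * (-np.log10(q))
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    df = pd.DataFrame({"metric": np.asarray(metric), "gene": table.index.astype(str)}).reset_index(drop=True)
    df = df.sort_values(["metric", "gene"], ascending=[False, True], kind="stable")
    return RankedList(genes=list(df["gene"]), metric=df["metric"].to_numpy(), mode=mode)


def enrichment_score(
    ranked: RankedList,
    gene_set: list[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Weighted KS running-sum enrichment score of one gene set.

    Returns (ES, running sum over list positions). Weight 0 reduces to the
    unweighted KS statistic (difference of hit and miss empirical CDFs).
    When the positive and negative extrema tie in magnitude (to 1e-12
    relative) the positive one is reported.
    """
    hits = np.isin(ranked.genes, list(gene_set))
    n_hits = int(hits.sum())
    n = len(ranked.genes)
    if n_hits == 0 or n_hits == n:
        raise ValueError("gene set must hit a strict, non-empty subset of the ranked list")
    running = _running_sum(ranked.metric, hits, weight)
    es = _extremum(float(running.max()), float(running.min()))
    return float(es), running


def _extremum(pos: float, neg: float) -> float:
    """Signed extremum of a running sum; positive wins a magnitude tie."""
    return pos if pos >= -neg - 1e-12 * max(1.0, abs(pos)) else neg


def _running_sum(metric: np.ndarray, hits: np.ndarray, weight: float) -> np.ndarray:
    w = np.abs(metric) ** weight
    w_hit = np.where(hits, w, 0.0)
    total = w_hit.sum()
    if total == 0.0:  # all hit metrics zero: fall back to equal increments
        w_hit = hits.astype(float)
        total = w_hit.sum()
    miss_dec = 1.0 / (hits.size - hits.sum())
    steps = w_hit / total - np.where(hits, 0.0, miss_dec)
    return np.cumsum(steps)


def _null_es(metric: np.ndarray, set_size: int, n_perm: int, weight: float, rng: np.random.Generator) -> np.ndarray:
    """ES of n_perm random same-size sets drawn from the ranked universe."""
    n = metric.size
    w = np.abs(metric) ** weight
    # random subset per permutation via partial argsort of uniform keys
    keys = rng.random((n_perm, n))
    idx = np.argpartition(keys, set_size, axis=1)[:, :set_size]
    hit = np.zeros((n_perm, n), dtype=bool)
    np.put_along_axis(hit, idx, True, axis=1)

    w_hit = np.where(hit, w[None, :], 0.0)
    totals = w_hit.sum(axis=1)
    zero = totals == 0.0
    if zero.any():
        w_hit[zero] = hit[zero].astype(float)
        totals[zero] = set_size
    miss_dec = 1.0 / (n - set_size)
    steps = w_hit / totals[:, None] - np.where(hit, 0.0, miss_dec)
    run = np.cumsum(steps, axis=1)
    pos = run.max(axis=1)
    neg = run.min(axis=1)
    return np.where(pos >= -neg - 1e-12 * np.maximum(1.0, np.abs(pos)), pos, neg)


def _leading_edge(ranked: RankedList, gene_set: list[str], running: np.ndarray, es: float) -> list[str]:
    hits = np.isin(ranked.genes, list(gene_set))
    peak = int(np.argmax(running)) if es >= 0 else int(np.argmin(running))
    if es >= 0:
        idx = np.flatnonzero(hits[: peak + 1])
    else:
        idx = peak + np.flatnonzero(hits[peak:])
    return [ranked.genes[i] for i in idx]


def gsea_preranked(
    ranked: RankedList,
    sets: GeneSetCollection,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
    min_size: int = 5,
    max_size: int = 2000,
) -> pd.DataFrame:
    """Preranked GSEA over a gene-set collection.

    Per set: ES, permutation NES (ES over mean same-sign |null ES|),
    nominal p (same-sign null tail with add-one correction), FDR q
    (positive/negative-pool procedure), leading-edge genes and post-
    intersection size. Sets outside [min_size, max_size] after intersection
    with the ranked universe are skipped with a warning.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    rng = np.random.default_rng(seed)
    universe = set(ranked.genes)

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name in sets:
        members = [g for g in sets[name] if g in universe]
        if not min_size <= len(members) <= max_size or len(members) == len(universe):
            logger.warning("set %s skipped: size %d outside [%d, %d]", name, len(members), min_size, max_size)
            continue
        es, running = enrichment_score(ranked, members, weight=weight)
        null = _null_es(ranked.metric, len(members), n_perm, weight, rng)

        pos, neg = null[null >= 0], null[null < 0]
        mean_pos = np.abs(pos).mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        nes = es / (mean_pos if es >= 0 else mean_neg)
        same = pos if es >= 0 else neg
        p = (1 + (np.abs(same) >= abs(es)).sum()) / (1 + same.size) if same.size else 1.0

        null_nes = np.where(null >= 0, null / mean_pos, null / mean_neg)
        null_nes_pool.append(null_nes[np.isfinite(null_nes)])
        rows.append(
            {
                "set": name,
                "es": es,
                "nes": float(nes),
                "p": float(p),
                "size": len(members),
                "leading_edge": ",".join(_leading_edge(ranked, members, running, es)),
            }
        )

    if not rows:
        logger.warning("no gene set passed the size filter")
        return pd.DataFrame(columns=["set", "es", "nes", "p", "fdr", "size", "leading_edge"]).set_index("set")

    res = pd.DataFrame(rows).set_index("set")
    pooled = np.concatenate(null_nes_pool)
    obs = res["nes"].to_numpy()
    fdr = np.empty(len(res))
    for i, nes in enumerate(obs):
        if nes >= 0:
            null_tail = (pooled[pooled >= 0] >= nes).mean() if (pooled >= 0).any() else 1.0
            obs_tail = (obs[obs >= 0] >= nes).mean()
        else:
            null_tail = (pooled[pooled < 0] <= nes).mean() if (pooled < 0).any() else 1.0
            obs_tail = (obs[obs < 0] <= nes).mean()
        fdr[i] = min(1.0, null_tail / obs_tail) if obs_tail > 0 else 1.0
    res["fdr"] = fdr
    return res[["es", "nes", "p", "fdr", "size", "leading_edge"]]
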