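"""Gene-signature scoring, lineage-state and cell-cycle assignment.

Two scoring schemes:

* ``binned_control_score`` — the control-gene scheme: all analyzed genes
  are binned by aggregate expression, each signature gene draws control
  genes from its own bin, and the cell's score is the mean expression of
  the signature minus the mean expression of the pooled controls. Scores
  are centered near zero for a signature with no coherent effect.
* ``recovery_auc_score`` — the recovery-curve AUC scheme: genes are ranked
  by expression within each cell and the score is the normalized area
  under the curve of signature-gene recovery over the top fraction of
  ranks (rank-based, hence invariant to monotone transforms of
  expression).

Lineage is the argmax over the six lineage signatures (MES1, MES2, AC,
NPC1, NPC2, OPC) with MES1/2 and NPC1/2 aggregated to MES and NPC; cycle
phase is G0 when both the G1/S and G2/M scores are non-positive, otherwise
the larger of the two (G0 = quiescent, G1/S or G2/M = proliferative).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.stats

from gliostate.io import CountMatrix

logger = logging.getLogger(__name__)

LINEAGE_SIGNATURES = ("MES1", "MES2", "AC", "OPC", "NPC1", "NPC2")
LINEAGE_AGGREGATION = {"MES1": "MES", "MES2": "MES", "NPC1": "NPC", "NPC2": "NPC", "AC": "AC", "OPC": "OPC"}


def log_normalize(m: CountMatrix) -> pd.DataFrame:
    """log2(CP10K + 1) normalized expression, genes x cells."""
    totals = m.cell_totals().astype(float)
    totals[totals == 0] = 1.0
    expr = np.asarray(m.counts.todense()) / totals * 1e4
    return pd.DataFrame(np.log2(expr + 1.0), index=m.genes, columns=m.cells)


def binned_control_score(
    norm_expr: pd.DataFrame,
    gene_set: list[str],
    n_bins: int = 100,
    n_ctrl: int = 100,
    seed: int = 0,
) -> pd.Series:
    """Signature score as signature mean minus bin-matched control mean.

    Genes are ranked by aggregate expression (mean of normalized expression
    across cells) and cut into ``n_bins`` equal-size rank bins; for each
    signature gene, ``n_ctrl`` control genes are sampled with replacement
    from its bin. Signature genes absent from the matrix are dropped with a
    warning; if none remain it is an error.
    """
    if n_bins < 1 or n_ctrl < 1:
        raise ValueError("n_bins and n_ctrl must be >= 1")
    present = [g for g in gene_set if g in norm_expr.index]
    missing = len(gene_set) - len(present)
    if missing:
        logger.warning("%d/%d signature genes absent from matrix, dropped", missing, len(gene_set))
    if not present:
        raise ValueError("no signature gene present in the matrix")

    aggregate = norm_expr.mean(axis=1)
    order = np.argsort(aggregate.to_numpy(), kind="stable")
    bin_of = np.empty(len(order), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bin_of[chunk] = b
    bin_members = {b: np.flatnonzero(bin_of == b) for b in range(n_bins)}
    gene_pos = {g: i for i, g in enumerate(norm_expr.index)}

    rng = np.random.default_rng(seed)
    ctrl_idx: list[np.ndarray] = []
    for g in present:
        members = bin_members[bin_of[gene_pos[g]]]
        ctrl_idx.append(rng.choice(members, size=n_ctrl, replace=True))
    ctrl = np.concatenate(ctrl_idx)

    x = norm_expr.to_numpy()
    sig_mean = x[[gene_pos[g] for g in present]].mean(axis=0)
    ctrl_mean = x[ctrl].mean(axis=0)
    return pd.Series(sig_mean - ctrl_mean, index=norm_expr.columns, name="score")


def recovery_auc_score(
    counts: CountMatrix | pd.DataFrame,
    gene_set: list[str],
    top_frac: float = 0.05,
    seed: int = 0,
) -> pd.Series:
    """Recovery-curve AUC of a gene set within each cell's expression ranking.

    Genes are ranked per cell by decreasing expression (ties broken by a
    seeded random jitter); the step recovery curve counts signature hits
    over the top ``ceil(top_frac * n_genes)`` ranks, and the score is the
    area under it normalized by the maximum attainable area, in [0, 1].
    """
    if not 0.0 < top_frac <= 1.0:
        raise ValueError("top_frac must be in (0, 1]")
    if isinstance(counts, CountMatrix):
        expr = pd.DataFrame(np.asarray(counts.counts.todense(), dtype=float), index=counts.genes, columns=counts.cells)
    else:
        expr = counts
    hits = expr.index.isin(gene_set)
    if not hits.any():
        raise ValueError("no signature gene present in the matrix")

    n_genes, n_cells = expr.shape
    k = int(np.ceil(top_frac * n_genes))
    n_set = int(hits.sum())
    rng = np.random.default_rng(seed)
    jitter = rng.random((n_genes, n_cells)) * 1e-9
    # ranks[g, c] = 0-based rank of gene g in cell c, descending expression
    order = np.argsort(-(expr.to_numpy() + jitter), axis=0, kind="stable")
    ranks = np.empty_like(order)
    np.put_along_axis(ranks, order, np.arange(n_genes)[:, None], axis=0)

    hit_ranks = ranks[hits]  # n_set x n_cells
    # AUC of the step recovery curve over ranks 1..k equals
    # sum over hits of (k - rank) for ranks < k
    contrib = np.clip(k - hit_ranks, 0, None)
    auc_raw = contrib.sum(axis=0)
    best = np.arange(min(n_set, k))
    auc_max = (k - best).sum()
    return pd.Series(auc_raw / auc_max, index=expr.columns, name="auc")


def score_signatures(
    counts: CountMatrix,
    signatures: dict[str, list[str]],
    method: str = "binned_control",
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Score every signature for every cell; returns cells x signatures."""
    if method == "binned_control":
        norm = log_normalize(counts)
        cols = {name: binned_control_score(norm, genes, seed=seed, **kwargs) for name, genes in signatures.items()}
    elif method == "recovery_auc":
        cols = {name: recovery_auc_score(counts, genes, seed=seed, **kwargs) for name, genes in signatures.items()}
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    return pd.DataFrame(cols)


def assign_lineage(score_matrix: pd.DataFrame) -> pd.Series:
    """Lineage call per cell: argmax over the six lineage signature scores.

    MES1/MES2 and NPC1/NPC2 calls are aggregated to MES and NPC. Ties are
    broken by the fixed signature order (MES1, MES2, AC, OPC, NPC1, NPC2)
    and counted in the log.
    """
    missing = [s for s in LINEAGE_SIGNATURES if s not in score_matrix.columns]
    if missing:
        raise ValueError(f"missing lineage signature columns: {missing}")
    scores = score_matrix[list(LINEAGE_SIGNATURES)].to_numpy()
    best = scores.argmax(axis=1)  # first maximum = fixed-order tie-break
    n_ties = int((scores == scores.max(axis=1, keepdims=True)).sum(axis=1).max() > 1)
    if n_ties:
        tied = ((scores == scores.max(axis=1, keepdims=True)).sum(axis=1) > 1).sum()
        logger.info("%d cells had tied lineage scores; fixed-order tie-break applied", tied)
    raw = np.array(LINEAGE_SIGNATURES)[best]
    return pd.Series([LINEAGE_AGGREGATION[s] for s in raw], index=score_matrix.index, name="lineage")


def classify_cycle(g1s_scores: pd.Series, g2m_scores: pd.Series) -> pd.DataFrame:
    """Phase per cell: G0 if both scores <= 0, else the larger phase.

    Returns a table with columns ``phase`` and ``proliferative``
    (proliferative iff phase != G0).
    """
    g1s = pd.Series(g1s_scores)
    g2m = pd.Series(g2m_scores).reindex(g1s.index)
    phase = np.where(
        np.maximum(g1s, g2m) <= 0,
        "G0",
        np.where(g1s >= g2m, "G1/S", "G2/M"),
    )
    return pd.DataFrame({"phase": phase, "proliferative": phase != "G0"}, index=g1s.index)


def score_correlations(score_matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise tie-aware Spearman correlation between signature scores.

    Constant score vectors yield NaN (undefined), never a silent 0.
    """
    if len(score_matrix) < 3:
        raise ValueError("need >= 3 cells for rank correlation")
    cols = list(score_matrix.columns)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        va = score_matrix[a].to_numpy()
        if np.ptp(va) == 0:
            out.loc[a, :] = np.nan
            out.loc[:, a] = np.nan
            continue
        for b in cols[i + 1 :]:
            vb = score_matrix[b].to_numpy()
            if np.ptp(vb) == 0:
                rho = np.nan
            else:
                rho = scipy.stats.spearmanr(va, vb).statistic
            out.loc[a, b] = rho
            out.loc[b, a] = rho
    return out
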