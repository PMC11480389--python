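"""Malignant-cell identification and chromosome copy-number estimation.

Aneuploid glioma cells are separated from diploid microenvironment cells by
the *malignancy score*: the per-cell log2 ratio of the average normalized
expression of genes on an amplified chromosome (Chr7 in IDH-wild-type
glioblastoma; an unaltered chromosome in the IDH-mutant variant) to that of
genes on a deleted chromosome (Chr10, or Chr1). A two-component Gaussian
mixture is fit to the score distribution and the decision threshold placed
1.96 standard deviations below the mean of the higher-mean component; cells
whose putative (cluster-derived) identity disagrees with the threshold side
are discarded as non-malignant or potential multiplets.

Average chromosome copy number is estimated from paired tumor/germline WGS
read counts by the ratio-of-ratios: per-chromosome read fractions in tumor
divided by those in germline, normalized by the median ratio across somatic
chromosomes, times two.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gliostate.io import CountMatrix

logger = logging.getLogger(__name__)

SD_FLOOR = 1e-3
SEX_CHROMOSOMES = frozenset({"X", "Y", "chrX", "chrY"})


@dataclass
class MalignancyScoreVector:
    scores: pd.Series  # index = barcode
    amp_chrom: str
    del_chrom: str
    pseudocount: float


@dataclass
class MixtureFit:
    """Two-component univariate Gaussian mixture; component 2 has the higher mean."""

    weights: tuple[float, float]
    means: tuple[float, float]
    sds: tuple[float, float]
    log_likelihood: float
    n_iter: int
    converged: bool
    unimodal: bool


@dataclass
class MalignancyCall:
    calls: pd.DataFrame  # columns: score, putative, label
    threshold: float


def _cp10k(m: CountMatrix) -> np.ndarray:
    totals = m.cell_totals().astype(float)
    totals[totals == 0] = 1.0
    return np.asarray(m.counts.todense()) / totals * 1e4


def malignancy_score(
    m: CountMatrix,
    annotation: dict[str, str],
    amp_chrom: str,
    del_chrom: str,
    pseudocount: float = 0.1,
) -> MalignancyScoreVector:
    """Per-cell log2 ratio of amplified- to deleted-chromosome expression.

    Counts are normalized to counts-per-10,000 per cell; the score is
    log2((mean CP10K over amp-chromosome genes + eps) /
    (mean CP10K over del-chromosome genes + eps)) with eps = pseudocount.
    The score is invariant to per-cell library size by construction.
    """
    chrom = np.array([annotation.get(g, "") for g in m.genes])
    amp_idx = np.flatnonzero(chrom == amp_chrom)
    del_idx = np.flatnonzero(chrom == del_chrom)
    if amp_idx.size == 0:
        raise ValueError(f"no genes annotated to chromosome {amp_chrom!r} present in matrix")
    if del_idx.size == 0:
        raise ValueError(f"no genes annotated to chromosome {del_chrom!r} present in matrix")
    expr = _cp10k(m)
    amp_mean = expr[amp_idx].mean(axis=0)
    del_mean = expr[del_idx].mean(axis=0)
    scores = np.log2((amp_mean + pseudocount) / (del_mean + pseudocount))
    return MalignancyScoreVector(
        scores=pd.Series(scores, index=m.cells, name="malignancy_score"),
        amp_chrom=amp_chrom,
        del_chrom=del_chrom,
        pseudocount=pseudocount,
    )


def fit_two_gaussian(
    scores,
    tol: float = 1e-8,
    max_iter: int = 1000,
) -> MixtureFit:
    """EM fit of a two-component Gaussian mixture to a score vector.

    Initialization is deterministic: the scores are split at their median
    and each half seeds one component (mean/sd of the half, weight 0.5).
    Convergence when the log-likelihood improves by less than ``tol``.
    Standard deviations are floored at 1e-3 to prevent singular components.
    The fit is flagged ``unimodal`` when the component means are closer
    than half the larger sd.
    """
    x = np.asarray(scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise ValueError(f"need >=10 finite scores to fit a mixture, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("degenerate score distribution (zero variance); bypass thresholding")

    med = np.median(x)
    lo, hi = x[x <= med], x[x > med]
    if hi.size == 0:  # >half the mass exactly at the median
        lo, hi = x[x < med], x[x >= med]
    mu = np.array([lo.mean(), hi.mean()])
    sd = np.maximum([lo.std(), hi.std()], SD_FLOOR)
    w = np.array([0.5, 0.5])

    prev_ll = -np.inf
    ll = prev_ll
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step in log space for stability
        log_pdf = (
            -0.5 * ((x[:, None] - mu[None, :]) / sd[None, :]) ** 2
            - np.log(sd[None, :])
            - 0.5 * np.log(2 * np.pi)
            + np.log(w[None, :])
        )
        m = log_pdf.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(log_pdf - m).sum(axis=1))
        ll = lse.sum()
        assert ll >= prev_ll - 1e-9 * max(1.0, abs(prev_ll)), "EM log-likelihood decreased"
        resp = np.exp(log_pdf - lse[:, None])
        if ll - prev_ll < tol and np.isfinite(prev_ll):
            converged = True
            break
        prev_ll = ll
        # M-step
        nk = resp.sum(axis=0)
        w = nk / x.size
        mu = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - mu[None, :]) ** 2).sum(axis=0) / nk
        sd = np.maximum(np.sqrt(var), SD_FLOOR)

    order = np.argsort(mu)
    mu, sd, w = mu[order], sd[order], w[order]
    unimodal = abs(mu[1] - mu[0]) < 0.5 * max(sd)
    if unimodal:
        logger.warning("mixture components overlap (|mu2-mu1| < 0.5*max sd); distribution may be unimodal")
    return MixtureFit(
        weights=(float(w[0]), float(w[1])),
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        log_likelihood=float(ll),
        n_iter=it,
        converged=converged,
        unimodal=bool(unimodal),
    )


def malignancy_threshold(fit: MixtureFit) -> float:
    """Decision threshold: 1.96 SD below the mean of the higher-mean component."""
    return fit.means[1] - 1.96 * fit.sds[1]


def classify_cells(
    scores: pd.Series,
    threshold: float,
    putative_labels: pd.Series,
) -> MalignancyCall:
    """Reconcile putative (cluster-derived) identities with the score threshold.

    putative_tumor cells at or above the threshold are called tumor;
    putative_non_tumor cells below it are called non_tumor; every cell whose
    putative identity disagrees with its threshold side is discarded as
    non-malignant or a potential multiplet. A score exactly at the threshold
    counts as above it.
    """
    scores = pd.Series(scores)
    putative = pd.Series(putative_labels).reindex(scores.index)
    if putative.isna().any():
        missing = list(putative.index[putative.isna()])[:5]
        raise ValueError(f"missing putative label for cells {missing}")
    bad = ~putative.isin(["putative_tumor", "putative_non_tumor"])
    if bad.any():
        raise ValueError(f"invalid putative labels: {sorted(putative[bad].unique())}")

    above = scores >= threshold
    label = np.where(
        (putative == "putative_tumor") & above,
        "tumor",
        np.where((putative == "putative_non_tumor") & ~above, "non_tumor", "discarded"),
    )
    calls = pd.DataFrame({"score": scores, "putative": putative, "label": label})
    counts = calls["label"].value_counts().to_dict()
    logger.info("malignancy calls: %s (threshold %.4f)", counts, threshold)
    return MalignancyCall(calls=calls, threshold=float(threshold))


def call_malignant(
    m: CountMatrix,
    annotation: dict[str, str],
    amp_chrom: str,
    del_chrom: str,
    putative_labels: pd.Series,
    pseudocount: float = 0.1,
    tol: float = 1e-8,
    max_iter: int = 1000,
    fit_on: str = "all",
) -> tuple[MalignancyCall, MixtureFit, MalignancyScoreVector]:
    """Score, fit, threshold and classify in one pass.

    ``fit_on`` selects the cells used for the mixture fit: "all" (default)
    or "putative_tumor" to restrict to the putatively malignant cells.
    """
    sv = malignancy_score(m, annotation, amp_chrom, del_chrom, pseudocount)
    if fit_on == "putative_tumor":
        fit_scores = sv.scores[pd.Series(putative_labels).reindex(sv.scores.index) == "putative_tumor"]
    elif fit_on == "all":
        fit_scores = sv.scores
    else:
        raise ValueError(f"fit_on must be 'all' or 'putative_tumor', got {fit_on!r}")
    fit = fit_two_gaussian(fit_scores, tol=tol, max_iter=max_iter)
    call = classify_cells(sv.scores, malignancy_threshold(fit), putative_labels)
    return call, fit, sv


def chromosome_copy_number(
    tumor_reads: pd.Series,
    germline_reads: pd.Series,
    sex_chromosomes: frozenset[str] = SEX_CHROMOSOMES,
) -> pd.Series:
    """Average chromosome copy number from paired read-count tables.

    ratio_c = (tumor_c / sum tumor) / (germline_c / sum germline);
    CN_c = 2 * ratio_c / median(ratio over somatic chromosomes). The result
    is invariant to total-depth scaling of either table, and the median
    somatic chromosome sits at CN 2 by construction.
    """
    tumor_reads = pd.Series(tumor_reads, dtype=float)
    germline_reads = pd.Series(germline_reads, dtype=float)
    if set(tumor_reads.index) != set(germline_reads.index):
        raise ValueError("tumor and germline tables cover different chromosome sets")
    germline_reads = germline_reads.reindex(tumor_reads.index)
    if (germline_reads <= 0).any():
        zero = list(germline_reads.index[germline_reads <= 0])
        raise ValueError(f"non-positive germline read count for chromosomes {zero}")
    ratio = (tumor_reads / tumor_reads.sum()) / (germline_reads / germline_reads.sum())
    somatic = [c for c in ratio.index if c not in sex_chromosomes]
    cn = 2.0 * ratio / np.median(ratio[somatic])
    cn.name = "copy_number"
    return cn
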