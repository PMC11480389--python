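"""Synthetic scRNA-seq cohorts with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every module can be validated against known truth:

* tumor cells carry chromosome-level dosage shifts (amplified/deleted
  chromosomes scale gene means by copy_number/2), non-tumor cells are
  diploid;
* tumor cells belong to one of four lineage states (MES/AC/NPC/OPC), each
  boosting its own disjoint signature gene set, plus G1/S / G2/M cycling
  subsets on top of the lineage;
* treatment removes cells of a state with a state-specific probability
  (state-selective depletion);
* hashtag (HTO) count matrices with singlets, doublets and negatives;
* paired tumor/germline per-chromosome WGS read-count tables.

Counts are negative binomial: for mean m and size r (inverse dispersion),
a Gamma(r, m/r) rate is drawn per entry and then Poisson-sampled. All
outputs are bit-reproducible from ``SimParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from gliostate.io import CountMatrix

STATE_NAMES = ("MES", "AC", "NPC", "OPC")
CYCLE_NAMES = ("G1/S", "G2/M")


def _default_chromosomes(n_genes: int = 2000) -> dict[str, int]:
    """22 somatic chromosomes with near-equal gene counts summing to n_genes."""
    names = [str(i) for i in range(1, 23)]
    base = n_genes // 22
    extra = n_genes - base * 22
    return {name: base + (1 if i < extra else 0) for i, name in enumerate(names)}


@dataclass
class SimParams:
    """Ground-truth parameters of the synthetic cohort.

    Defaults describe the standard study conditions used throughout the
    test suite: 2,000 genes on 22 somatic chromosomes, 2,000 cells per
    sample, chromosome 7 amplified to 4 copies and chromosome 10 reduced to
    1 copy in tumor cells, four lineage states with 50-gene signatures
    boosted 3-fold, 30% cycling cells, and 60% treatment depletion of the
    AC state.
    """

    n_genes: int = 2000
    n_cells: int = 2000
    chromosomes: dict[str, int] | None = None
    copy_number: dict[str, float] = field(default_factory=lambda: {"7": 4.0, "10": 1.0})
    tumor_fraction: float = 0.75
    gene_mean_log_scale: float = 1.0
    mean_library_size: float = 5000.0
    library_log_scale: float = 0.3
    nb_size: float = 10.0
    signature_size: int = 50
    state_boost: float = 3.0
    state_proportions: dict[str, float] = field(
        default_factory=lambda: {"MES": 0.25, "AC": 0.25, "NPC": 0.25, "OPC": 0.25}
    )
    cycle_boost: float = 3.0
    cycle_proportions: dict[str, float] = field(
        default_factory=lambda: {"G0": 0.70, "G1/S": 0.15, "G2/M": 0.15}
    )
    depletion: dict[str, float] = field(default_factory=lambda: {"AC": 0.6})
    # HTO layer
    n_tags: int = 4
    doublet_rate: float = 0.05
    hto_signal_mean: float = 200.0
    hto_background_mean: float = 5.0
    hto_nb_size: float = 5.0
    # WGS layer
    wgs_total_reads: float = 1_000_000.0
    seed: int = 17

    def __post_init__(self) -> None:
        if self.chromosomes is None:
            self.chromosomes = _default_chromosomes(self.n_genes)
        if sum(self.chromosomes.values()) != self.n_genes:
            raise ValueError("chromosome gene counts must sum to n_genes")
        if abs(sum(self.state_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("state proportions must sum to 1")
        if abs(sum(self.cycle_proportions.values()) - 1.0) > 1e-9:
            raise ValueError("cycle proportions must sum to 1")
        if self.state_boost <= 0 or self.cycle_boost <= 0:
            raise ValueError("fold boosts must be > 0")
        for s, p in self.depletion.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"depletion[{s}] must be in [0,1]")
        if self.hto_signal_mean <= self.hto_background_mean:
            raise ValueError("HTO signal mean must exceed background mean (inseparable by construction)")


@dataclass
class SyntheticTruth:
    """Planted ground truth for one generated cohort.

    cells_vehicle / cells_treated: per-cell tables (index = barcode) with
    columns tumor (bool), state, phase, proliferative (bool).
    genes: per-gene table with chromosome and signature membership.
    copy_number: chromosome -> true average copy number in tumor cells.
    signatures: signature name -> list of member gene identifiers.
    """

    cells_vehicle: pd.DataFrame
    cells_treated: pd.DataFrame
    genes: pd.DataFrame
    copy_number: dict[str, float]
    signatures: dict[str, list[str]]


def _gene_table(p: SimParams, rng: np.random.Generator) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    genes = [f"G{i:05d}" for i in range(p.n_genes)]
    chrom = np.repeat(list(p.chromosomes.keys()), list(p.chromosomes.values()))
    altered = set(p.copy_number) - {c for c, cn in p.copy_number.items() if cn == 2.0}
    # signatures live on unaltered chromosomes so dosage and state effects
    # stay orthogonal in the planted truth
    eligible = np.flatnonzero(~np.isin(chrom, list(altered)))
    sig_names = list(STATE_NAMES) + list(CYCLE_NAMES)
    need = p.signature_size * len(sig_names)
    if need > eligible.size:
        raise ValueError("not enough genes on unaltered chromosomes for disjoint signatures")
    picked = rng.choice(eligible, size=need, replace=False)
    signatures = {
        name: np.sort(picked[i * p.signature_size : (i + 1) * p.signature_size])
        for i, name in enumerate(sig_names)
    }
    member = np.full(p.n_genes, "", dtype=object)
    for name, idx in signatures.items():
        member[idx] = name
    table = pd.DataFrame({"gene": genes, "chromosome": chrom, "signature": member}).set_index("gene")
    return table, signatures


def _nb_counts(mean: np.ndarray, size: float, rng: np.random.Generator) -> np.ndarray:
    lam = rng.gamma(shape=size, scale=mean / size)
    return rng.poisson(lam)


def _sample_cells(
    p: SimParams,
    n: int,
    prefix: str,
    base_mean: np.ndarray,
    gene_table: pd.DataFrame,
    signatures: dict[str, np.ndarray],
    rng: np.random.Generator,
) -> tuple[CountMatrix, pd.DataFrame]:
    tumor = rng.random(n) < p.tumor_fraction
    states = np.full(n, "none", dtype=object)
    n_tum = int(tumor.sum())
    state_names = list(p.state_proportions)
    states[tumor] = rng.choice(state_names, size=n_tum, p=list(p.state_proportions.values()))
    phases = np.full(n, "G0", dtype=object)
    phase_names = list(p.cycle_proportions)
    phases[tumor] = rng.choice(phase_names, size=n_tum, p=list(p.cycle_proportions.values()))

    lib = np.exp(rng.normal(0.0, p.library_log_scale, size=n))
    lib /= lib.mean()
    mean = np.outer(base_mean, lib)
    chrom = gene_table["chromosome"].to_numpy()
    for c, cn in p.copy_number.items():
        if cn != 2.0:
            rows = np.flatnonzero(chrom == c)
            mean[np.ix_(rows, np.flatnonzero(tumor))] *= cn / 2.0
    for s in STATE_NAMES:
        cols = np.flatnonzero(states == s)
        if cols.size:
            mean[np.ix_(signatures[s], cols)] *= p.state_boost
    for ph in CYCLE_NAMES:
        cols = np.flatnonzero(phases == ph)
        if cols.size:
            mean[np.ix_(signatures[ph], cols)] *= p.cycle_boost

    counts = _nb_counts(mean, p.nb_size, rng)
    barcodes = [f"{prefix}_{i:05d}" for i in range(n)]
    truth = pd.DataFrame(
        {
            "tumor": tumor,
            "state": states,
            "phase": phases,
            "proliferative": phases != "G0",
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    meta = pd.DataFrame({"condition": prefix.lower()}, index=truth.index)
    cm = CountMatrix(
        genes=list(gene_table.index),
        cells=barcodes,
        counts=sp.csr_matrix(counts),
        cell_meta=meta,
    )
    return cm, truth


def generate_cohort(p: SimParams) -> tuple[CountMatrix, CountMatrix, SyntheticTruth]:
    """Generate a matched vehicle/treated pair of samples with planted truth.

    The treated sample is drawn from the same generative process and then
    each cell of state ``s`` is removed with probability ``p.depletion[s]``,
    emulating state-selective drug-induced depletion.
    """
    rng = np.random.default_rng(p.seed)
    gene_table, signatures = _gene_table(p, rng)
    rel = np.exp(rng.normal(0.0, p.gene_mean_log_scale, size=p.n_genes))
    base_mean = rel / rel.sum() * p.mean_library_size

    vehicle, truth_v = _sample_cells(p, p.n_cells, "VEH", base_mean, gene_table, signatures, rng)
    treated_full, truth_t = _sample_cells(p, p.n_cells, "TRT", base_mean, gene_table, signatures, rng)

    drop_p = np.array([p.depletion.get(s, 0.0) for s in truth_t["state"]])
    keep = rng.random(len(drop_p)) >= drop_p
    treated = treated_full.subset_cells(keep)
    truth_t = truth_t.loc[keep]

    sig_genes = {name: [gene_table.index[i] for i in idx] for name, idx in signatures.items()}
    truth = SyntheticTruth(
        cells_vehicle=truth_v,
        cells_treated=truth_t,
        genes=gene_table,
        copy_number={c: p.copy_number.get(c, 2.0) for c in p.chromosomes},
        signatures=sig_genes,
    )
    return vehicle, treated, truth


def generate_hto(p: SimParams, cell_truth: pd.DataFrame | None = None) -> tuple[CountMatrix, pd.DataFrame]:
    """Generate a tags x cells hashtag count matrix with known identities.

    Singlets have their own tag at the signal mean and all others at the
    background mean; doublets (rate ``p.doublet_rate``) carry two tags at
    signal level. ``cell_truth`` supplies barcodes (its index); when omitted,
    ``p.n_cells`` synthetic barcodes are used.
    """
    if p.n_tags < 2:
        raise ValueError("need at least 2 HTO tags")
    rng = np.random.default_rng([p.seed, 1])
    if cell_truth is not None:
        barcodes = list(cell_truth.index)
    else:
        barcodes = [f"HTO_{i:05d}" for i in range(p.n_cells)]
    n = len(barcodes)
    tags = [f"tag{i + 1}" for i in range(p.n_tags)]

    primary = rng.integers(0, p.n_tags, size=n)
    is_doublet = rng.random(n) < p.doublet_rate
    secondary = (primary + rng.integers(1, p.n_tags, size=n)) % p.n_tags

    mean = np.full((p.n_tags, n), p.hto_background_mean, dtype=float)
    mean[primary, np.arange(n)] = p.hto_signal_mean
    dbl = np.flatnonzero(is_doublet)
    mean[secondary[dbl], dbl] = p.hto_signal_mean
    if p.hto_background_mean == 0.0:
        counts = np.zeros_like(mean, dtype=np.int64)
        signal = mean > 0
        counts[signal] = _nb_counts(mean[signal], p.hto_nb_size, rng)
    else:
        counts = _nb_counts(mean, p.hto_nb_size, rng)

    truth = pd.DataFrame(
        {
            "tag": [tags[t] for t in primary],
            "doublet": is_doublet,
            "second_tag": [tags[secondary[i]] if is_doublet[i] else "" for i in range(n)],
        },
        index=pd.Index(barcodes, name="barcode"),
    )
    hto = CountMatrix(genes=tags, cells=barcodes, counts=sp.csr_matrix(counts))
    return hto, truth


def generate_wgs_readcounts(
    p: SimParams, noise: bool = False
) -> tuple[pd.Series, pd.Series, dict[str, float]]:
    """Generate paired tumor/germline per-chromosome read-count tables.

    Germline reads are proportional to chromosome gene counts (diploid);
    tumor reads are additionally scaled by copy_number/2. With ``noise``,
    counts are Poisson-sampled at the configured total depth.
    """
    rng = np.random.default_rng([p.seed, 2])
    chroms = list(p.chromosomes)
    weights = np.array([p.chromosomes[c] for c in chroms], dtype=float)
    cn = np.array([p.copy_number.get(c, 2.0) for c in chroms])

    germ = weights / weights.sum() * p.wgs_total_reads
    tum_w = weights * cn / 2.0
    tum = tum_w / tum_w.sum() * p.wgs_total_reads
    if noise:
        germ = rng.poisson(germ).astype(float)
        tum = rng.poisson(tum).astype(float)
    true_cn = {c: p.copy_number.get(c, 2.0) for c in chroms}
    return (
        pd.Series(tum, index=chroms, name="tumor_reads"),
        pd.Series(germ, index=chroms, name="germline_reads"),
        true_cn,
    )


def generate_de_pair(
    n_genes: int,
    n_cells: int,
    planted_genes: int = 0,
    fold: float = 4.0,
    direction: str = "down",
    mean_library_size: float = 5000.0,
    nb_size: float = 10.0,
    seed: int = 17,
) -> tuple[CountMatrix, CountMatrix, list[str]]:
    """Two-condition pair for differential-expression validation.

    Condition A is the baseline; in condition B the first ``planted_genes``
    genes are scaled by ``fold`` (direction="up") or ``1/fold``
    (direction="down"). With ``planted_genes=0`` the two conditions share
    one generative process (global null). Returns (A, B, planted gene ids).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    rel = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    base = rel / rel.sum() * mean_library_size

    factor = np.ones(n_genes)
    planted_idx = rng.choice(n_genes, size=planted_genes, replace=False) if planted_genes else np.array([], int)
    factor[planted_idx] = fold if direction == "up" else 1.0 / fold

    def _draw(prefix: str, gene_factor: np.ndarray) -> CountMatrix:
        lib = np.exp(rng.normal(0.0, 0.3, size=n_cells))
        lib /= lib.mean()
        mean = np.outer(base * gene_factor, lib)
        counts = _nb_counts(mean, nb_size, rng)
        barcodes = [f"{prefix}_{i:05d}" for i in range(n_cells)]
        return CountMatrix(genes=genes, cells=barcodes, counts=sp.csr_matrix(counts))

    a = _draw("A", np.ones(n_genes))
    b = _draw("B", factor)
    return a, b, [genes[i] for i in planted_idx]


def generate_replicate_design(
    n_genes: int = 1000,
    n_cells: int = 300,
    planted_up: int = 40,
    planted_down: int = 40,
    fold: float = 4.0,
    mean_library_size: float = 5000.0,
    nb_size: float = 10.0,
    seed: int = 17,
) -> tuple[list[CountMatrix], list[CountMatrix], list[str], list[str]]:
    """Two models x two biological replicates with planted signature genes.

    Model A expresses ``planted_up`` genes ``fold`` times higher and
    ``planted_down`` genes ``fold`` times lower than model B; replicates
    within a model share the planted effects but are sampled
    independently. Returns (A replicates, B replicates, up genes, down
    genes) — the inputs of the four pairwise comparisons feeding the
    consistency-rule signature.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:05d}" for i in range(n_genes)]
    rel = np.exp(rng.normal(0.0, 1.0, size=n_genes))
    base = rel / rel.sum() * mean_library_size

    idx = rng.choice(n_genes, size=planted_up + planted_down, replace=False)
    up_idx, down_idx = idx[:planted_up], idx[planted_up:]
    factor_a = np.ones(n_genes)
    factor_a[up_idx] = fold
    factor_a[down_idx] = 1.0 / fold

    def _draw(prefix: str, gene_factor: np.ndarray) -> CountMatrix:
        lib = np.exp(rng.normal(0.0, 0.3, size=n_cells))
        lib /= lib.mean()
        mean = np.outer(base * gene_factor, lib)
        counts = _nb_counts(mean, nb_size, rng)
        barcodes = [f"{prefix}_{i:05d}" for i in range(n_cells)]
        return CountMatrix(genes=genes, cells=barcodes, counts=sp.csr_matrix(counts))

    a_reps = [_draw(f"A{r + 1}", factor_a) for r in range(2)]
    b_reps = [_draw(f"B{r + 1}", np.ones(n_genes)) for r in range(2)]
    return a_reps, b_reps, [genes[i] for i in up_idx], [genes[i] for i in down_idx]
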