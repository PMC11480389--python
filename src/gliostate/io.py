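"""Readers/writers for the standard formats the pipeline touches.

Count matrices travel as the droplet-pipeline triplet (MatrixMarket MTX with
genes as rows and cells as columns, plus one-column gene and barcode TSV
sidecars); gene sets as GMT; the gene->chromosome annotation as a two-column
TSV. Readers validate and refuse rather than coerce: every rejection names
the offending entry.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Raised when an input file or in-memory object violates its contract."""


@dataclass
class CountMatrix:
    """Sparse genes x cells UMI count matrix with identifiers.

    Parameters
    ----------
    genes
        Gene identifiers, one per matrix row, unique.
    cells
        Cell barcodes, one per matrix column, unique.
    counts
        Non-negative integer sparse matrix of shape (len(genes), len(cells)).
    cell_meta
        Optional per-cell table indexed by barcode (sample, condition, ...).
    """

    genes: list[str]
    cells: list[str]
    counts: sp.csr_matrix
    cell_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.genes), len(self.cells)):
            raise FormatError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.cells)} cells"
            )
        if len(set(self.genes)) != len(self.genes):
            dup = pd.Series(self.genes)
            raise FormatError(f"duplicate gene identifiers: {sorted(dup[dup.duplicated()].unique())[:5]}")
        if len(set(self.cells)) != len(self.cells):
            dup = pd.Series(self.cells)
            raise FormatError(f"duplicate barcodes: {sorted(dup[dup.duplicated()].unique())[:5]}")
        data = self.counts.data
        if data.size:
            if data.min() < 0:
                raise FormatError("negative count entry")
            if not np.allclose(data, np.round(data)):
                raise FormatError("non-integer count entry")
        if self.cell_meta is not None and not self.cell_meta.index.equals(pd.Index(self.cells)):
            raise FormatError("cell_meta index does not match barcodes")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cell_totals(self) -> np.ndarray:
        """Total molecules per cell."""
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def subset_cells(self, mask_or_idx) -> "CountMatrix":
        idx = np.asarray(mask_or_idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        meta = self.cell_meta.iloc[idx] if self.cell_meta is not None else None
        return CountMatrix(
            genes=list(self.genes),
            cells=[self.cells[i] for i in idx],
            counts=self.counts[:, idx],
            cell_meta=meta,
        )


@dataclass
class GeneSetCollection:
    """Ordered, named gene sets (GMT semantics)."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise FormatError(f"gene set {name!r} contains duplicate genes")

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass
class RunConfig:
    """Flat run configuration with documented defaults.

    Unknown keys in a config file warn; missing keys take the defaults below.
    """

    config_version: int = 1
    seed: int = 17
    pseudocount: float = 0.1
    mixture_tol: float = 1e-8
    mixture_max_iter: int = 1000
    de_lfc_thresh: float = 1.0
    de_fdr_thresh: float = 0.05
    de_min_support: int = 3
    gsea_n_perm: int = 1000
    gsea_weight: float = 1.0
    aucell_top_frac: float = 0.05
    hto_quantile: float = 0.99

    def __post_init__(self) -> None:
        if not (isinstance(self.seed, (int, np.integer)) and self.seed >= 0):
            raise FormatError("seed must be a non-negative integer")
        for f in fields(self):
            v = getattr(self, f.name)
            if isinstance(v, float) and not np.isfinite(v):
                raise FormatError(f"config value {f.name} is not finite")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise FormatError("config file must be a flat key-value mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            warnings.warn(f"unknown config keys ignored: {sorted(unknown)}", stacklevel=2)
        return cls(**{k: v for k, v in raw.items() if k in known})

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump({f.name: getattr(self, f.name) for f in fields(self)}, sort_keys=True))


def read_count_matrix(mtx_path, genes_path, barcodes_path) -> CountMatrix:
    """Read the MTX + genes + barcodes triplet into a :class:`CountMatrix`.

    The MTX file must be MatrixMarket coordinate with genes as rows and
    cells as columns; sidecars have one identifier per line. Dimensions of
    the header and sidecars must agree.
    """
    try:
        mat = scipy.io.mmread(str(mtx_path))
    except ValueError as e:
        raise FormatError(f"cannot parse MTX file {mtx_path}: {e}") from e
    genes = _read_sidecar(genes_path)
    cells = _read_sidecar(barcodes_path)
    if mat.shape != (len(genes), len(cells)):
        raise FormatError(
            f"MTX header declares {mat.shape} but sidecars list "
            f"{len(genes)} genes and {len(cells)} barcodes"
        )
    return CountMatrix(genes=genes, cells=cells, counts=sp.csr_matrix(mat))


def _read_sidecar(path) -> list[str]:
    text = Path(path).read_text()
    # first tab-separated field per line (10x-style sidecars may carry extras)
    return [line.split("\t")[0] for line in text.splitlines() if line.strip()]


def write_count_matrix(m: CountMatrix, dir_path) -> dict[str, Path]:
    """Write the triplet readable by :func:`read_count_matrix`.

    Output is bit-stable for identical input (canonical COO order, integer
    field). Returns the paths written.
    """
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    paths = {
        "mtx": d / "matrix.mtx",
        "genes": d / "genes.tsv",
        "barcodes": d / "barcodes.tsv",
    }
    coo = sp.coo_matrix(m.counts)
    coo.sum_duplicates()
    scipy.io.mmwrite(str(paths["mtx"]), coo.astype(np.int64), field="integer")
    paths["genes"].write_text("".join(f"{g}\n" for g in m.genes))
    paths["barcodes"].write_text("".join(f"{b}\n" for b in m.cells))
    return paths


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated genes per line).

    Duplicate genes within one line are deduplicated with a logged warning;
    a line with fewer than three fields is a format error.
    """
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line has {len(parts)} fields, need >=3")
        name, desc, genes = parts[0], parts[1], [g for g in parts[2:] if g]
        if not genes:
            raise FormatError(f"{path}:{lineno}: gene set {name!r} has no genes")
        seen: dict[str, None] = {}
        for g in genes:
            if g in seen:
                logger.warning("GMT set %s: duplicate gene %s deduplicated", name, g)
            seen[g] = None
        sets[name] = list(seen)
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(c: GeneSetCollection, path) -> None:
    lines = []
    for name, genes in c.sets.items():
        desc = c.descriptions.get(name, "na")
        lines.append("\t".join([name, desc, *genes]))
    Path(path).write_text("".join(line + "\n" for line in lines))


def read_gene_annotation(path) -> dict[str, str]:
    """Read the two-column gene -> chromosome TSV (header ``gene\\tchromosome``).

    A gene listed twice with conflicting chromosomes is a format error;
    consistent repeats collapse silently.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["gene", "chromosome"]:
        raise FormatError(f"{path}: expected header 'gene<TAB>chromosome', got {list(df.columns[:2])}")
    ann: dict[str, str] = {}
    for _, row in df.iterrows():
        g, c = row["gene"], row["chromosome"]
        if g in ann and ann[g] != c:
            raise FormatError(f"{path}: gene {g} mapped to both {ann[g]} and {c}")
        ann[g] = c
    return ann


def write_gene_annotation(ann: dict[str, str], path) -> None:
    pd.DataFrame({"gene": list(ann), "chromosome": [ann[g] for g in ann]}).to_csv(path, sep="\t", index=False)
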