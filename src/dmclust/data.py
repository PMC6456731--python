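"""Multi-individual UMI count containers, readers/writers and preprocessing.

The clustering model consumes raw UMI counts; the only preprocessing applied
before inference is removal of genes expressed in too few cells and selection
of the most variable genes. No normalization, log-transform or imputation is
performed anywhere in this package.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse


class FormatError(ValueError):
    """Input files are structurally inconsistent (e.g. dimension mismatch)."""


class ValidationError(ValueError):
    """Input values violate the data model (negative counts, empty gene set...)."""


@dataclass
class CountDataset:
    """UMI counts for L individuals over a shared, ordered gene universe.

    ``matrices[l]`` is the genes x cells integer matrix of individual ``l``;
    all matrices share row order ``gene_ids``. Per-cell totals may differ
    freely across cells and individuals (unequal sequencing depth is part of
    the model, not something to correct away).
    """

    matrices: List[np.ndarray]
    gene_ids: List[str]
    cell_ids: List[List[str]]
    individual_ids: List[str]

    def __post_init__(self):
        if len(self.matrices) < 1:
            raise ValidationError("need at least one individual")
        g = len(self.gene_ids)
        if len(self.cell_ids) != len(self.matrices):
            raise ValidationError("cell_ids and matrices length mismatch")
        if len(self.individual_ids) != len(self.matrices):
            raise ValidationError("individual_ids and matrices length mismatch")
        mats = []
        for l, m in enumerate(self.matrices):
            m = np.asarray(m)
            if m.ndim != 2 or m.shape[0] != g:
                raise ValidationError(
                    f"individual {l}: matrix shape {m.shape} inconsistent with {g} genes"
                )
            if m.shape[1] != len(self.cell_ids[l]):
                raise ValidationError(f"individual {l}: cell id count mismatch")
            if m.shape[1] < 1:
                raise ValidationError(f"individual {l}: needs at least one cell")
            if np.any(m < 0):
                raise ValidationError("counts must be non-negative")
            if not np.issubdtype(m.dtype, np.integer):
                if not np.allclose(m, np.round(m)):
                    raise ValidationError("counts must be integers")
                m = np.round(m).astype(np.int64)
            mats.append(m)
        self.matrices = mats

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_individuals(self) -> int:
        return len(self.matrices)

    @property
    def cells_per_individual(self) -> List[int]:
        return [m.shape[1] for m in self.matrices]

    @property
    def total_cells(self) -> int:
        return sum(self.cells_per_individual)

    def subset_genes(self, idx: np.ndarray) -> "CountDataset":
        """New dataset restricted to the given gene row indices, in order."""
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValidationError("gene subset is empty")
        return CountDataset(
            matrices=[m[idx, :] for m in self.matrices],
            gene_ids=[self.gene_ids[i] for i in idx],
            cell_ids=[list(c) for c in self.cell_ids],
            individual_ids=list(self.individual_ids),
        )

    def subset_cells(self, idx_per_individual: Sequence[np.ndarray]) -> "CountDataset":
        """New dataset restricted to the given cell columns per individual."""
        mats, cells = [], []
        for l, idx in enumerate(idx_per_individual):
            idx = np.asarray(idx)
            mats.append(self.matrices[l][:, idx])
            cells.append([self.cell_ids[l][i] for i in idx])
        return CountDataset(mats, list(self.gene_ids), cells, list(self.individual_ids))

    def pooled_counts(self) -> np.ndarray:
        """Genes x (all cells) matrix, individuals concatenated in order."""
        return np.concatenate(self.matrices, axis=1)


@dataclass
class LabelSet:
    """Per-individual cluster labels in 1..K, aligned to cell order."""

    labels: List[np.ndarray]
    K: int

    def __post_init__(self):
        labs = []
        for z in self.labels:
            z = np.asarray(z, dtype=int)
            if z.size and (z.min() < 1 or z.max() > self.K):
                raise ValidationError("labels must lie in 1..K")
            labs.append(z)
        self.labels = labs

    def pooled(self) -> np.ndarray:
        return np.concatenate(self.labels)


# ---------------------------------------------------------------------------
# readers / writers


def _read_id_column(path: str) -> List[str]:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return df.iloc[:, 0].tolist()


def read_counts(path: str, format: str = "10x-mtx"):
    """Read one individual's genes x cells count matrix.

    ``"10x-mtx"`` expects a directory holding ``matrix.mtx`` (MatrixMarket
    coordinate, 1-based indices), ``genes.tsv`` (first column = gene id) and
    ``barcodes.tsv``. ``"dense"`` expects a delimited table with gene rows,
    first column gene id and a header of cell barcodes.

    Returns ``(matrix, gene_ids, cell_ids)`` with an integer ndarray.
    """
    if format == "10x-mtx":
        mtx_path = os.path.join(path, "matrix.mtx")
        genes_path = os.path.join(path, "genes.tsv")
        barcodes_path = os.path.join(path, "barcodes.tsv")
        for p in (mtx_path, genes_path, barcodes_path):
            if not os.path.exists(p):
                raise FormatError(f"missing file: {p}")
        mat = scipy.io.mmread(mtx_path)
        mat = np.asarray(scipy.sparse.coo_matrix(mat).todense())
        genes = _read_id_column(genes_path)
        cells = _read_id_column(barcodes_path)
        if mat.shape != (len(genes), len(cells)):
            raise FormatError(
                f"matrix is {mat.shape} but gene/barcode lists have "
                f"{len(genes)}/{len(cells)} entries"
            )
    elif format == "dense":
        sep = "," if str(path).endswith(".csv") else r"\s+"
        df = pd.read_csv(path, sep=sep, index_col=0)
        genes = [str(g) for g in df.index]
        cells = [str(c) for c in df.columns]
        mat = df.to_numpy()
    else:
        raise ValueError(f"unknown format: {format!r}")

    if not np.allclose(mat, np.round(mat)) or np.any(mat < 0):
        raise ValidationError("counts must be non-negative integers")
    return np.round(mat).astype(np.int64), genes, cells


def write_counts(matrix: np.ndarray, gene_ids, cell_ids, path: str,
                 format: str = "10x-mtx") -> None:
    """Write one individual's matrix in either supported format (round-trips
    with :func:`read_counts`)."""
    matrix = np.asarray(matrix)
    if format == "10x-mtx":
        os.makedirs(path, exist_ok=True)
        sp = scipy.sparse.coo_matrix(matrix.astype(np.int64))
        scipy.io.mmwrite(os.path.join(path, "matrix.mtx"), sp, field="integer")
        pd.Series(list(gene_ids)).to_csv(
            os.path.join(path, "genes.tsv"), sep="\t", index=False, header=False)
        pd.Series(list(cell_ids)).to_csv(
            os.path.join(path, "barcodes.tsv"), sep="\t", index=False, header=False)
    elif format == "dense":
        df = pd.DataFrame(matrix, index=list(gene_ids), columns=list(cell_ids))
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown format: {format!r}")


def merge_individuals(per_individual_matrices, per_individual_gene_lists,
                      cell_ids=None, individual_ids=None) -> CountDataset:
    """Pool individuals onto their common gene universe.

    The shared gene set is the intersection of all per-individual gene lists,
    ordered as in the first individual's list; rows are re-indexed accordingly
    and cells are never merged across individuals.
    """
    mats = list(per_individual_matrices)
    gene_lists = [list(g) for g in per_individual_gene_lists]
    if len(mats) < 1:
        raise ValidationError("need at least one individual")
    common = set(gene_lists[0])
    for g in gene_lists[1:]:
        common &= set(g)
    if not common:
        raise ValidationError("gene intersection across individuals is empty")
    order = [g for g in gene_lists[0] if g in common]
    out_mats = []
    for m, genes in zip(mats, gene_lists):
        pos = {g: i for i, g in enumerate(genes)}
        idx = np.array([pos[g] for g in order])
        out_mats.append(np.asarray(m)[idx, :])
    L = len(mats)
    if individual_ids is None:
        individual_ids = [f"indiv{l + 1}" for l in range(L)]
    if cell_ids is None:
        cell_ids = [
            [f"cell{l + 1}_{j + 1}" for j in range(out_mats[l].shape[1])]
            for l in range(L)
        ]
    return CountDataset(out_mats, order, cell_ids, list(individual_ids))


# ---------------------------------------------------------------------------
# preprocessing


def filter_low_expressed(dataset: CountDataset, min_cell_fraction: float = 0.01) -> CountDataset:
    """Drop genes detected (count > 0) in fewer than ``min_cell_fraction`` of
    pooled cells.

    The fraction is computed over all cells pooled across individuals; a gene
    is kept iff its detected fraction is >= the threshold (removal is for
    strictly-below).
    """
    if not 0 <= min_cell_fraction <= 1:
        raise ValueError("min_cell_fraction must be in [0, 1]")
    pooled = dataset.pooled_counts()
    frac = (pooled > 0).sum(axis=1) / pooled.shape[1]
    keep = np.flatnonzero(frac >= min_cell_fraction)
    if keep.size == 0:
        raise ValidationError("low-expression filter removed every gene")
    if keep.size == dataset.n_genes:
        return dataset
    return dataset.subset_genes(keep)


def select_hvg(dataset: CountDataset, n_genes: int = 1000) -> CountDataset:
    """Keep the ``n_genes`` genes with the largest raw-count standard
    deviation over pooled cells (population SD; ties keep the earlier gene)."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if n_genes >= dataset.n_genes:
        return dataset
    pooled = dataset.pooled_counts().astype(float)
    sd = pooled.std(axis=1)  # population SD
    # stable sort on -sd keeps original order among ties
    order = np.argsort(-sd, kind="stable")[:n_genes]
    keep = np.sort(order)  # preserve relative gene order
    return dataset.subset_genes(keep)


# ---------------------------------------------------------------------------
# result output / parameter dump


def write_result(result, path: str) -> None:
    """Write a clustering result to ``path`` (a directory).

    Emits ``labels.tsv`` (individual_id, cell_id, cluster, max_posterior,
    vague_flag), ``posterior.tsv`` (one row per cell, K columns) and
    ``model_params.json`` — the alpha/pi/mu/sigma2 estimates, reloadable with
    :func:`load_model` for supervised classification.
    """
    os.makedirs(path, exist_ok=True)
    post = np.asarray(result.posterior)
    rows = []
    r = 0
    for l, cid in enumerate(result.cell_ids):
        for j, c in enumerate(cid):
            mp = float(post[r].max())
            rows.append({
                "individual_id": result.individual_ids[l],
                "cell_id": c,
                "cluster": int(result.final_labels.labels[l][j]),
                "max_posterior": mp,
                "vague_flag": bool(mp < 0.95),
            })
            r += 1
    pd.DataFrame(rows).to_csv(os.path.join(path, "labels.tsv"), sep="\t", index=False)
    pd.DataFrame(
        post, columns=[f"cluster{k + 1}" for k in range(post.shape[1])]
    ).to_csv(os.path.join(path, "posterior.tsv"), sep="\t", index=False)

    dump = {
        "format_version": 1,
        "K": int(post.shape[1]),
        "gene_ids": list(result.gene_ids),
        "individual_ids": list(result.individual_ids),
        "alpha": np.asarray(result.alpha_hat.alpha).tolist(),
        "pi": np.asarray(result.pi_hat.pi).tolist(),
        "mu": np.asarray(result.mu_hat).tolist(),
        "sigma2": np.asarray(result.sigma2_hat).tolist(),
    }
    with open(os.path.join(path, "model_params.json"), "w") as fh:
        json.dump(dump, fh)


def load_model(path: str):
    """Reload a parameter dump written by :func:`write_result`.

    Returns a :class:`~dmclust.classify.TrainedModel`.
    """
    from .classify import TrainedModel
    from .kernel import DirichletParamBlock, MixingProportions

    p = path
    if os.path.isdir(p):
        p = os.path.join(p, "model_params.json")
    with open(p) as fh:
        dump = json.load(fh)
    return TrainedModel(
        alpha_hat=DirichletParamBlock(np.asarray(dump["alpha"], dtype=float)),
        pi_hat=MixingProportions(np.asarray(dump["pi"], dtype=float)),
        K=int(dump["K"]),
        gene_ids=list(dump["gene_ids"]),
        individual_ids=list(dump.get("individual_ids", [])),
    )
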