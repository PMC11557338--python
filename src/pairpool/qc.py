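"""Cell/gene quality filters, cross-genotype doublet removal, normalization.

Filters follow the standard droplet scRNA-seq recipe: drop cells detecting
fewer than 200 or more than 4000 genes (boundaries kept: exactly 200 and
exactly 4000 survive), then drop genes detected in fewer than 3 of the
surviving cells.  Cell filters run before gene filters; "detected" means a
nonzero count.  Counts are then depth-normalized to 10,000 per cell and
log(x + 1) transformed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scanpy as sc
import scipy.sparse as sp
from anndata import AnnData

from .errors import ValidationError
from .genotype import ClusterAssignment

__all__ = ["QcThresholds", "filter_cells_genes",
           "remove_cross_genotype_doublets", "normalize_log1p"]


@dataclass
class QcThresholds:
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 4000
    min_cells_per_gene: int = 3
    target_sum: float = 10_000.0

    def validate(self) -> None:
        if not (0 < self.min_genes_per_cell < self.max_genes_per_cell):
            raise ValidationError(
                "need 0 < min_genes_per_cell < max_genes_per_cell")
        if self.min_cells_per_gene <= 0 or self.target_sum <= 0:
            raise ValidationError("thresholds must be positive")


def _check_nonnegative(adata: AnnData) -> None:
    x = adata.X
    mn = x.min() if not sp.issparse(x) else x.data.min() if x.nnz else 0
    if mn < 0:
        raise ValidationError("count matrix has negative entries")


def filter_cells_genes(adata: AnnData,
                       thresholds: QcThresholds | None = None,
                       ) -> tuple[AnnData, dict[str, int]]:
    """Apply cell filters (min then max detected genes), then the gene filter.

    Returns the filtered matrix and a report with ``n_cells_removed`` and
    ``n_genes_removed``; an empty result is valid.
    """
    thr = thresholds or QcThresholds()
    thr.validate()
    _check_nonnegative(adata)
    out = adata.copy()
    n_cells0, n_genes0 = out.shape
    if out.n_obs:
        sc.pp.filter_cells(out, min_genes=thr.min_genes_per_cell)
    if out.n_obs:
        sc.pp.filter_cells(out, max_genes=thr.max_genes_per_cell)
    if out.n_obs and out.n_vars:
        sc.pp.filter_genes(out, min_cells=thr.min_cells_per_gene)
    elif out.n_obs == 0:
        out = out[:, 0:0].copy()  # no surviving cell detects any gene
    report = {
        "n_cells_removed": n_cells0 - out.n_obs,
        "n_genes_removed": n_genes0 - out.n_vars,
    }
    return out, report


def remove_cross_genotype_doublets(adata: AnnData,
                                   assignment: ClusterAssignment) -> AnnData:
    """Drop every barcode called a cross-genotype doublet; keep the rest."""
    status = dict(zip(assignment.barcodes, assignment.status))
    missing = [b for b in adata.obs_names if b not in status]
    if missing:
        raise ValidationError(
            f"{len(missing)} matrix barcodes absent from the cluster "
            f"assignment, e.g. {missing[:3]}")
    keep = [b for b in adata.obs_names if status[b] != "doublet"]
    return adata[keep].copy()


def normalize_log1p(adata: AnnData,
                    target_sum: float = 10_000.0) -> AnnData:
    """Scale each cell to ``target_sum`` total counts, then log(x + 1).

    All-zero cells pass through unchanged.
    """
    _check_nonnegative(adata)
    out = adata.copy()
    if out.n_obs and out.n_vars:
        sc.pp.normalize_total(out, target_sum=target_sum)
        sc.pp.log1p(out)
    return out
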