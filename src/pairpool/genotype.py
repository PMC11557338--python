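"""Desk-scale SNP demultiplexer: binomial-mixture EM on per-cell allele counts.

Cells from K pooled donors are clustered by their alt-allele read fractions.
The model per cluster k is a vector of allele fractions q_lk, and a cell's
log-likelihood under cluster k is the binomial term

    l(c | k) = sum_l [ a_cl * log q_lk + r_cl * log(1 - q_lk) ]

over the loci the cell covers.  EM alternates soft assignment (uniform
mixing weights) with a responsibility-weighted alt-fraction update, q
clipped away from {0, 1} by the error rate.  Cross-genotype doublets are
flagged by comparing the best singlet likelihood against the best two-cluster
mixture with q = (q_i + q_j) / 2.

This is a simplified reimplementation of the souporcell-style core: no read
remapping, no ambient-RNA term, uniform mixing weights.  Real souporcell
outputs can be substituted through the readers in :mod:`pairpool.io`; both
paths produce identical downstream types.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import scipy.sparse as sp
from scipy.special import logsumexp
from sklearn.cluster import kmeans_plusplus

from .errors import ValidationError
from .simdata import CellAlleleCounts

__all__ = [
    "ClusterModel",
    "ClusterAssignment",
    "fit_genotype_clusters",
    "call_doublets",
    "consensus_genotypes",
    "NO_CALL",
]

#: sentinel for a locus with no confident consensus call
NO_CALL = np.nan


@dataclass
class ClusterModel:
    """Fitted per-cluster allele-fraction profiles."""

    K: int
    allele_fraction: np.ndarray  # (n_loci, K), clipped to [eps, 1-eps]
    log_likelihood: float
    eps: float
    locus_keys: list[str]


@dataclass
class ClusterAssignment:
    """Per-cell singlet/doublet/unassigned calls with log-likelihoods."""

    barcodes: list[str]
    status: list[str]  # singlet | doublet | unassigned
    assignment: list[str]  # "2" for singlets, "0/1" for doublets, "" otherwise
    log_prob_singleton: np.ndarray
    log_prob_doublet: np.ndarray
    cluster_log_likelihood: np.ndarray  # (n_cells, K)

    def doublet_barcodes(self) -> list[str]:
        return [b for b, s in zip(self.barcodes, self.status) if s == "doublet"]

    def singlet_clusters(self) -> dict[str, int]:
        return {
            b: int(a)
            for b, s, a in zip(self.barcodes, self.status, self.assignment)
            if s == "singlet"
        }


def _cell_loglik(ref: sp.csr_matrix, alt: sp.csr_matrix,
                 q: np.ndarray) -> np.ndarray:
    """(n_cells, K) binomial log-likelihood over covered loci."""
    return alt @ np.log(q) + ref @ np.log1p(-q)


def _m_step(ref: sp.csr_matrix, alt: sp.csr_matrix, resp: np.ndarray,
            eps: float) -> np.ndarray:
    num = alt.T @ resp
    den = num + ref.T @ resp
    with np.errstate(invalid="ignore"):
        q = np.where(den > 0, num / np.maximum(den, 1e-300), 0.5)
    return np.clip(q, eps, 1.0 - eps)


def _run_em(ref, alt, q0: np.ndarray, max_iter: int, tol: float,
            eps: float) -> tuple[np.ndarray, float]:
    q = q0
    prev = -np.inf
    K = q.shape[1]
    for _ in range(max_iter):
        ll = _cell_loglik(ref, alt, q)
        total = float(np.sum(logsumexp(ll, axis=1) - np.log(K)))
        if np.isfinite(prev) and total - prev < tol:
            return q, total
        prev = total
        resp = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
        q = _m_step(ref, alt, resp, eps)
    ll = _cell_loglik(ref, alt, q)
    return q, float(np.sum(logsumexp(ll, axis=1) - np.log(K)))


def _seed_kmeanspp(ref, alt, K: int, eps: float, seed: int) -> np.ndarray:
    """Initial q: k-means++ centers on mean-imputed per-cell alt fractions."""
    depth = (ref + alt).toarray()
    alt_d = alt.toarray()
    observed = depth > 0
    with np.errstate(invalid="ignore"):
        frac = np.where(observed, alt_d / np.maximum(depth, 1), 0.0)
    n_obs = observed.sum(axis=0)
    col_mean = np.where(n_obs > 0, frac.sum(axis=0) / np.maximum(n_obs, 1), 0.5)
    frac = np.where(observed, frac, col_mean[None, :])
    centers, _ = kmeans_plusplus(frac, n_clusters=K, random_state=seed)
    return np.clip(centers.T, eps, 1.0 - eps)


def fit_genotype_clusters(counts: CellAlleleCounts, K: int,
                          n_restarts: int = 4, max_iter: int = 200,
                          tol: float = 1e-4, seed: int = 0,
                          eps: float = 0.01,
                          ) -> tuple[ClusterModel, ClusterAssignment]:
    """Fit K genotype clusters by EM; best of ``n_restarts`` initializations.

    The first restart is seeded k-means++-style on per-cell alt-fraction
    vectors (missing loci mean-imputed); the rest use random hard
    assignments.  Ties between restarts break toward the lower index.
    Cells with zero covered loci are excluded from the fit and reported
    ``unassigned``.
    """
    if K < 1:
        raise ValidationError("K must be >= 1")
    coverage = np.asarray((counts.ref + counts.alt).sum(axis=1)).ravel()
    covered = coverage > 0
    n_cov = int(covered.sum())
    if n_cov == 0:
        raise ValidationError("no cell has nonzero coverage")
    if K > n_cov:
        raise ValidationError(f"K={K} exceeds {n_cov} cells with coverage")

    ref = counts.ref[covered].tocsr()
    alt = counts.alt[covered].tocsr()
    n_loci = len(counts.locus_keys)

    best_q, best_ll = None, -np.inf
    for restart in range(n_restarts):
        rng = np.random.default_rng([seed, restart])
        if restart == 0 and K > 1:
            q0 = _seed_kmeanspp(ref, alt, K, eps, seed)
        elif K == 1:
            q0 = np.full((n_loci, 1), 0.5)
        else:
            hard = rng.integers(0, K, size=ref.shape[0])
            resp = np.zeros((ref.shape[0], K))
            resp[np.arange(ref.shape[0]), hard] = 1.0
            q0 = _m_step(ref, alt, resp, eps)
        q, ll = _run_em(ref, alt, q0, max_iter, tol, eps)
        if ll > best_ll:
            best_q, best_ll = q, ll
        if K == 1:
            break  # closed form; restarts are identical

    model = ClusterModel(K, best_q, best_ll, eps, list(counts.locus_keys))

    ll_cells = _cell_loglik(ref, alt, best_q)
    full_ll = np.full((len(counts.barcodes), K), np.nan)
    full_ll[covered] = ll_cells
    status, assignment = [], []
    best_singlet = np.full(len(counts.barcodes), np.nan)
    idx = 0
    for i, bc in enumerate(counts.barcodes):
        if covered[i]:
            k = int(np.argmax(ll_cells[idx]))
            status.append("singlet")
            assignment.append(str(k))
            best_singlet[i] = ll_cells[idx, k]
            idx += 1
        else:
            status.append("unassigned")
            assignment.append("")
    assign = ClusterAssignment(
        barcodes=list(counts.barcodes),
        status=status,
        assignment=assignment,
        log_prob_singleton=best_singlet,
        log_prob_doublet=np.full(len(counts.barcodes), np.nan),
        cluster_log_likelihood=full_ll,
    )
    return model, assign


def call_doublets(counts: CellAlleleCounts, model: ClusterModel,
                  delta: float = 2.0) -> ClusterAssignment:
    """Flag cells better explained by a two-cluster mixture than any singlet.

    A cell is a doublet when the best mixture log-likelihood (profiles
    averaged pairwise) beats the best singlet log-likelihood by more than
    ``delta`` nats; the recorded pair is the argmax mixture.
    """
    if model.K < 2:
        raise ValidationError("doublet calling needs K >= 2 (no pairs exist)")
    coverage = np.asarray((counts.ref + counts.alt).sum(axis=1)).ravel()
    covered = coverage > 0
    ref = counts.ref[covered].tocsr()
    alt = counts.alt[covered].tocsr()

    q = model.allele_fraction
    pairs = list(combinations(range(model.K), 2))
    q_mix = np.stack([(q[:, i] + q[:, j]) / 2 for i, j in pairs], axis=1)

    ll_singlet = _cell_loglik(ref, alt, q)
    ll_mix = _cell_loglik(ref, alt, q_mix)

    n = len(counts.barcodes)
    status = ["unassigned"] * n
    assignment = [""] * n
    best_singlet = np.full(n, np.nan)
    best_doublet = np.full(n, np.nan)
    full_ll = np.full((n, model.K), np.nan)

    cov_idx = np.flatnonzero(covered)
    k_best = np.argmax(ll_singlet, axis=1)
    m_best = np.argmax(ll_mix, axis=1)
    for row, i in enumerate(cov_idx):
        s_ll = ll_singlet[row, k_best[row]]
        d_ll = ll_mix[row, m_best[row]]
        best_singlet[i], best_doublet[i] = s_ll, d_ll
        full_ll[i] = ll_singlet[row]
        if d_ll - s_ll > delta:
            a, b = pairs[m_best[row]]
            status[i] = "doublet"
            assignment[i] = f"{a}/{b}"
        else:
            status[i] = "singlet"
            assignment[i] = str(int(k_best[row]))
    return ClusterAssignment(
        barcodes=list(counts.barcodes),
        status=status,
        assignment=assignment,
        log_prob_singleton=best_singlet,
        log_prob_doublet=best_doublet,
        cluster_log_likelihood=full_ll,
    )


def consensus_genotypes(model: ClusterModel,
                        counts: CellAlleleCounts | None = None,
                        assignment: ClusterAssignment | None = None,
                        hom_threshold: float = 0.1,
                        het_band: float = 0.15,
                        min_reads: int = 3) -> np.ndarray:
    """Discretize allele fractions to genotype calls {0, 0.5, 1, no-call}.

    q below ``hom_threshold`` -> 0; above 1 - hom_threshold -> 1; within
    ``het_band`` of 0.5 -> 0.5; anything else, or any locus whose aggregate
    read count within the cluster's singlet cells is below ``min_reads``,
    is a no-call (NaN).
    """
    if hom_threshold >= 0.5 - het_band:
        raise ValidationError(
            "overlapping thresholds: need hom_threshold < 0.5 - het_band")
    q = model.allele_fraction
    calls = np.full_like(q, NO_CALL, dtype=float)
    calls[q < hom_threshold] = 0.0
    calls[q > 1.0 - hom_threshold] = 1.0
    calls[np.abs(q - 0.5) < het_band] = 0.5

    if counts is not None and assignment is not None:
        depth = (counts.ref + counts.alt).tocsr()
        cluster_of = assignment.singlet_clusters()
        bc_index = {b: i for i, b in enumerate(counts.barcodes)}
        for k in range(model.K):
            rows = [bc_index[b] for b, c in cluster_of.items() if c == k]
            if rows:
                agg = np.asarray(depth[rows].sum(axis=0)).ravel()
            else:
                agg = np.zeros(depth.shape[1])
            calls[agg < min_reads, k] = NO_CALL
    return calls
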