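"""Readers and writers for on-disk formats.

Covers the souporcell-compatible cluster table (TSV), per-cluster consensus
genotypes (VCF with one sample column per cluster), pooling designs and run
configuration (YAML), match tables (TSV) and donor rosters (CSV).  The
cluster-table reader accepts both tab and arbitrary whitespace delimiters
and ignores columns beyond the documented set, since field counts vary
across souporcell versions.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .design import Donor, PoolingDesign, Sex
from .errors import ParseError, ValidationError
from .genotype import ClusterAssignment, ClusterModel

__all__ = [
    "read_roster_csv", "load_design", "save_design",
    "read_souporcell_clusters", "write_clusters_tsv",
    "read_cluster_genotypes_vcf", "write_cluster_genotypes_vcf",
    "RunConfig",
]

_STATUSES = {"singlet", "doublet", "unassigned"}


# ---------------------------------------------------------------------------
# roster / design
# ---------------------------------------------------------------------------

def read_roster_csv(path: str | Path) -> list[Donor]:
    """CSV with header ``donor_id,sex`` (sex in {male, female, unknown})."""
    df = pd.read_csv(path)
    if not {"donor_id", "sex"} <= set(df.columns):
        raise ParseError(f"{path}: roster needs columns donor_id,sex")
    try:
        return [Donor(str(r.donor_id), Sex(r.sex)) for r in df.itertuples()]
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def save_design(design: PoolingDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(design.to_dict(), fh, sort_keys=False)


def load_design(path: str | Path) -> PoolingDesign:
    with open(path) as fh:
        return PoolingDesign.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# souporcell-compatible cluster table
# ---------------------------------------------------------------------------

def read_souporcell_clusters(path: str | Path) -> ClusterAssignment:
    """Parse a souporcell-dialect cluster table into a ClusterAssignment."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: empty file")
    header = lines[0].split()
    if header[:3] != ["barcode", "status", "assignment"]:
        raise ParseError(
            f"{path}: header must begin 'barcode status assignment', "
            f"got {header[:3]}")
    n_extra = len(header) - 3
    cluster_cols = [h for h in header if h.startswith("cluster")]

    barcodes, statuses, assignments = [], [], []
    singletons, doublets = [], []
    cluster_ll_rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split()
        if len(parts) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 fields")
        bc, status, assign = parts[0], parts[1], parts[2]
        if status not in _STATUSES:
            raise ParseError(f"{path}:{lineno}: unknown status {status!r}")
        if status == "doublet":
            try:
                a, b = assign.split("/")
                a, b = int(a), int(b)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: doublet assignment must be 'i/j'") from exc
            if a == b:
                raise ParseError(
                    f"{path}:{lineno}: doublet pair {assign!r} is not a pair "
                    "of distinct clusters")
        elif status == "singlet":
            try:
                int(assign)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: singlet assignment must be an "
                    f"integer, got {assign!r}") from exc
        else:
            assign = ""
        barcodes.append(bc)
        statuses.append(status)
        assignments.append(assign)

        def _f(tok: str) -> float:
            try:
                return float(tok)
            except ValueError:
                return np.nan

        extras = [_f(t) for t in parts[3:3 + n_extra]]
        singletons.append(extras[0] if len(extras) >= 1 else np.nan)
        doublets.append(extras[1] if len(extras) >= 2 else np.nan)
        cluster_ll_rows.append(extras[2:2 + len(cluster_cols)])

    k = max((len(r) for r in cluster_ll_rows), default=0)
    ll = np.full((len(barcodes), k), np.nan)
    for i, row in enumerate(cluster_ll_rows):
        ll[i, :len(row)] = row
    return ClusterAssignment(
        barcodes=barcodes, status=statuses, assignment=assignments,
        log_prob_singleton=np.array(singletons),
        log_prob_doublet=np.array(doublets),
        cluster_log_likelihood=ll,
    )


def write_clusters_tsv(assignment: ClusterAssignment, path: str | Path) -> None:
    k = assignment.cluster_log_likelihood.shape[1]
    cols = ["barcode", "status", "assignment", "log_prob_singleton",
            "log_prob_doublet"] + [f"cluster{i}" for i in range(k)]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for i, bc in enumerate(assignment.barcodes):
            row = [
                bc, assignment.status[i], assignment.assignment[i] or "NA",
                _fmt(assignment.log_prob_singleton[i]),
                _fmt(assignment.log_prob_doublet[i]),
            ] + [_fmt(v) for v in assignment.cluster_log_likelihood[i]]
            fh.write("\t".join(row) + "\n")


def _fmt(v: float) -> str:
    return "nan" if not np.isfinite(v) else f"{v:.6g}"


# ---------------------------------------------------------------------------
# per-cluster genotype VCF
# ---------------------------------------------------------------------------

_GT_TO_CALL = {(0, 0): 0.0, (0, 1): 0.5, (1, 0): 0.5, (1, 1): 1.0}
_CALL_TO_GT = {0.0: "0/0", 0.5: "0/1", 1.0: "1/1"}


def write_cluster_genotypes_vcf(locus_keys: list[str], calls: np.ndarray,
                                path: str | Path) -> None:
    """One sample column per cluster; calls {0, 0.5, 1, NaN} -> GT."""
    k = calls.shape[1]
    contigs = sorted({key.split(":")[0] for key in locus_keys})
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pairpool\n")
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(f"cluster{i}" for i in range(k))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{samples}\n")
        for li, key in enumerate(locus_keys):
            chrom, pos, ref, alt = key.split(":")
            gts = "\t".join(
                _CALL_TO_GT.get(calls[li, ki], "./.")
                if not np.isnan(calls[li, ki]) else "./."
                for ki in range(k)
            )
            fh.write(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t.\tGT\t{gts}\n")


def read_cluster_genotypes_vcf(path: str | Path,
                               ) -> tuple[list[str], np.ndarray]:
    """Read per-cluster genotype calls; returns (locus_keys, calls matrix).

    Multi-allelic records are skipped with a warning; phased separators are
    accepted; ``./.`` maps to a NaN no-call.
    """
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise ParseError(f"{path}: VCF has no sample columns")
        keys, rows = [], []
        n_multiallelic = 0
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                n_multiallelic += 1
                continue
            if "GT" not in rec.format:
                raise ParseError(f"{path}: record at {rec.chrom}:{rec.pos} "
                                 "is missing the GT format field")
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or None in gt:
                    row.append(np.nan)
                else:
                    row.append(_GT_TO_CALL.get(tuple(gt), np.nan))
            keys.append(f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}")
            rows.append(row)
    if n_multiallelic:
        warnings.warn(f"{path}: skipped {n_multiallelic} multi-allelic records")
    calls = np.array(rows, dtype=float) if rows else np.empty((0, len(samples)))
    return keys, calls


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """End-to-end pipeline parameters; every field has the module default."""

    design_path: str = ""
    out_dir: str = "pairpool_out"
    seed: int = 0
    # simulation (used when no real inputs are given)
    simulate: bool = True
    sim: dict = field(default_factory=dict)  # SimConfig overrides
    # real-data mode: per-reaction demultiplexer outputs; each item is a dict
    # {reaction_id, clusters, genotypes_vcf, matrix?, features?, barcodes?}
    real_inputs: list = field(default_factory=list)
    # clustering
    eps: float = 0.01
    n_restarts: int = 4
    max_iter: int = 200
    tol: float = 1e-4
    delta_doublet: float = 2.0
    hom_threshold: float = 0.1
    het_band: float = 0.15
    min_reads: int = 3
    # matching
    tau_match: float = 0.9
    min_shared_loci: int = 20
    # sex inference
    tau_male: float = 0.02
    use_sex: bool = True
    # QC
    min_genes_per_cell: int = 200
    max_genes_per_cell: int = 4000
    min_cells_per_gene: int = 3
    target_sum: float = 10_000.0

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
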