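"""Synthetic pooled-experiment generator with ground truth.

Emulates the data a pooled paired-tissue experiment produces after alignment:
per-donor SNP genotypes drawn under Hardy-Weinberg equilibrium, sparse
per-cell ref/alt allele counts (Poisson sequencing depth per locus, binomial
alt reads given the genotype, with a base-call error rate), same-reaction
doublets formed by summing two independently drawn cells, and an expression
matrix whose Y-chromosome genes carry the donor-sex signal (Poisson UMI
rates, high for male donors, a small leak rate for female ones).

Every stage records ground truth per barcode so each downstream step —
clustering, doublet calling, cross-reaction matching, sex inference,
identity resolution — can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .design import PoolingDesign, Sex
from .errors import ValidationError

#: Y-chromosome genes used as the male-sex proxy.
Y_GENES: tuple[str, ...] = (
    "ZFY", "RPS4Y1", "EIF1AY", "KDM5D", "NLGN4Y", "TMSB4Y", "UTY", "DDX3Y",
    "USP9Y",
)

__all__ = [
    "Y_GENES",
    "SimConfig",
    "DonorGenotypes",
    "CellAlleleCounts",
    "simulate_donor_genotypes",
    "simulate_reaction",
    "write_fixture",
    "read_fixture",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic pooled experiment.

    Defaults are a deliberately sparse, desk-scale regime: ~2 reads per cell
    per SNP locus is typical of what scRNA-seq yields at common exonic SNPs,
    and 5% doublets matches standard 10X loading.
    """

    n_loci: int = 300
    maf_low: float = 0.1
    maf_high: float = 0.5
    cells_per_sample: int = 200
    mean_depth: float = 2.0
    error_rate: float = 0.01
    doublet_rate: float = 0.05
    y_gene_rate_male: float = 0.5
    y_leak_rate_female: float = 0.005
    background_genes: int = 100
    bg_gene_rate: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci < 1:
            raise ValidationError("n_loci must be >= 1")
        if not (0.0 <= self.maf_low <= self.maf_high <= 1.0):
            raise ValidationError("need 0 <= maf_low <= maf_high <= 1")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValidationError("error_rate must be in [0, 0.5)")
        if not (0.0 <= self.doublet_rate < 0.5):
            raise ValidationError("doublet_rate must be in [0, 0.5)")
        for name in ("cells_per_sample", "mean_depth", "y_gene_rate_male",
                     "y_leak_rate_female", "background_genes", "bg_gene_rate"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")
        if not self.y_leak_rate_female < self.y_gene_rate_male:
            raise ValidationError(
                "y_leak_rate_female must be below y_gene_rate_male")


@dataclass
class DonorGenotypes:
    """Alt-allele copy numbers (0/1/2) per locus per donor, plus MAFs."""

    genotypes: np.ndarray  # (n_loci, n_donors) int8
    maf: np.ndarray  # (n_loci,)
    donor_ids: list[str]
    locus_keys: list[str]  # CHROM:POS:REF:ALT

    def column(self, donor_id: str) -> np.ndarray:
        return self.genotypes[:, self.donor_ids.index(donor_id)]


@dataclass
class CellAlleleCounts:
    """Sparse per-cell ref/alt read counts at SNP loci (cells x loci)."""

    barcodes: list[str]
    locus_keys: list[str]
    ref: sp.csr_matrix
    alt: sp.csr_matrix

    def __post_init__(self) -> None:
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValidationError("barcodes must be unique within a reaction")
        n, m = len(self.barcodes), len(self.locus_keys)
        if self.ref.shape != (n, m) or self.alt.shape != (n, m):
            raise ValidationError("ref/alt shape mismatch with barcodes/loci")


def default_locus_keys(n_loci: int) -> list[str]:
    return [f"1:{i + 1}:A:G" for i in range(n_loci)]


def simulate_donor_genotypes(roster, config: SimConfig) -> DonorGenotypes:
    """Draw per-donor genotypes: MAF ~ U(low, high), two HWE allele draws."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    donor_ids = [d.donor_id for d in roster]
    maf = rng.uniform(config.maf_low, config.maf_high, size=config.n_loci)
    geno = rng.binomial(
        2, maf[:, None], size=(config.n_loci, len(donor_ids))
    ).astype(np.int8)
    return DonorGenotypes(geno, maf, donor_ids, default_locus_keys(config.n_loci))


def _alt_prob(genotypes: np.ndarray, eps: float) -> np.ndarray:
    """Per-read alt probability for genotype 0/1/2 with error rate eps."""
    return np.choose(genotypes, [eps, 0.5, 1.0 - eps])


def simulate_reaction(design: PoolingDesign, reaction_id: str,
                      genotypes: DonorGenotypes, config: SimConfig,
                      ) -> tuple[CellAlleleCounts, AnnData, pd.DataFrame]:
    """Simulate one pooled reaction: allele counts, expression, and truth.

    Emits ``cells_per_sample * n_members`` droplets.  Each droplet draws its
    member sample uniformly; a fraction ``doublet_rate`` of droplets are
    doublets whose counts are the sum of two independently drawn cells
    (cross-genotype when the two donors differ).
    """
    config.validate()
    rxn_map = design.reaction_by_id()
    if reaction_id not in rxn_map:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    rxn = rxn_map[reaction_id]
    smap = design.sample_by_id()
    dmap = design.donor_by_id()
    member_donors = [smap[sid].donor_id for sid in rxn.members]
    for d in member_donors:
        if d not in genotypes.donor_ids:
            raise ValidationError(f"genotypes missing donor {d}")

    rxn_index = [r.reaction_id for r in design.reactions].index(reaction_id)
    rng = np.random.default_rng([config.seed, rxn_index])

    n_cells = config.cells_per_sample * len(rxn.members)
    n_loci = config.n_loci
    members = list(rxn.members)

    primary = rng.integers(0, len(members), size=n_cells)
    is_doublet = rng.random(n_cells) < config.doublet_rate
    secondary = rng.integers(0, len(members), size=n_cells)

    geno_cols = np.stack([genotypes.column(d) for d in member_donors], axis=1)

    def draw_counts(member_idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        depth = rng.poisson(config.mean_depth, size=(len(member_idx), n_loci))
        p = _alt_prob(geno_cols[:, member_idx].T, config.error_rate)
        alt = rng.binomial(depth, p)
        return depth - alt, alt

    ref, alt = draw_counts(primary)
    if is_doublet.any():
        ref2, alt2 = draw_counts(secondary[is_doublet])
        ref[is_doublet] += ref2
        alt[is_doublet] += alt2

    # expression: Y genes (sex signal) + background genes
    genes = list(Y_GENES) + [f"BG{i + 1:04d}" for i in range(config.background_genes)]
    sexes = np.array(
        [dmap[d].sex is Sex.MALE if d in dmap else False for d in member_donors]
    )

    def draw_expr(member_idx: np.ndarray) -> np.ndarray:
        k = len(member_idx)
        y_rate = np.where(sexes[member_idx], config.y_gene_rate_male,
                          config.y_leak_rate_female)
        y = rng.poisson(y_rate[:, None], size=(k, len(Y_GENES)))
        bg = rng.poisson(config.bg_gene_rate,
                         size=(k, config.background_genes))
        return np.hstack([y, bg])

    expr = draw_expr(primary)
    if is_doublet.any():
        expr[is_doublet] += draw_expr(secondary[is_doublet])

    barcodes = [f"{reaction_id}_BC{i + 1:05d}" for i in range(n_cells)]
    counts = CellAlleleCounts(
        barcodes, list(genotypes.locus_keys),
        sp.csr_matrix(ref), sp.csr_matrix(alt),
    )
    adata = AnnData(
        X=sp.csr_matrix(expr),
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth = pd.DataFrame({
        "barcode": barcodes,
        "sample_id": [members[i] for i in primary],
        "donor_id": [member_donors[i] for i in primary],
        "is_doublet": is_doublet,
        "second_donor_id": [
            member_donors[s] if dbl else ""
            for s, dbl in zip(secondary, is_doublet)
        ],
        "sex": [
            dmap[member_donors[i]].sex.value if member_donors[i] in dmap
            else "unknown"
            for i in primary
        ],
    })
    return counts, adata, truth


# ---------------------------------------------------------------------------
# fixture IO
# ---------------------------------------------------------------------------

def write_fixture(out_dir: str | Path, counts: CellAlleleCounts,
                  adata: AnnData, truth: pd.DataFrame, config: SimConfig,
                  overwrite: bool = False) -> None:
    """Write one reaction's simulated outputs as MatrixMarket/TSV/JSON."""
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not overwrite:
        raise ValidationError(
            f"{out} exists and is not empty; pass overwrite=True to replace")
    out.mkdir(parents=True, exist_ok=True)

    # allele matrices, loci x cells
    scipy.io.mmwrite(out / "ref.mtx", counts.ref.T.tocoo())
    scipy.io.mmwrite(out / "alt.mtx", counts.alt.T.tocoo())
    pd.Series(counts.locus_keys).to_csv(out / "loci.tsv", sep="\t",
                                        index=False, header=False)
    pd.Series(counts.barcodes).to_csv(out / "barcodes.tsv", sep="\t",
                                      index=False, header=False)
    # expression, genes x cells (10X orientation)
    scipy.io.mmwrite(out / "matrix.mtx", sp.coo_matrix(adata.X.T))
    pd.Series(adata.var_names).to_csv(out / "features.tsv", sep="\t",
                                      index=False, header=False)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump({"sim_config": asdict(config)}, fh, indent=2)


def read_fixture(out_dir: str | Path,
                 ) -> tuple[CellAlleleCounts, AnnData, pd.DataFrame, SimConfig]:
    out = Path(out_dir)
    barcodes = _read_lines(out / "barcodes.tsv")
    loci = _read_lines(out / "loci.tsv")
    ref = sp.csr_matrix(scipy.io.mmread(out / "ref.mtx").T)
    alt = sp.csr_matrix(scipy.io.mmread(out / "alt.mtx").T)
    counts = CellAlleleCounts(barcodes, loci, ref, alt)
    genes = _read_lines(out / "features.tsv")
    x = sp.csr_matrix(scipy.io.mmread(out / "matrix.mtx").T)
    adata = AnnData(
        X=x,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="barcode")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )
    truth = pd.read_csv(out / "truth.tsv", sep="\t",
                        keep_default_na=False,
                        dtype={"second_donor_id": str})
    with open(out / "manifest.json") as fh:
        config = SimConfig(**json.load(fh)["sim_config"])
    return counts, adata, truth, config


def _read_lines(path: Path) -> list[str]:
    text = path.read_text()
    return [line for line in text.splitlines() if line]
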