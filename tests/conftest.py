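import numpy as np
import pytest
import scipy.sparse as sp

from pairpool.design import (Donor, PoolingDesign, Reaction, SampleSpec, Sex,
                             Tissue, design_strategy1, design_strategy2)
from pairpool.simdata import (CellAlleleCounts, SimConfig,
                              simulate_donor_genotypes, simulate_reaction)


def make_roster(n: int, sexes: str | None = None) -> list[Donor]:
    """n donors S1..Sn; sexes is a string like 'MFMFM...' (default alternating)."""
    if sexes is None:
        sexes = "".join("MF"[i % 2] for i in range(n))
    return [
        Donor(f"S{i + 1}", Sex.MALE if s == "M" else Sex.FEMALE)
        for i, s in enumerate(sexes)
    ]


@pytest.fixture(scope="session")
def roster9() -> list[Donor]:
    return make_roster(9)


@pytest.fixture(scope="session")
def table2_design(roster9) -> PoolingDesign:
    return design_strategy1(roster9)


@pytest.fixture(scope="session")
def table3_design(roster9) -> PoolingDesign:
    return design_strategy2(roster9)


def forbidden_two_donor_design() -> PoolingDesign:
    """The layout the dual strategy forbids: two donors swapped across two
    reactions, symmetric under donor exchange."""
    return PoolingDesign(
        strategy="dual",
        reactions=[
            Reaction("R01", ("A-pbmc", "B-skin")),
            Reaction("R02", ("A-skin", "B-pbmc")),
        ],
        samples=[
            SampleSpec("A-pbmc", "A", Tissue.PBMC),
            SampleSpec("A-skin", "A", Tissue.SKIN),
            SampleSpec("B-pbmc", "B", Tissue.PBMC),
            SampleSpec("B-skin", "B", Tissue.SKIN),
        ],
        anchors=[],
        donors=[Donor("A", Sex.MALE), Donor("B", Sex.MALE)],
    )


def single_pool_design(n_donors: int = 2, sexes: str | None = None,
                       ) -> PoolingDesign:
    """One reaction pooling one skin sample from each of n donors (for
    exercising the clusterer/sex caller on their own)."""
    donors = make_roster(n_donors, sexes)
    samples = [SampleSpec(f"{d.donor_id}-skin", d.donor_id, Tissue.SKIN)
               for d in donors]
    return PoolingDesign(
        strategy="custom",
        reactions=[Reaction("R01", tuple(s.sample_id for s in samples))],
        samples=samples,
        anchors=[],
        donors=donors,
    )


@pytest.fixture(scope="session")
def two_donor_sim():
    """Default-condition simulation of one reaction pooling 2 donors, no
    doublets; returns (design, genotypes, counts, adata, truth, config)."""
    design = single_pool_design(2, "MF")
    cfg = SimConfig(doublet_rate=0.0, seed=7)
    genotypes = simulate_donor_genotypes(design.donors, cfg)
    counts, adata, truth = simulate_reaction(design, "R01", genotypes, cfg)
    return design, genotypes, counts, adata, truth, cfg


def counts_from_arrays(ref: np.ndarray, alt: np.ndarray) -> CellAlleleCounts:
    n, m = ref.shape
    return CellAlleleCounts(
        [f"BC{i:04d}" for i in range(n)],
        [f"1:{j + 1}:A:G" for j in range(m)],
        sp.csr_matrix(ref), sp.csr_matrix(alt),
    )
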