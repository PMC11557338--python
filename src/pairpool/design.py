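"""Pooling designs for label-free multiplexing of paired-tissue samples.

A donor contributes one skin and one PBMC sample.  Both strategies place a
donor's two samples in *different* reactions so that the shared genotype of
the pair links the two reactions after SNP-based demultiplexing:

* **Strategy 1 (dual)** pools two samples per reaction.  Donors are chained
  into blocks so that every pair of genotype-linked reactions shares exactly
  one donor, which makes every cluster identity decodable from genotype
  sharing alone.
* **Strategy 2 (triplet)** pools three samples per reaction: one *anchor*
  sample whose matched pair sits in the adjacent reaction of the same dual
  block, plus two *filler* samples from donors of different sexes.  Genotype
  sharing pins the anchors; Y-chromosome expression (donor sex) then
  disambiguates the two fillers of each reaction.

`check_identifiability` proves, by exact enumeration, whether a layout's
cluster identities are uniquely decodable from these observables.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import InfeasibleDesignError, ValidationError

__all__ = [
    "Sex",
    "Tissue",
    "Donor",
    "SampleSpec",
    "Reaction",
    "PoolingDesign",
    "IdentifiabilityReport",
    "design_strategy1",
    "design_strategy2",
    "check_identifiability",
    "design_cost",
]


class Sex(str, Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"


class Tissue(str, Enum):
    SKIN = "skin"
    PBMC = "pbmc"


@dataclass(frozen=True)
class Donor:
    donor_id: str
    sex: Sex = Sex.UNKNOWN

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))


@dataclass(frozen=True)
class SampleSpec:
    """One tissue sample from one donor; at most one per (donor, tissue)."""

    sample_id: str
    donor_id: str
    tissue: Tissue

    def __post_init__(self) -> None:
        object.__setattr__(self, "tissue", Tissue(self.tissue))


@dataclass(frozen=True)
class Reaction:
    """A pooled 10X reaction; members are sample ids, distinct donors."""

    reaction_id: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "members", tuple(self.members))


@dataclass
class PoolingDesign:
    strategy: str  # "dual" | "triplet"
    reactions: list[Reaction]
    samples: list[SampleSpec]
    anchors: list[tuple[str, str, str]]  # (donor_id, reaction_a, reaction_b)
    donors: list[Donor] = field(default_factory=list)

    # -- derived lookups -------------------------------------------------
    def sample_by_id(self) -> dict[str, SampleSpec]:
        return {s.sample_id: s for s in self.samples}

    def donor_by_id(self) -> dict[str, Donor]:
        return {d.donor_id: d for d in self.donors}

    def reaction_by_id(self) -> dict[str, Reaction]:
        return {r.reaction_id: r for r in self.reactions}

    def donor_reactions(self) -> dict[str, set[str]]:
        """Map donor id -> set of reaction ids holding one of its samples."""
        smap = self.sample_by_id()
        out: dict[str, set[str]] = {}
        for rxn in self.reactions:
            for sid in rxn.members:
                out.setdefault(smap[sid].donor_id, set()).add(rxn.reaction_id)
        return out

    def validate(self) -> None:
        sids = [s.sample_id for s in self.samples]
        if len(set(sids)) != len(sids):
            raise ValidationError("duplicate sample_id in design")
        pairs = [(s.donor_id, s.tissue) for s in self.samples]
        if len(set(pairs)) != len(pairs):
            raise ValidationError("a donor contributes two samples of one tissue")
        smap = self.sample_by_id()
        placed: list[str] = []
        want = {"dual": 2, "triplet": 3}.get(self.strategy)
        for rxn in self.reactions:
            if len(set(rxn.members)) != len(rxn.members):
                raise ValidationError(f"{rxn.reaction_id}: duplicate member")
            if want is not None and len(rxn.members) != want:
                raise ValidationError(
                    f"{rxn.reaction_id}: {self.strategy} design requires "
                    f"{want} members, got {len(rxn.members)}"
                )
            donors_here = [smap[sid].donor_id for sid in rxn.members]
            if len(set(donors_here)) != len(donors_here):
                raise ValidationError(
                    f"{rxn.reaction_id}: two members share a donor"
                )
            placed.extend(rxn.members)
        if sorted(placed) != sorted(sids):
            raise ValidationError("every sample must appear in exactly one reaction")
        # skin and pbmc of one donor must sit in different reactions
        for donor_id, rxns in self.donor_reactions().items():
            n_samples = sum(1 for s in self.samples if s.donor_id == donor_id)
            if len(rxns) != n_samples:
                raise ValidationError(
                    f"donor {donor_id}: paired samples placed in one reaction"
                )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "strategy": self.strategy,
            "reactions": [
                {"reaction_id": r.reaction_id, "members": list(r.members)}
                for r in self.reactions
            ],
            "samples": [
                {"sample_id": s.sample_id, "donor_id": s.donor_id,
                 "tissue": s.tissue.value}
                for s in self.samples
            ],
            "anchors": [list(a) for a in self.anchors],
            "donors": [
                {"donor_id": d.donor_id, "sex": d.sex.value} for d in self.donors
            ],
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "PoolingDesign":
        design = cls(
            strategy=data["strategy"],
            reactions=[
                Reaction(r["reaction_id"], tuple(r["members"]))
                for r in data["reactions"]
            ],
            samples=[
                SampleSpec(s["sample_id"], s["donor_id"], Tissue(s["tissue"]))
                for s in data["samples"]
            ],
            anchors=[tuple(a) for a in data.get("anchors", [])],
            donors=[
                Donor(d["donor_id"], Sex(d["sex"]))
                for d in data.get("donors", [])
            ],
        )
        design.validate()
        return design


@dataclass
class IdentifiabilityReport:
    n_consistent_assignments: int
    identifiable: bool
    ambiguous_groups: list[set[tuple[str, str]]]
    used_sex: bool


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _sample_id(donor_id: str, tissue: Tissue) -> str:
    return f"{donor_id}-{tissue.value}"


def _check_roster(roster: Sequence[Donor],
                  tissues: Mapping[str, Iterable[Tissue]] | None) -> list[Donor]:
    ids = [d.donor_id for d in roster]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate donor_id in roster")
    if tissues is not None:
        for d in roster:
            have = {Tissue(t) for t in tissues.get(d.donor_id, ())}
            if have != {Tissue.SKIN, Tissue.PBMC}:
                raise ValidationError(
                    f"donor {d.donor_id} is missing a tissue: has {sorted(t.value for t in have)}"
                )
    return sorted(roster, key=lambda d: d.donor_id)


def _reaction_ids(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"R{i + 1:0{width}d}" for i in range(n)]


# ---------------------------------------------------------------------------
# strategy 1: dual pooling (two samples per reaction)
# ---------------------------------------------------------------------------

def design_strategy1(roster: Sequence[Donor],
                     tissues: Mapping[str, Iterable[Tissue]] | None = None,
                     ) -> PoolingDesign:
    """Dual (two-per-reaction) pooling of N paired samples into N reactions.

    Donors (sorted by id) are split into consecutive groups of three (the
    last group absorbs a remainder of one or two).  Within a group of m
    donors, m-1 block reactions chain the donors — reaction i pools the same
    tissue of donors i and i+1, tissues alternating skin/pbmc — so that each
    interior donor's pair spans a dual block.  The leftover first-donor PBMC
    and last-donor sample of each group are paired up into closing reactions
    (same-tissue pairs first, one mixed-tissue closer when the group count
    is odd).  Every pair of genotype-linked reactions then shares exactly
    one donor, so the layout is identifiable without sex information.
    """
    donors = _check_roster(roster, tissues)
    n = len(donors)
    if n < 3:
        raise InfeasibleDesignError(
            f"dual pooling needs at least 3 donors (got {n}): with fewer, every "
            "genetically unrelated addition would be the other donor's paired sample"
        )

    # group sizes: all 3, last group 4 or 5 when N % 3 != 0
    sizes = [3] * (n // 3)
    if n % 3:
        sizes[-1] += n % 3

    groups: list[list[Donor]] = []
    pos = 0
    for m in sizes:
        groups.append(donors[pos:pos + m])
        pos += m

    block_members: list[tuple[tuple[str, Tissue], ...]] = []
    anchors_raw: list[tuple[str, int, int]] = []  # donor, block idx a, idx b
    heads: list[tuple[str, Tissue]] = []  # leftover pbmc of each group head
    tails: list[tuple[str, Tissue]] = []  # leftover sample of each group tail
    for grp in groups:
        m = len(grp)
        first = len(block_members)
        for i in range(m - 1):
            t = Tissue.SKIN if i % 2 == 0 else Tissue.PBMC
            block_members.append(((grp[i].donor_id, t), (grp[i + 1].donor_id, t)))
        for i in range(1, m - 1):  # interior donors span adjacent blocks
            anchors_raw.append((grp[i].donor_id, first + i - 1, first + i))
        heads.append((grp[0].donor_id, Tissue.PBMC))
        # last block's tissue is skin when m is even, so the tail donor's
        # unused tissue is pbmc then, skin when m is odd
        tail_t = Tissue.SKIN if m % 2 == 1 else Tissue.PBMC
        tails.append((grp[-1].donor_id, tail_t))

    closing: list[tuple[tuple[str, Tissue], ...]] = []
    g = len(groups)
    for i in range(0, g - 1, 2):
        closing.append((tails[i], tails[i + 1]))
    for i in range(0, g - 1, 2):
        closing.append((heads[i], heads[i + 1]))
    if g % 2 == 1:  # one mixed-tissue closing reaction, as in the printed layout
        closing.append((tails[-1], heads[-1]))

    all_members = block_members + closing
    rids = _reaction_ids(len(all_members))
    reactions = [
        Reaction(rid, tuple(sorted(_sample_id(d, t) for d, t in mem)))
        for rid, mem in zip(rids, all_members)
    ]
    samples = sorted(
        (SampleSpec(_sample_id(d.donor_id, t), d.donor_id, t)
         for d in donors for t in (Tissue.SKIN, Tissue.PBMC)),
        key=lambda s: s.sample_id,
    )
    anchors = [(d, rids[a], rids[b]) for d, a, b in anchors_raw]
    design = PoolingDesign("dual", reactions, samples, anchors, list(donors))
    design.validate()
    return design


# ---------------------------------------------------------------------------
# strategy 2: triplet pooling (three samples per reaction, sex-encoded)
# ---------------------------------------------------------------------------

def design_strategy2(roster: Sequence[Donor],
                     tissues: Mapping[str, Iterable[Tissue]] | None = None,
                     ) -> PoolingDesign:
    """Triplet (three-per-reaction) pooling of N paired samples into 2N/3 reactions.

    N/3 donors are chosen as anchors; each anchor's pair spans one dual block
    (PBMC in the skin-side reaction, skin in the PBMC-side reaction, mirroring
    the published layout).  The remaining 2N/3 filler donors must split evenly
    by sex; each reaction receives one male and one female filler sample, and
    a filler's two tissues are rotated to adjacent blocks so no dual block
    shares more than the anchor genotype.  Identifiable with sex observables.
    """
    donors = _check_roster(roster, tissues)
    n = len(donors)
    if n < 6 or n % 3 != 0:
        raise InfeasibleDesignError(
            f"triplet pooling needs N >= 6 with N divisible by 3 (got {n})"
        )
    for d in donors:
        if d.sex is Sex.UNKNOWN:
            raise ValidationError(
                f"donor {d.donor_id}: sex must be known for triplet pooling"
            )
    g = n // 3
    n_male = sum(1 for d in donors if d.sex is Sex.MALE)
    n_female = n - n_male
    if n_male < g or n_female < g:
        limiting = "male" if n_male < g else "female"
        raise InfeasibleDesignError(
            f"need at least {g} {limiting} filler donors, have "
            f"{min(n_male, n_female)}: sex composition cannot satisfy the "
            "different-sex filler constraint"
        )

    # greedy anchor selection on sorted ids, keeping g fillers of each sex
    anchor_quota = {Sex.MALE: n_male - g, Sex.FEMALE: n_female - g}
    anchors_d: list[Donor] = []
    fillers: dict[Sex, list[Donor]] = {Sex.MALE: [], Sex.FEMALE: []}
    for d in donors:
        if len(anchors_d) < g and anchor_quota[d.sex] > 0:
            anchors_d.append(d)
            anchor_quota[d.sex] -= 1
        else:
            fillers[d.sex].append(d)
    males, females = fillers[Sex.MALE], fillers[Sex.FEMALE]

    rids = _reaction_ids(2 * g)
    reactions: list[Reaction] = []
    anchors: list[tuple[str, str, str]] = []
    for j in range(g):
        a = anchors_d[j]
        skin_side = [
            _sample_id(males[j].donor_id, Tissue.SKIN),
            _sample_id(females[j].donor_id, Tissue.SKIN),
            _sample_id(a.donor_id, Tissue.PBMC),
        ]
        jn = (j + 1) % g  # rotate fillers' pbmc one block forward
        pbmc_side = [
            _sample_id(males[jn].donor_id, Tissue.PBMC),
            _sample_id(females[jn].donor_id, Tissue.PBMC),
            _sample_id(a.donor_id, Tissue.SKIN),
        ]
        reactions.append(Reaction(rids[2 * j], tuple(sorted(skin_side))))
        reactions.append(Reaction(rids[2 * j + 1], tuple(sorted(pbmc_side))))
        anchors.append((a.donor_id, rids[2 * j], rids[2 * j + 1]))

    samples = sorted(
        (SampleSpec(_sample_id(d.donor_id, t), d.donor_id, t)
         for d in donors for t in (Tissue.SKIN, Tissue.PBMC)),
        key=lambda s: s.sample_id,
    )
    design = PoolingDesign("triplet", reactions, samples, anchors, list(donors))
    design.validate()
    return design


# ---------------------------------------------------------------------------
# identifiability: exact enumeration on noise-free observables
# ---------------------------------------------------------------------------

def check_identifiability(design: PoolingDesign, use_sex: bool = False,
                          ) -> IdentifiabilityReport:
    """Count slot->sample assignments consistent with noise-free observables.

    The observables a perfect demultiplexing run would yield are (i) the
    partition of per-reaction cluster slots into same-donor equivalence
    classes (distinct classes are known to be distinct donors) and (ii),
    optionally, the sex of each slot's donor.  A consistent assignment maps
    every equivalence class to a donor present in exactly the class's set of
    reactions, injectively.  The design is identifiable iff exactly one such
    mapping exists.
    """
    design.validate()
    donor_map = design.donor_by_id()
    if use_sex:
        for d in design.donors:
            if d.sex is Sex.UNKNOWN:
                raise ValidationError(
                    f"use_sex requires known sexes; donor {d.donor_id} is unknown"
                )
    smap = design.sample_by_id()
    donor_rxns: dict[str, frozenset[str]] = {
        d: frozenset(r) for d, r in design.donor_reactions().items()
    }
    donor_slots: dict[str, list[tuple[str, str]]] = {}
    for rxn in design.reactions:
        for sid in rxn.members:
            donor_slots.setdefault(smap[sid].donor_id, []).append(
                (rxn.reaction_id, sid))

    # one anonymous class per true donor: (reaction set, sex label if used)
    class_donors = sorted(donor_rxns)  # class i <-> true donor class_donors[i]
    classes = [donor_rxns[d] for d in class_donors]
    sexes = None
    if use_sex:
        sexes = [donor_map[d].sex if d in donor_map else Sex.UNKNOWN
                 for d in class_donors]
        if any(s is Sex.UNKNOWN for s in sexes):
            raise ValidationError("use_sex requires a donor roster with known sexes")

    # candidate donors per class: identical reaction support (and sex)
    candidates: list[list[str]] = []
    for i, rset in enumerate(classes):
        cand = [d for d in class_donors if donor_rxns[d] == rset]
        if use_sex:
            cand = [d for d in cand if donor_map[d].sex is sexes[i]]
        candidates.append(cand)

    order = sorted(range(len(classes)), key=lambda i: len(candidates[i]))
    used: set[str] = set()
    assignment: dict[int, str] = {}
    solutions: list[dict[int, str]] = []
    count = 0

    def backtrack(pos: int) -> None:
        nonlocal count
        if pos == len(order):
            count += 1
            if count <= 10000:
                solutions.append(dict(assignment))
            return
        i = order[pos]
        for d in candidates[i]:
            if d in used:
                continue
            used.add(d)
            assignment[i] = d
            backtrack(pos + 1)
            used.discard(d)
            del assignment[i]

    backtrack(0)

    ambiguous: list[set[tuple[str, str]]] = []
    if count > 1 and solutions:
        options: dict[int, set[str]] = {}
        for sol in solutions:
            for i, d in sol.items():
                options.setdefault(i, set()).add(d)
        by_option_set: dict[frozenset[str], set[tuple[str, str]]] = {}
        for i, opts in options.items():
            if len(opts) > 1:
                key = frozenset(opts)
                by_option_set.setdefault(key, set()).update(
                    donor_slots[class_donors[i]])
        ambiguous = [by_option_set[k] for k in sorted(by_option_set, key=sorted)]

    return IdentifiabilityReport(
        n_consistent_assignments=count,
        identifiable=(count == 1),
        ambiguous_groups=ambiguous,
        used_sex=use_sex,
    )


def design_cost(design: PoolingDesign) -> dict:
    """Reactions used, samples processed, and fold reduction vs one-per-reaction."""
    if not design.reactions:
        raise ValidationError("empty design")
    n_samples = sum(len(r.members) for r in design.reactions)
    n_reactions = len(design.reactions)
    return {
        "n_reactions": n_reactions,
        "n_samples": n_samples,
        "fold_reduction": n_samples / n_reactions,
    }
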