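"""Pooling-design generation, identifiability, and cost accounting."""

import pytest
import yaml

from conftest import forbidden_two_donor_design, make_roster
from oracles import brute_force_consistent_count

from pairpool.design import (PoolingDesign, Sex, Tissue, check_identifiability,
                             design_cost, design_strategy1, design_strategy2)
from pairpool.errors import InfeasibleDesignError, ValidationError

# the published 9-donor dual layout: reaction -> {(donor, tissue), ...}
TABLE2_INCIDENCE = [
    {("S1", "skin"), ("S2", "skin")},
    {("S2", "pbmc"), ("S3", "pbmc")},
    {("S4", "skin"), ("S5", "skin")},
    {("S5", "pbmc"), ("S6", "pbmc")},
    {("S7", "skin"), ("S8", "skin")},
    {("S8", "pbmc"), ("S9", "pbmc")},
    {("S3", "skin"), ("S6", "skin")},
    {("S1", "pbmc"), ("S4", "pbmc")},
    {("S7", "pbmc"), ("S9", "skin")},
]


class TestStrategy1:
    def test_nine_donors_reproduces_published_dual_layout(self, table2_design):
        smap = table2_design.sample_by_id()
        incidence = [
            {(smap[sid].donor_id, smap[sid].tissue.value) for sid in r.members}
            for r in table2_design.reactions
        ]
        assert incidence == TABLE2_INCIDENCE
        assert [a[0] for a in table2_design.anchors] == ["S2", "S5", "S8"]

    def test_three_donors_is_uniquely_decodable_without_sex(self):
        design = design_strategy1(make_roster(3))
        assert len(design.reactions) == 3
        report = check_identifiability(design, use_sex=False)
        assert report.identifiable
        assert report.n_consistent_assignments == \
            brute_force_consistent_count(design, use_sex=False) == 1

    def test_two_donors_is_infeasible(self):
        with pytest.raises(InfeasibleDesignError):
            design_strategy1(make_roster(2))

    def test_missing_tissue_is_rejected(self):
        roster = make_roster(3)
        tissues = {d.donor_id: [Tissue.SKIN, Tissue.PBMC] for d in roster}
        tissues["S2"] = [Tissue.SKIN]
        with pytest.raises(ValidationError, match="missing a tissue"):
            design_strategy1(roster, tissues=tissues)

    @pytest.mark.parametrize("n", range(3, 16))
    def test_reaction_count_and_self_identifiability(self, n):
        design = design_strategy1(make_roster(n))
        assert len(design.reactions) == n
        assert all(len(r.members) == 2 for r in design.reactions)
        assert check_identifiability(design, use_sex=False).identifiable


class TestStrategy2:
    def test_nine_donors_six_triplet_reactions(self, table3_design):
        assert len(table3_design.reactions) == 6
        assert all(len(r.members) == 3 for r in table3_design.reactions)
        # each dual block holds exactly one anchor whose pair spans the block
        assert len(table3_design.anchors) == 3
        smap = table3_design.sample_by_id()
        dmap = table3_design.donor_by_id()
        for donor_id, ra, rb in table3_design.anchors:
            pools = [
                {smap[s].donor_id for s in table3_design.reaction_by_id()[r].members}
                for r in (ra, rb)
            ]
            assert pools[0] & pools[1] == {donor_id}
        # the two filler members of every reaction differ in sex
        anchor_ids = {a[0] for a in table3_design.anchors}
        for r in table3_design.reactions:
            filler_sexes = [
                dmap[smap[s].donor_id].sex for s in r.members
                if smap[s].donor_id not in anchor_ids
            ]
            assert set(filler_sexes) == {Sex.MALE, Sex.FEMALE}

    def test_all_male_roster_is_infeasible(self):
        with pytest.raises(InfeasibleDesignError, match="female"):
            design_strategy2(make_roster(9, "M" * 9))

    @pytest.mark.parametrize("n", [4, 5, 7, 8])
    def test_non_multiple_of_three_is_infeasible(self, n):
        with pytest.raises(InfeasibleDesignError):
            design_strategy2(make_roster(n))

    def test_unknown_sex_is_rejected(self):
        roster = make_roster(9)
        roster[0] = type(roster[0])("S1", Sex.UNKNOWN)
        with pytest.raises(ValidationError, match="sex"):
            design_strategy2(roster)

    def test_six_donors_identifiable_with_sex_oracle_checked(self):
        design = design_strategy2(make_roster(6))
        assert len(design.reactions) == 4
        for use_sex in (False, True):
            report = check_identifiability(design, use_sex=use_sex)
            assert report.n_consistent_assignments == \
                brute_force_consistent_count(design, use_sex=use_sex)
        assert check_identifiability(design, use_sex=True).identifiable

    def test_naive_variant_pairing_a_filler_inside_its_block_is_flagged(self):
        # swap two male fillers' pbmc samples so that S3's skin and pbmc land
        # in the two reactions of one dual block: that block then shares two
        # same-sex genotypes and neither sharing nor sex can split them
        design = design_strategy2(make_roster(6))
        data = design.to_dict()
        by_id = {r["reaction_id"]: r["members"] for r in data["reactions"]}
        assert "S3-skin" in by_id["R01"]
        a = next(r for r, m in by_id.items() if "S3-pbmc" in m)
        b = next(r for r, m in by_id.items() if "S5-pbmc" in m)
        by_id[a][by_id[a].index("S3-pbmc")] = "S5-pbmc"
        by_id[b][by_id[b].index("S5-pbmc")] = "S3-pbmc"
        naive = PoolingDesign.from_dict(data)
        assert "S3-pbmc" in naive.reaction_by_id()["R02"].members
        report = check_identifiability(naive, use_sex=True)
        assert not report.identifiable
        n_oracle = brute_force_consistent_count(naive, use_sex=True)
        assert report.n_consistent_assignments == n_oracle
        assert n_oracle >= 2

    @pytest.mark.parametrize("n", [6, 9, 12, 15])
    def test_reaction_count_and_self_identifiability(self, n):
        design = design_strategy2(make_roster(n))
        assert len(design.reactions) == 2 * n // 3
        assert check_identifiability(design, use_sex=True).identifiable


class TestIdentifiabilityChecker:
    def test_dual_layout_unique_without_sex_matches_oracle(self, table2_design):
        report = check_identifiability(table2_design, use_sex=False)
        assert report.identifiable
        assert report.n_consistent_assignments == 1
        assert brute_force_consistent_count(table2_design, use_sex=False) == 1

    def test_triplet_layout_needs_sex_matches_oracle(self, table3_design):
        no_sex = check_identifiability(table3_design, use_sex=False)
        with_sex = check_identifiability(table3_design, use_sex=True)
        assert not no_sex.identifiable and no_sex.n_consistent_assignments >= 2
        assert with_sex.identifiable
        assert no_sex.n_consistent_assignments == \
            brute_force_consistent_count(table3_design, use_sex=False)
        assert brute_force_consistent_count(table3_design, use_sex=True) == 1
        # the filler pairs of each block are the interchangeable slots
        assert len(no_sex.ambiguous_groups) >= 1

    def test_forbidden_two_donor_swap_is_twofold_ambiguous(self):
        design = forbidden_two_donor_design()
        report = check_identifiability(design, use_sex=False)
        assert report.n_consistent_assignments == 2
        assert not report.identifiable
        assert report.ambiguous_groups  # the symmetric slots are reported

    def test_sex_constraint_removal_never_shrinks_solution_set(self):
        for n in (6, 9, 12):
            design = design_strategy2(make_roster(n))
            with_sex = check_identifiability(design, use_sex=True)
            no_sex = check_identifiability(design, use_sex=False)
            assert no_sex.n_consistent_assignments >= \
                with_sex.n_consistent_assignments

    def test_use_sex_requires_known_sexes(self):
        design = forbidden_two_donor_design()
        design.donors = [type(d)(d.donor_id, Sex.UNKNOWN)
                         for d in design.donors]
        with pytest.raises(ValidationError):
            check_identifiability(design, use_sex=True)


class TestCostAndSerialization:
    def test_fold_reduction(self, table2_design, table3_design):
        assert design_cost(table2_design) == {
            "n_reactions": 9, "n_samples": 18, "fold_reduction": 2.0}
        assert design_cost(table3_design) == {
            "n_reactions": 6, "n_samples": 18, "fold_reduction": 3.0}
        one = forbidden_two_donor_design()
        one.reactions = one.reactions[:1]
        one.samples = [s for s in one.samples
                       if s.sample_id in one.reactions[0].members]
        assert design_cost(one)["fold_reduction"] == 2.0

    def test_empty_design_rejected(self, table2_design):
        empty = PoolingDesign("dual", [], [], [], [])
        with pytest.raises(ValidationError):
            design_cost(empty)

    @pytest.mark.parametrize("fixture", ["table2_design", "table3_design"])
    def test_yaml_round_trip_is_lossless(self, fixture, request):
        design = request.getfixturevalue(fixture)
        data = yaml.safe_load(yaml.safe_dump(design.to_dict()))
        again = PoolingDesign.from_dict(data)
        assert again.to_dict() == design.to_dict()

    def test_validation_catches_paired_samples_in_one_reaction(self):
        design = forbidden_two_donor_design()
        data = design.to_dict()
        # put both of donor A's tissues in the first reaction
        data["reactions"][0]["members"] = ["A-pbmc", "A-skin"]
        data["reactions"][1]["members"] = ["B-skin", "B-pbmc"]
        with pytest.raises(ValidationError):
            PoolingDesign.from_dict(data)
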