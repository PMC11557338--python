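"""Binomial-mixture EM clusterer, doublet calling, consensus genotypes."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from conftest import counts_from_arrays, single_pool_design
from oracles import brute_force_best_loglik, complete_data_loglik

from pairpool.errors import ValidationError
from pairpool.genotype import (_cell_loglik, _m_step, call_doublets,
                               consensus_genotypes, fit_genotype_clusters)
from pairpool.simdata import SimConfig, simulate_donor_genotypes, \
    simulate_reaction


class TestFit:
    def test_single_cluster_recovers_pooled_alt_fraction(self):
        rng = np.random.default_rng(0)
        ref = rng.poisson(2, size=(30, 10))
        alt = rng.poisson(1, size=(30, 10))
        counts = counts_from_arrays(ref, alt)
        model, _ = fit_genotype_clusters(counts, K=1, eps=0.01)
        pooled = np.clip(alt.sum(0) / (alt.sum(0) + ref.sum(0)), 0.01, 0.99)
        np.testing.assert_allclose(model.allele_fraction[:, 0], pooled,
                                   atol=1e-9)

    def test_two_donor_default_conditions_high_ari(self, two_donor_sim):
        _, _, counts, _, truth, _ = two_donor_sim
        model, assign = fit_genotype_clusters(counts, K=2, seed=0)
        singlets = assign.singlet_clusters()
        pred = [singlets[b] for b in truth["barcode"] if b in singlets]
        true = [d for b, d in zip(truth["barcode"], truth["donor_id"])
                if b in singlets]
        assert adjusted_rand_score(true, pred) >= 0.95

    def test_zero_coverage_cell_is_unassigned(self):
        ref = np.array([[2, 0], [0, 0], [1, 1]])
        alt = np.array([[0, 1], [0, 0], [2, 0]])
        counts = counts_from_arrays(ref, alt)
        _, assign = fit_genotype_clusters(counts, K=1)
        assert assign.status[1] == "unassigned"
        assert assign.status[0] == assign.status[2] == "singlet"
        assert np.isnan(assign.log_prob_singleton[1])

    def test_k_larger_than_covered_cells_rejected(self):
        counts = counts_from_arrays(np.array([[1], [0]]), np.array([[1], [0]]))
        with pytest.raises(ValidationError):
            fit_genotype_clusters(counts, K=2)

    def test_em_total_loglik_is_nondecreasing(self):
        rng = np.random.default_rng(3)
        geno = rng.integers(0, 3, size=(2, 40))
        depth = rng.poisson(3, size=(60, 40))
        which = rng.integers(0, 2, size=60)
        p = np.choose(geno[which], [0.05, 0.5, 0.95])
        alt = rng.binomial(depth, p)
        counts = counts_from_arrays(depth - alt, alt)
        from scipy.special import logsumexp
        q = np.full((40, 2), [0.3, 0.7])
        prev = -np.inf
        for _ in range(25):
            ll = _cell_loglik(counts.ref, counts.alt, q)
            total = float(np.sum(logsumexp(ll, axis=1) - np.log(2)))
            assert total >= prev - 1e-9
            prev = total
            resp = np.exp(ll - logsumexp(ll, axis=1, keepdims=True))
            q = _m_step(counts.ref, counts.alt, resp, 0.01)

    def test_label_permutation_leaves_likelihood_and_calls_unchanged(self):
        rng = np.random.default_rng(7)
        ref = rng.poisson(2, size=(40, 20))
        alt = rng.poisson(2, size=(40, 20))
        counts = counts_from_arrays(ref, alt)
        model, _ = fit_genotype_clusters(counts, K=2, seed=5)
        flipped = type(model)(model.K, model.allele_fraction[:, ::-1].copy(),
                              model.log_likelihood, model.eps,
                              model.locus_keys)
        a = call_doublets(counts, model, delta=2.0)
        b = call_doublets(counts, flipped, delta=2.0)
        assert a.status == b.status
        np.testing.assert_allclose(a.log_prob_singleton, b.log_prob_singleton)
        np.testing.assert_allclose(a.log_prob_doublet, b.log_prob_doublet)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_em_matches_exhaustive_search_on_tiny_instances(self, seed):
        # <= 8 cells, 2 clusters, 4 loci: EM's best hard assignment must
        # attain the brute-force maximum complete-data likelihood
        design = single_pool_design(2)
        cfg = SimConfig(n_loci=4, cells_per_sample=4, mean_depth=6,
                        error_rate=0.05, doublet_rate=0.0,
                        maf_low=0.3, maf_high=0.7, seed=seed)
        g = simulate_donor_genotypes(design.donors, cfg)
        counts, _, _ = simulate_reaction(design, "R01", g, cfg)
        covered = np.asarray((counts.ref + counts.alt).sum(axis=1)).ravel() > 0
        ref = counts.ref.toarray()[covered]
        alt = counts.alt.toarray()[covered]
        _, assign = fit_genotype_clusters(counts, K=2, n_restarts=8,
                                          seed=seed, eps=0.05)
        labels = np.array([int(a) for a, c in zip(assign.assignment, covered)
                           if c])
        em_ll = complete_data_loglik(ref, alt, labels, 2, eps=0.05)
        best = brute_force_best_loglik(ref, alt, 2, eps=0.05)
        assert em_ll == pytest.approx(best, abs=1e-8)


@pytest.fixture(scope="module")
def doublet_sim():
    design = single_pool_design(2)
    cfg = SimConfig(cells_per_sample=200, mean_depth=5, doublet_rate=0.1,
                    seed=21)
    g = simulate_donor_genotypes(design.donors, cfg)
    counts, _, truth = simulate_reaction(design, "R01", g, cfg)
    model, _ = fit_genotype_clusters(counts, K=2, seed=0)
    return counts, truth, model


class TestDoublets:
    def test_infinite_margin_calls_no_doublets(self, doublet_sim):
        counts, _, model = doublet_sim
        assign = call_doublets(counts, model, delta=np.inf)
        assert "doublet" not in assign.status

    def test_cross_genotype_recall_at_depth_five(self, doublet_sim):
        counts, truth, model = doublet_sim
        assign = call_doublets(counts, model, delta=2.0)
        status = dict(zip(assign.barcodes, assign.status))
        cross = truth[truth["is_doublet"]
                      & (truth["second_donor_id"] != truth["donor_id"])]
        recall = np.mean([status[b] == "doublet" for b in cross["barcode"]])
        assert recall >= 0.8

    def test_pure_profile_cell_is_called_singlet(self, doublet_sim):
        counts, _, model = doublet_sim
        # a synthetic cell following cluster 0's profile exactly at depth 50
        q = model.allele_fraction[:, 0]
        depth = np.full(len(q), 50)
        alt = np.round(depth * q).astype(int)
        pure = counts_from_arrays((depth - alt)[None, :], alt[None, :])
        assign = call_doublets(pure, model, delta=2.0)
        assert assign.status == ["singlet"]
        assert assign.assignment == ["0"]

    def test_doublet_pair_is_distinct_and_recorded(self, doublet_sim):
        counts, _, model = doublet_sim
        assign = call_doublets(counts, model, delta=2.0)
        for st, a in zip(assign.status, assign.assignment):
            if st == "doublet":
                i, j = a.split("/")
                assert i != j

    def test_k1_model_rejected(self):
        counts = counts_from_arrays(np.ones((3, 2)), np.ones((3, 2)))
        model, _ = fit_genotype_clusters(counts, K=1)
        with pytest.raises(ValidationError):
            call_doublets(counts, model)


class TestConsensus:
    def test_threshold_bands(self):
        from pairpool.genotype import ClusterModel
        q = np.array([[0.5], [0.01], [0.99], [0.3]])
        model = ClusterModel(1, q, 0.0, 0.01, [f"L{i}" for i in range(4)])
        calls = consensus_genotypes(model, hom_threshold=0.1, het_band=0.15)
        assert calls[0, 0] == 0.5  # band center
        assert calls[1, 0] == 0.0  # clipped boundary
        assert calls[2, 0] == 1.0
        assert np.isnan(calls[3, 0])  # between bands -> no-call

    def test_overlapping_thresholds_rejected(self):
        from pairpool.genotype import ClusterModel
        model = ClusterModel(1, np.array([[0.5]]), 0.0, 0.01, ["L0"])
        with pytest.raises(ValidationError):
            consensus_genotypes(model, hom_threshold=0.4, het_band=0.15)

    def test_low_coverage_loci_are_no_calls(self, two_donor_sim):
        _, _, counts, _, _, _ = two_donor_sim
        model, assign = fit_genotype_clusters(counts, K=2, seed=0)
        calls = consensus_genotypes(model, counts, assign, min_reads=10 ** 6)
        assert np.isnan(calls).all()

    def test_calls_match_true_donor_genotypes(self, two_donor_sim):
        _, genotypes, counts, _, truth, _ = two_donor_sim
        model, assign = fit_genotype_clusters(counts, K=2, seed=0)
        assign = call_doublets(counts, model, delta=2.0)
        calls = consensus_genotypes(model, counts, assign)
        # map clusters to donors by majority vote of true labels
        singlets = assign.singlet_clusters()
        lab = truth.set_index("barcode")["donor_id"]
        acc = []
        for k in range(2):
            members = [b for b, c in singlets.items() if c == k]
            donor = lab.loc[members].mode()[0]
            true_calls = genotypes.column(donor) / 2.0
            called = ~np.isnan(calls[:, k])
            acc.append(np.mean(calls[called, k] == true_calls[called]))
        assert min(acc) >= 0.95
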