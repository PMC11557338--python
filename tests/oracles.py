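"""Independent brute-force oracles used to validate the implementation.

These deliberately avoid the package's own solver paths: identifiability is
checked by enumerating every per-reaction permutation, and the clustering
optimum by scoring every possible hard assignment.
"""

from itertools import combinations, permutations, product

import numpy as np

from pairpool.design import PoolingDesign, Sex


def brute_force_consistent_count(design: PoolingDesign,
                                 use_sex: bool = False) -> int:
    """Count slot->sample mappings consistent with noise-free observables.

    Enumerates the full product of per-reaction sample permutations and keeps
    those where (i) two slots get samples of the same donor exactly when
    their true samples share a donor, and (ii) if use_sex, each slot's
    candidate donor sex equals its true donor sex.
    """
    smap = design.sample_by_id()
    sex_of = {d.donor_id: d.sex for d in design.donors}
    rxns = design.reactions
    count = 0
    for combo in product(*[permutations(r.members) for r in rxns]):
        class_to_donor: dict[str, set[str]] = {}
        ok = True
        for r, perm in zip(rxns, combo):
            for true_sid, cand_sid in zip(r.members, perm):
                td = smap[true_sid].donor_id
                cd = smap[cand_sid].donor_id
                class_to_donor.setdefault(td, set()).add(cd)
                if use_sex and sex_of[cd] is not sex_of[td]:
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        donors_used = []
        for cands in class_to_donor.values():
            if len(cands) != 1:
                ok = False
                break
            donors_used.append(next(iter(cands)))
        if ok and len(set(donors_used)) == len(donors_used):
            count += 1
    return count


def complete_data_loglik(ref: np.ndarray, alt: np.ndarray,
                         labels: np.ndarray, K: int, eps: float) -> float:
    """Max complete-data log-likelihood of a hard assignment (optimal q)."""
    total = 0.0
    for k in range(K):
        rows = labels == k
        a = alt[rows].sum(axis=0)
        d = a + ref[rows].sum(axis=0)
        with np.errstate(invalid="ignore"):
            q = np.where(d > 0, a / np.maximum(d, 1), 0.5)
        q = np.clip(q, eps, 1 - eps)
        total += float((alt[rows] * np.log(q)).sum()
                       + (ref[rows] * np.log1p(-q)).sum())
    return total


def brute_force_best_loglik(ref: np.ndarray, alt: np.ndarray, K: int,
                            eps: float) -> float:
    """Exhaustive maximum of the complete-data log-likelihood over labelings."""
    n = ref.shape[0]
    best = -np.inf
    for labels in product(range(K), repeat=n):
        best = max(best,
                   complete_data_loglik(ref, alt, np.array(labels), K, eps))
    return best


def hwe_concordance_expectation(p: float) -> float:
    """P(two independent HWE donors share a genotype) at alt frequency p."""
    probs = [(1 - p) ** 2, 2 * p * (1 - p), p ** 2]
    return sum(x * x for x in probs)
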