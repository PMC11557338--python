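"""Sex inference from Y-gene expression and cluster-identity resolution.

After demultiplexing and cross-reaction matching, each (reaction, cluster)
slot must be resolved to one pooled sample.  Two observables drive this:

* genotype sharing — all slots in one match-graph component belong to one
  donor, and (for reaction pairs with enough co-called loci) slots in
  different components belong to different donors;
* donor sex — the percentage of a cluster's UMIs coming from a fixed list of
  Y-chromosome genes separates male from female donors by orders of
  magnitude, so a simple threshold call suffices.

Resolution is exact constraint satisfaction with exhaustive backtracking:
either a unique mapping, the full set of consistent alternatives
(ambiguous), or an inconsistency witness is returned — never a guess.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .design import PoolingDesign, Sex
from .errors import ValidationError
from .genotype import ClusterAssignment
from .linkage import MatchGraph, Node
from .simdata import Y_GENES

logger = logging.getLogger(__name__)

__all__ = ["SexCall", "IdentityAssignment", "infer_sex", "resolve_identities",
           "Y_GENES"]

#: default male-call threshold on y_pct (percent of UMIs from Y genes)
TAU_MALE_DEFAULT = 0.02


@dataclass
class SexCall:
    y_pct: float  # percent of cluster UMIs from Y genes
    call: str | None  # "male" | "female" | None (no-call: zero UMIs)
    n_cells: int
    total_umis: int


@dataclass
class IdentityAssignment:
    mapping: dict[Node, str]  # slots fixed across all consistent assignments
    status: str  # unique | ambiguous | inconsistent
    n_consistent: int
    assignments: list[dict[Node, str]]  # all consistent, capped
    evidence: list[str]
    witness: str | None = None  # violated constraint when inconsistent


def infer_sex(adata: AnnData, assignment: ClusterAssignment,
              y_genes: tuple[str, ...] = Y_GENES,
              tau_male: float = TAU_MALE_DEFAULT) -> dict[int, SexCall]:
    """Per-cluster sex call from the Y-gene share of the transcriptome.

    Aggregates singlet cells only (doublets mix two donors and would blur
    the signal): y_pct = 100 * (Y-gene UMIs) / (all UMIs) over the cluster's
    cells; the call is male iff y_pct >= ``tau_male``.  A cluster with zero
    total UMIs yields a no-call (``call=None``).
    """
    if not y_genes:
        raise ValidationError("y_gene_list must be non-empty")
    present = [g for g in y_genes if g in adata.var_names]
    missing = sorted(set(y_genes) - set(present))
    if not present:
        raise ValidationError("none of the Y genes is present in the features")
    if missing:
        warnings.warn(f"Y genes absent from features, skipped: {missing}")

    bc_index = {b: i for i, b in enumerate(adata.obs_names)}
    singlets = assignment.singlet_clusters()
    for b in singlets:
        if b not in bc_index:
            raise ValidationError(
                f"barcode {b!r} in cluster assignment but not in matrix")

    x = sp.csr_matrix(adata.X)
    y_cols = [adata.var_names.get_loc(g) for g in present]
    total_per_cell = np.asarray(x.sum(axis=1)).ravel()
    y_per_cell = np.asarray(x[:, y_cols].sum(axis=1)).ravel()

    clusters = sorted(set(singlets.values()))
    calls: dict[int, SexCall] = {}
    for k in clusters:
        rows = [bc_index[b] for b, c in singlets.items() if c == k]
        total = int(total_per_cell[rows].sum())
        y_tot = int(y_per_cell[rows].sum())
        if total == 0:
            calls[k] = SexCall(float("nan"), None, len(rows), 0)
            logger.warning("cluster %d has zero UMIs: sex no-call", k)
            continue
        y_pct = 100.0 * y_tot / total
        calls[k] = SexCall(y_pct, "male" if y_pct >= tau_male else "female",
                           len(rows), total)
    return calls


def resolve_identities(design: PoolingDesign, match_graph: MatchGraph,
                       sex_calls: dict[str, dict[int, SexCall]] | None = None,
                       max_enumeration: int = 100) -> IdentityAssignment:
    """Resolve every (reaction, cluster) slot to a pooled sample.

    Constraint model — variables are the match-graph components; a component
    spanning reactions {r1, ...} may take any donor with a sample in each of
    those reactions.  Constraints: per-reaction injectivity; distinct
    components in comparable reaction pairs take distinct donors; an assigned
    donor's sex must equal every sex call among the component's slots.
    Conflicted match-graph nodes are detached into singleton components
    (their sharing evidence is treated as unknown) with a warning.
    """
    design.validate()
    smap = design.sample_by_id()
    dmap = design.donor_by_id()
    donor_sample_in: dict[str, dict[str, str]] = {}
    for rxn in design.reactions:
        for sid in rxn.members:
            donor_sample_in.setdefault(smap[sid].donor_id, {})[
                rxn.reaction_id] = sid

    expected_slots = {
        (r.reaction_id, k) for r in design.reactions
        for k in range(len(r.members))
    }
    graph_nodes = set(match_graph.graph.nodes)
    if not expected_slots <= graph_nodes:
        raise ValidationError(
            "match graph does not cover every (reaction, cluster) slot "
            f"implied by the design: missing {sorted(expected_slots - graph_nodes)[:5]}")

    conflicted = set(match_graph.conflicts)
    if conflicted:
        warnings.warn(
            f"conflicted match-graph nodes relaxed to unknown: {sorted(conflicted)}")

    components: list[frozenset[Node]] = []
    for comp in match_graph.components:
        keep = {n for n in comp if n in expected_slots}
        clean = keep - conflicted
        if clean:
            components.append(frozenset(clean))
        for node in sorted(keep & conflicted):
            components.append(frozenset([node]))

    def slot_sex(node: Node) -> str | None:
        if sex_calls is None:
            return None
        call = sex_calls.get(node[0], {}).get(node[1])
        return call.call if call is not None else None

    # domains: donors with a sample in every reaction a component spans
    evidence: list[str] = []
    domains: list[list[str]] = []
    comp_rxns: list[frozenset[str]] = []
    for comp in components:
        rxns = {n[0] for n in comp}
        if len(rxns) < len(comp):
            return IdentityAssignment(
                {}, "inconsistent", 0, [], evidence,
                witness=f"component {sorted(comp)} has two slots in one reaction")
        comp_rxns.append(frozenset(rxns))
        sexes = {s for s in (slot_sex(n) for n in comp) if s is not None}
        if len(sexes) > 1:
            return IdentityAssignment(
                {}, "inconsistent", 0, [], evidence,
                witness=f"component {sorted(comp)} has conflicting sex calls")
        cand = [
            d for d, placed in sorted(donor_sample_in.items())
            if rxns <= set(placed)
            and (not sexes or (d in dmap and dmap[d].sex.value in sexes))
        ]
        if not cand:
            return IdentityAssignment(
                {}, "inconsistent", 0, [], evidence,
                witness=f"no donor fits component {sorted(comp)}")
        domains.append(cand)
        if len(comp) > 1:
            evidence.append(
                f"component {sorted(comp)} spans reactions {sorted(rxns)}; "
                f"candidate donors: {cand}")

    order = sorted(range(len(components)), key=lambda i: len(domains[i]))
    chosen: dict[int, str] = {}
    rxn_used: dict[str, set[str]] = {}  # reaction -> donors taken
    donor_comps: dict[str, list[int]] = {}
    solutions: list[dict[Node, str]] = []
    n_solutions = 0

    def compatible(i: int, d: str) -> bool:
        for r in comp_rxns[i]:
            if d in rxn_used.get(r, set()):
                return False  # injectivity within the reaction
        # same donor on two components only if no comparable reaction pair
        for j in donor_comps.get(d, ()):
            for ra in comp_rxns[i]:
                for rb in comp_rxns[j]:
                    if frozenset((ra, rb)) in match_graph.comparable:
                        return False
        return True

    def backtrack(pos: int) -> None:
        nonlocal n_solutions
        if pos == len(order):
            n_solutions += 1
            if n_solutions <= max_enumeration:
                sol: dict[Node, str] = {}
                for i, comp in enumerate(components):
                    d = chosen[i]
                    for node in comp:
                        sol[node] = donor_sample_in[d][node[0]]
                solutions.append(sol)
            return
        i = order[pos]
        for d in domains[i]:
            if not compatible(i, d):
                continue
            chosen[i] = d
            for r in comp_rxns[i]:
                rxn_used.setdefault(r, set()).add(d)
            donor_comps.setdefault(d, []).append(i)
            backtrack(pos + 1)
            donor_comps[d].pop()
            for r in comp_rxns[i]:
                rxn_used[r].discard(d)
            del chosen[i]

    backtrack(0)

    if n_solutions == 0:
        return IdentityAssignment({}, "inconsistent", 0, [], evidence,
                                  witness="no consistent assignment exists")
    fixed: dict[Node, str] = {}
    for node in solutions[0]:
        values = {sol[node] for sol in solutions}
        if len(values) == 1 and n_solutions <= max_enumeration:
            fixed[node] = solutions[0][node]
    if n_solutions == 1:
        fixed = solutions[0]
        for node in sorted(fixed):
            evidence.append(f"slot {node} -> {fixed[node]}")
    status = "unique" if n_solutions == 1 else "ambiguous"
    return IdentityAssignment(fixed, status, n_solutions, solutions, evidence)


def sex_calls_table(sex_calls: dict[str, dict[int, SexCall]]) -> pd.DataFrame:
    rows = [
        (rxn, k, c.y_pct, c.call or "no-call", c.n_cells, c.total_umis)
        for rxn, calls in sorted(sex_calls.items())
        for k, c in sorted(calls.items())
    ]
    return pd.DataFrame(rows, columns=["reaction", "cluster", "y_pct", "call",
                                       "n_cells", "total_umis"])
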