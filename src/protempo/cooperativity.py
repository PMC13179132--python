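"""Cooperative-protein detection around known complexes and pathways.

A cooperative protein is a network node outside a known module whose edges
to the module's members are enriched beyond chance.  For each (candidate,
module) pair the network's edge set is partitioned into a 2x2 table:

    a  edges linking the candidate to module members
    b  edges touching the module but not the candidate (intra-module
       edges included, preserving the partition)
    c  edges touching the candidate but not the module
    d  edges touching neither

``a + b + c + d`` always equals the edge count of the (sign-selected)
network under test.  Significance is a one-sided Fisher exact test
(enrichment direction), BH-adjusted jointly across *all* (candidate,
module) tests.  Positive edges are counted by default.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .datatypes import CorrelationNetwork, GeneSetCollection, ValidationError
from .stats import bh_adjust, fisher_one_sided

log = logging.getLogger(__name__)

RESULT_COLUMNS = ["candidate", "module", "a", "b", "c", "d",
                  "p_raw", "p_adj", "significant"]


def cooperative_proteins(
    network: CorrelationNetwork,
    modules: GeneSetCollection,
    edge_sign: str = "positive",
    alpha: float = 0.05,
    min_module_members: int = 3,
) -> pd.DataFrame:
    """Fisher-exact cooperativity of every network node against every module.

    Candidates are all network nodes outside the module's detected members.
    Modules with fewer than ``min_module_members`` members in the network
    are skipped (logged).  Results are sorted by adjusted p, then by larger
    ``a``, then candidate ID.
    """
    edges = network.signed(edge_sign)
    n_edges = len(edges)
    nodes = sorted(network.nodes)
    node_pos = {n: i for i, n in enumerate(nodes)}
    ea = edges["protein_a"].map(node_pos).to_numpy()
    eb = edges["protein_b"].map(node_pos).to_numpy()
    degree = np.zeros(len(nodes), dtype=int)
    np.add.at(degree, ea, 1)
    np.add.at(degree, eb, 1)

    frames = []
    for gs in modules:
        members = gs.detected if gs.detected is not None else gs.members
        present = set(members) & set(nodes)
        if len(present) < min_module_members:
            log.info("skipping module %r: %d member(s) in network",
                     gs.name, len(present))
            continue
        in_mod = np.zeros(len(nodes), dtype=bool)
        in_mod[[node_pos[m] for m in present]] = True
        a_in = in_mod[ea]
        b_in = in_mod[eb]
        touches = a_in | b_in
        t_m = int(touches.sum())
        # edges with exactly one endpoint in the module credit the outside node
        a_counts = np.zeros(len(nodes), dtype=int)
        one_sided = a_in ^ b_in
        outside = np.where(a_in[one_sided], eb[one_sided], ea[one_sided])
        np.add.at(a_counts, outside, 1)
        cand_mask = ~in_mod
        cand_idx = np.flatnonzero(cand_mask)
        a = a_counts[cand_idx]
        b = t_m - a
        c = degree[cand_idx] - a
        d = n_edges - a - b - c
        assert np.all(a + b + c + d == n_edges), "2x2 partition broken"
        frames.append(pd.DataFrame({
            "candidate": [nodes[i] for i in cand_idx],
            "module": gs.name,
            "a": a, "b": b, "c": c, "d": d,
        }))
    if not frames:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    out = pd.concat(frames, ignore_index=True)
    # a = 0 can never be enriched one-sided: P(X >= 0) = 1 by construction
    out["p_raw"] = fisher_one_sided(out["a"], out["b"], out["c"], out["d"])
    out["p_adj"] = bh_adjust(out["p_raw"].to_numpy())
    out["significant"] = out["p_adj"] < alpha
    out = out.sort_values(
        ["p_adj", "a", "candidate"], ascending=[True, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    return out[RESULT_COLUMNS]


def withheld_member_validation(
    network: CorrelationNetwork,
    complex_members: set[str],
    withheld: set[str],
    edge_sign: str = "positive",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Rank withheld complex members among the reduced module's candidates.

    The module is reduced to ``members - withheld`` and cooperativity is
    recomputed; each withheld member's 1-based rank (by adjusted p, ties by
    larger ``a`` then candidate ID) is reported.  Withholding everything is
    an error; withholding nothing returns an empty rank table.
    """
    withheld = set(withheld)
    complex_members = set(complex_members)
    if not withheld <= complex_members:
        raise ValidationError("withheld proteins must be complex members")
    remaining = complex_members - withheld
    if not remaining:
        raise ValidationError("cannot withhold every complex member")
    if not withheld:
        return pd.DataFrame(columns=["candidate", "rank", "p_adj", "a"])
    from .datatypes import GeneSet

    reduced = GeneSetCollection({
        "reduced": GeneSet("reduced", frozenset(remaining), "complex")
    })
    results = cooperative_proteins(network, reduced, edge_sign=edge_sign,
                                   alpha=alpha)
    results = results.reset_index(drop=True)
    results["rank"] = np.arange(1, len(results) + 1)
    hit = results[results["candidate"].isin(withheld)]
    return hit[["candidate", "rank", "p_adj", "a"]].reset_index(drop=True)


def shared_cooperativity(
    results: pd.DataFrame,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Jaccard similarity of significant cooperative sets between modules.

    ``J(M1, M2) = |coop(M1) & coop(M2)| / |coop(M1) | coop(M2)|`` over
    significant cooperative proteins.  Modules with an empty cooperative set
    keep their (all-zero) row, flagged by a log message.  Returns the
    Jaccard matrix and an average-linkage hierarchy over its rows using
    Euclidean distances.
    """
    modules = sorted(results["module"].unique())
    if len(modules) < 2:
        raise ValidationError("need >= 2 modules for shared-cooperativity analysis")
    coop = {
        m: set(results.loc[(results["module"] == m) & results["significant"],
                           "candidate"])
        for m in modules
    }
    for m, s in coop.items():
        if not s:
            log.warning("module %r has no significant cooperative proteins", m)
    jac = np.zeros((len(modules), len(modules)))
    for i, m1 in enumerate(modules):
        for j, m2 in enumerate(modules):
            union = coop[m1] | coop[m2]
            jac[i, j] = len(coop[m1] & coop[m2]) / len(union) if union else 0.0
    jdf = pd.DataFrame(jac, index=modules, columns=modules)
    link = hierarchy.linkage(pdist(jac, metric="euclidean"), method="average")
    return jdf, link


def linkage_to_newick(link: np.ndarray, labels: list[str]) -> str:
    """Serialize a scipy linkage matrix as a newick string."""
    tree = hierarchy.to_tree(link)

    def _walk(node) -> str:
        if node.is_leaf():
            return labels[node.id]
        left = _walk(node.get_left())
        right = _walk(node.get_right())
        return f"({left}:{node.dist / 2:.6g},{right}:{node.dist / 2:.6g})"

    return _walk(tree) + ";"


def ppi_support(
    results: pd.DataFrame,
    ppi: set[frozenset[str]],
    modules: GeneSetCollection,
) -> tuple[pd.DataFrame, dict]:
    """Interaction support for significant cooperative (candidate, module) hits.

    A hit is supported when the candidate has at least one catalogued
    interaction with any module member.  Returns the significant results
    with a ``ppi_supported`` column plus global fractions (of cooperative
    edges, and of distinct cooperative proteins, with support).
    """
    sig = results[results["significant"]].copy()
    supported = []
    for cand, module in zip(sig["candidate"], sig["module"]):
        gs = modules[module]
        members = gs.detected if gs.detected is not None else gs.members
        supported.append(any(frozenset((cand, m)) in ppi for m in members))
    sig["ppi_supported"] = supported
    frac_edges = float(np.mean(supported)) if supported else 0.0
    by_protein = sig.groupby("candidate")["ppi_supported"].any()
    frac_proteins = float(by_protein.mean()) if len(by_protein) else 0.0
    return sig, {
        "n_significant": len(sig),
        "fraction_edges_supported": frac_edges,
        "fraction_proteins_supported": frac_proteins,
    }
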