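"""Multi-species combination of motif scores.

Orthologous window scores from several species are combined either by a
simple arithmetic mean or by a Brownian-motion (BM) temporal tree
average: the score is modeled as a trait evolving by BM along the
phylogeny, and the reported value is the expected time-average of the
trait over all branches, conditioned on the observed leaf values,

    E[ (1/T) \\int_tree X(t) dt | leaves ]
      = sum_b  tau_b * (m_parent(b) + m_child(b)) / 2  /  sum_b tau_b,

where ``m_v`` is the posterior mean of the trait at node ``v`` and
``tau_b`` the branch length.  The posterior means are computed with a
diffuse (flat) root prior by one upward (pruning) and one downward pass,
each O(n) in the number of species; because conditional Gaussian means
do not depend on the BM rate, the result is rate-free.  A quadratic-time
covariance-conditioning oracle is provided for cross-validation.
"""

from __future__ import annotations

from typing import Mapping

import dendropy
import numpy as np

from .hmm import MotifProfile

_INF = float("inf")

LeafValues = Mapping[str, float]


def _leaf_label(node: dendropy.Node) -> str:
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    return node.label or ""


def simple_average(values: LeafValues) -> float:
    """Unweighted mean over the observed species (missing ones omitted)."""
    if len(values) == 0:
        raise ValueError("no observed species")
    return float(np.mean(list(values.values())))


def _combine(messages):
    """Precision-weighted product of Gaussian messages (mean, var).

    var may be 0 (exact observation) or inf (no information).
    """
    for m, v in messages:
        if v == 0.0:
            return m, 0.0
    prec = 0.0
    pm = 0.0
    for m, v in messages:
        if v == _INF:
            continue
        prec += 1.0 / v
        pm += m / v
    if prec == 0.0:
        return 0.0, _INF
    return pm / prec, 1.0 / prec


def _check_inputs(tree: dendropy.Tree, values: LeafValues):
    leaf_labels = {_leaf_label(n) for n in tree.leaf_node_iter()}
    unknown = set(values) - leaf_labels
    if unknown:
        raise ValueError(f"values given for non-leaf taxa: {sorted(unknown)}")
    if len(values) < 2:
        raise ValueError("BM averaging needs at least 2 observed leaves")
    total = 0.0
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        if edge.length is None or edge.length < 0:
            raise ValueError("tree has a branch without a valid length")
        total += edge.length
    if total <= 0:
        raise ValueError("tree has zero total branch length")
    return total


def bm_tree_average(tree: dendropy.Tree, values: LeafValues) -> float:
    """Linear-time BM temporal tree average (upward-downward algorithm)."""
    total = _check_inputs(tree, values)
    up: dict[int, tuple[float, float]] = {}
    # upward (pruning) pass: message from the subtree below each node
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = _leaf_label(node)
            if label in values:
                up[id(node)] = (float(values[label]), 0.0)
            else:
                up[id(node)] = (0.0, _INF)
        else:
            msgs = []
            for child in node.child_nodes():
                m, v = up[id(child)]
                tau = child.edge.length or 0.0
                msgs.append((m, v if v == _INF else v + tau))
            up[id(node)] = _combine(msgs)
    # downward pass: message from the rest of the tree, then posterior mean
    down: dict[int, tuple[float, float]] = {id(tree.seed_node): (0.0, _INF)}
    mean: dict[int, float] = {}
    for node in tree.preorder_node_iter():
        m, v = _combine([down[id(node)], up[id(node)]])
        if v == _INF:
            raise ValueError("posterior undefined (no observed leaves reach node)")
        mean[id(node)] = m
        children = node.child_nodes()
        for child in children:
            sib_msgs = [down[id(node)]]
            for sib in children:
                if sib is child:
                    continue
                ms, vs = up[id(sib)]
                tau_s = sib.edge.length or 0.0
                sib_msgs.append((ms, vs if vs == _INF else vs + tau_s))
            md, vd = _combine(sib_msgs)
            tau = child.edge.length or 0.0
            down[id(child)] = (md, vd if vd == _INF else vd + tau)
    num = 0.0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        tau = node.edge.length or 0.0
        num += tau * 0.5 * (mean[id(node.parent_node)] + mean[id(node)])
    return num / total


def bm_tree_average_oracle(tree: dendropy.Tree, values: LeafValues) -> float:
    """Quadratic-time reference: explicit Gaussian conditioning.

    Treats the root value as an unknown constant mu estimated by GLS;
    under BM the covariance of two nodes is their shared path length
    from the root.  Conditional means of all nodes follow from one
    linear solve.  For testing the O(n) algorithm only.
    """
    total = _check_inputs(tree, values)
    nodes = [n for n in tree.preorder_node_iter() if n.parent_node is not None]
    idx = {id(n): i for i, n in enumerate(nodes)}
    # depth (path length from root) and ancestor chains
    depth = {id(tree.seed_node): 0.0}
    for n in nodes:
        depth[id(n)] = depth[id(n.parent_node)] + (n.edge.length or 0.0)

    def shared(a, b):
        anc_a = {}
        x = a
        while x is not None:
            anc_a[id(x)] = depth[id(x)]
            x = x.parent_node
        x = b
        while x is not None:
            if id(x) in anc_a:
                return depth[id(x)]
            x = x.parent_node
        return 0.0

    obs = [
        n for n in nodes
        if n.is_leaf() and _leaf_label(n) in values
    ]
    y = np.array([values[_leaf_label(n)] for n in obs])
    k = len(obs)
    S = np.empty((k, k))
    for i in range(k):
        for j in range(k):
            S[i, j] = depth[id(obs[i])] if i == j else shared(obs[i], obs[j])
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as e:
        raise ValueError(f"singular conditioning system: {e}") from e
    ones = np.ones(k)
    denom = ones @ Sinv @ ones
    if denom <= 0:
        raise ValueError("singular conditioning system")
    mu = (ones @ Sinv @ y) / denom
    resid = Sinv @ (y - mu)
    mean = {id(tree.seed_node): float(mu)}
    for n in nodes:
        c = np.array([shared(n, o) if n is not o else depth[id(n)] for o in obs])
        mean[id(n)] = float(mu + c @ resid)
    num = 0.0
    for n in nodes:
        tau = n.edge.length or 0.0
        num += tau * 0.5 * (mean[id(n.parent_node)] + mean[id(n)])
    return num / total


def combine_profiles(
    tree: dendropy.Tree,
    profiles: Mapping[str, MotifProfile],
    orthology_map: Mapping[int, Mapping[str, int]],
    method: str = "simple",
    reference: str | None = None,
) -> MotifProfile:
    """Combine per-species window profiles into a multi-species profile.

    ``orthology_map`` sends each reference-species window index to the
    orthologous window index in each other species (precomputed; indels
    and alignment are out of scope here).  Windows with no orthologs
    keep the reference-species score.
    """
    if method not in ("simple", "bm"):
        raise ValueError(f"unknown averaging method {method!r}")
    if reference is None:
        reference = next(iter(profiles))
    ref = profiles[reference]
    combined = np.empty_like(ref.scores)
    for i in range(len(ref.scores)):
        vals = {reference: float(ref.scores[i])}
        for sp, j in orthology_map.get(i, {}).items():
            if sp == reference:
                continue
            vals[sp] = float(profiles[sp].scores[j])
        if len(vals) == 1:
            combined[i] = vals[reference]
        elif method == "simple":
            combined[i] = simple_average(vals)
        else:
            combined[i] = bm_tree_average(tree, vals)
    return MotifProfile(
        tf_name=ref.tf_name,
        windows=list(ref.windows),
        scores=combined,
        species="combined",
    )
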