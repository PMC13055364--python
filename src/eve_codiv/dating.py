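"""Relative-rate (RelTime-style) divergence dating with host calibrations.

A rooted tree with substitutions/site branch lengths is converted into
relative node times without assuming a global clock: at every internal
node the two descendant lineage lengths (stem branch plus mean tip path
within the already rate-corrected subtree) are equalised by assigning
the lineages relative rates r_i = 2·L_i/(L_1+L_2); corrections propagate
multiplicatively toward the tips, so each node's corrected mean tip-path
depth is its relative height (root = 1). Point calibrations — externally
known node ages, here host divergence times in MYA — are fitted by least
squares through the origin to give the scale from relative height to
absolute age; maximum-age calibrations are checked post hoc. Outgroup
nodes are excluded from timing: ingroup rates are not assumed to apply
to the outgroup, so heights are estimated on the ingroup subtree only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import yaml

__all__ = ["CalibrationPoint", "TimedTree", "reltime_heights", "reltime",
           "calibrate", "load_calibrations"]


@dataclass
class CalibrationPoint:
    mrca_of: tuple[str, str]
    age_mya: float
    kind: str = "point"          # point | max

    def __post_init__(self):
        if self.age_mya <= 0:
            raise ValueError("calibration age must be positive")
        if self.kind not in ("point", "max"):
            raise ValueError("kind must be 'point' or 'max'")


@dataclass
class TimedTree:
    tree: dendropy.Tree
    relative_heights: dict        # node -> height in [0, 1]; timed nodes only
    lineage_rates: dict           # node -> relative rate of its stem branch
    outgroup: set = field(default_factory=set)
    absolute_ages: dict = field(default_factory=dict)
    scale: float | None = None
    max_violations: list = field(default_factory=list)

    def age_table(self):
        rows = []
        for node, h in sorted(self.relative_heights.items(),
                              key=lambda kv: -kv[1]):
            tips = sorted(t.taxon.label for t in node.leaf_iter())
            label = (node.taxon.label if node.taxon
                     else f"mrca({tips[0]},{tips[-1]})")
            rows.append({"node": label, "relative_height": h,
                         "age_mya": self.absolute_ages.get(node)})
        return rows


def _binarize(tree: dendropy.Tree) -> None:
    """Resolve polytomies arbitrarily with zero-length branches."""
    tree.resolve_polytomies(limit=2, update_bipartitions=False)


def reltime_heights(tree: dendropy.Tree
                    ) -> tuple[dict, dict]:
    """Relative node heights and per-branch relative lineage rates.

    Bottom-up pass: at node v with children A and B, lineage lengths
    L_A, L_B are the stem branches plus each child's locally corrected
    mean tip-path; rates r = 2L/(L_A+L_B) equalise the two sides, giving
    v the local height (L_A+L_B)/2. Top-down pass: dividing a child's
    subtree by its rate rescales everything below, so the final height
    of a node is its local height divided by the product of the rates on
    its root path; the per-branch lineage rate is that same cumulative
    product. Heights are returned normalised by the root height.
    """
    root = tree.seed_node
    if root is None or len(root.child_nodes()) == 0:
        raise ValueError("tree must be rooted with at least one split")
    _binarize(tree)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ValueError("negative branch length")

    local_h: dict = {}
    local_rate: dict = {}
    for node in tree.postorder_node_iter():
        kids = node.child_nodes()
        if not kids:
            local_h[node] = 0.0
            continue
        if len(kids) != 2:
            raise ValueError("tree must be binary after polytomy resolution")
        L = [(k.edge.length or 0.0) + local_h[k] for k in kids]
        total = L[0] + L[1]
        for k, li in zip(kids, L):
            r = 2.0 * li / total if total > 0 else 1.0
            # a zero-length lineage has zero depth everywhere below it;
            # rate 1 keeps the cumulative correction well defined
            local_rate[k] = r if r > 0 else 1.0
        local_h[node] = total / 2.0

    heights: dict = {}
    cum_rate: dict = {root: 1.0}
    lineage_rates: dict = {}
    for node in tree.preorder_node_iter():
        if node is not root:
            cum_rate[node] = cum_rate[node.parent_node] * local_rate[node]
            lineage_rates[node] = cum_rate[node]
        heights[node] = local_h[node] / cum_rate[node]

    root_h = heights[root]
    if root_h <= 0:
        raise ValueError("tree has zero total depth")
    rel = {n: h / root_h for n, h in heights.items()}
    return rel, lineage_rates


def _ingroup_subtree(tree: dendropy.Tree, outgroup_tips: set[str]):
    """Check monophyly of the outgroup at the root and return the ingroup
    root node; raises if the outgroup does not form one side of the root."""
    all_tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if not outgroup_tips:
        return tree.seed_node, set()
    if outgroup_tips >= all_tips:
        raise ValueError("outgroup cannot contain every tip")
    if not outgroup_tips <= all_tips:
        raise ValueError("outgroup tips missing from tree")
    kids = tree.seed_node.child_nodes()
    for k in kids:
        tips = {leaf.taxon.label for leaf in k.leaf_iter()}
        if tips == all_tips - outgroup_tips:
            out_nodes = set()
            for other in kids:
                if other is not k:
                    out_nodes.add(other)
                    out_nodes.update(other.preorder_iter())
            return k, out_nodes
    raise ValueError("outgroup is not monophyletic at the root")


def reltime(tree: dendropy.Tree | str,
            outgroup: set[str] | None = None) -> TimedTree:
    """Time a rooted tree, excluding ``outgroup`` tips from estimation."""
    if isinstance(tree, str):
        tree = dendropy.Tree.get(data=tree, schema="newick",
                                 preserve_underscores=True)
    tree.is_rooted = True
    outgroup = set(outgroup or ())
    ingroup_root, out_nodes = _ingroup_subtree(tree, outgroup)
    if outgroup:
        sub = tree.clone(depth=1)
        ingroup = [l.taxon.label for l in tree.leaf_node_iter()
                   if l.taxon.label not in outgroup]
        sub.retain_taxa_with_labels(ingroup)
    else:
        sub = tree.clone(depth=1)
    rel, rates = reltime_heights(sub)
    # map back by leaf-set signature
    by_sig = {frozenset(l.taxon.label for l in n.leaf_iter()): n
              for n in tree.preorder_node_iter()
              if n not in out_nodes}
    rel_main, rates_main = {}, {}
    for node, h in rel.items():
        sig = frozenset(l.taxon.label for l in node.leaf_iter())
        if sig in by_sig:
            rel_main[by_sig[sig]] = h
    for node, r in rates.items():
        sig = frozenset(l.taxon.label for l in node.leaf_iter())
        if sig in by_sig:
            rates_main[by_sig[sig]] = r
    return TimedTree(tree=tree, relative_heights=rel_main,
                     lineage_rates=rates_main, outgroup=outgroup)


def calibrate(timed: TimedTree,
              calibrations: list[CalibrationPoint]) -> TimedTree:
    """Fit the relative-to-absolute scale and assign node ages (MYA).

    scale = sum(t_i * a_i) / sum(t_i^2) over point calibrations (least
    squares through the origin); max-type calibrations are verified
    afterwards and violations recorded on the result.
    """
    pts, maxs = [], []
    for cal in calibrations:
        node = _find_mrca(timed, cal)
        (pts if cal.kind == "point" else maxs).append((node, cal))
    if not pts:
        raise ValueError("at least one point calibration is required")
    t = np.array([timed.relative_heights[n] for n, _ in pts])
    a = np.array([c.age_mya for _, c in pts])
    scale = float((t * a).sum() / (t * t).sum())
    timed.scale = scale
    timed.absolute_ages = {n: scale * h
                           for n, h in timed.relative_heights.items()}
    timed.max_violations = [
        (cal, timed.absolute_ages[node])
        for node, cal in maxs if timed.absolute_ages[node] > cal.age_mya]
    return timed


def _find_mrca(timed: TimedTree, cal: CalibrationPoint):
    a, b = cal.mrca_of
    if a in timed.outgroup or b in timed.outgroup:
        raise ValueError(f"calibration {cal.mrca_of} touches the outgroup")
    node = timed.tree.mrca(taxon_labels=[a, b])
    if node is None or node not in timed.relative_heights:
        raise ValueError(f"calibration node for {cal.mrca_of} is untimed")
    return node


def load_calibrations(path) -> list[CalibrationPoint]:
    """YAML list of {mrca: [tipA, tipB], age_mya: float, kind: point|max}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return [CalibrationPoint(tuple(item["mrca"]), float(item["age_mya"]),
                             item.get("kind", "point"))
            for item in raw]
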