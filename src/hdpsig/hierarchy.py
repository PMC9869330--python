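"""Hierarchy of Dirichlet processes over a tumor cohort.

The model nests Dirichlet processes: every tumor (catalog sample) has its own
DP whose base distribution is a parent DP shared across tumors, and ultimately
the root DP draws brand-new signatures from a symmetric Dirichlet base over
the mutation classes.  Two layouts are supported:

* two-layer: a single root DP is the parent of every tumor's DP;
* three-layer: tumors are grouped (typically by cancer type); each group has
  its own DP under the root, and tumor DPs sit under their group's DP.

Each node carries a concentration parameter; by default all nodes at the same
depth share one (per-level grouping), optionally every node gets its own.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["HdpHierarchy", "build_hierarchy"]


@dataclass
class HdpHierarchy:
    """Tree of DP nodes: index 0 is the root; leaves map 1:1 to samples."""

    parent: list[int]           # parent[0] == -1 (the Dirichlet base H)
    node_kind: list[str]        # "root" | "group" | "leaf"
    leaf_sample: dict[int, int]  # node index -> catalog sample index
    cp_group: list[int]         # node index -> concentration-parameter group

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def n_cp_groups(self) -> int:
        return max(self.cp_group) + 1

    @property
    def leaves(self) -> list[int]:
        return [i for i, k in enumerate(self.node_kind) if k == "leaf"]

    def sample_leaf(self) -> dict[int, int]:
        """Inverse of ``leaf_sample``: catalog sample index -> leaf node."""
        return {s: n for n, s in self.leaf_sample.items()}

    def validate(self) -> None:
        if self.node_kind[0] != "root" or self.parent[0] != -1:
            raise ValueError("node 0 must be the root with parent -1")
        if self.node_kind.count("root") != 1:
            raise ValueError("exactly one root required")
        for i in range(1, self.n_nodes):
            if not 0 <= self.parent[i] < i:
                raise ValueError("parents must precede children (tree order)")
        samples = sorted(self.leaf_sample.values())
        if samples != list(range(len(samples))):
            raise ValueError("leaves must cover samples 0..n-1 exactly once")


def build_hierarchy(
    sample_ids: list[str],
    sample_groups: dict[str, str] | None = None,
    per_node_alpha: bool = False,
) -> HdpHierarchy:
    """Build a two-layer (no groups) or three-layer (grouped) DP hierarchy.

    Parameters
    ----------
    sample_ids:
        Catalog sample identifiers, in catalog column order.
    sample_groups:
        Optional map sample id -> group label (e.g. cancer type).  When given,
        every sample must be covered and a group node is inserted per label.
    per_node_alpha:
        If True each node gets its own concentration parameter; otherwise one
        parameter is shared per hierarchy level.
    """
    if not sample_ids:
        raise ValueError("sample_ids must be non-empty")
    parent = [-1]
    kind = ["root"]
    leaf_sample: dict[int, int] = {}
    level = [0]
    if sample_groups is None:
        for s, _ in enumerate(sample_ids):
            parent.append(0)
            kind.append("leaf")
            level.append(1)
            leaf_sample[len(parent) - 1] = s
    else:
        missing = [s for s in sample_ids if s not in sample_groups]
        if missing:
            raise ValueError(f"samples missing from sample_groups: {missing}")
        group_node: dict[str, int] = {}
        for sid in sample_ids:  # group order = first appearance
            g = sample_groups[sid]
            if g not in group_node:
                parent.append(0)
                kind.append("group")
                level.append(1)
                group_node[g] = len(parent) - 1
        for s, sid in enumerate(sample_ids):
            parent.append(group_node[sample_groups[sid]])
            kind.append("leaf")
            level.append(2)
            leaf_sample[len(parent) - 1] = s
    if per_node_alpha:
        cp_group = list(range(len(parent)))
    else:
        cp_group = level
    return HdpHierarchy(parent, kind, leaf_sample, cp_group)
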