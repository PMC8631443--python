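"""Three-level cell-type taxonomy used for hierarchical marker selection.

The default tree covers 24 leaf cell types. Level 1 splits the tissue into
epithelial, endothelial, fibroblast and immune compartments; the immune
compartment subdivides at level 2 into lineages, and lineages subdivide at
level 3 into fine phenotypes — among them the three natural-killer activation
phenotypes (resting, IL-2-expanded, PDGF-DD-activated) that this package
tracks through deconvolution and survival analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field


#: Default tree: level-1 unit -> level-2 unit -> tuple of leaves.
#: A unit mapping to an empty tuple is itself a leaf at that level.
DEFAULT_TREE: dict[str, dict[str, tuple[str, ...]]] = {
    "epithelial": {},
    "endothelial": {},
    "fibroblast": {},
    "immune": {
        "b_cell": ("b_memory", "b_naive"),
        "dendritic": ("dc_immature", "dc_mature"),
        "granulocyte": ("eosinophil", "neutrophil", "mast"),
        "macrophage": ("macrophage_m1", "macrophage_m2"),
        "monocyte": (),
        "nk": ("nk_resting", "nk_il2", "nk_pdgfdd"),
        "t_cell": (
            "t_cd4_cm",
            "t_cd4_em",
            "t_cd8_cm",
            "t_cd8_em",
            "t_cd8_naive",
            "t_gd",
            "t_helper",
            "t_reg",
        ),
    },
}


@dataclass(frozen=True)
class CellTypeTaxonomy:
    """A fixed three-level hierarchy of cell-type categories.

    ``tree`` maps each level-1 unit to its level-2 units, each mapping to a
    tuple of level-3 leaves.  A unit with no children is a leaf at its own
    level (e.g. ``epithelial`` at level 1, ``monocyte`` at level 2).
    """

    tree: dict[str, dict[str, tuple[str, ...]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_TREE.items()
        }
    )

    def __post_init__(self) -> None:
        leaves = self.leaves
        if len(set(leaves)) != len(leaves):
            raise ValueError("taxonomy leaves must have unique names")
        for l1, branch in self.tree.items():
            for l2, kids in branch.items():
                if l2 == l1 and kids:
                    raise ValueError(f"unit {l1!r} cannot be its own internal child")

    @property
    def level1_units(self) -> list[str]:
        return list(self.tree)

    def level2_units(self, level1: str) -> list[str]:
        return list(self.tree[level1])

    def level3_leaves(self, level1: str, level2: str) -> list[str]:
        return list(self.tree[level1][level2])

    @property
    def leaves(self) -> list[str]:
        """Ordered list of leaf cell-type names (depth-first)."""
        out: list[str] = []
        for l1, branch in self.tree.items():
            if not branch:
                out.append(l1)
                continue
            for l2, kids in branch.items():
                if not kids:
                    out.append(l2)
                else:
                    out.extend(kids)
        return out

    def level_of(self, node: str) -> int:
        """Level (1-3) at which ``node`` appears as a unit."""
        for l1, branch in self.tree.items():
            if node == l1:
                return 1
            for l2, kids in branch.items():
                if node == l2:
                    return 2
                if node in kids:
                    return 3
        raise KeyError(f"unknown taxonomy node: {node!r}")

    def descendant_leaves(self, node: str) -> list[str]:
        """All leaves under ``node`` (the node itself if it is a leaf)."""
        for l1, branch in self.tree.items():
            if node == l1:
                if not branch:
                    return [l1]
                out: list[str] = []
                for l2, kids in branch.items():
                    out.extend(kids if kids else [l2])
                return out
            for l2, kids in branch.items():
                if node == l2:
                    return list(kids) if kids else [l2]
                if node in kids:
                    return [node]
        raise KeyError(f"unknown taxonomy node: {node!r}")

    def parent(self, node: str) -> str | None:
        for l1, branch in self.tree.items():
            for l2, kids in branch.items():
                if node == l2:
                    return l1
                if node in kids:
                    return l2
        if node in self.tree:
            return None
        raise KeyError(f"unknown taxonomy node: {node!r}")

    def sibling_scopes(self) -> list[tuple[int, list[str]]]:
        """Comparison scopes for marker selection.

        Returns ``(level, units)`` pairs: the root's children at level 1,
        each level-1 branch's children at level 2, and each level-2 branch's
        children at level 3.  Scopes with fewer than two units are omitted
        (nothing to compare).
        """
        scopes: list[tuple[int, list[str]]] = [(1, self.level1_units)]
        for l1, branch in self.tree.items():
            if len(branch) >= 2:
                scopes.append((2, list(branch)))
            for l2, kids in branch.items():
                if len(kids) >= 2:
                    scopes.append((3, list(kids)))
        return scopes

    def to_rows(self) -> list[tuple[str, str, str]]:
        """Flatten to (level1, level2, leaf) rows for TSV round-trips."""
        rows = []
        for l1, branch in self.tree.items():
            if not branch:
                rows.append((l1, l1, l1))
                continue
            for l2, kids in branch.items():
                if not kids:
                    rows.append((l1, l2, l2))
                else:
                    rows.extend((l1, l2, leaf) for leaf in kids)
        return rows

    @classmethod
    def from_rows(cls, rows: list[tuple[str, str, str]]) -> "CellTypeTaxonomy":
        tree: dict[str, dict[str, tuple[str, ...]]] = {}
        for l1, l2, leaf in rows:
            branch = tree.setdefault(l1, {})
            if l2 == l1 and leaf == l1:
                continue  # level-1 leaf: empty branch
            kids = branch.setdefault(l2, ())
            if leaf != l2:
                branch[l2] = kids + (leaf,)
        return cls(tree=tree)


def gen_taxonomy() -> CellTypeTaxonomy:
    """Return the default 24-leaf, three-level taxonomy."""
    return CellTypeTaxonomy()
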