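"""Rooted taxonomy tree with rank labels and lowest-common-ancestor queries.

The tree is stored as parent pointers (NCBI-dump style), which is all the
LCA classifier and phylum lookups need. Construction validates that the
table describes a single rooted, acyclic tree.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

STANDARD_RANKS = (
    "domain",
    "phylum",
    "class",
    "order",
    "family",
    "genus",
    "species",
)


class TaxonomyError(ValueError):
    pass


class TaxonomyTree:
    """Rooted tree of taxon ids with per-node rank and name.

    Parameters
    ----------
    parent
        Mapping child id -> parent id. The root maps to itself or to a
        parent absent from the table.
    rank
        Mapping id -> rank label (free-form; ``phylum`` is what downstream
        aggregation looks for).
    name
        Optional mapping id -> scientific name.
    """

    def __init__(
        self,
        parent: Mapping[str, str],
        rank: Mapping[str, str] | None = None,
        name: Mapping[str, str] | None = None,
    ) -> None:
        self._parent = dict(parent)
        self._rank = dict(rank or {})
        self._name = dict(name or {})
        self.root = self._validate()
        self._depth: dict[str, int] = {}

    # -- construction / validation -------------------------------------

    def _validate(self) -> str:
        roots = []
        for child, par in self._parent.items():
            if par == child or par not in self._parent:
                roots.append(child)
        if not roots:
            raise TaxonomyError("no root found (cycle covering all nodes?)")
        if len(roots) > 1:
            raise TaxonomyError(f"multiple roots: {sorted(roots)!r}")
        root = roots[0]
        # every node must reach the root without revisiting a node
        for node in self._parent:
            seen = {node}
            cur = node
            while cur != root:
                cur = self._parent[cur]
                if cur in seen:
                    raise TaxonomyError(f"cycle detected at node {cur!r}")
                seen.add(cur)
        return root

    def __contains__(self, taxid: str) -> bool:
        return taxid in self._parent

    def __len__(self) -> int:
        return len(self._parent)

    def nodes(self) -> Iterable[str]:
        return self._parent.keys()

    def parent(self, taxid: str) -> str:
        return self._parent[taxid]

    def rank(self, taxid: str) -> str:
        return self._rank.get(taxid, "no rank")

    def name(self, taxid: str) -> str:
        return self._name.get(taxid, taxid)

    def depth(self, taxid: str) -> int:
        """Number of edges from the root (root has depth 0)."""
        cached = self._depth.get(taxid)
        if cached is not None:
            return cached
        d = len(self.path_to_root(taxid)) - 1
        self._depth[taxid] = d
        return d

    # -- queries --------------------------------------------------------

    def path_to_root(self, taxid: str) -> list[str]:
        """Node ids from ``taxid`` up to and including the root."""
        if taxid not in self._parent:
            raise KeyError(taxid)
        path = [taxid]
        cur = taxid
        while cur != self.root:
            cur = self._parent[cur]
            path.append(cur)
        return path

    def lca(self, taxa: Sequence[str]) -> str:
        """Lowest common ancestor of a non-empty set of taxon ids.

        Computed as the deepest node on the common prefix of the
        root-to-node paths. The LCA of a set containing the root is the
        root; duplicates are irrelevant.
        """
        uniq = list(dict.fromkeys(taxa))
        if not uniq:
            raise TaxonomyError("LCA of empty taxon set")
        paths = [self.path_to_root(t)[::-1] for t in uniq]  # root first
        lca = self.root
        for level in zip(*paths):
            if len(set(level)) == 1:
                lca = level[0]
            else:
                break
        return lca

    def rank_ancestor(self, taxid: str, rank: str) -> str | None:
        """Ancestor (or self) of ``taxid`` with the given rank, else None."""
        for node in self.path_to_root(taxid):
            if self.rank(node) == rank:
                return node
        return None

    def phylum_of(self, taxid: str) -> str | None:
        return self.rank_ancestor(taxid, "phylum")

    # -- export ---------------------------------------------------------

    def to_child_parent(self) -> list[tuple[str, str, str, str]]:
        """Rows (child, parent, rank, name), root included, sorted by id."""
        return [
            (c, self._parent[c], self.rank(c), self.name(c))
            for c in sorted(self._parent)
        ]
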