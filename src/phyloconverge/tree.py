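"""Phylogenetic trees and Brownian-motion covariance structure.

A :class:`PhyloTree` is a rooted tree with uniquely labelled tips and
non-negative branch lengths in units of time (here, millions of years).
Under Brownian motion (BM) the trait values at the tips are jointly
Gaussian with covariance proportional to shared evolutionary history:
``C[i, j]`` equals the depth (root-to-node path length) of the most
recent common ancestor of tips *i* and *j*, and ``C[i, i]`` is the
root-to-tip depth.  Pagel's lambda rescales the off-diagonal entries,
interpolating between a star phylogeny (lambda = 0, independent tips)
and the full BM structure (lambda = 1).

Newick I/O is delegated to :mod:`dendropy`; this module adds validation,
label normalisation and the covariance algebra used by the rest of the
package.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger("phyloconverge")

__all__ = [
    "PhyloTree",
    "PhyloCovariance",
    "NewickParseError",
    "parse_newick",
    "write_newick",
    "prune_to_taxa",
    "bm_covariance",
    "lambda_transform",
]


class NewickParseError(ValueError):
    """Raised when a Newick string is malformed or violates tree invariants."""


def normalize_label(label: str) -> str:
    """Canonicalise a species label: strip whitespace, spaces -> underscores.

    Trait tables conventionally write ``Genus species`` while Newick files
    write ``Genus_species``; both map to the same canonical form so that
    tree/table matching is an exact string comparison.
    """
    return "_".join(str(label).strip().split())


@dataclass
class PhyloTree:
    """Rooted phylogeny with labelled tips and branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the
    invariants required by the comparative analyses: unique tip labels,
    non-negative branch lengths, a single root, and at least two tips.
    """

    _tree: dendropy.Tree = field(repr=False)

    def __post_init__(self) -> None:
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree) -> "PhyloTree":
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is not None:
                leaf.taxon.label = normalize_label(leaf.taxon.label)
        return cls(tree)

    def _validate(self) -> None:
        labels = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise NewickParseError("unlabelled tip in tree")
            labels.append(leaf.taxon.label)
        if len(labels) < 2:
            raise NewickParseError(f"tree needs >= 2 tips, got {len(labels)}")
        dupes = {t for t in labels if labels.count(t) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                if node.edge.length is None:
                    node.edge.length = 0.0
                continue
            if node.edge.length is None:
                name = node.taxon.label if node.taxon else "<internal>"
                raise NewickParseError(f"missing branch length on edge above {name!r}")
            if node.edge.length < 0:
                name = node.taxon.label if node.taxon else "<internal>"
                raise NewickParseError(
                    f"negative branch length {node.edge.length} above {name!r}"
                )
            if node.is_leaf() and node.edge.length == 0:
                logger.warning(
                    "zero-length terminal branch above %r; covariance may be "
                    "singular if another tip shares its position",
                    node.taxon.label,
                )

    # -- basic queries -----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in a stable (postorder) order."""
        return [lf.taxon.label for lf in self._tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    def depths(self) -> dict[str, float]:
        """Root-to-tip path length for every tip.

        The seed node's own edge length (a stem left by pruning) counts
        toward the depth, so pruning preserves depths exactly.
        """
        out = {}
        stem = self._tree.seed_node.edge.length or 0.0
        for leaf in self._tree.leaf_node_iter():
            d = stem
            node = leaf
            while node is not self._tree.seed_node:
                d += node.edge.length
                node = node.parent_node
            out[leaf.taxon.label] = d
        return out

    def height(self) -> float:
        return max(self.depths().values())

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = np.array(list(self.depths().values()))
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1.0))

    def node_depths(self) -> dict[int, float]:
        """Depth of every node keyed by ``id(node)`` (internal helper)."""
        depth: dict[int, float] = {
            id(self._tree.seed_node): self._tree.seed_node.edge.length or 0.0
        }
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue
            depth[id(node)] = depth[id(node.parent_node)] + node.edge.length
        return depth

    def dendropy_tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (treat as read-only)."""
        return self._tree

    def clone(self) -> "PhyloTree":
        return PhyloTree(self._tree.clone(depth=1))

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"PhyloTree(n_tips={self.n_tips}, height={self.height():.4g})"


@dataclass
class PhyloCovariance:
    """BM trait covariance: taxa order, matrix, and the lambda applied.

    ``matrix[i, j]`` is the shared root-to-MRCA path length of taxa *i*
    and *j* (scaled by lambda off the diagonal); the diagonal holds each
    tip's root-to-tip depth.
    """

    taxa: tuple[str, ...]
    matrix: np.ndarray
    lam: float = 1.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.taxa)
        if self.matrix.shape != (n, n):
            raise ValueError("covariance matrix shape does not match taxa")
        if not np.allclose(self.matrix, self.matrix.T, rtol=1e-10, atol=1e-12):
            raise ValueError("covariance matrix must be symmetric")

    def reorder(self, taxa: list[str] | tuple[str, ...]) -> "PhyloCovariance":
        """Return the covariance with rows/columns in the given taxa order."""
        idx = [self.taxa.index(t) for t in taxa]
        return PhyloCovariance(tuple(taxa), self.matrix[np.ix_(idx, idx)], self.lam)


# ---------------------------------------------------------------------------
# Newick I/O


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Underscores in unquoted labels are preserved verbatim (the standard
    convention for ``Genus_species`` names); labels are then normalised
    so that spaces and underscores compare equal.

    Raises
    ------
    NewickParseError
        On malformed syntax, duplicate tip labels, missing or negative
        branch lengths; the message names the offending token.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises assorted DataError subclasses
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return PhyloTree.from_dendropy(tree)


def read_newick(path) -> PhyloTree:
    """Read the first tree from a Newick file."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def write_newick(tree: PhyloTree, path=None) -> str:
    """Serialise to Newick (branch lengths always written).

    Returns the Newick string; also writes it to ``path`` if given.
    Round-trips through :func:`parse_newick` to an isomorphic tree.
    """
    s = tree.dendropy_tree().as_string(
        schema="newick",
        unquoted_underscores=True,
        suppress_rooting=True,
    ).strip() + "\n"
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(s)
    return s


# ---------------------------------------------------------------------------
# Pruning


def prune_to_taxa(tree: PhyloTree, keep) -> PhyloTree:
    """Induced subtree on the taxa in ``keep``.

    Root-to-tip depths and pairwise MRCA depths of the retained taxa are
    unchanged; internal nodes left with a single child are suppressed
    with their branch lengths summed.

    Raises
    ------
    KeyError
        If ``keep`` names taxa absent from the tree (all are listed).
    ValueError
        If fewer than two taxa are kept.
    """
    keep = {normalize_label(k) for k in keep}
    have = set(tree.tip_labels)
    missing = sorted(keep - have)
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    if len(keep) < 2:
        raise ValueError("need at least 2 taxa to keep")

    src = tree.dendropy_tree()
    out = dendropy.Tree()
    ns = out.taxon_namespace

    def build(node, stem):
        """Copy the induced subtree below ``node``; ``stem`` is the edge
        length accumulated through suppressed unifurcations above it."""
        if node.is_leaf():
            if node.taxon.label not in keep:
                return None
            cp = dendropy.Node()
            cp.taxon = ns.new_taxon(label=node.taxon.label)
            cp.edge.length = stem
            return cp
        kids = [
            build(c, stem_c)
            for c, stem_c in ((c, (c.edge.length or 0.0)) for c in node.child_nodes())
        ]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:  # unifurcation: splice, summing lengths
            kids[0].edge.length += stem
            return kids[0]
        cp = dendropy.Node()
        cp.label = node.label
        cp.edge.length = stem
        for k in kids:
            cp.add_child(k)
        return cp

    root = build(src.seed_node, src.seed_node.edge.length or 0.0)
    # the retained MRCA keeps its path to the original root as a stem edge,
    # so root-to-tip depths are unchanged
    out.seed_node = root
    return PhyloTree.from_dendropy(out)


# ---------------------------------------------------------------------------
# Covariance


def bm_covariance(tree: PhyloTree, taxa: list[str] | None = None) -> PhyloCovariance:
    """Brownian-motion covariance matrix of the tips.

    ``C[i, j]`` is the depth of the MRCA of tips *i* and *j* (their shared
    path length from the root); ``C[i, i]`` is tip *i*'s depth.  For an
    ultrametric tree the diagonal is constant (the tree height).  Computed
    in one postorder sweep; polytomies need no special handling.
    """
    dtree = tree.dendropy_tree()
    labels = tree.tip_labels
    index = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    depth = tree.node_depths()
    C = np.zeros((n, n))
    tips_below: dict[int, list[int]] = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            C[i, i] = depth[id(node)]
            tips_below[id(node)] = [i]
        else:
            child_sets = [tips_below.pop(id(c)) for c in node.child_nodes()]
            d = depth[id(node)]
            for a in range(len(child_sets)):
                for b in range(a + 1, len(child_sets)):
                    for i in child_sets[a]:
                        for j in child_sets[b]:
                            C[i, j] = C[j, i] = d
            tips_below[id(node)] = [i for s in child_sets for i in s]
    cov = PhyloCovariance(tuple(labels), C, lam=1.0)
    if taxa is not None:
        cov = cov.reorder([normalize_label(t) for t in taxa])
    return cov


def lambda_transform(cov: PhyloCovariance, lam: float) -> PhyloCovariance:
    """Apply Pagel's lambda: multiply off-diagonal entries by ``lam``.

    ``lam = 1`` leaves the BM covariance untouched; ``lam = 0`` yields the
    star-phylogeny (diagonal) covariance.  The result is positive
    semidefinite for any lam in [0, 1] because it is a convex combination
    of the BM covariance and its diagonal.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    M = cov.matrix
    out = lam * M + (1.0 - lam) * np.diag(np.diag(M))
    return PhyloCovariance(cov.taxa, out, lam=lam * cov.lam)


def patristic_distances(tree: PhyloTree) -> tuple[tuple[str, ...], np.ndarray]:
    """Pairwise tip-to-tip path lengths, derived from the BM covariance.

    ``d(i, j) = C[i, i] + C[j, j] - 2 C[i, j]``.
    """
    cov = bm_covariance(tree)
    diag = np.diag(cov.matrix)
    D = diag[:, None] + diag[None, :] - 2.0 * cov.matrix
    return cov.taxa, D
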