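"""Phylogenies and the Brownian-motion covariance structure.

A rooted tree with branch lengths induces the expected among-species
covariance of a trait evolving by Brownian motion: ``C[i, j]`` is the shared
path length from the root down to the most recent common ancestor of tips
``i`` and ``j``, and the diagonal holds each tip's root-to-tip depth.  Pagel's
lambda rescales the off-diagonal entries of that matrix by a factor in
``[0, 1]``: lambda = 1 keeps the full Brownian expectation, lambda = 0 erases
all shared history (a star phylogeny, under which species are independent).

Newick parsing and taxon pruning are delegated to :mod:`dendropy`; this
module adds the validation contract (unique non-empty tip labels, finite
non-negative branch lengths, >= 2 tips) and the deterministic lexicographic
tip ordering used for every matrix the package produces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "NewickParseError",
    "TreeValidationError",
    "PhyloTree",
    "VCVMatrix",
    "parse_newick",
    "vcv_from_tree",
    "lambda_transform",
    "prune_to_taxa",
]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed (message carries position)."""


class TreeValidationError(ValueError):
    """Raised when a parsed tree violates the structural contract."""


@dataclass(frozen=True)
class VCVMatrix:
    """Among-species trait covariance structure under Brownian motion.

    Attributes
    ----------
    labels : tuple of str
        Tip labels in the (lexicographic) order of the rows/columns.
    values : ndarray of shape (n, n)
        Shared branch lengths: ``values[i, j]`` is the root-to-MRCA path
        length of tips i and j; the diagonal is each tip's depth.
    """

    labels: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.all(np.isfinite(v)):
            raise ValueError("covariance matrix has non-finite entries")
        if not np.allclose(v, v.T, rtol=0.0, atol=1e-12):
            raise ValueError("covariance matrix is not symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return len(self.labels)

    def submatrix(self, labels) -> "VCVMatrix":
        """Exact restriction to a subset of tips, preserving sorted order."""
        labels = sorted(labels)
        missing = [l for l in labels if l not in self.labels]
        if missing:
            raise KeyError(f"labels not in matrix: {missing}")
        idx = [self.labels.index(l) for l in labels]
        return VCVMatrix(tuple(labels), self.values[np.ix_(idx, idx)])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=list(self.labels), columns=list(self.labels))


class PhyloTree:
    """A validated rooted phylogeny with branch lengths.

    Thin wrapper over a :class:`dendropy.Tree` enforcing the invariants the
    downstream likelihood machinery relies on: a single root, unique
    non-empty tip labels, finite non-negative branch lengths on every
    non-root edge, and at least two tips.  Polytomies are allowed.

    Zero-length terminal branches are legal but flagged with a warning,
    because after the lambda = 0 transform they can make the covariance
    matrix singular.
    """

    def __init__(self, dtree: dendropy.Tree):
        self._dtree = dtree
        self._validate()

    # -- validation -------------------------------------------------------

    def _validate(self) -> None:
        leaves = [nd for nd in self._dtree.leaf_node_iter()]
        if len(leaves) < 2:
            raise TreeValidationError(f"tree must have >= 2 tips, found {len(leaves)}")
        labels = []
        for leaf in leaves:
            label = leaf.taxon.label if leaf.taxon is not None else None
            if not label or not str(label).strip():
                raise TreeValidationError("tip with empty or missing label")
            labels.append(str(label).strip())
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {sorted(dupes)}")

        root = self._dtree.seed_node
        zero_terminals = []
        for nd in self._dtree.preorder_node_iter():
            bl = nd.edge.length
            if nd is root:
                if bl is not None and (not np.isfinite(bl) or bl < 0):
                    raise TreeValidationError(f"invalid root edge length {bl!r}")
                continue
            if bl is None:
                raise TreeValidationError(
                    "missing branch length on edge leading to "
                    f"{nd.taxon.label if nd.taxon else 'an internal node'}"
                )
            if not np.isfinite(bl) or bl < 0:
                who = nd.taxon.label if nd.taxon else "an internal node"
                raise TreeValidationError(f"negative or non-finite branch length {bl!r} on edge to {who}")
            if nd.is_leaf() and bl == 0.0:
                zero_terminals.append(nd.taxon.label)
        if zero_terminals:
            warnings.warn(
                f"zero-length terminal branches for {sorted(zero_terminals)}: "
                "the covariance matrix can become singular at lambda = 0",
                UserWarning,
                stacklevel=3,
            )
        self._tip_labels = tuple(sorted(labels))

    # -- basic accessors --------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        """Tip labels in lexicographic order (the matrix row order)."""
        return self._tip_labels

    @property
    def n_tips(self) -> int:
        return len(self._tip_labels)

    def as_newick(self) -> str:
        s = self._dtree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        )
        return s.strip()

    def tip_depths(self) -> dict[str, float]:
        """Root-to-tip path lengths (the root edge length, if any, included)."""
        depths: dict[str, float] = {}
        root = self._dtree.seed_node
        base = root.edge.length or 0.0

        def walk(node, d):
            if node.is_leaf():
                depths[str(node.taxon.label).strip()] = d
                return
            for ch in node.child_nodes():
                walk(ch, d + ch.edge.length)

        walk(root, base)
        return depths

    def is_ultrametric(self, rel_tol: float = 1e-8) -> bool:
        d = np.array(list(self.tip_depths().values()))
        return bool(np.ptp(d) <= rel_tol * max(d.max(), 1.0))

    def scale_branches(self, factor: float) -> "PhyloTree":
        """Return a copy with every branch length multiplied by ``factor``."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        clone = self._dtree.clone(depth=1)
        for nd in clone.preorder_node_iter():
            if nd.edge.length is not None:
                nd.edge.length *= factor
        return PhyloTree(clone)

    def __repr__(self) -> str:
        return f"PhyloTree(n_tips={self.n_tips})"


def parse_newick(text: str) -> PhyloTree:
    """Parse a single-tree Newick string into a validated :class:`PhyloTree`.

    Branch lengths are required on all non-root edges; internal node labels
    are ignored; single-quoted labels are supported; polytomies are kept.

    Raises
    ------
    NewickParseError
        On malformed input (the message includes line/column position).
    TreeValidationError
        On negative branch lengths, duplicate or empty tip labels, < 2 tips.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as e:
        raise TreeValidationError(f"duplicate tip label: {e}") from e
    except Exception as e:  # dendropy raises several reader-error subclasses
        raise NewickParseError(str(e)) from e
    return PhyloTree(dtree)


def read_newick(path) -> PhyloTree:
    """Read a Newick file containing one tree."""
    with open(path) as fh:
        return parse_newick(fh.read())


def vcv_from_tree(tree: PhyloTree) -> VCVMatrix:
    """Brownian-motion variance-covariance matrix of a tree.

    Rows/columns follow ``tree.tip_labels`` (lexicographic).  Entry (i, j)
    is the path length from the root to MRCA(i, j); the diagonal is each
    tip's root-to-tip depth.
    """
    labels = tree.tip_labels
    n = len(labels)
    index = {l: i for i, l in enumerate(labels)}
    C = np.zeros((n, n))
    root = tree._dtree.seed_node
    base = root.edge.length or 0.0

    def walk(node, depth):
        """Return tip indices below ``node``; fill cross-subtree entries."""
        if node.is_leaf():
            i = index[str(node.taxon.label).strip()]
            C[i, i] = depth
            return [i]
        groups = []
        for ch in node.child_nodes():
            groups.append(walk(ch, depth + ch.edge.length))
        for a in range(len(groups)):
            for b in range(a + 1, len(groups)):
                C[np.ix_(groups[a], groups[b])] = depth
                C[np.ix_(groups[b], groups[a])] = depth
        out = groups[0]
        for g in groups[1:]:
            out.extend(g)
        return out

    walk(root, base)
    return VCVMatrix(labels, C)


def lambda_transform(C: VCVMatrix, lam: float) -> VCVMatrix:
    """Pagel's lambda transform: off-diagonals scaled by ``lam``, diagonal kept.

    ``lam = 1`` returns the matrix unchanged; ``lam = 0`` is the star-phylogeny
    limit, under which species covary only through the residual variance.
    """
    lam = float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    out = lam * C.values
    np.fill_diagonal(out, np.diag(C.values))
    return VCVMatrix(C.labels, out)


def prune_to_taxa(tree: PhyloTree, taxa) -> PhyloTree:
    """Restrict a tree to a subset of tips.

    Path lengths between retained tips, and their depths from the original
    root, are preserved: degree-2 nodes left by the pruning are collapsed
    with branch lengths summed, and the path from the old root to the new
    one is kept as the new root's edge length.  Hence the covariance matrix
    of the pruned tree equals the corresponding submatrix of the full one.
    """
    taxa = {str(t).strip() for t in taxa}
    missing = sorted(taxa - set(tree.tip_labels))
    if missing:
        raise KeyError(f"taxa not in tree: {missing}")
    if len(taxa) < 2:
        raise ValueError(f"need >= 2 taxa to keep, got {len(taxa)}")
    sub = tree._dtree.extract_tree_with_taxa_labels(labels=sorted(taxa))
    return PhyloTree(sub)
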