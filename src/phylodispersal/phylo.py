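"""Tree ingestion and phylogenetic covariance structures.

Trees are rooted phylogenies with branch lengths in time units, read from
Newick (one tree per line) or Nexus files.  Every downstream analysis in this
package consumes the phylogenetic variance-covariance matrix (VCV): the n x n
matrix whose entry (i, j) is the shared root-to-MRCA path length of tips i and
j, and whose diagonal holds root-to-tip distances.  Pagel's lambda enters as a
multiplier on the off-diagonal entries of that matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

__all__ = [
    "PhyloTree",
    "PhyloVCV",
    "read_trees",
    "lambda_transform",
    "normalize_label",
    "cholesky_psd",
]


def cholesky_psd(V: np.ndarray) -> np.ndarray:
    """Lower Cholesky factor, tolerating numerically semi-definite input.

    Tree covariances with near-simultaneous splits can fail the exact
    factorization by rounding alone; an escalating (but tiny) diagonal ridge
    is tried before giving up.
    """
    from scipy import linalg  # local import keeps module load light

    scale = float(np.mean(np.diag(V))) or 1.0
    for ridge in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return linalg.cholesky(V + ridge * scale * np.eye(len(V)),
                                   lower=True)
        except linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        "covariance matrix is not positive semi-definite"
    )


def normalize_label(label: str) -> str:
    """Canonical tip label: stripped, spaces replaced by underscores.

    This is the Newick convention and makes joins between trees and trait
    tables deterministic.
    """
    return label.strip().replace(" ", "_")


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural requirement."""


@dataclass(frozen=True)
class PhyloVCV:
    """Phylogenetic variance-covariance matrix with its tip ordering.

    ``matrix[i, j]`` is the depth (distance from the root) of the most recent
    common ancestor of tips ``labels[i]`` and ``labels[j]``; the diagonal is
    the root-to-tip distance.  Symmetric and positive semi-definite for any
    valid tree.
    """

    labels: tuple[str, ...]
    matrix: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("VCV matrix must be square")
        if m.shape[0] != len(self.labels):
            raise ValueError("VCV labels do not match matrix dimension")
        object.__setattr__(self, "matrix", m)

    @property
    def n(self) -> int:
        return len(self.labels)

    def reorder(self, order: list[str]) -> "PhyloVCV":
        """Return the VCV restricted to / permuted into ``order``."""
        pos = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in order if lab not in pos]
        if missing:
            raise KeyError(f"labels not in VCV: {missing}")
        idx = np.array([pos[lab] for lab in order])
        return PhyloVCV(tuple(order), self.matrix[np.ix_(idx, idx)])


def lambda_transform(vcv: PhyloVCV, lam: float) -> PhyloVCV:
    """Pagel's lambda transform: multiply off-diagonal covariances by ``lam``.

    lambda = 1 leaves the Brownian expectation untouched; lambda = 0 removes
    all shared history (star-phylogeny limit).  The diagonal is unchanged, so
    the result stays positive semi-definite for lam in [0, 1].
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    V = vcv.matrix
    out = lam * V + (1.0 - lam) * np.diag(np.diag(V))
    return PhyloVCV(vcv.labels, out)


class PhyloTree:
    """A rooted phylogeny with branch lengths, backed by a dendropy tree.

    Tip labels are normalized (whitespace stripped, spaces -> underscores) and
    must be unique.  Zero-length *internal* branches are collapsed on
    construction so that the VCV never contains duplicated rows; zero-length
    terminal branches are allowed.  Polytomies are accepted as-is.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate_and_normalize()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except Exception as exc:
            if "Duplicate taxon labels" in str(exc):
                raise TreeValidationError(
                    f"duplicate tip labels: {exc}"
                ) from exc
            raise
        return cls(tree)

    def _validate_and_normalize(self) -> None:
        tree = self._tree
        labels = []
        for leaf in tree.leaf_node_iter():
            if leaf.taxon is None or leaf.taxon.label is None:
                raise TreeValidationError("tree has an unlabeled tip")
            leaf.taxon.label = normalize_label(leaf.taxon.label)
            labels.append(leaf.taxon.label)
        dupes = sorted({lab for lab in labels if labels.count(lab) > 1})
        if dupes:
            raise TreeValidationError(f"duplicate tip labels: {dupes}")
        if len(labels) < 2:
            raise TreeValidationError("tree must have at least 2 tips")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue  # root edge length, if any, is ignored
            if edge.length is None:
                raise TreeValidationError(
                    "tree has an edge without a branch length"
                )
            if edge.length < 0:
                raise TreeValidationError(
                    f"negative branch length: {edge.length}"
                )
        # collapse zero-length internal edges (keeps the VCV nonsingular)
        zero_internal = [
            e
            for e in tree.preorder_edge_iter()
            if e.head_node is not tree.seed_node
            and not e.head_node.is_leaf()
            and e.length == 0
        ]
        for edge in zero_internal:
            edge.collapse()

    # -- basic accessors ---------------------------------------------------

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(l.taxon.label for l in self._tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self._tree.leaf_nodes())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def root_to_tip_distances(self) -> dict[str, float]:
        """Distance from the root node to each tip (root edge ignored)."""
        depths = self._node_depths()
        return {
            leaf.taxon.label: depths[leaf]
            for leaf in self._tree.leaf_node_iter()
        }

    def is_ultrametric(self, rel_tol: float = 1e-6) -> bool:
        d = np.array(list(self.root_to_tip_distances().values()))
        scale = max(d.max(), 1e-12)
        return bool((d.max() - d.min()) / scale <= rel_tol)

    def _node_depths(self) -> dict:
        depths: dict = {}
        for node in self._tree.preorder_node_iter():
            if node.parent_node is None:
                depths[node] = 0.0
            else:
                depths[node] = depths[node.parent_node] + node.edge.length
        return depths

    def as_newick(self) -> str:
        return self._tree.as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()

    # -- operations --------------------------------------------------------

    def prune(self, keep) -> "PhyloTree":
        """Restrict the tree to the tips in ``keep``.

        Degree-2 internal nodes created by pruning are collapsed with branch
        lengths summed, so root-to-tip distances of retained tips are exactly
        preserved.
        """
        keep = {normalize_label(k) for k in keep}
        present = set(self.tip_labels)
        missing = sorted(keep - present)
        if missing:
            raise KeyError(f"species not in tree: {missing}")
        if len(keep) < 2:
            raise ValueError("cannot prune to fewer than 2 tips")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep))
        return PhyloTree(clone)

    def vcv(self, order=None) -> PhyloVCV:
        """Phylogenetic variance-covariance matrix.

        V[i, j] is the depth of MRCA(i, j); V[i, i] the root-to-tip distance.
        If ``order`` (a subset of tip labels) is given, the tree is pruned to
        it first and rows follow that order.  Non-ultrametric trees trigger a
        warning: all analyses here assume time-calibrated trees, though the
        matrix itself is well-defined regardless.
        """
        if order is not None:
            order = [normalize_label(o) for o in order]
            tree = self.prune(order) if set(order) != set(self.tip_labels) else self
        else:
            tree = self
            order = list(tree.tip_labels)
        if not tree.is_ultrametric():
            warnings.warn(
                "tree is not ultrametric; analyses assume a time-calibrated "
                "tree",
                UserWarning,
                stacklevel=2,
            )
        depths = tree._node_depths()
        idx = {lab: i for i, lab in enumerate(order)}
        n = len(order)
        V = np.zeros((n, n))
        # tips under each node, collected post-order
        tipsets: dict = {}
        for node in tree._tree.postorder_node_iter():
            if node.is_leaf():
                tipsets[node] = [idx[node.taxon.label]]
            else:
                tipsets[node] = [
                    t for ch in node.child_nodes() for t in tipsets[ch]
                ]
        for node in tree._tree.preorder_node_iter():
            if node.is_leaf():
                i = idx[node.taxon.label]
                V[i, i] = depths[node]
            else:
                d = depths[node]
                kids = [tipsets[ch] for ch in node.child_nodes()]
                for a in range(len(kids)):
                    for b in range(a + 1, len(kids)):
                        for i in kids[a]:
                            for j in kids[b]:
                                V[i, j] = V[j, i] = d
        return PhyloVCV(tuple(order), V)


def read_trees(path) -> list[PhyloTree]:
    """Read one or more trees from a Newick (one per line) or Nexus file.

    Returns trees in file order with tip labels preserved verbatim (modulo
    label normalization).  Malformed Newick raises an error naming the line.
    """
    with open(path) as fh:
        text = fh.read()
    if text.lstrip().upper().startswith("#NEXUS"):
        tl = dendropy.TreeList.get(
            data=text, schema="nexus", preserve_underscores=True
        )
        return [PhyloTree(t) for t in tl]
    trees = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        try:
            trees.append(PhyloTree.from_newick(line))
        except TreeValidationError:
            raise
        except Exception as exc:
            raise ValueError(
                f"{path}: malformed Newick on line {lineno}: {exc}"
            ) from exc
    if not trees:
        raise ValueError(f"{path}: no trees found")
    return trees
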