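"""Distance phylogenetics with delete-half jackknife consensus support.

The workflow mirrors the classic PHYLIP-style pipeline: protein distances
from a multiple sequence alignment, a distance tree per replicate, and a
majority-rule consensus whose internal-edge supports count the replicates
containing each bipartition.  Column resampling is delete-half jackknife
(each replicate keeps floor(L/2) distinct columns, original order kept).

Two documented substitutions relative to that classic stack: distances are
Kimura-corrected p-distances, d = −ln(1 − p − 0.2 p²), with pairwise
deletion of gapped columns and a saturation clamp; and trees are built by
neighbor joining (via scikit-bio) instead of Fitch–Margoliash least squares.
Both choices preserve clustering-level conclusions while staying closed-form
and fast.
"""

from __future__ import annotations


import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

import dendropy
import numpy as np

GAP_CHARS = b"-."

MSALike = Union[Mapping[str, str], Sequence]


def _as_rows(aln: MSALike) -> tuple[list, list]:
    """Normalise an MSA-like input to (labels, rows)."""
    if isinstance(aln, Mapping):
        items = list(aln.items())
    else:
        try:  # Bio.Align.MultipleSeqAlignment or iterable of SeqRecords
            items = [(rec.id, str(rec.seq)) for rec in aln]
        except AttributeError:
            items = [(name, str(seq)) for name, seq in aln]
    labels = [name for name, _ in items]
    rows = [row.upper() for _, row in items]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate taxon labels in alignment")
    if len({len(r) for r in rows}) > 1:
        raise ValueError("alignment rows have unequal lengths")
    return labels, rows


def _encode(rows: list) -> np.ndarray:
    return np.frombuffer("".join(rows).encode("ascii"),
                         dtype=np.uint8).reshape(len(rows), -1)


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with ordered taxon labels."""

    taxa: tuple
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        if d.shape != (len(self.taxa), len(self.taxa)):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(d), 0):
            raise ValueError("nonzero diagonal")
        if not np.all(np.isfinite(d)):
            raise ValueError("non-finite distances")
        object.__setattr__(self, "d", d)

    def to_tsv(self, path) -> None:
        import pandas as pd
        pd.DataFrame(self.d, index=list(self.taxa),
                     columns=list(self.taxa)).to_csv(path, sep="\t")


def kimura_distance(p: float) -> float:
    """Kimura's correction of a protein p-distance: −ln(1 − p − 0.2 p²)."""
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0:
        return float("inf")
    return -float(np.log(arg))


def protein_distance(aln: MSALike, saturation: float = 0.85,
                     d_max: float = 5.0) -> DistanceMatrix:
    """Kimura-corrected pairwise distances with pairwise gap deletion.

    Columns gapped in either member of a pair are skipped; pairs at or above
    the saturation p-distance (default 0.85) are clamped to ``d_max``.  A
    pair with no comparable columns is an error (named in the message).
    """
    labels, rows = _as_rows(aln)
    if len(labels) < 3:
        raise ValueError("need at least 3 taxa")
    A = _encode(rows)
    valid = ~np.isin(A, np.frombuffer(GAP_CHARS, dtype=np.uint8))
    both = valid[:, None, :] & valid[None, :, :]
    ncomp = both.sum(axis=-1)
    nm = ((A[:, None, :] != A[None, :, :]) & both).sum(axis=-1)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if ncomp[i, j] == 0:
                raise ValueError(
                    f"no comparable columns for pair ({labels[i]}, {labels[j]})")
            p = nm[i, j] / ncomp[i, j]
            dij = d_max if p >= saturation else min(kimura_distance(p), d_max)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(taxa=tuple(labels), d=d)


@dataclass(frozen=True)
class JackknifeConfig:
    n_replicates: int = 1000
    fraction_deleted: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.fraction_deleted != 0.5:
            raise ValueError("only delete-half jackknife is supported")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate")


def jackknife_columns(n_columns: int, cfg: JackknifeConfig) -> list[np.ndarray]:
    """Per-replicate sorted column index arrays, floor(L/2) columns each.

    Replicate i draws from its own spawned substream of the seed, so partial
    re-runs with the same seed reproduce the same replicates.
    """
    if n_columns < 2:
        raise ValueError("alignment must have at least 2 columns")
    keep = n_columns // 2
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.n_replicates)
    out = []
    for s in streams:
        rng = np.random.default_rng(s)
        cols = np.sort(rng.choice(n_columns, size=keep, replace=False))
        out.append(cols)
    return out


def jackknife_resample(aln: MSALike, cfg: JackknifeConfig) -> list[dict]:
    """Delete-half jackknife sub-alignments (order of kept columns preserved)."""
    labels, rows = _as_rows(aln)
    A = _encode(rows)
    out = []
    for cols in jackknife_columns(A.shape[1], cfg):
        sub = A[:, cols]
        out.append({lab: sub[i].tobytes().decode("ascii")
                    for i, lab in enumerate(labels)})
    return out


# ---------------------------------------------------------------------------
# tree building

def build_tree(dm: DistanceMatrix,
               taxon_namespace: Optional[dendropy.TaxonNamespace] = None
               ) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix (unrooted, branch lengths).

    Uses scikit-bio's NJ (deterministic tie handling), returned as a dendropy
    tree; slightly negative NJ branch lengths are clamped to zero.
    """
    if len(dm.taxa) < 3:
        raise ValueError("need at least 3 taxa to build a tree")
    if np.allclose(dm.d, 0):
        warnings.warn("all-zero distance matrix: returning a star-like tree "
                      "with zero branch lengths")
    from skbio import DistanceMatrix as _SkbioDM
    from skbio.tree import nj as _skbio_nj
    newick = str(_skbio_nj(_SkbioDM(dm.d, ids=list(dm.taxa))))
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True,
                             taxon_namespace=taxon_namespace)
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return tree


def tree_bipartitions(tree: dendropy.Tree) -> set:
    """Non-trivial bipartitions as pivot-normalised frozensets of leaf labels.

    Each bipartition is represented by its side not containing the
    lexicographically smallest leaf label.
    """
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    pivot = min(labels)
    out = set()
    below: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is None:
            continue
        s = below[node]
        if pivot in s:
            s = labels - s
        if 1 < len(s) < len(labels) - 1:
            out.add(s)
    return out


def _compatible(a: frozenset, b: frozenset) -> bool:
    # pivot-normalised sets are compatible iff nested or disjoint
    return a.issubset(b) or b.issubset(a) or not (a & b)


@dataclass
class ConsensusResult:
    """Extended-majority consensus tree plus raw bipartition counts."""

    tree: dendropy.Tree
    bipartition_counts: dict = field(repr=False)  # frozenset -> replicate count
    n_replicates: int
    labels: frozenset
    pivot: str

    def clade_support(self, leaf_set: Iterable[str]) -> int:
        """Replicate count supporting the bipartition separating ``leaf_set``.

        Singletons and the full leaf set are trivial bipartitions, supported
        by every replicate by convention; an absent bipartition scores 0.
        """
        s = frozenset(leaf_set)
        if not s.issubset(self.labels):
            raise ValueError("leaf_set contains unknown labels")
        if len(s) <= 1 or len(s) >= len(self.labels) - 1:
            return self.n_replicates
        if self.pivot in s:
            s = self.labels - s
        return self.bipartition_counts.get(s, 0)


def consensus(trees: Sequence[dendropy.Tree]) -> ConsensusResult:
    """Extended majority-rule consensus with integer replicate supports.

    Bipartitions occurring in more than half of the trees are retained;
    remaining bipartitions are added greedily in order of decreasing
    frequency when compatible with everything already accepted.  Internal
    node labels of the returned tree carry the support counts.
    """
    if not trees:
        raise ValueError("no trees given")
    all_bips = [tree_bipartitions(t) for t in trees]
    label_sets = [frozenset(lf.taxon.label for lf in t.leaf_node_iter())
                  for t in trees]
    labels = label_sets[0]
    if any(ls != labels for ls in label_sets):
        raise ValueError("trees must share an identical leaf set")
    pivot = min(labels)
    n = len(trees)
    counts: dict = {}
    for bips in all_bips:
        for s in bips:
            counts[s] = counts.get(s, 0) + 1

    accepted = [s for s, c in counts.items() if c > n / 2]
    rest = sorted((s for s, c in counts.items() if c <= n / 2),
                  key=lambda s: (-counts[s], len(s), tuple(sorted(s))))
    for s in rest:
        if all(_compatible(s, a) for a in accepted):
            accepted.append(s)

    newick = _newick_from_clades(labels, pivot, accepted, counts)
    tree = dendropy.Tree.get(data=newick, schema="newick",
                             preserve_underscores=True)
    return ConsensusResult(tree=tree, bipartition_counts=counts,
                           n_replicates=n, labels=labels, pivot=pivot)


def _newick_from_clades(labels: frozenset, pivot: str,
                        clades: Sequence[frozenset], counts: dict) -> str:
    """Assemble a newick string from a compatible set of pivot-free clades."""
    ordered = sorted(clades, key=len)

    def render(members: frozenset, available: list) -> str:
        # children: maximal accepted clades inside `members`, then loose leaves
        children = []
        used: set = set()
        for s in sorted(available, key=len, reverse=True):
            if s.issubset(members) and not (s & used):
                children.append(s)
                used |= s
        parts = []
        for s in sorted(children, key=lambda s: min(s)):
            inner = [c for c in ordered if c < s]
            parts.append(render(s, inner) + str(counts.get(s, "")))
        parts.extend(sorted(members - used))
        return "(" + ",".join(parts) + ")"

    body = render(labels - {pivot}, list(ordered))
    return f"({pivot},{body});"


def root_tree(tree: dendropy.Tree, outgroup) -> dendropy.Tree:
    """Root a tree on the edge separating the outgroup from the ingroup.

    ``outgroup`` is a leaf label or an iterable of labels; the outgroup must
    form a clade of the unrooted tree, otherwise an error is raised.
    Re-rooting an already-rooted tree on the same outgroup is idempotent (up
    to branch-length placement on the root edge).
    """
    og = frozenset([outgroup] if isinstance(outgroup, str) else outgroup)
    tree = tree.clone(depth=1)
    labels = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    if not og.issubset(labels):
        raise ValueError("outgroup labels not all present in the tree")
    if og == labels:
        raise ValueError("outgroup cannot be the full leaf set")
    below: dict = {}
    target = None
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[node] = frozenset([node.taxon.label])
        else:
            below[node] = frozenset().union(*(below[c] for c in node.child_nodes()))
        if node.parent_node is not None and (below[node] == og
                                             or below[node] == labels - og):
            target = node
    if target is None:
        raise ValueError("outgroup is not monophyletic in this tree")
    edge = target.edge
    if edge.length is not None:
        tree.reroot_at_edge(edge, length1=edge.length / 2,
                            length2=edge.length / 2, update_bipartitions=False)
    else:
        tree.reroot_at_edge(edge, update_bipartitions=False)
    return tree


def jackknife_consensus(aln: MSALike, cfg: JackknifeConfig,
                        saturation: float = 0.85, d_max: float = 5.0
                        ) -> ConsensusResult:
    """Delete-half jackknife → NJ per replicate → majority consensus."""
    labels, rows = _as_rows(aln)
    A = _encode(rows)
    tns = dendropy.TaxonNamespace()
    trees = []
    for cols in jackknife_columns(A.shape[1], cfg):
        sub = A[:, cols]
        sub_rows = {lab: sub[i].tobytes().decode("ascii")
                    for i, lab in enumerate(labels)}
        dm = protein_distance(sub_rows, saturation=saturation, d_max=d_max)
        trees.append(build_tree(dm, taxon_namespace=tns))
    return consensus(trees)
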