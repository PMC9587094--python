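"""Sequence similarity networks from pairwise alignment bitscores.

All-vs-all optimal pairwise alignment (local Smith–Waterman with affine
gaps, BLOSUM62, gap open 11 / extend 1 by default), raw scores converted to
bitscores with the standard gapped Karlin–Altschul parameters
``bits = (λ·raw − ln K) / ln 2`` (λ = 0.267, K = 0.041).  Edges are kept
when the bitscore strictly exceeds the threshold (default 380); when two
directed scores exist for a pair, only the higher one is kept.  Bitscores
rather than E-values are used throughout so query length does not enter the
edge weight.

Note that no compositional score adjustment is applied, so absolute
bitscores can deviate slightly from BLAST's on real data; the threshold is
therefore a parameter, not a constant.

Graphs are ``networkx.Graph`` objects with node attributes (linker family,
relative length, class, taxonomy) and a ``bits`` edge attribute; GraphML and
TSV export round-trip the full structure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from sklearn.metrics import rand_score

DEFAULT_THRESHOLD_BITS = 380.0


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters and Karlin–Altschul constants.

    A gap of length k costs ``gap_open + k * gap_extend`` (BLAST convention).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    lam: float = 0.267
    K: float = 0.041
    mode: str = "local"  # "local" (BLAST-like) or "global"

    def __post_init__(self):
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")
        if self.mode not in ("local", "global"):
            raise ValueError(f"unknown alignment mode {self.mode!r}")

    def aligner(self) -> Align.PairwiseAligner:
        al = Align.PairwiseAligner()
        al.substitution_matrix = substitution_matrices.load(self.matrix_name)
        al.mode = self.mode
        # Biopython charges open_gap_score for the first gap residue
        al.open_gap_score = -(self.gap_open + self.gap_extend)
        al.extend_gap_score = -self.gap_extend
        return al

    def bits(self, raw: float) -> float:
        return (self.lam * raw - math.log(self.K)) / math.log(2)


@dataclass(frozen=True)
class PairScore:
    """Score of one unordered sequence pair (ids stored sorted)."""

    id_a: str
    id_b: str
    raw_score: float
    bits: float

    @property
    def pair(self) -> tuple:
        return (self.id_a, self.id_b)


def _sanitise(seq: str, alphabet: str) -> str:
    return "".join(c if c in alphabet else "X" for c in seq.upper())


def pairwise_bitscore(id_a: str, a: str, id_b: str, b: str,
                      scheme: Optional[ScoringScheme] = None,
                      _aligner: Optional[Align.PairwiseAligner] = None) -> PairScore:
    """Optimal affine-gap alignment score of one pair, in raw and bit units.

    Residues outside the substitution matrix alphabet are scored as X.  The
    pair is stored unordered (ids sorted), so the result is symmetric in its
    arguments by construction.
    """
    if not a or not b:
        raise ValueError("sequences must be nonempty")
    scheme = scheme or ScoringScheme()
    aligner = _aligner if _aligner is not None else scheme.aligner()
    alpha = str(aligner.substitution_matrix.alphabet)
    raw = float(aligner.score(_sanitise(a, alpha), _sanitise(b, alpha)))
    if id_b < id_a:
        id_a, id_b = id_b, id_a
    return PairScore(id_a=id_a, id_b=id_b, raw_score=raw, bits=scheme.bits(raw))


def all_vs_all(sequences: Mapping[str, str],
               scheme: Optional[ScoringScheme] = None) -> list[PairScore]:
    """Bitscores for every unordered pair of distinct sequences."""
    scheme = scheme or ScoringScheme()
    aligner = scheme.aligner()  # built once; alignment dominates the cost
    out = []
    for (ia, sa), (ib, sb) in itertools.combinations(sequences.items(), 2):
        out.append(pairwise_bitscore(ia, sa, ib, sb, scheme, _aligner=aligner))
    return out


def keep_higher_of_pair(directed: Iterable[PairScore]) -> list[PairScore]:
    """Collapse directed score lists to one score per unordered pair (the max)."""
    best: dict[tuple, PairScore] = {}
    for s in directed:
        key = tuple(sorted((s.id_a, s.id_b)))
        if key not in best or s.bits > best[key].bits:
            best[key] = s
    return [best[k] for k in sorted(best)]


def build_ssn(pairs: Iterable[PairScore],
              node_attrs: Mapping[str, Mapping],
              threshold: float = DEFAULT_THRESHOLD_BITS) -> nx.Graph:
    """Thresholded similarity network: edges where bits strictly exceed threshold.

    All ids in ``node_attrs`` become nodes even when isolated; self-pairs are
    ignored and duplicate pairs keep the higher score.
    """
    pairs = keep_higher_of_pair(pairs)
    missing = {s.id_a for s in pairs} | {s.id_b for s in pairs}
    missing -= set(node_attrs)
    if missing:
        raise ValueError(f"node attributes missing for: {sorted(missing)}")
    g = nx.Graph(threshold=float(threshold))
    for node, attrs in node_attrs.items():
        g.add_node(node, **{k: v for k, v in attrs.items() if v is not None})
    for s in pairs:
        if s.id_a == s.id_b:
            continue
        if s.bits > threshold:
            g.add_edge(s.id_a, s.id_b, bits=float(s.bits))
    return g


def components(graph: nx.Graph) -> dict:
    """Connected-component labelling; each cluster is named by its smallest member."""
    labels = {}
    for comp in nx.connected_components(graph):
        rep = min(comp)
        for node in comp:
            labels[node] = rep
    return labels


def cluster_concordance(clusters: Mapping, labels: Mapping) -> tuple[float, float]:
    """(purity, Rand index) of a clustering against reference labels.

    Purity sums, over clusters, the count of the cluster's majority label,
    divided by the number of nodes; the Rand index is the pairwise agreement
    between the two partitions.
    """
    nodes = sorted(clusters)
    if set(nodes) - set(labels):
        raise ValueError("labels missing for some nodes")
    c = [clusters[n] for n in nodes]
    l = [labels[n] for n in nodes]
    purity = 0
    for cluster in set(c):
        counts: dict = {}
        for ci, li in zip(c, l):
            if ci == cluster:
                counts[li] = counts.get(li, 0) + 1
        purity += max(counts.values())
    return purity / len(nodes), float(rand_score(l, c))


def threshold_sweep(pairs: Sequence[PairScore],
                    node_attrs: Mapping[str, Mapping],
                    labels: Mapping,
                    thresholds: Sequence[float]) -> pd.DataFrame:
    """Edge count, component count and purity at each ascending threshold."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    for t in thresholds:
        g = build_ssn(pairs, node_attrs, threshold=t)
        comp = components(g)
        purity, rand = cluster_concordance(comp, labels)
        rows.append({"threshold": t, "edges": g.number_of_edges(),
                     "components": len(set(comp.values())),
                     "purity": purity, "rand_index": rand})
    return pd.DataFrame(rows)


def write_edge_tsv(pairs: Iterable[PairScore], path) -> None:
    df = pd.DataFrame([{"id_a": s.id_a, "id_b": s.id_b,
                        "raw_score": s.raw_score, "bits": s.bits}
                       for s in keep_higher_of_pair(pairs)])
    df.to_csv(path, sep="\t", index=False)


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def read_graphml(path) -> nx.Graph:
    return nx.read_graphml(path)
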