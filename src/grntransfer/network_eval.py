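"""Evaluation of a predicted GRN against a reference network.

Two binary-classification views are provided, both treating network
comparison as a retrieval problem:

* **edge level** — every directed TF->TG edge is an item; edges in
  both networks are true positives, edges only in the reference are
  false negatives, edges only in the prediction are false positives.
* **graphlet level** — items are the 13 weakly connected directed
  3-node induced-subgraph classes (the triad/motif vocabulary that
  includes the feed-forward loop); an instance is a (node triple,
  class) pair.

From the counts, precision P = TP/(TP+FP), recall R = TP/(TP+FN) and
F1 = 2PR/(P+R) are derived.  A randomization null — permuting TF
identity labels over the TF positions while keeping targets, edge
count and gene set fixed — yields expected counts, and a G-test
(likelihood-ratio goodness of fit) measures whether the observed
counts could arise by chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy import stats

from grntransfer.annotation_io import GRN, RegulatoryInteraction
from grntransfer.errors import UnknownGeneError, UsageError
from grntransfer.orthology import OrthologMap

#: Number of weakly connected directed 3-node isomorphism classes.
N_TRIAD_CLASSES = 13

# Standard triad-census nomenclature (number of mutual / asymmetric /
# null dyads + orientation letter).  021D is the single-regulator fan,
# 030T the feed-forward loop, 021C the cascade/chain.
TRIAD_CLASSES = (
    "021D", "021U", "021C", "111D", "111U", "030T", "030C",
    "201", "120D", "120U", "120C", "210", "300",
)

_FFL = "030T"
_CASCADE = "021C"


# ---------------------------------------------------------------------------
# Metric containers
# ---------------------------------------------------------------------------


@dataclass
class BinaryComparison:
    """TP/FP/FN (+optional TN) counts with derived P, R, F1."""

    level: str  # "edge" | "graphlet"
    tp: int
    fp: int
    fn: int
    tn: int | None = None
    precision: float = field(init=False)
    recall: float = field(init=False)
    f1: float = field(init=False)
    degenerate: bool = field(init=False, default=False)

    def __post_init__(self) -> None:
        self.precision, self.recall, self.f1 = compute_metrics(
            self.tp, self.fp, self.fn
        )
        self.degenerate = (self.tp + self.fp == 0) or (self.tp + self.fn == 0)

    def counts(self, include_tn: bool = False) -> list[int]:
        base = [self.tp, self.fp, self.fn]
        if include_tn:
            if self.tn is None:
                raise UsageError("TN not defined for this comparison")
            base.append(self.tn)
        return base


def compute_metrics(tp: int, fp: int, fn: int) -> tuple[float, float, float]:
    """Precision, recall and F1 from raw counts.

    P = TP/(TP+FP); R = TP/(TP+FN); F1 = 2PR/(P+R).  A zero
    denominator yields 0 for the affected metric (degenerate case).
    """
    if min(tp, fp, fn) < 0:
        raise UsageError("classification counts must be non-negative")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


# ---------------------------------------------------------------------------
# Consensus renaming
# ---------------------------------------------------------------------------


def consensus_rename(
    grns: Sequence[GRN],
    maps: Iterable[OrthologMap],
) -> list[GRN]:
    """Rename genes so orthologs share one canonical name across networks.

    Ortholog groups are the connected components of the pairwise
    ortholog graph (transitively closed union of all maps); each group
    member is renamed to the lexicographically smallest identifier in
    its group.  Genes without orthology keep their own names.
    """
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:  # path compression
            parent[x], x = root, parent[x]
        return root

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            # smaller id becomes the root so the canonical pick is stable
            lo, hi = sorted((ra, rb))
            parent[hi] = lo

    for omap in maps:
        for a, b, _, _ in omap.pairs:
            union(a, b)

    canonical: dict[str, str] = {}
    for gene in list(parent):
        root = find(gene)
        cur = canonical.get(root, root)
        canonical[root] = min(cur, gene)

    def rename(gene: str) -> str:
        if gene not in parent:
            return gene
        return canonical[find(gene)]

    renamed: list[GRN] = []
    for grn in grns:
        out = GRN(grn.organism)
        for inter in sorted(grn, key=lambda i: i.key):
            c = inter.copy()
            c.tf, c.tg = rename(c.tf), rename(c.tg)
            out.add(c)
        renamed.append(out)
    return renamed


# ---------------------------------------------------------------------------
# Edge-level comparison
# ---------------------------------------------------------------------------


def compare_edges(
    reference: GRN,
    predicted: GRN,
    node_universe: int | None = None,
) -> BinaryComparison:
    """Edge-level binary classification of predicted vs reference.

    TP = |E_ref ∩ E_pred|, FN = |E_ref \\ E_pred|, FP = |E_pred \\ E_ref|.
    TN is defined only when a ``node_universe`` count of possible edges
    is supplied (TN = universe − TP − FP − FN).
    """
    e_ref, e_pred = reference.edges(), predicted.edges()
    tp = len(e_ref & e_pred)
    fn = len(e_ref - e_pred)
    fp = len(e_pred - e_ref)
    tn = None
    if node_universe is not None:
        tn = node_universe - tp - fp - fn
        if tn < 0:
            raise UsageError("node universe smaller than observed edge union")
    return BinaryComparison(level="edge", tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# Graphlet enumeration and comparison
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GraphletInstance:
    """One weakly connected induced 3-node subgraph occurrence."""

    nodes: frozenset[str]
    motif_class: str

    def __post_init__(self) -> None:
        if len(self.nodes) != 3:
            raise UsageError("a graphlet instance needs exactly 3 distinct nodes")
        if self.motif_class not in TRIAD_CLASSES:
            raise UsageError(f"unknown motif class {self.motif_class!r}")


def _build_triad_table() -> dict[int, str]:
    """Canonical-arc-mask -> triad-class lookup for labeled 3-node digraphs.

    The 6 possible arcs among nodes (0,1,2) are bits
    (0->1, 0->2, 1->0, 1->2, 2->0, 2->1); the canonical form of a mask
    is its minimum over the 6 node permutations.  Class names are
    derived from the dyad census (mutual/asymmetric/null counts) plus
    the standard orientation letter.
    """
    arcs = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    arc_bit = {a: i for i, a in enumerate(arcs)}

    def permute_mask(mask: int, perm: tuple[int, int, int]) -> int:
        out = 0
        for (u, v), bit in arc_bit.items():
            if mask >> bit & 1:
                out |= 1 << arc_bit[(perm[u], perm[v])]
        return out

    def canonical(mask: int) -> int:
        return min(permute_mask(mask, p) for p in permutations((0, 1, 2)))

    def classify(mask: int) -> str | None:
        has = {a for a, bit in arc_bit.items() if mask >> bit & 1}
        pairs = list(combinations(range(3), 2))
        mutual_pairs = [p for p in pairs if (p[0], p[1]) in has and (p[1], p[0]) in has]
        connected_pairs = [p for p in pairs if (p[0], p[1]) in has or (p[1], p[0]) in has]
        if len(connected_pairs) < 2:  # triple not weakly connected
            return None
        mutual = len(mutual_pairs)
        asym = len(connected_pairs) - mutual
        null = 3 - len(connected_pairs)
        base = f"{mutual}{asym}{null}"
        if base in ("201", "300", "210"):
            return base
        singles = [a for a in has if (a[1], a[0]) not in has]
        outdeg = [0, 0, 0]
        indeg = [0, 0, 0]
        for u, v in singles:
            outdeg[u] += 1
            indeg[v] += 1
        if base == "021":
            if 2 in outdeg:
                return "021D"  # divergent fan: one source regulates both
            if 2 in indeg:
                return "021U"  # convergent: both regulate one sink
            return "021C"  # chain / cascade
        if base == "030":
            if max(outdeg) == 2:
                return "030T"  # transitive triangle = feed-forward loop
            return "030C"  # 3-cycle
        # one mutual dyad remains (111 and 120); orient the single arc(s)
        # relative to the node outside the mutual dyad
        other = ({0, 1, 2} - set(mutual_pairs[0])).pop()
        from_other = sum(1 for u, _ in singles if u == other)
        into_other = sum(1 for _, v in singles if v == other)
        if base == "111":
            return "111D" if from_other else "111U"
        if base == "120":
            if from_other == 2:
                return "120D"
            if into_other == 2:
                return "120U"
            return "120C"
        return None

    table: dict[int, str] = {}
    for mask in range(64):
        cls = classify(mask)
        if cls is not None:
            table[canonical(mask)] = table.get(canonical(mask), cls)
    return table


_ARC_BIT = {
    (0, 1): 0, (0, 2): 1, (1, 0): 2, (1, 2): 3, (2, 0): 4, (2, 1): 5,
}
_PERMS = tuple(permutations((0, 1, 2)))
_TRIAD_TABLE = _build_triad_table()


def classify_triple(
    edges: set[tuple[str, str]], triple: tuple[str, str, str]
) -> str | None:
    """Class of the induced subgraph on a node triple, or None if not
    weakly connected.  Self-loops are ignored."""
    idx = {n: i for i, n in enumerate(triple)}
    mask = 0
    for u, v in combinations(triple, 2):
        if (u, v) in edges:
            mask |= 1 << _ARC_BIT[(idx[u], idx[v])]
        if (v, u) in edges:
            mask |= 1 << _ARC_BIT[(idx[v], idx[u])]
    canon = min(_permute_mask(mask, p) for p in _PERMS)
    return _TRIAD_TABLE.get(canon)


def _permute_mask(mask: int, perm: tuple[int, int, int]) -> int:
    out = 0
    m = mask
    while m:
        bit = (m & -m).bit_length() - 1
        m &= m - 1
        u, v = ((0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1))[bit]
        out |= 1 << _ARC_BIT[(perm[u], perm[v])]
    return out


def enumerate_graphlets(grn: GRN) -> set[GraphletInstance]:
    """All weakly connected induced 3-node subgraphs of the network.

    Enumeration walks edges and their endpoints' neighborhoods rather
    than all node triples: every weakly connected triple contains an
    edge whose endpoints touch the third node.  Self-loops are
    ignored.
    """
    edges = {(tf, tg) for tf, tg in grn.edges() if tf != tg}
    neighbors: dict[str, set[str]] = {}
    for u, v in edges:
        neighbors.setdefault(u, set()).add(v)
        neighbors.setdefault(v, set()).add(u)

    instances: set[GraphletInstance] = set()
    seen: set[frozenset[str]] = set()
    for u, v in edges:
        for w in (neighbors[u] | neighbors[v]) - {u, v}:
            key = frozenset((u, v, w))
            if key in seen:
                continue
            seen.add(key)
            cls = classify_triple(edges, (u, v, w))
            if cls is not None:
                instances.add(GraphletInstance(nodes=key, motif_class=cls))
    return instances


def compare_graphlets(
    reference: GRN,
    predicted: GRN,
) -> BinaryComparison:
    """Graphlet-level binary classification of predicted vs reference.

    Instances are (triple, class) pairs; TP are present in both
    networks, FN only in the reference, FP only in the prediction.
    TN counts the absent (triple, class) combinations over the
    universe C(n,3) x 13 built on the union node set — a convention
    stated here because reported TN magnitudes depend on it.
    """
    g_ref = enumerate_graphlets(reference)
    g_pred = enumerate_graphlets(predicted)
    tp = len(g_ref & g_pred)
    fn = len(g_ref - g_pred)
    fp = len(g_pred - g_ref)
    n = len(reference.genes | predicted.genes)
    universe = (n * (n - 1) * (n - 2) // 6) * N_TRIAD_CLASSES
    tn = universe - tp - fn - fp
    return BinaryComparison(level="graphlet", tp=tp, fp=fp, fn=fn, tn=tn)


# ---------------------------------------------------------------------------
# Randomization null and G-test
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RandomizationConfig:
    """Replicate count and seed for the TF-label permutation null."""

    n_replicates: int = 10000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise UsageError("n_replicates must be >= 1")


def randomize_tf_labels(
    grn: GRN, config: RandomizationConfig
) -> Iterator[GRN]:
    """Yield replicates with TF identity labels permuted.

    Each replicate applies one uniformly drawn permutation of the TF
    name set to the regulator side of every edge, preserving edge
    count, TF count, gene set and the out-degree sequence.  With fewer
    than 2 TFs every replicate equals the original (degenerate case,
    warned once).
    """
    tfs = sorted(grn.tfs)
    rng = np.random.default_rng(config.seed)
    if len(tfs) < 2:
        import logging

        logging.getLogger(__name__).warning(
            "%s: <2 TFs, randomization is the identity", grn.organism
        )
    for _ in range(config.n_replicates):
        perm = rng.permutation(len(tfs))
        relabel = {tfs[i]: tfs[perm[i]] for i in range(len(tfs))}
        out = GRN(grn.organism)
        for inter in sorted(grn, key=lambda i: i.key):
            c = inter.copy()
            c.tf = relabel[c.tf]
            out.add(c)
        yield out


def g_test(
    observed: Sequence[float], expected: Sequence[float]
) -> tuple[float, float]:
    """Likelihood-ratio goodness-of-fit test.

    G = 2 Σ Oᵢ ln(Oᵢ/Eᵢ) (a term with Oᵢ = 0 contributes 0); the
    p-value comes from the chi-square distribution with k−1 degrees of
    freedom.  Eᵢ = 0 with Oᵢ > 0 is undefined.
    """
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if obs.shape != exp.shape or obs.size < 2:
        raise UsageError("observed and expected must share a length >= 2")
    if np.any((exp <= 0) & (obs > 0)):
        raise UsageError("expected count of 0 where observed > 0: G undefined")
    mask = obs > 0
    g = 2.0 * float(np.sum(obs[mask] * np.log(obs[mask] / exp[mask])))
    p = float(stats.chi2.sf(g, df=obs.size - 1))
    return g, p


def null_distribution(
    reference: GRN,
    predicted: GRN,
    config: RandomizationConfig,
    include_tn: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Null counts from comparing TF-randomized predictions to the reference.

    Returns ``(expected, replicates)``: the per-class mean counts over
    replicates (the expectation for :func:`g_test`) and the full
    per-replicate count table.  Columns are (TP, FP, FN[, TN]); TN
    uses the possible-edge universe |TFs ∪| × |genes ∪| over the two
    networks so the four counts always total the same universe.
    """
    universe = _edge_universe(reference, predicted) if include_tn else None
    rows = []
    for replicate in randomize_tf_labels(predicted, config):
        cmp_ = compare_edges(reference, replicate, node_universe=universe)
        rows.append(cmp_.counts(include_tn=include_tn))
    replicates = np.asarray(rows, dtype=float)
    return replicates.mean(axis=0), replicates


def observed_counts(
    reference: GRN, predicted: GRN, include_tn: bool = True
) -> list[int]:
    """Observed (TP, FP, FN[, TN]) with the same TN universe as the null."""
    universe = _edge_universe(reference, predicted) if include_tn else None
    return compare_edges(reference, predicted, node_universe=universe).counts(
        include_tn=include_tn
    )


def _edge_universe(reference: GRN, predicted: GRN) -> int:
    tfs = reference.tfs | predicted.tfs
    genes = reference.genes | predicted.genes
    return len(tfs) * len(genes)
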