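"""Barcode-marker evaluation.

Candidate barcode genes are compared on four axes: Kimura 2-parameter
(K2P) inter-specific divergence within dominant genera and families,
monophyly resolution rate (Rf) on UPGMA trees, the barcoding-gap
criterion (smallest inter-specific distance strictly exceeding the
largest intra-specific distance), and amplification success across the
sampled flora.

K2P corrects transition (P) and transversion (Q) proportions separately:

    d = -1/2 * ln(1 - 2P - Q) - 1/4 * ln(1 - 2Q)

Sites where either sequence carries a gap or N are deleted pairwise.
When a log argument is non-positive the distance is saturated and is
propagated as a flag rather than a number; UPGMA refuses saturated
matrices rather than substituting an arbitrary large distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from anserdiet.io_core import SeqRecord, Taxon

# Alignment parameters for barcode comparison: conventional for
# near-equal-length barcodes, with a deterministic optimum.
MATCH = 1
MISMATCH = -2
GAP_OPEN = -5
GAP_EXTEND = -2


class SaturatedDistance:
    """Flag object returned when the K2P logarithm is undefined."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "SATURATED"


SATURATED = SaturatedDistance()

_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}
_VALID = {"A", "C", "G", "T"}


@dataclass
class AlignedPair:
    """Two equal-length gapped sequences ready for site classification."""

    seq_a: str
    seq_b: str

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise ValueError("aligned sequences must have equal length")

    def site_counts(self) -> tuple[int, int, int]:
        """(comparable_sites, transitions, transversions) with pairwise
        deletion of columns where either character is outside {A,C,G,T}."""
        comparable = transitions = transversions = 0
        for a, b in zip(self.seq_a, self.seq_b):
            if a not in _VALID or b not in _VALID:
                continue
            comparable += 1
            if a == b:
                continue
            if (a in _PURINES) == (b in _PURINES):
                transitions += 1
            else:
                transversions += 1
        return comparable, transitions, transversions

    @property
    def comparable_sites(self) -> int:
        return self.site_counts()[0]


def k2p_distance(pair: AlignedPair):
    """K2P distance for one aligned pair.

    Returns a float, or :data:`SATURATED` when ``1-2P-Q <= 0`` or
    ``1-2Q <= 0``.  Raises ``ValueError`` when no comparable sites exist.
    """
    comparable, ts, tv = pair.site_counts()
    if comparable == 0:
        raise ValueError("K2P distance undefined: zero comparable sites")
    p = ts / comparable
    q = tv / comparable
    a1 = 1.0 - 2.0 * p - q
    a2 = 1.0 - 2.0 * q
    if a1 <= 0.0 or a2 <= 0.0:
        return SATURATED
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def _aligner(mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.match_score = MATCH
    aligner.mismatch_score = MISMATCH
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


_GLOBAL_ALIGNER = _aligner("global")


def align_pairwise(seq_a: str, seq_b: str) -> AlignedPair:
    """Global (Needleman–Wunsch) alignment with affine gaps.

    Scoring: match +1, mismatch -2, gap open -5, gap extend -2; end gaps
    are penalized.  The first optimal traceback is used, which is
    deterministic for fixed inputs.
    """
    if not seq_a or not seq_b:
        raise ValueError("cannot align an empty sequence")
    aln = _GLOBAL_ALIGNER.align(seq_a, seq_b)[0]
    return AlignedPair(str(aln[0]), str(aln[1]))


@dataclass
class DistanceMatrix:
    """Pairwise K2P distances with per-pair P/Q retained.

    ``d`` holds NaN where a pair is saturated; ``saturated`` marks those
    entries explicitly.
    """

    labels: list[str]
    d: np.ndarray
    p: np.ndarray
    q: np.ndarray
    saturated: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])

    @property
    def n(self) -> int:
        return len(self.labels)

    def has_saturation(self) -> bool:
        return bool(self.saturated.any())

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        ix = np.ix_(idx, idx)
        return DistanceMatrix(list(labels), self.d[ix], self.p[ix],
                              self.q[ix], self.saturated[ix])


def pairwise_distances(records: Sequence[SeqRecord]) -> DistanceMatrix:
    """K2P distance matrix over all pairs.

    Equal-length inputs are treated as pre-aligned (columns compared
    directly); otherwise each pair is globally aligned first.  Sites with
    gaps or N are deleted per pair.  A pair with zero comparable sites is
    an error naming the pair.
    """
    n = len(records)
    d = np.zeros((n, n))
    p = np.zeros((n, n))
    q = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    prealigned = len({len(r.sequence) for r in records}) <= 1
    for i in range(n):
        for j in range(i + 1, n):
            if prealigned:
                pair = AlignedPair(records[i].sequence, records[j].sequence)
            else:
                pair = align_pairwise(records[i].sequence, records[j].sequence)
            comparable, ts, tv = pair.site_counts()
            if comparable == 0:
                raise ValueError(
                    f"pair ({records[i].id}, {records[j].id}): "
                    "zero comparable sites"
                )
            p[i, j] = p[j, i] = ts / comparable
            q[i, j] = q[j, i] = tv / comparable
            dist = k2p_distance(pair)
            if dist is SATURATED:
                sat[i, j] = sat[j, i] = True
                d[i, j] = d[j, i] = np.nan
            else:
                d[i, j] = d[j, i] = dist
    return DistanceMatrix([r.id for r in records], d, p, q, sat)


# ---------------------------------------------------------------------------
# divergence summaries and the barcoding gap


@dataclass
class DivergenceSummary:
    """Inter-specific K2P statistics for one genus or family."""

    group: str
    level: str  # "genus" | "family"
    max: float
    min: float
    mean: float
    sd: float
    n_pairs: int
    intra_max: float | None = None

    def as_row(self) -> dict:
        return {
            "group": self.group, "level": self.level,
            "max": self.max, "min": self.min,
            "mean": self.mean, "sd": self.sd,
            "n_pairs": self.n_pairs,
            "intra_max": "" if self.intra_max is None else self.intra_max,
        }


def divergence_summary(
    matrix: DistanceMatrix,
    taxonomy: Mapping[str, Taxon],
    group: str,
    level: str,
) -> DivergenceSummary:
    """Summarize inter-specific distances within one genus or family.

    Inter-specific pairs are pairs of sequences whose species labels
    differ, both lying in the group.  ``sd`` is the population standard
    deviation over those pairs.  ``intra_max`` is the largest
    same-species distance, absent when the group has no intra-specific
    pair.
    """
    if level not in ("genus", "family"):
        raise ValueError(f"level={level!r}")
    members = [
        l for l in matrix.labels
        if l in taxonomy and getattr(taxonomy[l], level) == group
    ]
    if not members:
        raise ValueError(f"group {group!r} absent from taxonomy at {level} level")
    inter: list[float] = []
    intra: list[float] = []
    for a_i, a in enumerate(members):
        for b in members[a_i + 1:]:
            dist = matrix[a, b]
            target = inter if taxonomy[a].species != taxonomy[b].species else intra
            target.append(dist)
    if not inter:
        raise ValueError(
            f"group {group!r}: no inter-specific pairs (single species)"
        )
    arr = np.asarray(inter)
    if np.isnan(arr).any():
        raise ValueError(f"group {group!r}: saturated distances present")
    return DivergenceSummary(
        group=group,
        level=level,
        max=float(arr.max()),
        min=float(arr.min()),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=0)),
        n_pairs=len(inter),
        intra_max=float(np.max(intra)) if intra else None,
    )


def barcoding_gap(summary: DivergenceSummary) -> bool | None:
    """True iff the minimal inter-specific distance strictly exceeds the
    maximal intra-specific distance; None (indeterminate) when the group
    has no intra-specific pairs."""
    if summary.intra_max is None:
        return None
    return summary.min > summary.intra_max


# ---------------------------------------------------------------------------
# UPGMA and monophyly resolution


@dataclass
class _Node:
    height: float
    label: str | None = None
    children: tuple["_Node", "_Node"] | None = None

    def leaves(self) -> list[str]:
        if self.children is None:
            return [self.label]  # type: ignore[list-item]
        return self.children[0].leaves() + self.children[1].leaves()


class UpgmaTree:
    """Rooted ultrametric tree from average-linkage clustering.

    Internal node heights are half the merge distance, so leaf-to-leaf
    cophenetic distances equal the linkage distances.
    """

    def __init__(self, linkage: np.ndarray, labels: Sequence[str]):
        self._linkage = linkage
        self.labels = list(labels)
        self.root = self._build()

    def _build(self) -> _Node:
        nodes: dict[int, _Node] = {
            i: _Node(0.0, label=l) for i, l in enumerate(self.labels)
        }
        n = len(self.labels)
        for k, (a, b, dist, _size) in enumerate(self._linkage):
            nodes[n + k] = _Node(
                height=dist / 2.0,
                children=(nodes[int(a)], nodes[int(b)]),
            )
        return nodes[n + len(self._linkage) - 1] if len(self._linkage) else nodes[0]

    def clades(self) -> list[frozenset[str]]:
        """Leaf sets of every internal node (including the root)."""
        out: list[frozenset[str]] = []

        def walk(node: _Node) -> None:
            if node.children is None:
                return
            out.append(frozenset(node.leaves()))
            for child in node.children:
                walk(child)

        walk(self.root)
        return out

    def cophenetic(self) -> DistanceMatrixLike:
        coph = hierarchy.cophenet(self._linkage)
        return DistanceMatrixLike(self.labels, squareform(coph))

    def newick(self) -> str:
        def fmt(node: _Node, parent_height: float) -> str:
            bl = parent_height - node.height
            if node.children is None:
                return f"{node.label}:{bl:.6f}"
            inner = ",".join(fmt(c, node.height) for c in node.children)
            return f"({inner}):{bl:.6f}"

        if self.root.children is None:
            return f"{self.root.label}:0.000000;"
        inner = ",".join(fmt(c, self.root.height) for c in self.root.children)
        return f"({inner});"

    def leaf_heights_from_root(self) -> dict[str, float]:
        out: dict[str, float] = {}

        def walk(node: _Node, acc: float) -> None:
            if node.children is None:
                out[node.label] = acc  # type: ignore[index]
                return
            for child in node.children:
                walk(child, acc + node.height - child.height)

        walk(self.root, 0.0)
        return out


@dataclass
class DistanceMatrixLike:
    labels: list[str]
    d: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.d[i, j])


def upgma(matrix: DistanceMatrix) -> UpgmaTree:
    """UPGMA (average-linkage) tree; refuses saturated distances."""
    if matrix.n < 2:
        raise ValueError("UPGMA requires at least two leaves")
    if matrix.has_saturation():
        raise ValueError("distance matrix contains saturated pairs")
    condensed = squareform(matrix.d, checks=False)
    linkage = hierarchy.linkage(condensed, method="average")
    return UpgmaTree(linkage, matrix.labels)


def resolution_rate(
    tree: UpgmaTree, species_of_leaf: Mapping[str, str]
) -> float | None:
    """Rf: percent of multi-sequence species recovered as monophyletic.

    Species represented by a single leaf are excluded from numerator and
    denominator (counting them as trivially monophyletic would inflate
    Rf).  Returns None when no species has two or more leaves.
    """
    missing = [l for l in tree.labels if l not in species_of_leaf]
    if missing:
        raise ValueError(f"leaves without species mapping: {missing}")
    by_species: dict[str, set[str]] = {}
    for leaf in tree.labels:
        by_species.setdefault(species_of_leaf[leaf], set()).add(leaf)
    multi = {sp: lv for sp, lv in by_species.items() if len(lv) >= 2}
    if not multi:
        return None
    clades = set(tree.clades())
    mono = sum(1 for leaves in multi.values() if frozenset(leaves) in clades)
    return 100.0 * mono / len(multi)


# ---------------------------------------------------------------------------
# marker ranking


@dataclass
class MarkerReport:
    """Per-gene evaluation summary."""

    gene: str
    amplification_success: float
    rf: float | None = None
    summaries: list[DivergenceSummary] = field(default_factory=list)
    gap_ok: dict[str, bool | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplification_success <= 1.0:
            raise ValueError("amplification_success must be in [0, 1]")
        if self.rf is not None and not 0.0 <= self.rf <= 100.0:
            raise ValueError("rf must be in [0, 100]")


def rank_markers(
    reports: Sequence[MarkerReport],
) -> tuple[list[MarkerReport], pd.DataFrame]:
    """Rank candidate markers.

    Lexicographic criteria: (1) amplification success, descending;
    (2) number of groups in which the marker attains the largest mean
    inter-specific divergence (ties in a group credit every tied marker);
    (3) number of groups with a barcoding gap; alphabetical gene name
    breaks remaining ties.  Returns the ordered reports and a
    per-criterion audit table.
    """
    if not reports:
        raise ValueError("no marker reports to rank")
    best_mean: dict[str, float] = {}
    for rep in reports:
        for s in rep.summaries:
            key = f"{s.level}:{s.group}"
            best_mean[key] = max(best_mean.get(key, -math.inf), s.mean)
    wins = {
        rep.gene: sum(
            1 for s in rep.summaries
            if s.mean >= best_mean[f"{s.level}:{s.group}"] - 1e-12
        )
        for rep in reports
    }
    gaps = {
        rep.gene: sum(1 for ok in rep.gap_ok.values() if ok is True)
        for rep in reports
    }
    ordered = sorted(
        reports,
        key=lambda r: (-r.amplification_success, -wins[r.gene],
                       -gaps[r.gene], r.gene),
    )
    audit = pd.DataFrame(
        {
            "rank": range(1, len(ordered) + 1),
            "gene": [r.gene for r in ordered],
            "amplification_success": [r.amplification_success for r in ordered],
            "n_groups_largest_mean_divergence": [wins[r.gene] for r in ordered],
            "n_groups_with_barcoding_gap": [gaps[r.gene] for r in ordered],
            "rf": [("" if r.rf is None else r.rf) for r in ordered],
        }
    )
    return ordered, audit
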