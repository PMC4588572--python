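"""LTR retrotransposon dynamics: insertion-age dating from the divergence of
the two terminal repeats, burst detection in the age distribution, 80–80–80
family clustering, singleton statistics, and gene-proximity annotation.

An LTR retroelement's two long terminal repeats are identical at insertion;
substitutions accumulate independently in each, so the Kimura two-parameter
distance K between them dates the insertion as T = K/(2r), with r the
substitution rate per site per year (cotton default 2.6e-9).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from polyevol import align, moldiv
from polyevol.align import ScoringScheme
from polyevol.moldiv import ClockParams
from polyevol._util import GeneModel


class UndatableElement(ValueError):
    """LTR pair unalignable or saturated; element excluded from dating."""


@dataclass
class LTRElement:
    """A full-length element with both terminal repeats present."""

    element_id: str
    chrom: str = "."
    start: int = 0
    end: int = 0
    strand: str = "+"
    left_ltr: str = ""
    right_ltr: str = ""
    family_id: str | None = None
    k2p: float | None = None
    age_years: float | None = None

    def __post_init__(self):
        if not self.left_ltr or not self.right_ltr:
            raise ValueError(f"{self.element_id}: both LTRs must be non-empty")


@dataclass
class FamilyAssignment:
    families: dict[str, list[str]] = field(default_factory=dict)

    @property
    def n_families(self) -> int:
        return len(self.families)

    @property
    def singleton_ratio(self) -> float:
        if not self.families:
            return math.nan
        singles = sum(1 for m in self.families.values() if len(m) == 1)
        return singles / len(self.families)


def ltr_insertion_age(elem: LTRElement, clock: ClockParams | None = None,
                      scoring: ScoringScheme | None = None) -> float:
    """Date one element: global LTR-vs-LTR alignment, K2P on gap-free
    columns, T = K/(2r).  Sets ``elem.k2p`` and ``elem.age_years``."""
    clock = clock or ClockParams()
    scoring = scoring or ScoringScheme.dna()
    _score, identity, (a, b) = align.global_align(elem.left_ltr, elem.right_ltr, scoring)
    if identity <= 0.5:
        raise UndatableElement(f"{elem.element_id}: LTR identity {identity:.2f} <= 50%")
    try:
        k = moldiv.k2p_distance(a, b)
    except moldiv.SaturatedDistance as exc:
        raise UndatableElement(f"{elem.element_id}: saturated K2P") from exc
    elem.k2p = k
    elem.age_years = moldiv.clock_convert(k, clock)
    return elem.age_years


def date_elements(elems: list[LTRElement], clock: ClockParams | None = None,
                  ) -> tuple[list[LTRElement], list[LTRElement]]:
    """Date all elements; returns (dated, undatable)."""
    dated, undated = [], []
    for e in elems:
        try:
            ltr_insertion_age(e, clock)
            dated.append(e)
        except UndatableElement:
            undated.append(e)
    return dated, undated


@dataclass
class AgeDistribution:
    bin_years: float
    counts: np.ndarray
    bursts: list[float]  # burst modes, years (bin midpoints)

    def midpoints(self) -> np.ndarray:
        return (np.arange(len(self.counts)) + 0.5) * self.bin_years


def _burst_bins(counts: np.ndarray, prominence: float) -> list[int]:
    """Modes of the age histogram: plateau-aware local maxima of a 3-bin
    moving average (edge-padded), kept when the smoothed peak exceeds the
    larger flanking minimum by ``prominence`` x the peak height.  Smoothing
    makes a component that straddles a bin boundary a single burst instead
    of two half-height bins; a flat histogram has no bursts."""
    n = len(counts)
    if n == 0:
        return []
    if n == 1:
        return [0] if counts[0] > 0 else []
    c = counts.astype(float)
    padded = np.concatenate([[c[0]], c, [c[-1]]])
    sm = np.convolve(padded, np.ones(3) / 3.0, mode="valid")
    runs: list[tuple[int, int, float]] = []  # maximal equal-value runs
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sm[j + 1] == sm[i]:
            j += 1
        runs.append((i, j, sm[i]))
        i = j + 1
    out = []
    for k, (a, b, v) in enumerate(runs):
        if v <= 0:
            continue
        left = runs[k - 1][2] if k > 0 else None
        right = runs[k + 1][2] if k + 1 < len(runs) else None
        if left is None and right is None:
            continue  # flat histogram
        if (left is not None and left >= v) or (right is not None and right >= v):
            continue
        left_min = sm[:a].min() if a > 0 else 0.0
        right_min = sm[b + 1 :].min() if b + 1 < n else 0.0
        if v - max(left_min, right_min) >= prominence * v:
            out.append(int(a + np.argmax(counts[a : b + 1])))
    return out


def age_distribution(elems: list[LTRElement], bin_years: float = 1e6,
                     prominence: float = 0.25) -> AgeDistribution:
    """Histogram of insertion ages plus burst modes (prominent local maxima)."""
    ages = [e.age_years for e in elems if e.age_years is not None]
    if not ages:
        raise ValueError("no dated elements: empty age distribution")
    idx = np.floor(np.asarray(ages) / bin_years).astype(int)
    counts = np.bincount(idx)
    bursts = [(i + 0.5) * bin_years for i in _burst_bins(counts, prominence)]
    return AgeDistribution(bin_years, counts, bursts)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def cluster_families_808080(elems: list[LTRElement],
                            scoring: ScoringScheme | None = None,
                            prefilter_k: int = 13) -> FamilyAssignment:
    """Cluster elements into families by the 80–80–80 rule.

    Two elements join one family when their terminal-repeat sequences share
    >= 80% identity over >= 80% of the shorter sequence's length with an
    aligned length > 80 bp; families are the connected components (single
    linkage), so the result is independent of input order.  A shared-k-mer
    prefilter skips pairs that cannot plausibly reach 80% identity.
    """
    scoring = scoring or ScoringScheme.dna()
    ids = [e.element_id for e in elems]
    uf = _UnionFind(ids)
    kmers = {e.element_id: {e.left_ltr[i : i + prefilter_k]
                            for i in range(len(e.left_ltr) - prefilter_k + 1)}
             for e in elems}
    for i, e1 in enumerate(elems):
        for e2 in elems[i + 1 :]:
            if not (kmers[e1.element_id] & kmers[e2.element_id]):
                continue
            s1, s2 = e1.left_ltr, e2.left_ltr
            hsps = align._extract_hsps(s1, s2, scoring, min_score=20.0, max_hsps=1)
            if not hsps:
                continue
            h = hsps[0]
            ident = h.identities / h.aligned_len
            shorter = min(len(s1), len(s2))
            span = min(h.q_end - h.q_start, h.s_end - h.s_start)
            if ident >= 0.80 and span >= 0.80 * shorter and h.aligned_len > 80:
                uf.union(e1.element_id, e2.element_id)
    fams: dict[str, list[str]] = {}
    for e in sorted(elems, key=lambda e: e.element_id):
        root = uf.find(e.element_id)
        fam = f"fam_{root}"
        fams.setdefault(fam, []).append(e.element_id)
        e.family_id = fam
    return FamilyAssignment(fams)


def annotate_ltr_proximity(genes: list[GeneModel], elems: list[LTRElement],
                           window: int = 20_000) -> dict[str, bool]:
    """Flag genes with an LTR element within ``window`` bp upstream of the
    start codon (strand-aware; half-open interval arithmetic)."""
    by_chrom: dict[str, list[LTRElement]] = {}
    for e in elems:
        by_chrom.setdefault(e.chrom, []).append(e)
    flags: dict[str, bool] = {}
    for g in genes:
        if g.strand not in "+-":
            raise ValueError(f"gene {g.gene_id} lacks strand")
        if g.strand == "+":
            w0, w1 = max(0, g.start - window), g.start
        else:  # upstream of a minus-strand gene extends toward larger coords
            w0, w1 = g.end, g.end + window
        flag = False
        for e in by_chrom.get(g.chrom, []):
            if e.start < w1 and w0 < e.end:
                flag = True
                break
        flags[g.gene_id] = flag
    return flags
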