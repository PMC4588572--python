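"""Molecular divergence: codon alignment, Ka/Ks by Nei–Gojobori counting
with Jukes–Cantor correction, Kimura two-parameter distances, Ks histograms
and molecular-clock dating T = K/(2r).

Estimator notes
---------------
Ka/Ks uses the NG86 scheme: the synonymous site content of a codon is the
fraction of its nine single-nucleotide neighbours (three per position) that
preserve the amino acid, with changes creating a stop codon counted as
nonsynonymous; site totals are averaged over the two sequences.  Codons
differing at several positions are resolved by averaging the synonymous /
nonsynonymous step counts over every ordering of single steps, excluding
pathways that pass through a stop codon (all orderings blocked -> fall back
to including them).  Proportions are corrected with the one-parameter
Jukes–Cantor formula d = -(3/4) ln(1 - 4p/3); p >= 3/4 is flagged saturated.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

from polyevol import align
from polyevol.align import ScoringScheme

_BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


class InvalidCDS(ValueError):
    """CDS not translatable: wrong length or internal stop."""


class SaturatedDistance(ValueError):
    """Distance formula undefined (log of a non-positive argument)."""


@lru_cache(maxsize=4)
def _translator(table_id: int = 1) -> dict[str, str]:
    tab = unambiguous_dna_by_id[table_id]
    mapping = dict(tab.forward_table)
    for stop in tab.stop_codons:
        mapping[stop] = "*"
    return mapping


def translate(cds: str, table_id: int = 1) -> str:
    """Translate a CDS; raises InvalidCDS on bad length or internal stop."""
    if len(cds) % 3 != 0 or not cds:
        raise InvalidCDS(f"CDS length {len(cds)} is not a positive multiple of 3")
    tr = _translator(table_id)
    aas = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3].upper()
        aa = tr.get(codon)
        if aa is None:
            raise InvalidCDS(f"unrecognized codon {codon!r}")
        if aa == "*" and i < len(cds) - 3:
            raise InvalidCDS(f"internal stop codon at nt {i}")
        aas.append(aa)
    if aas and aas[-1] == "*":
        aas.pop()  # trailing stop is tolerated and trimmed
    return "".join(aas)


@dataclass
class CodonAlignment:
    """A pair of aligned CDSs; gaps in whole-codon units."""

    seq1: str
    seq2: str
    id1: str = "seq1"
    id2: str = "seq2"

    def __post_init__(self):
        if len(self.seq1) != len(self.seq2) or len(self.seq1) % 3 != 0:
            raise InvalidCDS("aligned CDSs must be equal length, multiple of 3")

    def codon_pairs(self) -> list[tuple[str, str]]:
        """Gap-free aligned codon pairs."""
        out = []
        for i in range(0, len(self.seq1), 3):
            c1, c2 = self.seq1[i : i + 3], self.seq2[i : i + 3]
            if "-" not in c1 and "-" not in c2:
                out.append((c1.upper(), c2.upper()))
        return out


@dataclass
class DivergenceEstimate:
    N: float
    S: float
    Nd: float
    Sd: float
    pN: float
    pS: float
    Ka: float
    Ks: float
    omega: float
    saturated: bool


@dataclass
class ClockParams:
    """Molecular clock: substitutions per site per year.

    The default 2.6e-9 is the average substitution rate for cotton.
    """

    r: float = 2.6e-9

    def __post_init__(self):
        if self.r <= 0:
            raise ValueError("clock rate must be positive")


def codon_align(cds1: str, cds2: str, table_id: int = 1,
                scoring: ScoringScheme | None = None) -> CodonAlignment:
    """Codon-aware alignment: globally align the translations, then
    back-propagate gaps to the nucleotide sequences in whole codons."""
    p1, p2 = translate(cds1, table_id), translate(cds2, table_id)
    scoring = scoring or ScoringScheme.protein()
    _, _, (a1, a2) = align.global_align(p1, p2, scoring)
    out1, out2, i, j = [], [], 0, 0
    for x, y in zip(a1, a2):
        if x == "-":
            out1.append("---")
        else:
            out1.append(cds1[3 * i : 3 * i + 3])
            i += 1
        if y == "-":
            out2.append("---")
        else:
            out2.append(cds2[3 * j : 3 * j + 3])
            j += 1
    return CodonAlignment("".join(out1), "".join(out2))


@lru_cache(maxsize=256)
def syn_fraction(codon: str, table_id: int = 1) -> float:
    """Synonymous site count of a codon (0..3): per position, the fraction of
    the three single-nucleotide changes that preserve the amino acid.
    Changes to stop codons count as nonsynonymous."""
    tr = _translator(table_id)
    aa = tr[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if tr[mut] == aa and tr[mut] != "*":
                syn += 1
        s += syn / 3.0
    return s


def _is_syn_step(c1: str, c2: str, table_id: int = 1) -> bool:
    tr = _translator(table_id)
    return tr[c1] == tr[c2] and tr[c1] != "*"


@lru_cache(maxsize=4096)
def codon_path_counts(c1: str, c2: str, table_id: int = 1) -> tuple[float, float]:
    """(synonymous, nonsynonymous) difference counts between two codons,
    averaged over all single-step pathways; stop-crossing pathways excluded
    and the rest re-weighted equally."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    tr = _translator(table_id)
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        steps, blocked = [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if tr[nxt] == "*" and nxt != c2:
                blocked = True
            steps.append((cur, nxt))
            cur = nxt
        paths.append((steps, blocked))
    usable = [steps for steps, blocked in paths if not blocked]
    if not usable:  # every ordering crosses a stop; fall back to all
        usable = [steps for steps, _ in paths]
    sd = nd = 0.0
    for steps in usable:
        for a, b in steps:
            if _is_syn_step(a, b, table_id):
                sd += 1
            else:
                nd += 1
    k = len(usable)
    return sd / k, nd / k


def jukes_cantor(p: float) -> float:
    """JC69 correction; raises SaturatedDistance for p >= 3/4."""
    if p < 0:
        raise ValueError("proportion must be non-negative")
    if p >= 0.75:
        raise SaturatedDistance(f"p = {p:.4f} >= 3/4")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def ng86(aln: CodonAlignment, table_id: int = 1) -> DivergenceEstimate:
    """Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction."""
    pairs = aln.codon_pairs()
    if not pairs:
        raise InvalidCDS("no gap-free aligned codons")
    S1 = sum(syn_fraction(c1, table_id) for c1, _ in pairs)
    S2 = sum(syn_fraction(c2, table_id) for _, c2 in pairs)
    S = 0.5 * (S1 + S2)
    N = 3.0 * len(pairs) - S
    Sd = Nd = 0.0
    for c1, c2 in pairs:
        sd, nd = codon_path_counts(c1, c2, table_id)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    saturated = False
    try:
        Ks = jukes_cantor(pS) if not math.isnan(pS) else math.nan
    except SaturatedDistance:
        Ks, saturated = math.nan, True
    try:
        Ka = jukes_cantor(pN) if not math.isnan(pN) else math.nan
    except SaturatedDistance:
        Ka, saturated = math.nan, True
    omega = Ka / Ks if not math.isnan(Ks) and Ks > 0 and not math.isnan(Ka) else math.nan
    return DivergenceEstimate(N, S, Nd, Sd, pN, pS, Ka, Ks, omega, saturated)


def k2p_distance(a: str, b: str) -> float:
    """Kimura two-parameter distance K = -1/2 ln((1-2P-Q) sqrt(1-2Q)).

    P and Q are the transition and transversion proportions over columns
    where both sequences carry an unambiguous base; gap or ambiguity columns
    are excluded from the denominators.
    """
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    n = ts = tv = 0
    for x, y in zip(a.upper(), b.upper()):
        if x not in _BASES or y not in _BASES:
            continue
        n += 1
        if x == y:
            continue
        if _TRANSITION[x] == y:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise ValueError("no comparable columns")
    P, Q = ts / n, tv / n
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturatedDistance(f"K2P undefined for P={P:.3f}, Q={Q:.3f}")
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass
class KsHistogram:
    """Left-closed right-open binning of Ks values from 0."""

    bin_width: float
    counts: np.ndarray
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def bin_left(self, i: int) -> float:
        return i * self.bin_width

    def midpoints(self) -> np.ndarray:
        return (np.arange(len(self.counts)) + 0.5) * self.bin_width

    def to_tsv(self) -> str:
        lines = ["bin_left\tcount"]
        for i, c in enumerate(self.counts):
            lines.append(f"{self.bin_left(i):g}\t{int(c)}")
        return "\n".join(lines) + "\n"


def ks_histogram(values, bin_width: float) -> KsHistogram:
    """Histogram of finite Ks values; saturated/undefined counted separately."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    vals = np.asarray(list(values), dtype=float)
    finite = vals[np.isfinite(vals)]
    excluded = len(vals) - len(finite)
    if len(finite) == 0:
        return KsHistogram(bin_width, np.zeros(0, dtype=int), excluded)
    idx = np.floor(finite / bin_width).astype(int)
    counts = np.bincount(idx)
    return KsHistogram(bin_width, counts, excluded)


def find_peak(hist: KsHistogram) -> float:
    """Midpoint of the maximal-count bin; ties break toward smaller Ks."""
    if len(hist.counts) == 0 or hist.counts.sum() == 0:
        raise ValueError("empty histogram has no peak")
    i = int(np.argmax(hist.counts))  # argmax returns the first maximum
    return (i + 0.5) * hist.bin_width


def clock_convert(K: float, clock: ClockParams | None = None) -> float:
    """Date a divergence: T = K / (2 r) years."""
    if K < 0:
        raise ValueError("distance must be non-negative")
    clock = clock or ClockParams()
    return K / (2.0 * clock.r)


def pairwise_kaks(cds_pairs, table_id: int = 1):
    """NG86 over (id1, id2, cds1, cds2) tuples via codon alignment."""
    out = []
    for id1, id2, c1, c2 in cds_pairs:
        aln = codon_align(c1, c2, table_id)
        out.append((id1, id2, ng86(aln, table_id)))
    return out
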