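"""Pairwise alignment engine: global/local affine-gap alignment, HSPs,
identity/coverage bookkeeping and approximate Karlin–Altschul E-values.

The dynamic programming itself is delegated to Biopython's ``PairwiseAligner``
(a C implementation of Needleman–Wunsch / Smith–Waterman / Gotoh); this module
owns the scoring conventions, the iterative HSP extraction, the k-mer
prefilter that makes all-vs-all protein searches tractable, the seed-and-extend
path for short-query-vs-genome mapping, and the E-value model.

Conventions
-----------
* Coordinates are 0-based half-open throughout; conversion to 1-based
  inclusive happens only at GFF3/report boundaries.
* Gap penalties are positive numbers; a gap of length L costs
  ``gap_open + gap_extend * L`` (BLAST convention).
* E-values use the ungapped Karlin–Altschul formula E = K m n exp(-lambda S)
  with lambda solved exactly from sum_ij p_i p_j exp(lambda s_ij) = 1 under
  uniform background frequencies, and K fixed at 0.1.  Gapped scores reuse
  the ungapped lambda; this is an approximation adequate for thresholding at
  the E <= 1e-3 level used downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.optimize import brentq

KA_K = 0.1  # Karlin-Altschul K; fixed constant, see module docstring

_DNA_ALPHABET = "ACGTN#"
_PROT_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*#"
_MASK_SCORE = -1000.0  # '#' mask sentinel: nothing may align across it


class AlignmentError(ValueError):
    """Invalid alignment input (empty sequence, bad parameter)."""


@dataclass(frozen=True)
class ScoringScheme:
    """Scores for matches/mismatches (or a residue matrix) plus affine gaps."""

    gap_open: float = 5.0
    gap_extend: float = 2.0
    match: float = 1.0
    mismatch: float = -2.0
    matrix_name: str | None = None  # e.g. "BLOSUM62" for proteins
    alphabet: str = "DNA"
    # additive composition adjustment: shifts every residue-pair score so
    # that biased-composition sequences score negative on average (the role
    # of BLAST's composition-based statistics)
    matrix_shift: float = 0.0

    def __post_init__(self):
        if not (self.gap_open >= self.gap_extend >= 0):
            raise AlignmentError("require gap_open >= gap_extend >= 0 (penalties)")
        if self.matrix_name is None and not self.match > self.mismatch:
            raise AlignmentError("require match > mismatch")

    @staticmethod
    def dna(match: float = 1.0, mismatch: float = -2.0, gap_open: float = 5.0,
            gap_extend: float = 2.0) -> "ScoringScheme":
        return ScoringScheme(gap_open, gap_extend, match, mismatch, None, "DNA")

    @staticmethod
    def protein(gap_open: float = 11.0, gap_extend: float = 1.0,
                matrix_name: str = "BLOSUM62",
                matrix_shift: float = 0.0) -> "ScoringScheme":
        return ScoringScheme(gap_open, gap_extend, 0.0, -1.0, matrix_name,
                             "protein", matrix_shift)


@dataclass
class Hsp:
    """One high-scoring segment pair; coordinates 0-based half-open.

    ``q_aln``/``s_aln`` hold the gapped alignment rows of the local region
    when the producer retains them (empty otherwise).
    """

    q_start: int
    q_end: int
    s_start: int
    s_end: int
    score: float
    identities: int
    aligned_len: int
    q_aln: str = ""
    s_aln: str = ""

    def __post_init__(self):
        if not (0 <= self.identities <= self.aligned_len):
            raise AlignmentError("identities out of range")
        if self.q_end <= self.q_start:
            raise AlignmentError("empty HSP query interval")


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    hsps: list[Hsp] = field(default_factory=list)
    best_score: float = 0.0
    identity_pct: float = 0.0
    q_coverage: float = 0.0
    s_coverage: float = 0.0
    e_value: float = math.inf


@lru_cache(maxsize=32)
def _matrix_for(scheme: ScoringScheme) -> substitution_matrices.Array:
    """Substitution matrix extended with the '#' mask sentinel."""
    if scheme.alphabet == "protein":
        base = substitution_matrices.load(scheme.matrix_name or "BLOSUM62")
        mat = substitution_matrices.Array(_PROT_ALPHABET, dims=2)
        for a in _PROT_ALPHABET:
            for b in _PROT_ALPHABET:
                if a == "#" or b == "#":
                    mat[a, b] = _MASK_SCORE
                else:
                    try:
                        mat[a, b] = base[a, b] + scheme.matrix_shift
                    except IndexError:
                        mat[a, b] = _MASK_SCORE  # '*' vs residue
        return mat
    mat = substitution_matrices.Array(_DNA_ALPHABET, dims=2)
    for a in _DNA_ALPHABET:
        for b in _DNA_ALPHABET:
            if a == "#" or b == "#":
                mat[a, b] = _MASK_SCORE
            elif a == "N" or b == "N":
                mat[a, b] = 0.0
            else:
                mat[a, b] = scheme.match if a == b else scheme.mismatch
    return mat


def _aligner(scheme: ScoringScheme, mode: str) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = mode
    al.substitution_matrix = _matrix_for(scheme)
    # gap of length L costs gap_open + gap_extend * L
    al.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    al.extend_gap_score = -scheme.gap_extend
    return al


def _column_stats(alignment) -> tuple[int, int]:
    """(identities, columns) over an alignment's printed rows."""
    a_row, b_row = str(alignment[0]), str(alignment[1])
    ident = sum(1 for x, y in zip(a_row, b_row) if x == y and x != "-")
    return ident, len(a_row)


@lru_cache(maxsize=32)
def karlin_lambda(scheme: ScoringScheme) -> float:
    """Solve sum_ij p_i p_j exp(lambda s_ij) = 1 for lambda > 0.

    Background frequencies are uniform over the standard alphabet (4 bases or
    20 residues).
    """
    if scheme.alphabet == "protein":
        letters = "ARNDCQEGHILKMFPSTWYV"
    else:
        letters = "ACGT"
    mat = _matrix_for(scheme)
    scores = np.array([[mat[a, b] for b in letters] for a in letters])
    p = 1.0 / len(letters)

    def f(lam: float) -> float:
        return float(np.sum(p * p * np.exp(lam * scores)) - 1.0)

    if np.mean(scores) >= 0:
        raise AlignmentError("scoring scheme has non-negative expected score")
    hi = 1e-4
    while f(hi) < 0:
        hi *= 2
        if hi > 100:
            raise AlignmentError("failed to bracket lambda")
    return float(brentq(f, 1e-9, hi))


def e_value(score: float, m: int, n: int, scheme: ScoringScheme) -> float:
    """Ungapped Karlin–Altschul E-value for a score against an m x n search."""
    lam = karlin_lambda(scheme)
    return KA_K * m * n * math.exp(-lam * score)


# ---------------------------------------------------------------------------
# Global alignment

def global_align(a: str, b: str, scoring: ScoringScheme | None = None
                 ) -> tuple[float, float, tuple[str, str]]:
    """Optimal global (Needleman–Wunsch/Gotoh) alignment.

    Returns (score, identity fraction over alignment columns, aligned pair).
    """
    if not a or not b:
        raise AlignmentError("global_align requires two non-empty sequences")
    scoring = scoring or ScoringScheme.dna()
    aln = _aligner(scoring, "global").align(a, b)[0]
    ident, cols = _column_stats(aln)
    return float(aln.score), ident / cols, (str(aln[0]), str(aln[1]))


# ---------------------------------------------------------------------------
# Local search with HSPs

def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _extract_hsps(query: str, subject: str, scoring: ScoringScheme,
                  min_score: float, max_hsps: int = 4) -> list[Hsp]:
    """Iterative Smith–Waterman: report best local alignment, mask its query
    interval, repeat.  HSPs overlapping a kept one by >50% on either axis are
    discarded (greedy by score)."""
    al = _aligner(scoring, "local")
    hsps: list[Hsp] = []
    work = query
    for _ in range(max_hsps):
        try:
            best = al.align(work, subject)[0]
        except (IndexError, OverflowError):
            break
        if best.score < min_score or best.score <= 0:
            break
        q0, q1 = int(best.aligned[0][0][0]), int(best.aligned[0][-1][1])
        s0, s1 = int(best.aligned[1][0][0]), int(best.aligned[1][-1][1])
        ident, cols = _column_stats(best)
        cand = Hsp(q0, q1, s0, s1, float(best.score), ident, cols,
                   str(best[0]), str(best[1]))
        overlap = False
        for kept in hsps:
            qo = min(cand.q_end, kept.q_end) - max(cand.q_start, kept.q_start)
            so = min(cand.s_end, kept.s_end) - max(cand.s_start, kept.s_start)
            if qo > 0.5 * (cand.q_end - cand.q_start) or so > 0.5 * (cand.s_end - cand.s_start):
                overlap = True
                break
        if not overlap:
            hsps.append(cand)
        work = work[:q0] + "#" * (q1 - q0) + work[q1:]
    hsps.sort(key=lambda h: -h.score)
    return hsps


def _coverage(intervals: list[tuple[int, int]], length: int) -> float:
    if not intervals or length == 0:
        return 0.0
    intervals = sorted(intervals)
    total, cur_a, cur_b = 0, *intervals[0]
    for a, b in intervals[1:]:
        if a > cur_b:
            total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    total += cur_b - cur_a
    return total / length


def local_search(queries: dict[str, str], subjects: dict[str, str],
                 scoring: ScoringScheme | None = None, e_max: float = 1e-3,
                 prefilter_k: int | None = None, max_hsps: int = 4,
                 ) -> list[AlignmentHit]:
    """All-vs-all local (Smith–Waterman) search with E-value cutoff.

    A shared-k-mer prefilter (k defaults to 4 for protein, 11 for DNA) skips
    pairs that cannot plausibly align; pairs sharing no k-mer are never
    scored.  Hits are ordered per query by descending score, ties broken by
    subject id.
    """
    if e_max <= 0:
        raise AlignmentError("e_max must be positive")
    if not queries or not subjects:
        raise AlignmentError("local_search requires non-empty sequence sets")
    scoring = scoring or ScoringScheme.dna()
    if prefilter_k is None:
        prefilter_k = 4 if scoring.alphabet == "protein" else 11
    lam = karlin_lambda(scheme=scoring)

    # invert the subject k-mer space once
    kmer_index: dict[str, set[str]] = {}
    for sid, sseq in subjects.items():
        for km in _kmer_set(sseq, prefilter_k):
            kmer_index.setdefault(km, set()).add(sid)

    hits: list[AlignmentHit] = []
    for qid, qseq in queries.items():
        cand_ids: set[str] = set()
        for km in _kmer_set(qseq, prefilter_k):
            cand_ids |= kmer_index.get(km, set())
        q_hits = []
        for sid in cand_ids:
            sseq = subjects[sid]
            # minimum score that could pass the E-value threshold
            min_s = math.log(KA_K * len(qseq) * len(sseq) / e_max) / lam
            hsps = _extract_hsps(qseq, sseq, scoring, min_score=max(min_s, 1e-9),
                                 max_hsps=max_hsps)
            if not hsps:
                continue
            best = hsps[0]
            ev = e_value(best.score, len(qseq), len(sseq), scoring)
            if ev > e_max:
                continue
            q_hits.append(AlignmentHit(
                query_id=qid, subject_id=sid, hsps=hsps, best_score=best.score,
                identity_pct=100.0 * best.identities / best.aligned_len,
                q_coverage=_coverage([(h.q_start, h.q_end) for h in hsps], len(qseq)),
                s_coverage=_coverage([(h.s_start, h.s_end) for h in hsps], len(sseq)),
                e_value=ev))
        q_hits.sort(key=lambda h: (-h.best_score, h.subject_id))
        hits.extend(q_hits)
    return hits


# ---------------------------------------------------------------------------
# Seed-and-extend mapping of short queries against long references

def map_to_reference(query: str, refs: dict[str, str],
                     scoring: ScoringScheme | None = None, k: int = 13,
                     pad: int = 50, max_loci: int = 4) -> list[AlignmentHit]:
    """Map one query against long reference sequences.

    Exact k-mer seeds locate candidate windows; each window (padded) is then
    aligned locally with the full DP.  Returns hits sorted by descending
    score with reference coordinates.
    """
    scoring = scoring or ScoringScheme.dna()
    q_kmers: dict[str, list[int]] = {}
    for i in range(len(query) - k + 1):
        q_kmers.setdefault(query[i : i + k], []).append(i)
    out: list[AlignmentHit] = []
    for rid, rseq in refs.items():
        # diagonal clustering of seeds
        diags: dict[int, list[tuple[int, int]]] = {}
        for j in range(len(rseq) - k + 1):
            km = rseq[j : j + k]
            if km in q_kmers:
                for qi in q_kmers[km]:
                    diags.setdefault((j - qi) // 32, []).append((qi, j))
        windows: list[tuple[int, int]] = []
        for seeds in diags.values():
            rs = [j for _, j in seeds]
            qs = [qi for qi, _ in seeds]
            w0 = max(0, min(rs) - min(qs) - pad)
            w1 = min(len(rseq), max(rs) + (len(query) - max(qs)) + pad)
            windows.append((w0, w1))
        windows = _merge_windows(windows)
        windows = windows[:max_loci]
        for w0, w1 in windows:
            hsps = _extract_hsps(query, rseq[w0:w1], scoring, min_score=1.0, max_hsps=2)
            if not hsps:
                continue
            best = hsps[0]
            for h in hsps:
                h.s_start += w0
                h.s_end += w0
            out.append(AlignmentHit(
                query_id="query", subject_id=rid, hsps=hsps, best_score=best.score,
                identity_pct=100.0 * best.identities / best.aligned_len,
                q_coverage=_coverage([(h.q_start, h.q_end) for h in hsps], len(query)),
                s_coverage=_coverage([(h.s_start, h.s_end) for h in hsps], len(rseq)),
                e_value=e_value(best.score, len(query), len(rseq), scoring)))
    out.sort(key=lambda h: (-h.best_score, h.subject_id))
    return out


def _merge_windows(windows: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not windows:
        return []
    windows = sorted(windows)
    merged = [list(windows[0])]
    for a, b in windows[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [tuple(w) for w in merged]


def hits_to_tsv(hits: list[AlignmentHit]) -> str:
    """12-column BLAST outfmt-6 style table."""
    lines = []
    for h in hits:
        best = h.hsps[0]
        mismatches = best.aligned_len - best.identities
        lines.append("\t".join(str(x) for x in (
            h.query_id, h.subject_id, f"{h.identity_pct:.2f}", best.aligned_len,
            mismatches, len(h.hsps) - 1, best.q_start + 1, best.q_end,
            best.s_start + 1, best.s_end, f"{h.e_value:.2g}", f"{h.best_score:.1f}")))
    return "\n".join(lines) + ("\n" if lines else "")
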