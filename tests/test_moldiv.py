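"""Ka/Ks, K2P and dating tests with an independent pathway-enumeration oracle."""

import itertools
import math

import numpy as np
import pytest
from Bio.Seq import Seq

from polyevol import moldiv
from polyevol.moldiv import (ClockParams, CodonAlignment, InvalidCDS,
                             SaturatedDistance)

# ---------------------------------------------------------------------------
# Independent NG86 oracle (built on Biopython's translation, not the module's
# own code table plumbing)

_BASES = "ACGT"


def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_syn_sites(codon: str) -> float:
    s = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1:]
            if _aa(mut) == _aa(codon) and _aa(mut) != "*":
                s += 1 / 3
    return s


def oracle_diff_counts(c1: str, c2: str) -> tuple[float, float]:
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    usable, blocked = [], []
    for order in itertools.permutations(diff):
        cur, steps, hit_stop = c1, [], False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(nxt) == "*" and nxt != c2:
                hit_stop = True
            steps.append((cur, nxt))
            cur = nxt
        (blocked if hit_stop else usable).append(steps)
    paths = usable or blocked
    sd = nd = 0.0
    for steps in paths:
        for a, b in steps:
            if _aa(a) == _aa(b) and _aa(a) != "*":
                sd += 1
            else:
                nd += 1
    return sd / len(paths), nd / len(paths)


def oracle_ng86(codons1, codons2):
    S = 0.5 * (sum(map(oracle_syn_sites, codons1)) + sum(map(oracle_syn_sites, codons2)))
    N = 3 * len(codons1) - S
    Sd = Nd = 0.0
    for c1, c2 in zip(codons1, codons2):
        sd, nd = oracle_diff_counts(c1, c2)
        Sd += sd
        Nd += nd
    return N, S, Nd, Sd


_SENSE = [a + b + c for a in _BASES for b in _BASES for c in _BASES
          if _aa(a + b + c) != "*"]


def test_ng86_matches_oracle_on_random_codon_pairs():
    rng = np.random.default_rng(2024)
    for _ in range(150):
        k = int(rng.integers(1, 5))
        c1 = [_SENSE[i] for i in rng.integers(0, len(_SENSE), k)]
        c2 = [_SENSE[i] for i in rng.integers(0, len(_SENSE), k)]
        est = moldiv.ng86(CodonAlignment("".join(c1), "".join(c2)))
        N, S, Nd, Sd = oracle_ng86(c1, c2)
        assert est.N == pytest.approx(N)
        assert est.S == pytest.approx(S)
        assert est.Nd == pytest.approx(Nd)
        assert est.Sd == pytest.approx(Sd)


def test_ng86_worked_example():
    est = moldiv.ng86(CodonAlignment("GTTGCT", "GTCGCT"))
    assert (est.N, est.S, est.Nd, est.Sd) == (4.0, 2.0, 0.0, 1.0)
    assert est.pS == pytest.approx(0.5)
    assert est.Ka == 0.0
    assert round(est.Ks, 4) == 0.8240


def test_ng86_identical_and_symmetry():
    est = moldiv.ng86(CodonAlignment("ATGGTT", "ATGGTT"))
    assert est.Ka == est.Ks == 0.0 and est.Nd == est.Sd == 0.0
    a, b = "ATGGTTGCA", "ATGGCTGGA"
    e1 = moldiv.ng86(CodonAlignment(a, b))
    e2 = moldiv.ng86(CodonAlignment(b, a))
    for f in ("N", "S", "Nd", "Sd", "Ka", "Ks"):
        assert getattr(e1, f) == pytest.approx(getattr(e2, f))


def test_ng86_saturation_on_degenerate_input():
    est = moldiv.ng86(CodonAlignment("TTT", "TTC"))
    assert est.pS == pytest.approx(3.0)
    assert est.saturated and math.isnan(est.Ks)


def test_codon_align_gap_in_whole_codons():
    aln = moldiv.codon_align("ATGGTTGCTGCA", "ATGGCTGCA")
    assert len(aln.seq1) == len(aln.seq2)
    n_gap = aln.seq1.count("-") + aln.seq2.count("-")
    assert n_gap == 3
    with pytest.raises(InvalidCDS):
        moldiv.codon_align("ACGTA", "ACGTT")
    with pytest.raises(InvalidCDS):
        moldiv.translate("ATGTAAGTT")  # internal stop


def test_k2p_closed_form_and_saturation():
    assert moldiv.k2p_distance("ACGT", "ACGT") == 0.0
    # 20 sites, 2 transitions (A->G), 1 transversion (T->A): P=0.1, Q=0.05
    a = "A" * 17 + "GGT"
    b = "A" * 17 + "AAA"
    assert round(moldiv.k2p_distance(a, b), 5) == 0.17018
    with pytest.raises(SaturatedDistance):
        moldiv.k2p_distance("AG", "GA")  # P=1 -> 1-2P-Q < 0
    # gap columns excluded from denominators
    assert moldiv.k2p_distance("AC-T", "AC-T") == 0.0


def test_k2p_dominates_p_distance():
    rng = np.random.default_rng(5)
    for _ in range(20):
        n = 200
        a = "".join(rng.choice(list(_BASES), n))
        b = "".join(rng.choice(list(_BASES), n))
        try:
            k = moldiv.k2p_distance(a, b)
        except SaturatedDistance:
            continue
        p = sum(x != y for x, y in zip(a, b)) / n
        assert k >= p - 1e-12


def test_ks_histogram_binning_contract():
    h = moldiv.ks_histogram([0.0104, 0.0106], 0.001)
    assert h.counts[10] == 2
    h2 = moldiv.ks_histogram([0.011], 0.001)
    assert h2.counts[11] == 1  # left-closed: 0.011 belongs to [0.011, 0.012)
    h3 = moldiv.ks_histogram([0.01, float("nan"), float("inf")], 0.001)
    assert h3.n == 1 and h3.n_excluded == 2


def test_find_peak_and_tie_break():
    h = moldiv.ks_histogram([0.0005] * 5 + [0.0015] * 9, 0.001)
    assert moldiv.find_peak(h) == pytest.approx(0.0015)
    tie = moldiv.ks_histogram([0.0005] * 5 + [0.0025] * 5, 0.001)
    assert moldiv.find_peak(tie) == pytest.approx(0.0005)  # smaller Ks wins
    with pytest.raises(ValueError):
        moldiv.find_peak(moldiv.ks_histogram([], 0.001))


def test_clock_convert_dates_and_linearity():
    assert moldiv.clock_convert(0.0) == 0.0
    assert moldiv.clock_convert(0.005) == pytest.approx(961_538.46, rel=1e-4)
    assert moldiv.clock_convert(0.04) == pytest.approx(7.692e6, rel=1e-3)
    r = ClockParams()
    for a in (0.5, 2.0, 10.0):
        assert moldiv.clock_convert(a * 0.01, r) == pytest.approx(
            a * moldiv.clock_convert(0.01, r))
    with pytest.raises(ValueError):
        moldiv.clock_convert(-0.1)
    with pytest.raises(ValueError):
        ClockParams(r=0)
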