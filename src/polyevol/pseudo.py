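"""Pseudogene detection, three-way classification, exclusion filtering, and
divergence-to-parent estimation.

Pseudogenes are disabled gene copies lying in intergenic space.  Detection
searches parent proteins against all six reading frames of repeat-masked
intergenic regions; co-linear high-scoring segment pairs (HSPs) are chained
per parent and strand into candidate loci, reading disablements from the
chain (an in-frame stop inside an HSP, a reading-frame change between
chained HSPs).  Candidates are classified as

* processed  — intron-less copy of a spliced mRNA: aligns the parent CDS
  contiguously across at least one exon-exon junction (junction gap <= 30
  bp) with parent coverage >= 70%;
* duplicated — genomic copy retaining gene structure: intron-scale gaps
  (> 30 bp) at parent exon boundaries, or a single-exon parent covered
  >= 70%;
* fragmented — anything else (truncated remnants).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from polyevol import align, moldiv
from polyevol.align import ScoringScheme
from polyevol.moldiv import CodonAlignment, DivergenceEstimate
from polyevol.syndata import Genome
from polyevol._util import GeneModel, revcomp

_STOPS = {"TAA", "TAG", "TGA"}


class DataInconsistency(ValueError):
    pass


class UnalignableCandidate(ValueError):
    """No reading frame of the candidate aligns to the parent CDS."""


@dataclass
class IntergenicRegion:
    chrom: str
    start: int
    end: int
    seq: str


@dataclass
class PseudogeneCandidate:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    parent_gene_id: str
    seq: str  # locus sequence in coding orientation
    best_score: float = 0.0
    identity_pct: float = 0.0
    parent_coverage: float = 0.0
    disablements: list[tuple[str, int]] = field(default_factory=list)
    category: str | None = None
    ks_to_parent: float | None = None
    # chained alignment blocks: (q_start_aa, q_end_aa, nt_start, nt_end, frame)
    # with nt coordinates locus-relative in coding orientation
    chain: list[tuple[int, int, int, int, int]] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def intergenic_regions(genome: Genome, margin: int = 0) -> list[IntergenicRegion]:
    """Gene-masked intergenic space of a genome."""
    out = []
    for chrom, seq in genome.chroms.items():
        spans = sorted((g.start, g.end) for g in genome.genes if g.chrom == chrom)
        prev = 0
        for a, b in spans:
            if a - margin > prev:
                out.append(IntergenicRegion(chrom, prev, a - margin,
                                            seq[prev : a - margin]))
            prev = max(prev, b + margin)
        if len(seq) > prev:
            out.append(IntergenicRegion(chrom, prev, len(seq), seq[prev:]))
    return out


def _six_frames(region: IntergenicRegion) -> dict[str, str]:
    """Translations of all six frames; key encodes (strand, frame)."""
    tr = moldiv._translator(1)
    frames = {}
    for strand in "+-":
        s = region.seq if strand == "+" else revcomp(region.seq)
        for f in range(3):
            aas = []
            for i in range(f, len(s) - 2, 3):
                aas.append(tr.get(s[i : i + 3].upper(), "X"))
            if aas:
                frames[f"{strand}{f}"] = "".join(aas)
    return frames


def _aa_to_nt(region_len: int, strand: str, frame: int, aa_start: int,
              aa_end: int) -> tuple[int, int]:
    """Region-relative nt interval of an aa interval in a given frame."""
    nt0, nt1 = frame + 3 * aa_start, frame + 3 * aa_end
    if strand == "+":
        return nt0, nt1
    return region_len - nt1, region_len - nt0


def _col_scores(hsp, scoring: ScoringScheme) -> list[float]:
    mat = align._matrix_for(scoring)
    out, in_gap = [], False
    for a, b in zip(hsp.q_aln, hsp.s_aln):
        if a == "-" or b == "-":
            out.append(-(scoring.gap_extend + (scoring.gap_open if not in_gap else 0)))
            in_gap = True
        else:
            out.append(float(mat[a, b]))
            in_gap = False
    return out


def _xdrop_split(hsp, scoring: ScoringScheme, x: float = 22.0,
                 min_score: float = 25.0) -> list:
    """Split an HSP into maximal clean segments, BLAST X-drop style.

    Smith–Waterman happily bridges across introns or unrelated sequence when
    the flanking homology pays for the dip; cutting wherever the running
    score falls ``x`` below its maximum recovers the clean exon-level
    segments the chaining stage needs.
    """
    cols = list(zip(hsp.q_aln, hsp.s_aln))
    scores = _col_scores(hsp, scoring)
    segs: list[tuple[int, int]] = []
    i, n = 0, len(cols)
    while i < n:
        if scores[i] <= 0:
            i += 1
            continue
        running, best, best_j = 0.0, 0.0, i - 1
        start = i
        j = i
        while j < n:
            running += scores[j]
            if running > best:
                best, best_j = running, j
            if best - running > x:
                break
            j += 1
        if best >= min_score:
            segs.append((start, best_j + 1))
        i = best_j + 1 if best_j >= start else j + 1
    out = []
    for a, b in segs:
        q_off = sum(1 for qc, _ in cols[:a] if qc != "-")
        s_off = sum(1 for _, sc in cols[:a] if sc != "-")
        q_len = sum(1 for qc, _ in cols[a:b] if qc != "-")
        s_len = sum(1 for _, sc in cols[a:b] if sc != "-")
        ident = sum(1 for qc, sc in cols[a:b] if qc == sc and qc != "-")
        out.append(align.Hsp(
            hsp.q_start + q_off, hsp.q_start + q_off + q_len,
            hsp.s_start + s_off, hsp.s_start + s_off + s_len,
            sum(scores[a:b]), ident, b - a,
            "".join(qc for qc, _ in cols[a:b]),
            "".join(sc for _, sc in cols[a:b])))
    return out


def detect_pseudogenes(regions: list[IntergenicRegion],
                       parent_prots: dict[str, str],
                       scoring: ScoringScheme | None = None,
                       e_max: float = 1e-3, prefilter_k: int = 8,
                       chain_gap_aa: int = 400,
                       min_hsp_identity: float = 0.65) -> list[PseudogeneCandidate]:
    """Search parent proteins against six-frame translations of intergenic
    regions and chain co-linear HSPs into pseudogene candidates.

    Raw Smith–Waterman HSPs are X-drop-split into clean segments; segments
    below ``min_hsp_identity`` are discarded before chaining — genuine
    pseudogene copies sit far above that identity, chance similarity between
    unrelated proteins far below.  The default scoring applies a -1
    composition shift to BLOSUM62 so that chance similarity between
    composition-biased sequences scores negative on average and extensions
    across unrelated sequence terminate.
    """
    scoring = scoring or ScoringScheme.protein(matrix_shift=-1.0)
    cands: list[PseudogeneCandidate] = []
    n = 0
    for region in regions:
        frames = _six_frames(region)
        if not frames:
            continue
        hits = align.local_search(parent_prots, frames, scoring, e_max,
                                  prefilter_k=prefilter_k)
        # group clean HSP segments by (parent, strand), tagged with frame
        groups: dict[tuple[str, str], list] = {}
        for h in hits:
            strand, frame = h.subject_id[0], int(h.subject_id[1])
            for raw in h.hsps:
                for hsp in _xdrop_split(raw, scoring):
                    if hsp.identities < min_hsp_identity * hsp.aligned_len:
                        continue
                    groups.setdefault((h.query_id, strand), []).append((hsp, frame))
        for (parent, strand), tagged in groups.items():
            tagged.sort(key=lambda t: (t[0].q_start, t[0].q_end))
            chain, last_q = [], -1
            for hsp, frame in tagged:  # allow modest parent-side HSP overlap
                if hsp.q_start >= last_q - 40 and (not chain or
                        hsp.q_start - chain[-1][0].q_end < chain_gap_aa):
                    chain.append((hsp, frame))
                    last_q = max(last_q, hsp.q_end)
            if not chain:
                continue
            nt_spans = [_aa_to_nt(len(region.seq), strand, f, h.s_start, h.s_end)
                        for h, f in chain]
            nt0 = min(a for a, _ in nt_spans)
            nt1 = max(b for _, b in nt_spans)
            locus_seq = region.seq[nt0:nt1]
            if strand == "-":
                locus_seq = revcomp(locus_seq)

            def oriented(span: tuple[int, int]) -> tuple[int, int]:
                a, b = span
                if strand == "+":
                    return a - nt0, b - nt0
                return nt1 - b, nt1 - a

            chain_blocks = []
            for (hsp, frame), span in zip(chain, nt_spans):
                oa, ob = oriented(span)
                chain_blocks.append((hsp.q_start, hsp.q_end, oa, ob, frame))
            chain_blocks.sort(key=lambda t: t[0])

            dis: list[tuple[str, int]] = []
            for (hsp, frame), span in zip(chain, nt_spans):
                aa = frames[f"{strand}{frame}"][hsp.s_start : hsp.s_end]
                for k, ch in enumerate(aa):
                    if ch == "*":
                        a0, _ = _aa_to_nt(len(region.seq), strand, frame,
                                          hsp.s_start + k, hsp.s_start + k + 1)
                        pos = (a0 - nt0) if strand == "+" else (nt1 - a0 - 3)
                        dis.append(("premature_stop", pos))
            for (q0, q1, a0, a1, f1), (q2, q3, b0, b1, f2) in zip(
                    chain_blocks, chain_blocks[1:]):
                # a frame change without an intron-scale nt excess is a
                # frameshift; with one it is an intron boundary
                excess = (b0 - a1) - 3 * (q2 - q1)
                if f1 != f2 and excess <= 30:
                    dis.append(("frameshift", max(b0, 0)))
            best = max((h for h, _ in chain), key=lambda h: h.score)
            plen = len(parent_prots[parent])
            cov = align._coverage([(h.q_start, h.q_end) for h, _ in chain], plen)
            cands.append(PseudogeneCandidate(
                locus_id=f"cand{n:04d}", chrom=region.chrom,
                start=region.start + nt0, end=region.start + nt1, strand=strand,
                parent_gene_id=parent, seq=locus_seq,
                best_score=sum(h.score for h, _ in chain),
                identity_pct=100.0 * best.identities / best.aligned_len,
                parent_coverage=cov, disablements=sorted(set(dis), key=lambda d: d[1]),
                chain=chain_blocks))
            n += 1
    # one call per locus: keep the best-scoring parent among overlapping calls
    cands.sort(key=lambda c: -c.best_score)
    kept: list[PseudogeneCandidate] = []
    for c in cands:
        clash = False
        for k in kept:
            if k.chrom == c.chrom:
                ov = min(c.end, k.end) - max(c.start, k.start)
                if ov > 0.5 * min(c.length, k.length):
                    clash = True
                    break
        if not clash:
            kept.append(c)
    kept.sort(key=lambda c: (c.chrom, c.start))
    return kept


def _junctions(parent: GeneModel) -> list[int]:
    """Exon-exon junction positions in spliced-CDS coordinates."""
    lengths = [b - a for a, b in parent.exons]
    if parent.strand == "-":
        lengths = lengths[::-1]
    out, cum = [], 0
    for l in lengths[:-1]:
        cum += l
        out.append(cum)
    return out


# classification alignments must gap intron-scale insertions rather than
# absorb them as mismatch runs, so gaps extend cheaply and mismatches are harsh
_CLASSIFY_SCORING = ScoringScheme.dna(match=1.0, mismatch=-4.0,
                                      gap_open=6.0, gap_extend=0.5)


def _alignment_profile(cand_seq: str, parent_cds: str,
                       scoring: ScoringScheme | None = None):
    """Column walk of the candidate-vs-CDS global alignment.

    Returns (parent coverage, insertion list [(cds_pos, length)], aligned
    candidate string in the parent frame).
    """
    scoring = scoring or _CLASSIFY_SCORING
    _, _, (a_cand, a_par) = align.global_align(cand_seq, parent_cds, scoring)
    cds_pos = 0
    aligned = 0
    cand_in_frame: list[str] = []
    insertions: list[tuple[int, int]] = []  # (cds_pos, length)
    run = 0
    for x, y in zip(a_cand, a_par):
        if y == "-":
            run += 1
            continue
        if run:
            insertions.append((cds_pos, run))
            run = 0
        cand_in_frame.append(x)
        if x != "-":
            aligned += 1
        cds_pos += 1
    coverage = aligned / len(parent_cds)
    return coverage, insertions, "".join(cand_in_frame)


def classify_pseudogene(cand: PseudogeneCandidate, parent: GeneModel,
                        parent_cds: str | None = None, intron_gap: int = 30,
                        min_cov: float = 0.70,
                        junction_window_aa: int = 12) -> str:
    """Assign duplicated / processed / fragmented (exhaustive, exclusive).

    Works on the detection chain: a parent exon-exon junction crossed inside
    one clean alignment block (or between blocks with nt excess <=
    ``intron_gap``) is evidence of a spliced, processed copy; an
    intron-scale nt excess (> ``intron_gap``) at a junction is evidence of a
    duplicated genomic copy; single-exon parents covered >= ``min_cov``
    count as duplicated; everything else is fragmented.
    """
    if not parent.exons:
        raise DataInconsistency(f"parent {parent.gene_id} lacks exon structure")
    if not cand.chain:
        raise DataInconsistency(f"{cand.locus_id}: no alignment chain")
    chain = sorted(cand.chain, key=lambda t: t[0])
    if parent_cds is not None:
        plen_aa = len(parent_cds) // 3
    else:
        plen_aa = sum(b - a for a, b in parent.exons) // 3
    coverage = align._coverage([(q0, q1) for q0, q1, *_ in chain], plen_aa)
    junctions_aa = [j // 3 for j in _junctions(parent)]
    intron_at = clean_at = False
    for j in junctions_aa:
        within = any(q0 + 2 <= j <= q1 - 2 for q0, q1, *_ in chain)
        broken = False
        for (q0, q1, a0, a1, f1), (q2, q3, b0, b1, f2) in zip(chain, chain[1:]):
            if q1 - junction_window_aa <= j <= q2 + junction_window_aa:
                excess = (b0 - a1) - 3 * (q2 - q1)
                if excess > intron_gap:
                    broken = True
        if broken:
            intron_at = True
        elif within:
            clean_at = True
    if len(parent.exons) >= 2 and coverage >= min_cov and clean_at and not intron_at:
        cat = "processed"
    elif intron_at or (len(parent.exons) == 1 and coverage >= min_cov):
        cat = "duplicated"
    else:
        cat = "fragmented"
    cand.category = cat
    cand.parent_coverage = coverage
    return cat


def filter_pseudogenes(cands: list[PseudogeneCandidate],
                       gene_models: list[GeneModel],
                       parent_labels: dict[str, str] | None = None,
                       min_len: int = 150, max_gene_overlap: int = 30,
                       ) -> list[PseudogeneCandidate]:
    """Apply the exclusion filters; the three rules commute.

    Drops candidates shorter than ``min_len`` bp (strict), candidates whose
    parent is labelled a transposon or plastid gene, and candidates
    overlapping a functional gene annotation by more than
    ``max_gene_overlap`` bp.
    """
    parent_labels = parent_labels or {}
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in gene_models:
        by_chrom.setdefault(g.chrom, []).append(g)
    out = []
    for c in cands:
        if c.length < min_len:
            continue
        if parent_labels.get(c.parent_gene_id) in {"TE", "plastid"}:
            continue
        overlap = 0
        for g in by_chrom.get(c.chrom, []):
            overlap = max(overlap, min(c.end, g.end) - max(c.start, g.start))
        if overlap > max_gene_overlap:
            continue
        out.append(c)
    return out


def ks_to_parent(cand: PseudogeneCandidate, parent_cds: str,
                 scoring: ScoringScheme | None = None) -> DivergenceEstimate:
    """Ks between a pseudogene and its parent CDS.

    The candidate is globally aligned to the parent; candidate insertions
    (including frameshift remainders) are treated as alignment gaps so the
    parent reading frame is preserved, and codons where the candidate
    carries an in-frame stop are masked out.  The repaired pair then goes
    through the standard NG86 estimator.
    """
    _cov, _ins, cand_in_frame = _alignment_profile(cand.seq, parent_cds, scoring)
    if sum(1 for ch in cand_in_frame if ch != "-") < 30:
        raise UnalignableCandidate(cand.locus_id)
    par_codons, cand_codons = [], []
    for i in range(0, len(parent_cds) - 2, 3):
        pc = parent_cds[i : i + 3]
        cc = cand_in_frame[i : i + 3]
        if len(cc) < 3:
            break
        if "-" in cc or cc.upper() in _STOPS:
            cc = "---"
        par_codons.append(pc)
        cand_codons.append(cc)
    aln = CodonAlignment("".join(par_codons), "".join(cand_codons))
    est = moldiv.ng86(aln)
    cand.ks_to_parent = est.Ks
    return est
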