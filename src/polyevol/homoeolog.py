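"""Homoeolog identification and subgenome assignment.

Homoeologs — the corresponding gene copies on the two subgenomes of an
allopolyploid — are found by the bidirectional best hit (BBH) rule on
protein sets, with qualifying hits required to exceed 30% identity and 30%
query coverage.  The module also detects subgenome-unique genes (no protein
hit in the other subgenome and CDS-vs-genome HSP coverage under one third of
the CDS length) and partitions arbitrary sequences (e.g. sequencing reads)
between two diploid reference sets.
"""

from __future__ import annotations

from dataclasses import dataclass

from polyevol import align
from polyevol.align import AlignmentHit, ScoringScheme
from polyevol._util import revcomp


class DataInconsistency(ValueError):
    pass


@dataclass
class HomoeologPair:
    gene_a_id: str
    gene_d_id: str
    identity_pct: float
    q_coverage: float
    best_score: float


@dataclass
class PartitionLabel:
    sequence_id: str
    label: str  # A_unique | D_unique | shared | none
    score_a: float
    score_d: float


def _best_qualifying(hits: list[AlignmentHit], min_identity: float,
                     min_cov: float) -> dict[str, AlignmentHit]:
    """Best qualifying hit per query: highest score, then highest identity,
    then lexicographic subject id."""
    per_query: dict[str, list[AlignmentHit]] = {}
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.identity_pct > min_identity and h.q_coverage > min_cov:
            per_query.setdefault(h.query_id, []).append(h)
    return {q: min(hs, key=lambda h: (-h.best_score, -h.identity_pct, h.subject_id))
            for q, hs in per_query.items()}


def bbh_pairs(prots_a: dict[str, str], prots_d: dict[str, str],
              scoring: ScoringScheme | None = None, e_max: float = 1e-3,
              min_identity: float = 30.0, min_cov: float = 0.30,
              prefilter_k: int | None = None) -> list[HomoeologPair]:
    """Bidirectional best hits between two protein sets.

    A pair (a, d) is reported iff d is a's best qualifying hit and a is d's
    best qualifying hit, where qualifying means identity > ``min_identity``
    percent and query coverage > ``min_cov``.  Ties on score break by
    identity, then lexicographic subject id, so each gene joins at most one
    pair and the output is symmetric under swapping the inputs.
    """
    if not prots_a or not prots_d:
        raise DataInconsistency("both protein sets must be non-empty")
    scoring = scoring or ScoringScheme.protein()
    fwd = _best_qualifying(
        align.local_search(prots_a, prots_d, scoring, e_max,
                           prefilter_k=prefilter_k), min_identity, min_cov)
    rev = _best_qualifying(
        align.local_search(prots_d, prots_a, scoring, e_max,
                           prefilter_k=prefilter_k), min_identity, min_cov)
    pairs = []
    for a, hit in sorted(fwd.items()):
        d = hit.subject_id
        back = rev.get(d)
        if back is not None and back.subject_id == a:
            pairs.append(HomoeologPair(a, d, hit.identity_pct, hit.q_coverage,
                                       hit.best_score))
    return pairs


def unique_genes(prots_x: dict[str, str], prots_y: dict[str, str],
                 genome_y: dict[str, str], cds_x: dict[str, str],
                 scoring_prot: ScoringScheme | None = None,
                 scoring_dna: ScoringScheme | None = None,
                 e_max: float = 1e-3) -> set[str]:
    """Genes of set x with no counterpart in set y.

    A gene is unique iff (1) its protein has no hit in ``prots_y`` at
    E <= ``e_max`` and (2) the total non-overlapping HSP length of its CDS
    against ``genome_y`` is strictly less than one third of the CDS length.
    """
    missing = set(prots_x) - set(cds_x)
    if missing:
        raise DataInconsistency(f"proteins without CDS: {sorted(missing)[:3]}...")
    scoring_prot = scoring_prot or ScoringScheme.protein()
    scoring_dna = scoring_dna or ScoringScheme.dna()
    hits = align.local_search(prots_x, prots_y, scoring_prot, e_max)
    with_hit = {h.query_id for h in hits}
    out = set()
    for gid in prots_x:
        if gid in with_hit:
            continue
        cds = cds_x[gid]
        intervals = []
        for orient_seq in (cds, revcomp(cds)):
            for h in align.map_to_reference(orient_seq, genome_y, scoring_dna):
                intervals.extend((hsp.q_start, hsp.q_end) for hsp in h.hsps)
        covered = align._coverage(intervals, len(cds)) * len(cds)
        if covered < len(cds) / 3.0:
            out.add(gid)
    return out


def _best_ref_score(seq: str, refs: dict[str, str], scoring: ScoringScheme,
                    min_identity: float, min_cov: float) -> tuple[float, bool]:
    """(best score, qualifies) of a sequence against a reference set,
    checking both orientations."""
    best_score, qualifies = 0.0, False
    for orient in (seq, revcomp(seq)):
        for h in align.map_to_reference(orient, refs, scoring):
            if h.best_score > best_score:
                best_score = h.best_score
            if h.identity_pct / 100.0 >= min_identity and h.q_coverage >= min_cov:
                qualifies = True
    return best_score, qualifies


def partition_sequences(seqs: dict[str, str], ref_a: dict[str, str],
                        ref_d: dict[str, str], min_identity: float = 0.95,
                        min_cov: float = 0.9, delta: float = 0.02,
                        scoring: ScoringScheme | None = None,
                        ) -> list[PartitionLabel]:
    """Assign sequences to subgenome A, subgenome D, shared, or none.

    A reference qualifies when the best hit reaches ``min_identity`` over
    coverage ``min_cov``.  A_unique: only A qualifies, or both qualify with
    score_a/score_d > 1 + delta; D symmetric; shared: both qualify within
    delta; none otherwise.  Every sequence receives exactly one label.
    """
    if not (0 < min_identity <= 1 and 0 < min_cov <= 1):
        raise ValueError("min_identity and min_cov must lie in (0, 1]")
    if delta < 0:
        raise ValueError("delta must be non-negative")
    scoring = scoring or ScoringScheme.dna()
    labels = []
    for sid in sorted(seqs):
        seq = seqs[sid]
        score_a, qual_a = _best_ref_score(seq, ref_a, scoring, min_identity, min_cov)
        score_d, qual_d = _best_ref_score(seq, ref_d, scoring, min_identity, min_cov)
        if qual_a and not qual_d:
            label = "A_unique"
        elif qual_d and not qual_a:
            label = "D_unique"
        elif qual_a and qual_d:
            if score_d > 0 and score_a / score_d > 1 + delta:
                label = "A_unique"
            elif score_a > 0 and score_d / score_a > 1 + delta:
                label = "D_unique"
            else:
                label = "shared"
        else:
            label = "none"
        labels.append(PartitionLabel(sid, label, score_a, score_d))
    return labels


def pairs_to_tsv(pairs: list[HomoeologPair]) -> str:
    lines = ["gene_a\tgene_d\tidentity_pct\tq_coverage\tbest_score"]
    for p in pairs:
        lines.append(f"{p.gene_a_id}\t{p.gene_d_id}\t{p.identity_pct:.2f}"
                     f"\t{p.q_coverage:.3f}\t{p.best_score:.1f}")
    return "\n".join(lines) + "\n"
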