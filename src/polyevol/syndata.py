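"""Seeded generators of synthetic allopolyploid data with known ground truth.

Everything downstream of this module is validated by parameter recovery, so
the generators are built to make truth exact rather than merely plausible:

* Sequence evolution follows the Kimura (K80) two-parameter substitution
  model, sampled per site from the exact transition-probability matrix at
  the requested branch length.  The expected value of the K2P estimator
  applied to a simulated pair therefore equals the requested distance, with
  multiple hits handled implicitly by the matrix exponential.
* Coding sequences are built from codons whose third position is fourfold
  degenerate while positions one and two are fully nondegenerate (Val, Ala,
  Thr, Pro, Gly, Ser4 families).  Constrained ("pure Ks") evolution touches
  only those third positions, so the true synonymous divergence per
  synonymous site equals the branch length exactly and NG86 can recover it.
* Every entity draws its randomness from a hash-derived sub-stream of the
  root seed, so generation order can never change results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from polyevol._util import GeneModel, SequenceRecord, revcomp, substream
from polyevol.expr import ExpressionMatrix
from polyevol.ltrdyn import LTRElement

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
# codon stems with a fourfold-degenerate third position and fully
# nondegenerate first/second positions
_FOURFOLD_STEMS = ("GT", "GC", "AC", "CC", "GG", "TC")
_STOPS = {"TAA", "TAG", "TGA"}


class InvalidParameter(ValueError):
    pass


@dataclass
class EvolveParams:
    """K80 branch: expected substitutions per (mutable) site and ts/tv ratio.

    With ``exact_counts`` the number of transition/transversion events is
    conditioned on its expectation (stochastic rounding), so the realized
    divergence of every branch equals ``d_target`` up to one event; only the
    event positions stay random.  Used where the generator must hit a target
    divergence exactly rather than in expectation.
    """

    d_target: float
    kappa: float = 2.0
    coding_constraint: bool = False
    seed: int = 0
    exact_counts: bool = False

    def __post_init__(self):
        if self.kappa <= 0:
            raise InvalidParameter("kappa must be positive")
        if self.d_target < 0:
            raise InvalidParameter("d_target must be non-negative")


@dataclass
class DivergenceSchedule:
    """Named splits ordered oldest to youngest with target Ks per split.

    Recognized names: ``WGD`` (within-genome paralog duplication), ``AD``
    (divergence of the A and D diploid lineages), ``GbGh`` (divergence of
    the two allotetraploids).
    """

    splits: list[tuple[str, float]]

    def __post_init__(self):
        ks = [t for _, t in self.splits]
        if any(t < 0 for t in ks):
            raise InvalidParameter("target Ks must be non-negative")
        if any(a < b for a, b in zip(ks, ks[1:])):
            raise InvalidParameter("splits must be ordered oldest to youngest")
        names = [n for n, _ in self.splits]
        if len(set(names)) != len(names):
            raise InvalidParameter("duplicate split names")

    def get(self, name: str) -> float | None:
        for n, t in self.splits:
            if n == name:
                return t
        return None


@dataclass
class SimTruth:
    """Ground truth for generated entities; only relevant fields are filled."""

    homoeolog_pairs: list[tuple[str, str]] = field(default_factory=list)
    ortholog_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    paralog_pairs: dict[str, list[tuple[str, str]]] = field(default_factory=dict)
    ltr_ages: dict[str, float] = field(default_factory=dict)
    pseudogenes: list["PseudoLocusTruth"] = field(default_factory=list)
    read_origins: dict[str, str] = field(default_factory=dict)
    de: pd.DataFrame | None = None
    ts_tv: dict[str, tuple[int, int]] = field(default_factory=dict)


@dataclass
class Genome:
    """One haploid genome: chromosome sequences, gene models, spliced CDSs."""

    name: str
    chroms: dict[str, str] = field(default_factory=dict)
    genes: list[GeneModel] = field(default_factory=list)
    cds: dict[str, str] = field(default_factory=dict)

    def proteins(self) -> dict[str, str]:
        from polyevol.moldiv import translate

        return {gid: translate(c) for gid, c in self.cds.items()}


# ---------------------------------------------------------------------------
# K80 evolution

def _k80_site_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P(transition), P(any transversion)) after expected distance d."""
    bt = d / (kappa + 2.0)
    at = kappa * bt
    e1 = math.exp(-4.0 * bt)
    e2 = math.exp(-2.0 * (at + bt))
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.5 - 0.5 * e1
    return p_ts, p_tv


def _mutable_positions(seq: str, coding_constraint: bool) -> np.ndarray:
    if not coding_constraint:
        return np.arange(len(seq))
    pos = [i + 2 for i in range(0, len(seq) - 2, 3)
           if seq[i : i + 2] in _FOURFOLD_STEMS]
    return np.asarray(pos, dtype=int)


def evolve_sequence(record: SequenceRecord, params: EvolveParams,
                    rng: np.random.Generator | None = None,
                    ) -> tuple[SequenceRecord, tuple[int, int]]:
    """Evolve a copy of ``record`` one K80 branch of length ``d_target``.

    Returns (mutated copy, (realized transitions, realized transversions)).
    With ``coding_constraint`` only fourfold-degenerate third codon positions
    mutate, so d_target is the true synonymous divergence per synonymous
    site added on this branch.
    """
    if not record.seq:
        raise InvalidParameter("cannot evolve an empty sequence")
    if rng is None:
        rng = substream(params.seed, "evolve", record.id)
    seq = list(record.seq)
    p_ts, p_tv = _k80_site_probs(params.d_target, params.kappa)
    sites = _mutable_positions(record.seq, params.coding_constraint)
    n_ts = n_tv = 0
    if len(sites) and params.d_target > 0:
        if params.exact_counts:
            k_ts = _stochastic_round(len(sites) * p_ts, rng)
            k_tv = _stochastic_round(len(sites) * p_tv, rng)
            chosen = rng.choice(sites, size=min(k_ts + k_tv, len(sites)), replace=False)
            pick = rng.random(len(chosen))
            for j, i in enumerate(chosen):
                base = seq[i]
                if base not in _TRANSITION:
                    continue
                if j < k_ts:
                    seq[i] = _TRANSITION[base]
                    n_ts += 1
                else:
                    tv = _TRANSVERSIONS[base]
                    seq[i] = tv[0] if pick[j] < 0.5 else tv[1]
                    n_tv += 1
        else:
            u = rng.random(len(sites))
            pick = rng.random(len(sites))
            for j, i in enumerate(sites):
                base = seq[i]
                if base not in _TRANSITION:
                    continue
                if u[j] < p_ts:
                    seq[i] = _TRANSITION[base]
                    n_ts += 1
                elif u[j] < p_ts + p_tv:
                    tv = _TRANSVERSIONS[base]
                    seq[i] = tv[0] if pick[j] < 0.5 else tv[1]
                    n_tv += 1
    return SequenceRecord(record.id, "".join(seq), record.description), (n_ts, n_tv)


def _stochastic_round(x: float, rng: np.random.Generator) -> int:
    k = int(math.floor(x))
    return k + (1 if rng.random() < (x - k) else 0)


# ---------------------------------------------------------------------------
# Ancestral CDS

def gen_ancestral_cds(n_genes: int, n_codons: int, seed: int) -> list[SequenceRecord]:
    """Random ancestral CDSs: ATG + (n_codons - 1) fourfold-degenerate codons.

    Every sequence starts with ATG, contains no stop codon, and has length
    3 * n_codons.  Deterministic for a fixed seed.
    """
    if n_codons < 2:
        raise InvalidParameter("need at least 2 codons (ATG + 1)")
    records = []
    for i in range(n_genes):
        rng = substream(seed, "anc_cds", i)
        stems = rng.integers(0, len(_FOURFOLD_STEMS), size=n_codons - 1)
        thirds = rng.integers(0, 4, size=n_codons - 1)
        codons = [_FOURFOLD_STEMS[s] + _BASES[t] for s, t in zip(stems, thirds)]
        records.append(SequenceRecord(f"g{i:04d}", "ATG" + "".join(codons)))
    return records


# ---------------------------------------------------------------------------
# Allopolyploid gene sets

def _branch(rec: SequenceRecord, d: float, seed: int, *tokens,
            omega: float = 0.0) -> SequenceRecord:
    """One pure-Ks branch (exact-count K80 on fourfold third positions),
    optionally followed by a nonsynonymous pass at rate omega * d over first
    and second codon positions (stop-creating changes rejected)."""
    out, _ = evolve_sequence(
        rec, EvolveParams(d_target=d, coding_constraint=True, exact_counts=True),
        rng=substream(seed, *tokens, rec.id))
    if omega > 0 and d > 0:
        out = _evolve_nonsyn(out, omega * d, substream(seed, *tokens, rec.id, "ns"))
    return out


def _evolve_nonsyn(rec: SequenceRecord, d: float, rng: np.random.Generator,
                   kappa: float = 2.0) -> SequenceRecord:
    seq = list(rec.seq)
    p_ts, p_tv = _k80_site_probs(d, kappa)
    for ci in range(1, len(seq) // 3):  # never touch the ATG
        for off in (0, 1):
            i = 3 * ci + off
            u = rng.random()
            base = seq[i]
            if u < p_ts:
                new = _TRANSITION[base]
            elif u < p_ts + p_tv:
                tv = _TRANSVERSIONS[base]
                new = tv[0] if rng.random() < 0.5 else tv[1]
            else:
                continue
            codon = seq[3 * ci : 3 * ci + 3]
            codon[off] = new
            if "".join(codon) in _STOPS:
                continue
            seq[i] = new
    return SequenceRecord(rec.id, "".join(seq), rec.description)


def gen_allopolyploid(schedule: DivergenceSchedule, n_genes: int, seed: int,
                      n_codons: int = 500, assemble: bool = True,
                      omega: float = 0.0) -> tuple[dict[str, Genome], SimTruth]:
    """Generate diploid (A, D) and tetraploid subgenome gene sets whose true
    pairwise Ks matches the schedule targets in expectation.

    With a ``GbGh`` split the tetraploid sets are Gb_At/Gb_Dt/Gh_At/Gh_Dt;
    otherwise a single tetraploid At/Dt pair is emitted.  A ``WGD`` split
    adds a within-genome paralog of every gene, diverged at the WGD target.
    Homoeolog truth pairs At genes with their Dt partners.
    """
    truth = SimTruth()
    ks_wgd = schedule.get("WGD")
    ks_ad = schedule.get("AD") or 0.0
    ks_gbgh = schedule.get("GbGh")
    if ks_gbgh is not None and ks_gbgh > ks_ad:
        raise InvalidParameter("GbGh split must be younger than AD")

    roots = gen_ancestral_cds(n_genes, n_codons, seed)
    lineages: list[tuple[str, SequenceRecord]] = [(r.id, r) for r in roots]
    if ks_wgd is not None:
        if ks_wgd < ks_ad:
            raise InvalidParameter("WGD split must be older than AD")
        # both paralog copies later accumulate the full post-WGD species
        # divergence (ks_ad in total), so the duplication branch carries the
        # remainder and the paralog pair lands at the WGD target
        for r in roots:
            dup = _branch(SequenceRecord(f"{r.id}p", r.seq), ks_wgd - ks_ad,
                          seed, "wgd")
            lineages.append((f"{r.id}p", dup))

    inner = (ks_ad - (ks_gbgh or 0.0)) / 2.0
    tip = (ks_gbgh or 0.0) / 2.0

    sets: dict[str, dict[str, str]] = {}

    def emit(genome: str, recs: dict[str, SequenceRecord]):
        sets[genome] = {f"{genome}.{gid}": rec.seq for gid, rec in recs.items()}

    a_anc = {gid: _branch(rec, inner, seed, "A_anc", omega=omega)
             for gid, rec in lineages}
    d_anc = {gid: _branch(rec, inner, seed, "D_anc", omega=omega)
             for gid, rec in lineages}
    emit("A", {g: _branch(r, tip, seed, "A", omega=omega) for g, r in a_anc.items()})
    emit("D", {g: _branch(r, tip, seed, "D", omega=omega) for g, r in d_anc.items()})
    if ks_gbgh is not None:
        for species in ("Gb", "Gh"):
            emit(f"{species}_At", {g: _branch(r, tip, seed, f"{species}_At", omega=omega)
                                   for g, r in a_anc.items()})
            emit(f"{species}_Dt", {g: _branch(r, tip, seed, f"{species}_Dt", omega=omega)
                                   for g, r in d_anc.items()})
        at_name, dt_name = "Gb_At", "Gb_Dt"
        truth.ortholog_pairs["GbGh_At"] = [
            (f"Gb_At.{g}", f"Gh_At.{g}") for g, _ in lineages]
        truth.ortholog_pairs["GbGh_Dt"] = [
            (f"Gb_Dt.{g}", f"Gh_Dt.{g}") for g, _ in lineages]
    else:
        emit("At", {g: _branch(r, tip, seed, "At", omega=omega) for g, r in a_anc.items()})
        emit("Dt", {g: _branch(r, tip, seed, "Dt", omega=omega) for g, r in d_anc.items()})
        at_name, dt_name = "At", "Dt"
    truth.homoeolog_pairs = [(f"{at_name}.{g}", f"{dt_name}.{g}") for g, _ in lineages]
    if ks_wgd is not None:
        base_ids = [r.id for r in roots]
        for genome in sets:
            truth.paralog_pairs[genome] = [
                (f"{genome}.{g}", f"{genome}.{g}p") for g in base_ids]

    genomes: dict[str, Genome] = {}
    for name, cds in sets.items():
        if assemble:
            genomes[name] = assemble_genome(name, cds, seed)
        else:
            genomes[name] = Genome(name, {}, [], dict(cds))
    return genomes, truth


def assemble_genome(name: str, cds: dict[str, str], seed: int,
                    intergenic: tuple[int, int] = (300, 800),
                    intron: tuple[int, int] = (80, 300),
                    max_exons: int = 3, min_exon_codons: int = 15) -> Genome:
    """Lay genes on a single chromosome with random intergenic spacers,
    1..max_exons exons per gene, random strands.  Exons are at least
    ``min_exon_codons`` codons long (micro-exons below ~50 bp are rare in
    plant genomes and would make exon structure unrecoverable)."""
    chrom_name = f"{name}_chr1"
    parts: list[str] = []
    pos = 0
    models: list[GeneModel] = []
    for gid in sorted(cds):
        rng = substream(seed, "assemble", name, gid)
        spacer = "".join(_BASES[rng.integers(0, 4, rng.integers(*intergenic))])
        parts.append(spacer)
        pos += len(spacer)
        seq = cds[gid]
        n_codons = len(seq) // 3
        n_exons = int(rng.integers(1, max_exons + 1))
        n_exons = min(n_exons, max(1, n_codons // min_exon_codons))
        cuts = []
        if n_exons > 1:
            # cut points keeping every exon >= min_exon_codons codons
            slack = n_codons - n_exons * min_exon_codons
            offs = np.sort(rng.choice(np.arange(slack + 1), size=n_exons - 1,
                                      replace=True))
            cuts = [int(min_exon_codons * (i + 1) + offs[i])
                    for i in range(n_exons - 1)]
        bounds = [0, *[3 * c for c in cuts], len(seq)]
        exon_seqs = [seq[a:b] for a, b in zip(bounds, bounds[1:])]
        intron_seqs = ["".join(_BASES[rng.integers(0, 4, rng.integers(*intron))])
                       for _ in range(n_exons - 1)]
        region_parts, exon_coords, off = [], [], 0
        for i, ex in enumerate(exon_seqs):
            region_parts.append(ex)
            exon_coords.append((off, off + len(ex)))
            off += len(ex)
            if i < len(intron_seqs):
                region_parts.append(intron_seqs[i])
                off += len(intron_seqs[i])
        region = "".join(region_parts)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            L = len(region)
            region = revcomp(region)
            exon_coords = [(L - b, L - a) for a, b in exon_coords]
        exons = sorted((pos + a, pos + b) for a, b in exon_coords)
        models.append(GeneModel(gid, chrom_name, pos, pos + len(region), strand, exons))
        parts.append(region)
        pos += len(region)
    tail_rng = substream(seed, "assemble", name, "tail")
    parts.append("".join(_BASES[tail_rng.integers(0, 4, 500)]))
    return Genome(name, {chrom_name: "".join(parts)}, models, dict(cds))


# ---------------------------------------------------------------------------
# LTR elements

def gen_ltr_elements(n: int, age_mix: list[tuple[float, float]],
                     r: float = 2.6e-9, ltr_len: int = 2000, seed: int = 0,
                     internal_len: int = 1000, kappa: float = 2.0,
                     n_ancestors: int | None = None,
                     ) -> tuple[list[LTRElement], SimTruth]:
    """Generate full-length LTR elements of known insertion age.

    Each element's two terminal repeats start identical and evolve
    independently for age * r expected substitutions per site, so the
    expected inter-LTR K2P distance is 2 r age.  ``age_mix`` is a list of
    (age_years, weight) mixture components.  With ``n_ancestors`` the
    ancestral repeats are drawn from that many family prototypes; otherwise
    every element founds its own family.
    """
    if r <= 0:
        raise InvalidParameter("rate r must be positive")
    if ltr_len < 50:
        raise InvalidParameter("ltr_len < 50 gives unstable distance estimates")
    if any(age < 0 for age, _ in age_mix):
        raise InvalidParameter("ages must be non-negative")
    weights = np.array([w for _, w in age_mix], dtype=float)
    weights = weights / weights.sum()
    ages = [a for a, _ in age_mix]
    prototypes = None
    if n_ancestors is not None:
        prototypes = ["".join(_BASES[substream(seed, "ltr_proto", j).integers(0, 4, ltr_len)])
                      for j in range(n_ancestors)]
    elems, truth = [], SimTruth()
    pos = 0
    for i in range(n):
        rng = substream(seed, "ltr", i)
        age = ages[int(rng.choice(len(ages), p=weights))]
        if prototypes is not None:
            anc = prototypes[int(rng.integers(0, len(prototypes)))]
        else:
            anc = "".join(_BASES[rng.integers(0, 4, ltr_len)])
        d = r * age
        params = EvolveParams(d_target=d, kappa=kappa)
        eid = f"ltr{i:04d}"
        left, _ = evolve_sequence(SequenceRecord(eid, anc), params,
                                  rng=substream(seed, "ltr", i, "L"))
        right, _ = evolve_sequence(SequenceRecord(eid, anc), params,
                                   rng=substream(seed, "ltr", i, "R"))
        internal = "".join(_BASES[rng.integers(0, 4, internal_len)])
        total = 2 * ltr_len + internal_len
        elems.append(LTRElement(eid, "ltr_chr", pos, pos + total, "+",
                                left.seq, right.seq))
        pos += total + 500
        truth.ltr_ages[eid] = float(age)
    return elems, truth


# ---------------------------------------------------------------------------
# Pseudogenes

@dataclass
class PseudoLocusTruth:
    locus_id: str
    chrom: str
    start: int
    end: int
    strand: str
    parent_gene_id: str
    category: str
    disablements: list[tuple[str, int]]
    true_ks: float


CATEGORIES = ("duplicated", "processed", "fragmented")


def _inject_disablements(seq: str, exon_bounds: list[tuple[int, int]],
                         rng: np.random.Generator) -> tuple[str, list[tuple[str, int]]]:
    """Inject one premature stop and, half the time, one frameshift.

    ``exon_bounds`` are coding intervals of ``seq`` in reading-frame order;
    the stop replaces an in-frame codon, the frameshift deletes one base.
    """
    dis: list[tuple[str, int]] = []
    # pick an in-frame codon position inside coding sequence, not the first
    cum = 0
    codon_slots = []  # (seq_pos, cds_index)
    for a, b in exon_bounds:
        for p in range(a, b):
            if cum % 3 == 0 and cum >= 3:
                codon_slots.append((p, cum))
            cum += 1
    slot = codon_slots[int(rng.integers(0, len(codon_slots)))]
    stop = ("TAA", "TAG", "TGA")[int(rng.integers(0, 3))]
    seq = seq[: slot[0]] + stop + seq[slot[0] + 3 :]
    dis.append(("premature_stop", slot[0]))
    if rng.random() < 0.5:
        later = [s for s in codon_slots if s[0] > slot[0] + 6]
        if later:
            fpos = later[int(rng.integers(0, len(later)))][0]
            seq = seq[:fpos] + seq[fpos + 1 :]
            dis.append(("frameshift", fpos))
    return seq, dis


def gen_pseudogenes(genome: Genome, mix: dict[str, float], n: int, seed: int,
                    divergence: float = 0.08,
                    ) -> tuple[Genome, list[PseudoLocusTruth], SimTruth]:
    """Insert n pseudogenes into the intergenic space of ``genome``.

    Categories: ``duplicated`` copies the full gene region (introns kept),
    ``processed`` copies the spliced mRNA (introns lost), ``fragmented``
    copies a contiguous <70% piece of the CDS.  Every copy first diverges
    from its parent by ``divergence`` substitutions/site (unconstrained K80,
    emulating relaxed selection) and then receives at least one disablement.
    Returns the genome with loci inserted (coordinates shifted accordingly),
    the locus records, and truth.
    """
    for cat in mix:
        if cat not in CATEGORIES:
            raise InvalidParameter(f"unknown category {cat!r}")
    probs = np.array([mix.get(c, 0.0) for c in CATEGORIES], dtype=float)
    if probs.sum() <= 0:
        raise InvalidParameter("mix must have positive total weight")
    probs = probs / probs.sum()
    multi_exon = [g for g in genome.genes if len(g.exons) >= 2]
    if probs[CATEGORIES.index("processed")] > 0 and not multi_exon:
        raise InvalidParameter("processed pseudogenes need a multi-exon parent")

    chrom_name = next(iter(genome.chroms))
    chrom = genome.chroms[chrom_name]
    truth = SimTruth()
    loci: list[PseudoLocusTruth] = []
    inserts: list[tuple[int, str, PseudoLocusTruth]] = []

    # candidate insertion points: midpoints of intergenic gaps
    gaps = []
    prev = 0
    for g in sorted(genome.genes, key=lambda g: g.start):
        if g.start - prev > 400:
            gaps.append((prev + 100, g.start - 100))
        prev = g.end
    if len(chrom) - prev > 400:
        gaps.append((prev + 100, len(chrom) - 100))
    if not gaps:
        raise InvalidParameter("no intergenic space to insert into")

    for i in range(n):
        rng = substream(seed, "pseudo", i)
        cat = CATEGORIES[int(rng.choice(3, p=probs))]
        if cat == "processed":
            parent = multi_exon[int(rng.integers(0, len(multi_exon)))]
        else:
            parent = genome.genes[int(rng.integers(0, len(genome.genes)))]
        cds = genome.cds[parent.gene_id]
        if cat == "duplicated":
            # gene region in coding orientation, exon bounds in region coords
            region = chrom[parent.start : parent.end]
            exon_bounds = [(a - parent.start, b - parent.start) for a, b in parent.exons]
            if parent.strand == "-":
                L = len(region)
                region = revcomp(region)
                exon_bounds = sorted((L - b, L - a) for a, b in exon_bounds)
            seq, bounds = region, exon_bounds
        elif cat == "processed":
            seq, bounds = cds, [(0, len(cds))]
        else:  # fragmented: contiguous piece < 70% of the CDS
            n_codons = len(cds) // 3
            frac = rng.uniform(0.30, 0.65)
            k = max(2, int(frac * n_codons))
            start_c = int(rng.integers(0, n_codons - k + 1))
            seq = cds[3 * start_c : 3 * (start_c + k)]
            bounds = [(0, len(seq))]
        mutated, _ = evolve_sequence(
            SequenceRecord(f"ps{i:04d}", seq),
            EvolveParams(d_target=divergence, coding_constraint=False),
            rng=substream(seed, "pseudo", i, "evolve"))
        seq, dis = _inject_disablements(mutated.seq, bounds, rng)
        gap = gaps[int(rng.integers(0, len(gaps)))]
        point = int(rng.integers(gap[0], gap[1]))
        strand = "+" if rng.random() < 0.5 else "-"
        rec = PseudoLocusTruth(f"ps{i:04d}", chrom_name, point, point + len(seq),
                               strand, parent.gene_id, cat, dis, divergence)
        inserts.append((point, seq if strand == "+" else revcomp(seq), rec))

    # apply insertions right-to-left so earlier coordinates stay valid,
    # then shift records/genes for insertions to their left
    inserts.sort(key=lambda t: -t[0])
    new_chrom = chrom
    for point, seq, _rec in inserts:
        new_chrom = new_chrom[:point] + seq + new_chrom[point:]
    offsets = sorted((point, len(seq)) for point, seq, _ in inserts)

    def shift(x: int) -> int:
        return x + sum(l for p, l in offsets if p <= x)

    new_genes = [GeneModel(g.gene_id, g.chrom, shift(g.start), shift(g.end), g.strand,
                           [(shift(a), shift(b)) for a, b in g.exons])
                 for g in genome.genes]
    for point, seq, rec in sorted(inserts, key=lambda t: t[0]):
        delta = sum(l for p, l in offsets if p < point)
        rec.start = point + delta
        rec.end = rec.start + len(seq)
        loci.append(rec)
        truth.pseudogenes.append(rec)
    out = Genome(genome.name, {chrom_name: new_chrom}, new_genes, dict(genome.cds))
    return out, loci, truth


# ---------------------------------------------------------------------------
# Reads

def gen_reads(genome_a: Genome, genome_d: Genome, read_len: int, n_reads: int,
              err: float, seed: int) -> tuple[list[SequenceRecord], SimTruth]:
    """Sample error-bearing reads uniformly from two genomes (half each).

    Truth records the source genome of every read.  Only substitution errors
    are simulated.
    """
    if not 0 <= err <= 0.2:
        raise InvalidParameter("err must lie in [0, 0.2]")
    sources = {genome_a.name: genome_a, genome_d.name: genome_d}
    for g in sources.values():
        if min((len(s) for s in g.chroms.values()), default=0) < read_len:
            raise InvalidParameter("read_len exceeds a chromosome length")
    reads, truth = [], SimTruth()
    names = sorted(sources)
    for i in range(n_reads):
        rng = substream(seed, "read", i)
        src = names[int(rng.integers(0, 2))]
        g = sources[src]
        chroms = sorted(g.chroms)
        lens = np.array([len(g.chroms[c]) for c in chroms], dtype=float)
        ci = int(rng.choice(len(chroms), p=lens / lens.sum()))
        cseq = g.chroms[chroms[ci]]
        pos = int(rng.integers(0, len(cseq) - read_len + 1))
        seq = cseq[pos : pos + read_len]
        if rng.random() < 0.5:
            seq = revcomp(seq)
        if err > 0:
            chars = list(seq)
            hits = np.nonzero(rng.random(read_len) < err)[0]
            for h in hits:
                alts = [b for b in "ACGT" if b != chars[h]]
                chars[h] = alts[int(rng.integers(0, 3))]
            seq = "".join(chars)
        rid = f"read{i:06d}"
        reads.append(SequenceRecord(rid, seq))
        truth.read_origins[rid] = src
    return reads, truth


# ---------------------------------------------------------------------------
# Count matrices

def gen_counts(genes: list[str], tissues: dict[str, str], lib_sizes: dict[str, int],
               fold_changes: dict[str, dict[str, float]], seed: int,
               dispersion: float = 0.05, gene_lengths: dict[str, int] | None = None,
               rpkm_range: tuple[float, float] = (5.0, 200.0),
               baseline_groups: dict[str, str] | None = None,
               ) -> tuple[ExpressionMatrix, SimTruth]:
    """Negative-binomial count matrix with known per-gene fold changes.

    ``tissues`` maps sample id -> tissue label; ``fold_changes`` maps gene ->
    {tissue: fc} (unlisted genes/tissues have fc = 1).  Expected counts are
    rpkm_g * fc * length_g * lib_s / 1e9 with rpkm_g log-uniform in
    ``rpkm_range``; dispersion 0 degenerates to Poisson.  Genes sharing a
    ``baseline_groups`` label share one baseline draw — e.g. the two members
    of a homoeolog pair, so a fold change on one member is a true expression
    bias of the pair.
    """
    if any(l <= 0 for l in lib_sizes.values()):
        raise InvalidParameter("library sizes must be positive")
    for g, m in fold_changes.items():
        if any(fc < 0 for fc in m.values()):
            raise InvalidParameter("fold changes must be non-negative")
    samples = sorted(tissues)
    if gene_lengths is None:
        gene_lengths = {}
        for g in genes:
            rng = substream(seed, "genelen", g)
            gene_lengths[g] = int(rng.integers(500, 3000))
    counts = np.zeros((len(genes), len(samples)), dtype=int)
    base = {}
    baseline_groups = baseline_groups or {}
    for g in genes:
        rng = substream(seed, "baserpkm", baseline_groups.get(g, g))
        lo, hi = rpkm_range
        base[g] = math.exp(rng.uniform(math.log(lo), math.log(hi)))
    for gi, g in enumerate(genes):
        rng = substream(seed, "counts", g)
        for si, s in enumerate(samples):
            fc = fold_changes.get(g, {}).get(tissues[s], 1.0)
            mu = base[g] * fc * gene_lengths[g] * lib_sizes[s] / 1e9
            if mu <= 0:
                counts[gi, si] = 0
            elif dispersion <= 0:
                counts[gi, si] = rng.poisson(mu)
            else:
                nb_n = 1.0 / dispersion
                nb_p = nb_n / (nb_n + mu)
                counts[gi, si] = rng.negative_binomial(nb_n, nb_p)
    mat = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        gene_length=pd.Series(gene_lengths),
        lib_size=pd.Series({s: lib_sizes[s] for s in samples}),
        samples=pd.DataFrame({"tissue": pd.Series(tissues)}).loc[samples])
    de_rows = []
    for g in genes:
        fcs = fold_changes.get(g, {})
        is_de = any(fc != 1.0 for fc in fcs.values())
        de_rows.append((g, is_de, max(fcs.values(), default=1.0)))
    truth = SimTruth()
    truth.de = pd.DataFrame(de_rows, columns=["gene", "is_de", "max_fc"]).set_index("gene")
    return mat, truth
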