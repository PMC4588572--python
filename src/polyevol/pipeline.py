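"""Pipeline orchestration: configuration with the study's printed constants
as defaults, assembly-style summary statistics, and an end-to-end driver
that runs the synthetic-data stages through every analysis module and
writes TSV outputs plus a run report.

The numbered scripts under ``analysis/`` are thin drivers over this module;
`run_pipeline` is the single entry point they and the tests share.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from polyevol import expr, homoeolog, ltrdyn, moldiv, pseudo, syndata
from polyevol._util import GeneModel, SequenceRecord, write_fasta, write_gff3
from polyevol.moldiv import ClockParams
from polyevol.syndata import DivergenceSchedule


class DependencyError(RuntimeError):
    """A stage was requested without its upstream stage."""


@dataclass
class PipelineConfig:
    """All pipeline parameters; defaults follow the study's printed values
    wherever one exists (clock rate, identity/coverage thresholds, FDR and
    fold-change cutoffs, histogram bin widths, proximity window, the
    80-80-80 family rule and the 150-bp pseudogene length filter)."""

    seed: int = 1
    outdir: str = "results/pipeline"
    stages: tuple[str, ...] = ("simulate", "homoeolog", "kaks", "ltr",
                               "pseudo", "expr")
    # simulation sizes
    n_genes: int = 60
    n_codons: int = 300
    ks_ad: float = 0.04
    ks_gbgh: float | None = None
    n_ltr: int = 60
    ltr_ages_myr: tuple[float, ...] = (1.0, 5.0, 12.0)
    ltr_len: int = 2000
    n_pseudogenes: int = 30
    pseudo_divergence: float = 0.08
    n_expr_genes: int = 200
    # analysis constants (paper-printed values as defaults)
    clock_rate: float = 2.6e-9
    bbh_min_identity: float = 30.0
    bbh_min_cov: float = 0.30
    e_max: float = 1e-3
    ks_bin_ortholog: float = 0.001
    ks_bin_paralog: float = 0.01
    ltr_bin_years: float = 1e6
    burst_prominence: float = 0.25
    family_identity: float = 0.80
    family_len_frac: float = 0.80
    family_min_len: int = 80
    proximity_window: int = 20_000
    pseudo_min_len: int = 150
    pseudo_gene_overlap: int = 30
    fdr_max: float = 0.001
    min_abs_log2: float = 1.0
    partition_min_identity: float = 0.95
    partition_min_cov: float = 0.9
    partition_delta: float = 0.02

    def validate(self) -> None:
        known = {"simulate", "homoeolog", "kaks", "ltr", "pseudo", "expr"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        need_sim = set(self.stages) - {"simulate"}
        if need_sim and "simulate" not in self.stages:
            raise DependencyError(
                f"stage '{sorted(need_sim)[0]}' requires stage 'simulate'")


def serialize_config(cfg: PipelineConfig) -> str:
    """key=value text; round-trips through parse_config."""
    lines = []
    for f in fields(cfg):
        v = getattr(cfg, f.name)
        if isinstance(v, tuple):
            v = ",".join(str(x) for x in v)
        lines.append(f"{f.name}={v}")
    return "\n".join(lines) + "\n"


def parse_config(text: str) -> PipelineConfig:
    kv = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        k, v = line.split("=", 1)
        kv[k.strip()] = v.strip()
    kwargs = {}
    for f in fields(PipelineConfig):
        if f.name not in kv:
            continue
        raw = kv[f.name]
        if f.name == "stages":
            kwargs[f.name] = tuple(raw.split(",")) if raw else ()
        elif f.name == "ltr_ages_myr":
            kwargs[f.name] = tuple(float(x) for x in raw.split(","))
        elif f.name in ("outdir",):
            kwargs[f.name] = raw
        elif f.name == "ks_gbgh":
            kwargs[f.name] = None if raw == "None" else float(raw)
        elif f.type in ("int", int):
            kwargs[f.name] = int(raw)
        elif f.type in ("float", float):
            kwargs[f.name] = float(raw)
        else:
            kwargs[f.name] = type(getattr(PipelineConfig(), f.name))(raw)
    return PipelineConfig(**kwargs)


@dataclass
class RunReport:
    seed: int
    stages: list[str] = field(default_factory=list)
    counts: dict[str, int] = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)
    wall_clock_s: float = 0.0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


# ---------------------------------------------------------------------------
# Summary statistics

def n50(lengths: list[int]) -> int:
    """Smallest length L such that sequences >= L hold half the total."""
    if not lengths:
        raise ValueError("n50 of an empty set")
    if any(l <= 0 for l in lengths):
        raise ValueError("lengths must be positive")
    total = sum(lengths)
    acc = 0
    for l in sorted(lengths, reverse=True):
        acc += l
        if acc >= total / 2:
            return l
    return min(lengths)  # unreachable


def gene_stats(models: list[GeneModel]) -> dict[str, float]:
    """Table-1-style summary: counts and mean sizes (integer bp)."""
    if not models:
        raise ValueError("no gene models")
    gene_sizes, cds_sizes, exon_sizes, intron_sizes, exon_counts = [], [], [], [], []
    for m in models:
        for a, b in m.exons:
            if a < m.start or b > m.end:
                raise ValueError(f"gene {m.gene_id}: exon outside gene span")
        gene_sizes.append(m.span)
        cds_sizes.append(sum(b - a for a, b in m.exons))
        exon_sizes.extend(b - a for a, b in m.exons)
        intron_sizes.extend(b - a for a, b in m.introns())
        exon_counts.append(len(m.exons))
    return {
        "gene_count": len(models),
        "mean_gene_size": round(float(np.mean(gene_sizes))),
        "mean_cds_size": round(float(np.mean(cds_sizes))),
        "mean_exon_size": round(float(np.mean(exon_sizes))),
        "mean_intron_size": round(float(np.mean(intron_sizes))) if intron_sizes else 0,
        "mean_exons_per_gene": float(np.mean(exon_counts)),
        "max_gene_size": int(max(gene_sizes)),
    }


# ---------------------------------------------------------------------------
# Stage driver

def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in dependency order; deterministic for a
    fixed seed, with every output file listed in the returned report."""
    config.validate()
    t0 = time.time()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    clock = ClockParams(config.clock_rate)

    def emit(name: str, text: str) -> Path:
        p = out / name
        p.write_text(text)
        report.outputs.append(str(p))
        return p

    state: dict = {}

    if "simulate" in config.stages:
        splits = [("AD", config.ks_ad)]
        if config.ks_gbgh is not None:
            splits.append(("GbGh", config.ks_gbgh))
        genomes, truth = syndata.gen_allopolyploid(
            DivergenceSchedule(splits), config.n_genes, config.seed,
            n_codons=config.n_codons)
        at = genomes[truth.homoeolog_pairs[0][0].split(".")[0]]
        g_pseudo, loci, ps_truth = syndata.gen_pseudogenes(
            at, {"duplicated": 1, "processed": 1, "fragmented": 1},
            config.n_pseudogenes, config.seed, config.pseudo_divergence)
        elems, ltr_truth = syndata.gen_ltr_elements(
            config.n_ltr, [(a * 1e6, 1.0) for a in config.ltr_ages_myr],
            r=config.clock_rate, ltr_len=config.ltr_len, seed=config.seed)
        genes = [f"g{i:04d}" for i in range(config.n_expr_genes)]
        tissues = {f"fiber_{i}": "fiber" for i in range(2)}
        tissues.update({f"ovule_{i}": "ovule" for i in range(2)})
        libs = {s: 2_000_000 for s in tissues}
        fcs = {g: {"fiber": 4.0} for g in genes[: config.n_expr_genes // 10]}
        mat, de_truth = syndata.gen_counts(genes, tissues, libs, fcs, config.seed)
        state.update(genomes=genomes, truth=truth, pseudo_genome=g_pseudo,
                     loci=loci, ps_truth=ps_truth, elems=elems,
                     ltr_truth=ltr_truth, mat=mat, de_truth=de_truth)
        for name, g in genomes.items():
            write_fasta((SequenceRecord(gid, s) for gid, s in sorted(g.cds.items())),
                        out / f"cds_{name}.fasta")
            report.outputs.append(str(out / f"cds_{name}.fasta"))
            write_gff3(g.genes, out / f"genes_{name}.gff3")
            report.outputs.append(str(out / f"genes_{name}.gff3"))
        emit("homoeolog_truth.tsv", "gene_a\tgene_d\n" + "".join(
            f"{a}\t{d}\n" for a, d in truth.homoeolog_pairs))
        stats = gene_stats(at.genes)
        emit("gene_stats.tsv", "\n".join(f"{k}\t{v}" for k, v in stats.items()) + "\n")
        report.counts["simulate.genes"] = config.n_genes
        report.counts["simulate.ltr"] = len(elems)
        report.counts["simulate.pseudogenes"] = len(loci)
        report.stages.append("simulate")

    def need(key: str, stage: str):
        if key not in state:
            raise DependencyError(f"stage '{stage}' requires stage 'simulate'")
        return state[key]

    if "homoeolog" in config.stages:
        genomes = need("genomes", "homoeolog")
        truth = state["truth"]
        at_name = truth.homoeolog_pairs[0][0].split(".")[0]
        dt_name = truth.homoeolog_pairs[0][1].split(".")[0]
        pairs = homoeolog.bbh_pairs(
            genomes[at_name].proteins(), genomes[dt_name].proteins(),
            e_max=config.e_max, min_identity=config.bbh_min_identity,
            min_cov=config.bbh_min_cov)
        state["pairs"] = pairs
        emit("homoeolog_pairs.tsv", homoeolog.pairs_to_tsv(pairs))
        report.counts["homoeolog.pairs"] = len(pairs)
        report.stages.append("homoeolog")

    if "kaks" in config.stages:
        genomes = need("genomes", "kaks")
        truth = state["truth"]
        cds_by_id = {gid: s for g in genomes.values() for gid, s in g.cds.items()}
        rows = []
        ks_vals = []
        for a, d in truth.homoeolog_pairs:
            est = moldiv.ng86(moldiv.CodonAlignment(cds_by_id[a], cds_by_id[d]))
            rows.append((a, d, est))
            ks_vals.append(est.Ks)
        hist = moldiv.ks_histogram(ks_vals, config.ks_bin_ortholog)
        peak = moldiv.find_peak(hist)
        age = moldiv.clock_convert(peak, clock)
        lines = ["gene_a\tgene_d\tN\tS\tNd\tSd\tKa\tKs\tomega\tsaturated"]
        for a, d, e in rows:
            lines.append(f"{a}\t{d}\t{e.N:.1f}\t{e.S:.1f}\t{e.Nd:.2f}\t{e.Sd:.2f}"
                         f"\t{e.Ka:.4f}\t{e.Ks:.4f}\t{e.omega:.4f}\t{int(e.saturated)}")
        emit("kaks_pairs.tsv", "\n".join(lines) + "\n")
        emit("ks_histogram.tsv", hist.to_tsv())
        emit("ks_peak.tsv", f"peak_ks\tage_years\n{peak:.4f}\t{age:.0f}\n")
        state["ks_peak"] = peak
        report.counts["kaks.pairs"] = len(rows)
        report.stages.append("kaks")

    if "ltr" in config.stages:
        elems = need("elems", "ltr")
        dated, undated = ltrdyn.date_elements(elems, clock)
        dist = ltrdyn.age_distribution(dated, config.ltr_bin_years,
                                       config.burst_prominence)
        fams = ltrdyn.cluster_families_808080(dated)
        lines = ["element_id\tk2p\tage_years\tfamily_id"]
        for e in dated:
            lines.append(f"{e.element_id}\t{e.k2p:.5f}\t{e.age_years:.0f}\t{e.family_id}")
        emit("ltr_ages.tsv", "\n".join(lines) + "\n")
        emit("ltr_bursts.tsv", "burst_age_years\n" + "".join(
            f"{b:.0f}\n" for b in dist.bursts))
        report.counts["ltr.dated"] = len(dated)
        report.counts["ltr.bursts"] = len(dist.bursts)
        report.counts["ltr.families"] = fams.n_families
        state["ltr_dist"] = dist
        report.stages.append("ltr")

    if "pseudo" in config.stages:
        g2 = need("pseudo_genome", "pseudo")
        regions = pseudo.intergenic_regions(g2)
        cands = pseudo.detect_pseudogenes(regions, g2.proteins(),
                                          e_max=config.e_max)
        models = {m.gene_id: m for m in g2.genes}
        for c in cands:
            if c.parent_gene_id in models:
                pseudo.classify_pseudogene(c, models[c.parent_gene_id],
                                           g2.cds[c.parent_gene_id])
                try:
                    pseudo.ks_to_parent(c, g2.cds[c.parent_gene_id])
                except pseudo.UnalignableCandidate:
                    pass
        kept = pseudo.filter_pseudogenes(cands, g2.genes,
                                         min_len=config.pseudo_min_len,
                                         max_gene_overlap=config.pseudo_gene_overlap)
        lines = ["locus_id\tchrom\tstart\tend\tstrand\tparent\tcategory"
                 "\tcoverage\tks\tdisablements"]
        for c in kept:
            ks = f"{c.ks_to_parent:.4f}" if c.ks_to_parent is not None else "NA"
            dis = ";".join(f"{t}@{p}" for t, p in c.disablements) or "NA"
            lines.append(f"{c.locus_id}\t{c.chrom}\t{c.start}\t{c.end}\t{c.strand}"
                         f"\t{c.parent_gene_id}\t{c.category}\t{c.parent_coverage:.2f}"
                         f"\t{ks}\t{dis}")
        emit("pseudogenes.tsv", "\n".join(lines) + "\n")
        report.counts["pseudo.candidates"] = len(cands)
        report.counts["pseudo.kept"] = len(kept)
        state["pseudo_calls"] = kept
        report.stages.append("pseudo")

    if "expr" in config.stages:
        mat = need("mat", "expr")
        fiber = list(mat.samples.index[mat.samples["tissue"] == "fiber"])
        ovule = list(mat.samples.index[mat.samples["tissue"] == "ovule"])
        de = expr.call_de(mat, fiber, ovule, config.fdr_max, config.min_abs_log2)
        pref = expr.preferential_genes(mat, "fiber", config.fdr_max,
                                       config.min_abs_log2)
        de.to_csv(out / "de_results.tsv", sep="\t")
        report.outputs.append(str(out / "de_results.tsv"))
        emit("fiber_preferential.tsv", "gene\n" + "".join(f"{g}\n" for g in sorted(pref)))
        report.counts["expr.significant"] = int(de["significant"].sum())
        report.counts["expr.fiber_preferential"] = len(pref)
        report.stages.append("expr")

    report.wall_clock_s = round(time.time() - t0, 2)
    emit("run_report.json", report.to_json())
    return report
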