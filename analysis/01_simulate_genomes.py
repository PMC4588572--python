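#!/usr/bin/env python
"""Simulate the study system: an allotetraploid (At/Dt subgenomes) diverged
from two diploid progenitors, plus LTR retroelements of known insertion age,
pseudogenes of known category, sequencing reads of known subgenome origin,
and an expression count matrix with known fold changes.

Writes FASTA/GFF3/TSV ground-truth files under results/sim/.  Every
downstream script regenerates the same world from SEED, so this script's
role is to materialize the data and its truth for inspection.
"""

from pathlib import Path

from polyevol import syndata
from polyevol._util import SequenceRecord, write_fasta, write_gff3
from polyevol.pipeline import gene_stats, n50
from polyevol.syndata import DivergenceSchedule

SEED = 1
N_GENES = 150          # per subgenome
N_CODONS = 300         # ~0.9 kb CDS
KS_AD = 0.04           # At:Dt target divergence (paper's ortholog peak)
N_PSEUDO = 90
N_LTR = 120
LTR_AGES_MYR = (1.0, 5.0, 12.0)

OUT = Path("results/sim")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genomes, truth = syndata.gen_allopolyploid(
        DivergenceSchedule([("AD", KS_AD)]), N_GENES, SEED, n_codons=N_CODONS)
    for name, g in genomes.items():
        write_fasta((SequenceRecord(gid, s) for gid, s in sorted(g.cds.items())),
                    OUT / f"cds_{name}.fasta")
        write_fasta([SequenceRecord(c, s) for c, s in g.chroms.items()],
                    OUT / f"genome_{name}.fasta")
        write_gff3(g.genes, OUT / f"genes_{name}.gff3")
    (OUT / "homoeolog_truth.tsv").write_text(
        "gene_a\tgene_d\n" + "".join(f"{a}\t{d}\n"
                                     for a, d in truth.homoeolog_pairs))

    g2, loci, ps_truth = syndata.gen_pseudogenes(
        genomes["At"], {"duplicated": 1, "processed": 1, "fragmented": 1},
        N_PSEUDO, SEED)
    write_fasta([SequenceRecord(c, s) for c, s in g2.chroms.items()],
                OUT / "genome_At_with_pseudogenes.fasta")
    write_gff3(g2.genes, OUT / "genes_At_with_pseudogenes.gff3")
    (OUT / "pseudogene_truth.tsv").write_text(
        "locus_id\tchrom\tstart\tend\tstrand\tparent\tcategory\n" + "".join(
            f"{r.locus_id}\t{r.chrom}\t{r.start}\t{r.end}\t{r.strand}"
            f"\t{r.parent_gene_id}\t{r.category}\n" for r in loci))

    elems, ltr_truth = syndata.gen_ltr_elements(
        N_LTR, [(a * 1e6, 1.0) for a in LTR_AGES_MYR], seed=SEED)
    write_fasta([SequenceRecord(f"{e.element_id}_L", e.left_ltr) for e in elems]
                + [SequenceRecord(f"{e.element_id}_R", e.right_ltr)
                   for e in elems], OUT / "ltr_elements.fasta")
    (OUT / "ltr_truth.tsv").write_text(
        "element_id\ttrue_age_years\n" + "".join(
            f"{eid}\t{age:.0f}\n" for eid, age in sorted(ltr_truth.ltr_ages.items())))

    stats = gene_stats(genomes["At"].genes)
    chrom_lens = [len(s) for g in genomes.values() for s in g.chroms.values()]
    lines = [f"{k}\t{v}" for k, v in stats.items()]
    lines.append(f"genome_n50\t{n50(chrom_lens)}")
    (OUT / "summary_stats.tsv").write_text("\n".join(lines) + "\n")

    print(f"simulated {N_GENES} homoeolog pairs at Ks {KS_AD}, "
          f"{len(loci)} pseudogenes, {len(elems)} LTR elements -> {OUT}/")
    print("gene stats:", stats)


if __name__ == "__main__":
    main()
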