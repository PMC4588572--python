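# polyevol

Comparative molecular-evolution analyses for allopolyploid genomes, built
around the cotton (*Gossypium*) allotetraploid system: two diploid-derived
subgenomes (At and Dt) carried in one nucleus since an interspecific
hybridization roughly 1–2 million years ago, on top of diploid lineages that
split about 8 million years ago.

The package implements, as a tested library with ground-truthed simulation:

* **Homoeolog identification** — bidirectional best hit (BBH) on protein
  sets with the >30% identity / >30% coverage qualifying rules, plus
  subgenome-unique gene detection and partitioning of sequencing reads
  between two diploid references.
* **Molecular divergence** — codon-aware alignment, Ka/Ks by Nei–Gojobori
  (1986) counting with Jukes–Cantor correction, Kimura two-parameter (K2P)
  nucleotide distances, Ks histograms at 0.001/0.01-Ks resolution with peak
  detection, and molecular-clock dating T = K/(2r) at r = 2.6×10⁻⁹
  substitutions · site⁻¹ · yr⁻¹.
* **LTR retrotransposon dynamics** — insertion ages from the K2P divergence
  of the two terminal repeats (identical at insertion), burst detection in
  the age distribution, 80–80–80 family clustering (≥80% identity over ≥80%
  of the shorter sequence, alignment >80 bp), singleton statistics, and
  20-kb upstream gene-proximity flags.
* **Pseudogenes** — six-frame protein-vs-DNA search of intergenic space,
  HSP chaining, classification into duplicated / processed / fragmented,
  the exclusion filters (>30 bp gene overlap, TE/plastid parents, <150 bp
  loci), and Ks-to-parent estimation with frameshift repair.
* **Expression** — RPKM quantification, differential calls by a two-sided
  exact binomial test with Benjamini–Hochberg correction at FDR ≤ 0.001 and
  |log₂ ratio| ≥ 1, tissue-preferential gene sets, homoeolog expression
  bias, and the LTR-proximity expression contrast.
* **Synthetic data** (`polyevol.syndata`) — a seeded generator of
  allopolyploid gene sets diverged to target Ks values under the Kimura
  (K80) substitution model, LTR elements of known age, pseudogenes of known
  category, reads of known origin, and count matrices with known fold
  changes.  Every analysis above is validated by recovering this ground
  truth.

## Worked example

```python
from polyevol import moldiv, syndata, homoeolog
from polyevol.syndata import DivergenceSchedule

genomes, truth = syndata.gen_allopolyploid(
    DivergenceSchedule([("AD", 0.04)]), n_genes=150, seed=1, n_codons=300)
pairs = homoeolog.bbh_pairs(genomes["At"].proteins(),
                            genomes["Dt"].proteins(), prefilter_k=10)
ks = [moldiv.ng86(moldiv.CodonAlignment(genomes["At"].cds[a],
                                        genomes["Dt"].cds[d])).Ks
      for a, d in truth.homoeolog_pairs]
peak = moldiv.find_peak(moldiv.ks_histogram(ks, 0.001))
print(len(pairs), round(peak, 4),
      round(moldiv.clock_convert(peak) / 1e6, 2))
```

prints `150 0.0415 7.98`: all 150 true homoeolog pairs are recovered by BBH,
the modal 0.001-Ks bin of the pair divergences sits at 0.0415 (one bin from
the simulated target 0.04), and the molecular clock converts that peak to a
7.98-million-year A/D divergence — the analysis chain behind statements
like "Ks 0.04 ⇒ approximately 8 Mya".

The numbered scripts under `analysis/` run the full study end to end
(`python analysis/01_simulate_genomes.py`, then 02–06); each prints what it
found and writes its tables under `results/`.

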