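# Methods

This note records the models, estimators and numerical choices behind
`polyevol`, and what the synthetic-data validation does and does not
demonstrate.

## Substitution model and sequence simulation

All simulated sequence evolution follows the Kimura two-parameter (K80)
model with transition/transversion rate ratio κ (default 2). A branch of
expected length *d* substitutions/site is realized by sampling each site
from the exact K80 transition-probability matrix: with βt = d/(κ+2) and
αt = κβt,

    P(transition)        = 1/4 + 1/4·e^(−4βt) − 1/2·e^(−2(α+β)t)
    P(each transversion) = 1/4 − 1/4·e^(−4βt)

Because these are the same functions the K2P estimator inverts, the
estimator applied to a simulated pair is unbiased for *d* with multiple
hits handled implicitly — there is no per-event bookkeeping to approximate.

Two realization modes exist:

* **iid (default)** — every site draws independently; realized divergence
  has binomial variance. Used for LTR elements, pseudogene divergence and
  read errors.
* **exact counts** (`EvolveParams.exact_counts`) — the numbers of
  transitions and transversions are conditioned on their expectations
  (stochastic rounding); only event positions stay random. Used by
  `gen_allopolyploid` so that every gene pair's realized divergence equals
  the schedule target to within one event. This is what makes a 0.001-Ks
  modal bin a meaningful readout from 500 pairs: with iid sampling the
  per-pair standard deviation (~0.004 at Ks 0.04 over 2 000 synonymous
  sites) would dominate the bin width and the modal bin would wander.

### Ks targeting in coding sequence

Ancestral CDSs are ATG followed by codons whose third position is fourfold
degenerate while the first two positions are fully nondegenerate (Val, Ala,
Thr, Pro, Gly, Ser₄ families). Constrained branches mutate only those third
positions, so the synonymous site count is exactly (codons − 1) and the
branch length *is* the true Ks — no codon model is needed to set Ks
exactly. An optional ω > 0 adds an iid pass over first/second positions at
rate ω·d with stop-creating changes rejected, giving pairs a nonsynonymous
component when protein divergence matters.

A consequence of this codon alphabet is biased composition: proteins are
strings over six amino acids, and unrelated genes share short peptides far
more often than natural sequences do. The alignment stack treats this as a
composition-bias problem (see below) rather than hiding it, since low
complexity regions raise exactly the same issue in real genomes.

The allopolyploid topology supports splits named `WGD`, `AD`, `GbGh`
(oldest→youngest Ks targets). Branch lengths are assigned by subtraction so
that each *pair* of emitted gene sets meets its target: e.g. the WGD
duplication branch carries Ks(WGD) − Ks(AD) because both paralog copies
subsequently accumulate the full post-duplication species divergence.

Gene structures are laid on one chromosome per genome: 1–3 exons per gene
with introns of 80–300 bp and intergenic spacers of 300–800 bp, random
strands. Exons are at least 15 codons: micro-exons below ~50 bp are rare in
plant genomes and their junctions are unrecoverable by protein-level
alignment, which would make classification accuracy a property of the
generator rather than of the classifier.

All randomness flows from one root seed through hash-derived sub-streams
keyed by (seed, entity path), so outputs are independent of generation
order and byte-identical across runs.

## Alignment engine

Dynamic programming (global, local, affine gaps) is Biopython's
`PairwiseAligner`; the module owns scoring conventions (gap of length L
costs open + extend·L), iterative HSP extraction with query masking and a
>50%-overlap discard rule, a shared-k-mer prefilter for all-vs-all
searches, and seed-and-extend mapping of short queries against long
references. E-values use the ungapped Karlin–Altschul form
E = K·m·n·e^(−λS) with λ solved exactly from Σ pᵢpⱼe^(λsᵢⱼ) = 1 under
uniform background frequencies and K fixed at 0.1; gapped scores reuse the
ungapped λ. At the only operating point that matters downstream
(E ≤ 10⁻³ pass/fail) the approximation is inert.

For protein-vs-six-frame pseudogene search, two additional standard devices
are applied: a −1 composition shift of BLOSUM62 (the role of BLAST's
composition-based statistics) so chance similarity between biased-
composition sequences scores negative on average, and BLAST-style X-drop
splitting of raw Smith–Waterman HSPs (cut where the running score falls
22 below its maximum), which separates exon-level segments that SW would
otherwise bridge across introns or neighbouring loci.

## Ka/Ks (NG86) and K2P

Synonymous site content of a codon is the fraction of its nine single-
nucleotide neighbours preserving the amino acid; changes to stops count as
nonsynonymous; site totals average the two sequences. Multi-difference
codons average step counts over all orderings of single steps, excluding
stop-crossing pathways (re-including them only if every ordering is
blocked). Proportions are Jukes–Cantor corrected, d = −¾·ln(1 − 4p/3);
p ≥ ¾ sets a saturation flag and the estimate is excluded from histograms
and dating. The worked two-codon example (GTT·GCT vs GTC·GCT) gives
N = 4, S = 2, Sd = 1, Ks = 0.8240; a brute-force pathway-enumeration oracle
in the test suite checks site and difference counts over random codon
alignments.

K2P: K = −½·ln((1−2P−Q)·√(1−2Q)) over columns where both sequences carry
an unambiguous base; the saturation error is raised exactly when
1−2P−Q ≤ 0 or 1−2Q ≤ 0. Note (P,Q) = (0.1, 0.05) gives 0.17018.

Ks histograms are left-closed from 0 at bin widths 0.001 (orthologs,
pseudogenes) and 0.01 (paralogs); the peak is the midpoint of the first
maximal bin (ties break toward smaller Ks). Clock dating is T = K/(2r)
with r = 2.6×10⁻⁹ /site/yr, the average substitution rate used for cotton:
Ks 0.005 → 0.96 Myr ("≈1 Mya"), Ks 0.04 → 7.7 Myr ("≈8 Mya"), Ks 0.06–0.1
→ 11.5–19.2 Myr. Applying the same clock to a paralog Ks peak of 0.4–0.5
gives 77–96 Myr, not the 50–70 Myr usually quoted for the cotton-lineage
WGD — that dating evidently used a different (unstated) rate; the package
implements T = K/(2r) as printed and leaves the discrepancy to the user.

## Homoeologs, unique genes, read partitioning

BBH "best" means highest score, ties broken by identity then lexicographic
subject id, so every gene joins at most one pair and the output is
symmetric under swapping inputs. Qualifying hits need identity > 30% and
query coverage > 0.30 (the coverage rule is applied to the query; both
coverages are reported). Unique genes require no protein hit at E ≤ 10⁻³
and total non-overlapping CDS-vs-genome HSP length strictly below one third
of the CDS. Read partitioning maps both orientations against each diploid
reference; a reference qualifies at ≥95% identity over ≥90% coverage
(defaults, configurable), and labels follow the score-ratio rule with
δ = 0.02. These three thresholds are package defaults, not literature
values — the source analyses report outcome percentages, not criteria.

## LTR dating, bursts, families

Insertion age is the K2P distance between the globally aligned left and
right terminal repeats divided by 2r; elements whose repeats align below
50% identity or saturate are flagged undatable and excluded. Only elements
with both repeats present are dated (solo LTRs, the remnants of
intra-element recombination, have no partner to compare).

Bursts are modes of the age histogram: plateau-aware local maxima of a
3-bin moving average (edge-padded), kept when the smoothed peak exceeds the
larger flanking minimum by a prominence fraction (default 0.25) of the
peak. The smoothing exists because a mixture component centred on a bin
boundary otherwise splits into two half-height bins that individually lack
prominence; a flat histogram yields no bursts.

Families use the 80–80–80 rule — ≥80% identity over ≥80% of the shorter
terminal-repeat sequence with aligned length > 80 bp — with single-linkage
connected components (union-find), so clustering is independent of input
order. The singleton ratio is singleton families over total families.

The gene-proximity flag marks genes with any element interval overlapping
the strand-aware 20-kb window upstream of the start codon, in half-open
coordinate arithmetic; upstream of a minus-strand gene extends toward
larger coordinates.

## Pseudogenes

Detection searches parent proteins against all six reading frames of
gene-masked intergenic regions, splits raw HSPs by X-drop, drops segments
below 65% identity (genuine copies at the generator's 0.08 divergence sit
near 85%; chance matches under the biased composition sit below ~55%), and
chains co-linear segments per parent and strand, tolerating 40 aa of
parent-side overlap between consecutive segments. Disablements are read
from the chain: an aligned stop inside a segment is a premature stop; a
frame change between consecutive segments without an intron-scale
nucleotide excess is a frameshift. Overlapping candidates keep the
best-scoring parent.

Classification works on the chain geometry. A parent exon-exon junction
crossed inside one clean block, or between blocks whose nucleotide excess
over 3×(aa gap) is ≤ 30 bp, is processed-copy evidence; an excess > 30 bp
near a junction is an intron, i.e. duplicated-copy evidence; single-exon
parents covered ≥ 70% are duplicated; everything else is fragmented. The
30-bp intron threshold and the >30 bp "significant overlap" constant in
the exclusion filters are operational choices (smallest plausible intron ≫
alignment jitter) and are exposed as parameters, as are the 150-bp length
filter and the TE/plastid parent filter.

Ks to parent globally aligns the candidate to the parent CDS with
gap-friendly scoring (match 1, mismatch −4, open 6, extend 0.5 — chosen so
intron-scale insertions are gapped rather than absorbed as mismatch runs),
treats candidate insertions as alignment gaps to preserve the parent frame
(frameshift repair by gap insertion, never by editing sequence), masks
codons where the candidate carries an in-frame stop, and runs NG86.
Per-locus Ks estimates carry sd ≈ 0.014 at the generator's settings, so
the *mean* over hundreds of loci recovers the simulated divergence tightly
while the modal 0.001-bin of the histogram is only indicative.

## Expression

RPKM(g,s) = 10⁹·count/(lib_size·gene_length), with lib_size the total
mapped reads of the sample (configurable). Differential expression uses a
two-sided exact binomial test on pooled group counts against the
library-size expectation, BH-FDR across genes, and significance at
FDR ≤ 0.001 and |log₂ ratio| ≥ 1; the log₂ ratio adds a one-read
pseudocount to each group (ratio only, never the test). This replaces the
MA-plot-with-random-sampling statistic of DEGseq with an exactly
specifiable test at the same thresholds. Both tests model technical
(Poisson) sampling only: under negative-binomial overdispersion the test is
anti-conservative, which the generator demonstrates directly (dispersion
0.05 inflates the null call rate roughly tenfold). Error-control
validation therefore runs at dispersion 0; conclusions about overdispersed
biological replicates require a dispersion-aware model, which is out of
scope here.

Tissue-preferential genes must be significant against the pooled other
tissues *and* maximal in mean RPKM in the target tissue. Homoeolog bias
tests the two copies' pooled counts against the gene-length expectation
p₀ = L_At/(L_At+L_Dt) (read counts scale with transcript length), BH
across pairs, calling At-/Dt-biased at the same thresholds. The
LTR-proximity contrast compares stratum means of per-gene mean RPKM with a
seeded 10 000-permutation two-sided p-value.

## What the synthetic validation shows — and does not

The generator matches the statistical structure the estimators assume:
K80 substitution, independent repeat divergence, category-true pseudogene
construction, Poisson/NB counts. Passing recovery tests therefore shows
the analysis chain is correctly implemented and calibrated under its own
model. It does not establish robustness to features real data add on top:
indels and tandem repeats in LTRs, truncated and nested elements,
alignment through N-rich assembly gaps, GC-content variation, mapping
bias in read counts, or biological overdispersion beyond the NB family.
The composition-biased codon alphabet is in one respect *harder* than real
data (pervasive chance protein similarity), which the detection stack must
and does withstand.

## Problem sizes

Default validation scales, chosen to give each statistic a comfortable
margin over its acceptance threshold: 500 gene pairs (2 000 codons) for
Ks-peak recovery; 600 LTR elements of 2 000 bp repeats across three age
components; 300 pseudogenes over a 150-gene genome (~0.9 kb CDS); 500
pairs (300 codons) for BBH; 2 000 genes, four samples for the DE null and
power runs. The analysis scripts use the same machinery at similar or
smaller sizes.
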