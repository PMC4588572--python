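#!/usr/bin/env python
"""Identify homoeologs by bidirectional best hit, estimate Ka/Ks for every
pair, build the Ks histogram at 0.001-Ks resolution and date the At/Dt
divergence with the molecular clock T = Ks/(2r), r = 2.6e-9.

A second, larger simulation at two divergence targets (0.04 and 0.005)
checks that the modal histogram bin recovers both simulated peaks.
"""

from pathlib import Path

import numpy as np

from polyevol import homoeolog, moldiv, syndata
from polyevol.moldiv import ClockParams, CodonAlignment
from polyevol.syndata import DivergenceSchedule

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    genomes, truth = syndata.gen_allopolyploid(
        DivergenceSchedule([("AD", 0.04)]), 150, SEED, n_codons=300)
    pairs = homoeolog.bbh_pairs(genomes["At"].proteins(),
                                genomes["Dt"].proteins(), prefilter_k=10)
    found = {(p.gene_a_id, p.gene_d_id) for p in pairs}
    recovery = len(found & set(truth.homoeolog_pairs)) / len(truth.homoeolog_pairs)
    (OUT / "homoeolog_pairs.tsv").write_text(homoeolog.pairs_to_tsv(pairs))

    cds = {gid: s for g in genomes.values() for gid, s in g.cds.items()}
    rows, ks_vals = [], []
    for a, d in sorted(found):
        est = moldiv.ng86(CodonAlignment(cds[a], cds[d]))
        rows.append((a, d, est))
        ks_vals.append(est.Ks)
    lines = ["gene_a\tgene_d\tKa\tKs\tomega"]
    for a, d, e in rows:
        lines.append(f"{a}\t{d}\t{e.Ka:.4f}\t{e.Ks:.4f}\t{e.omega:.4f}")
    (OUT / "kaks_homoeologs.tsv").write_text("\n".join(lines) + "\n")

    clock = ClockParams(2.6e-9)
    hist = moldiv.ks_histogram(ks_vals, 0.001)
    peak = moldiv.find_peak(hist)
    (OUT / "ks_histogram_homoeologs.tsv").write_text(hist.to_tsv())
    print(f"BBH recovered {recovery:.1%} of {len(truth.homoeolog_pairs)} true pairs")
    print(f"At:Dt Ks peak {peak:.4f} (mean {np.mean(ks_vals):.4f}) "
          f"-> divergence {moldiv.clock_convert(peak, clock)/1e6:.2f} Mya")

    # dual-peak recovery at the study's two divergence targets
    genomes2, truth2 = syndata.gen_allopolyploid(
        DivergenceSchedule([("AD", 0.04), ("GbGh", 0.005)]), 500, SEED,
        n_codons=2000, assemble=False)
    cds2 = {gid: s for g in genomes2.values() for gid, s in g.cds.items()}
    for label, prs, target in [
            ("At:Dt", truth2.homoeolog_pairs, 0.04),
            ("GbAt:GhAt", truth2.ortholog_pairs["GbGh_At"], 0.005)]:
        ks = [moldiv.ng86(CodonAlignment(cds2[a], cds2[b])).Ks for a, b in prs]
        pk = moldiv.find_peak(moldiv.ks_histogram(ks, 0.001))
        age = moldiv.clock_convert(pk, clock)
        print(f"{label}: simulated Ks {target} -> peak {pk:.4f}, "
              f"clock date {age/1e6:.2f} Mya")


if __name__ == "__main__":
    main()
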