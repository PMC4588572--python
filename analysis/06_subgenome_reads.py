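#!/usr/bin/env python
"""Partition sequencing reads between the two diploid progenitor references
(A-unique / D-unique / shared / none) and score the labels against the
generator's known read origins.
"""

import collections
from pathlib import Path

from polyevol import homoeolog, syndata
from polyevol.syndata import DivergenceSchedule

SEED = 1
OUT = Path("results")


def main() -> None:
    OUT.mkdir(exist_ok=True)
    genomes, _ = syndata.gen_allopolyploid(
        DivergenceSchedule([("AD", 0.04)]), 60, SEED, n_codons=300)
    reads, truth = syndata.gen_reads(genomes["A"], genomes["D"],
                                     read_len=150, n_reads=300, err=0.01,
                                     seed=SEED)
    labels = homoeolog.partition_sequences(
        {r.id: r.seq for r in reads}, genomes["A"].chroms,
        genomes["D"].chroms, min_identity=0.95, min_cov=0.9, delta=0.02)
    frac = collections.Counter(l.label for l in labels)
    total = len(labels)
    print("label fractions: " + ", ".join(
        f"{k} {v/total:.1%}" for k, v in sorted(frac.items())))

    expected = {"A": "A_unique", "D": "D_unique"}
    scored = correct = 0
    for l in labels:
        if l.label in ("A_unique", "D_unique"):
            scored += 1
            correct += expected[truth.read_origins[l.sequence_id]] == l.label
    print(f"of {scored} uniquely assigned reads, {correct} match their true "
          f"subgenome ({correct/scored:.1%})")
    (OUT / "read_partition.tsv").write_text(
        "read_id\tlabel\tscore_a\tscore_d\ttrue_origin\n" + "".join(
            f"{l.sequence_id}\t{l.label}\t{l.score_a:.0f}\t{l.score_d:.0f}"
            f"\t{truth.read_origins[l.sequence_id]}\n" for l in labels))


if __name__ == "__main__":
    main()
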