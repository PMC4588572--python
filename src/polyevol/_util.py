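"""Shared helpers: deterministic sub-stream RNGs, FASTA/GFF3 round-trip IO."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np


@dataclass
class SequenceRecord:
    """A named sequence (DNA or protein)."""

    id: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GeneModel:
    """An annotated gene: exons are 0-based half-open intervals on ``chrom``.

    Exons are stored in ascending coordinate order regardless of strand; the
    spliced CDS of a minus-strand gene is the reverse complement of the
    concatenated exon sequences read right-to-left.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        self.exons.sort()
        for (a1, b1), (a2, _) in zip(self.exons, self.exons[1:]):
            if a2 < b1:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")

    @property
    def span(self) -> int:
        return self.end - self.start

    def introns(self) -> list[tuple[int, int]]:
        return [(b1, a2) for (_, b1), (a2, _) in zip(self.exons, self.exons[1:])]

    def spliced_cds(self, chrom_seq: str) -> str:
        s = "".join(chrom_seq[a:b] for a, b in self.exons)
        return revcomp(s) if self.strand == "-" else s


_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def substream(seed: int, *tokens) -> np.random.Generator:
    """Derive an independent RNG from a root seed and a path of tokens.

    Hash-based so the stream depends only on (seed, tokens), never on the
    order entities are generated in.
    """
    key = "/".join(str(t) for t in (seed, *tokens)).encode()
    digest = hashlib.blake2b(key, digest_size=16).digest()
    words = [int.from_bytes(digest[i : i + 4], "little") for i in range(0, 16, 4)]
    return np.random.default_rng(np.random.SeedSequence(words))


# ---------------------------------------------------------------------------
# FASTA / GFF3 / TSV plumbing (plain text, round-trip safe)

def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    records: list[SequenceRecord] = []
    name, desc, chunks = None, "", []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    records.append(SequenceRecord(name, "".join(chunks), desc))
                head = line[1:].split(None, 1)
                name = head[0]
                desc = head[1] if len(head) > 1 else ""
                chunks = []
            elif line:
                chunks.append(line)
    if name is not None:
        records.append(SequenceRecord(name, "".join(chunks), desc))
    return records


def write_gff3(models: Sequence[GeneModel], path: str | Path, source: str = "polyevol") -> None:
    """Write gene/exon features; coordinates converted to 1-based inclusive."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            fh.write(
                f"{m.chrom}\t{source}\tgene\t{m.start + 1}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={m.gene_id}\n"
            )
            for i, (a, b) in enumerate(m.exons, 1):
                fh.write(
                    f"{m.chrom}\t{source}\texon\t{a + 1}\t{b}\t.\t{m.strand}\t.\t"
                    f"ID={m.gene_id}.exon{i};Parent={m.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    genes: dict[str, GeneModel] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = line.rstrip(
                "\n"
            ).split("\t")
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = fields["ID"]
                genes[gid] = GeneModel(gid, chrom, int(start) - 1, int(end), strand, [])
            elif ftype == "exon":
                genes[fields["Parent"]].exons.append((int(start) - 1, int(end)))
    for g in genes.values():
        g.exons.sort()
    return list(genes.values())
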