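"""Expression analyses: RPKM quantification, differential calling at
FDR <= 0.001 and |log2 ratio| >= 1, tissue-preferential gene sets,
homoeolog expression bias, and the LTR-proximity expression contrast.

The differential test is a two-sided exact binomial test on pooled counts
against the library-size expectation, with Benjamini–Hochberg correction
across genes.  The significance thresholds (FDR <= 0.001, |log2| >= 1) are
applied exactly as stated; a pseudocount of one read enters only the ratio,
never the test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


class InvalidDesign(ValueError):
    """Experimental design cannot support the requested contrast."""


@dataclass
class ExpressionMatrix:
    """Integer read counts (genes x samples) with gene lengths and library
    sizes; ``samples`` carries per-sample metadata (tissue, stage)."""

    counts: pd.DataFrame                    # genes x samples, int
    gene_length: pd.Series                  # bp per gene
    lib_size: pd.Series                     # total mapped reads per sample
    samples: pd.DataFrame = field(default_factory=pd.DataFrame)  # index = sample

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.gene_length = self.gene_length.reindex(self.counts.index)
        if self.gene_length.isna().any() or (self.gene_length <= 0).any():
            raise ValueError("every gene needs a positive length")
        self.lib_size = self.lib_size.reindex(self.counts.columns)
        if self.lib_size.isna().any() or (self.lib_size <= 0).any():
            raise ValueError("library sizes must be positive")
        if (self.counts.sum(axis=0) > self.lib_size).any():
            raise ValueError("lib_size must be >= column count sum")

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def tissues(self) -> list[str]:
        return sorted(self.samples["tissue"].unique()) if "tissue" in self.samples else []


def rpkm(mat: ExpressionMatrix) -> pd.DataFrame:
    """Reads per kilobase of gene model per million mapped reads:
    10^9 * count / (lib_size * gene_length)."""
    if (mat.lib_size <= 0).any():
        raise ValueError("zero library size")
    denom = np.outer(mat.gene_length.to_numpy(), mat.lib_size.to_numpy())
    return pd.DataFrame(1e9 * mat.counts.to_numpy() / denom,
                        index=mat.counts.index, columns=mat.counts.columns)


def _bh_fdr(pvals: np.ndarray) -> np.ndarray:
    return stats.false_discovery_control(pvals, method="bh")


def _binom_p(k: int, n: int, p0: float) -> float:
    if n == 0:
        return 1.0
    return stats.binomtest(k, n, p0, alternative="two-sided").pvalue


def call_de(mat: ExpressionMatrix, group_a: list[str], group_b: list[str],
            fdr_max: float = 0.001, min_abs_log2: float = 1.0) -> pd.DataFrame:
    """Differential expression between two sample groups.

    Per gene, counts pooled within each group are tested with a two-sided
    exact binomial test against the expected proportion
    lib_a/(lib_a + lib_b); BH-FDR across genes.  ``significant`` requires
    fdr <= fdr_max and |log2_ratio| >= min_abs_log2.  The log2 ratio is taken
    between pooled-group RPKM values with a pseudocount of one read.
    """
    if not group_a or not group_b:
        raise InvalidDesign("both sample groups must be non-empty")
    a = mat.counts[group_a].sum(axis=1).to_numpy()
    b = mat.counts[group_b].sum(axis=1).to_numpy()
    lib_a = float(mat.lib_size[group_a].sum())
    lib_b = float(mat.lib_size[group_b].sum())
    p0 = lib_a / (lib_a + lib_b)
    pvals = np.array([_binom_p(int(ka), int(ka + kb), p0) for ka, kb in zip(a, b)])
    length = mat.gene_length.to_numpy()
    rpkm_a = 1e9 * (a + 1) / (lib_a * length)
    rpkm_b = 1e9 * (b + 1) / (lib_b * length)
    log2_ratio = np.log2(rpkm_a / rpkm_b)
    zero = (a == 0) & (b == 0)
    log2_ratio[zero] = 0.0
    pvals[zero] = 1.0
    fdr = _bh_fdr(pvals)
    sig = (fdr <= fdr_max) & (np.abs(log2_ratio) >= min_abs_log2)
    return pd.DataFrame({"log2_ratio": log2_ratio, "p_value": pvals,
                         "fdr": fdr, "significant": sig}, index=mat.genes)


def preferential_genes(mat: ExpressionMatrix, target_tissue: str,
                       fdr_max: float = 0.001, min_abs_log2: float = 1.0) -> set[str]:
    """Genes specifically or preferentially expressed in one tissue: the
    target-vs-pooled-others contrast is significant AND the target tissue has
    the maximal mean RPKM across tissues."""
    tissues = mat.tissues()
    if len(tissues) < 2:
        raise InvalidDesign("need >= 2 tissues")
    if target_tissue not in tissues:
        raise InvalidDesign(f"unknown tissue {target_tissue!r}")
    target = list(mat.samples.index[mat.samples["tissue"] == target_tissue])
    others = list(mat.samples.index[mat.samples["tissue"] != target_tissue])
    de = call_de(mat, target, others, fdr_max, min_abs_log2)
    up = de["significant"] & (de["log2_ratio"] > 0)
    expr = rpkm(mat)
    tissue_means = expr.T.groupby(mat.samples["tissue"]).mean().T
    is_max = tissue_means.idxmax(axis=1) == target_tissue
    return set(mat.genes[up & is_max])


def homoeolog_bias(pairs: list[tuple[str, str]], mat: ExpressionMatrix,
                   fdr_max: float = 0.001, min_abs_log2: float = 1.0,
                   ) -> pd.DataFrame:
    """Per homoeolog pair: At-vs-Dt expression bias within the same samples.

    Counts of the two copies are pooled across samples and tested with the
    exact binomial test against the gene-length expectation
    p0 = L_At/(L_At + L_Dt) (read counts scale with transcript length);
    BH-FDR across pairs.  Calls: At_biased / Dt_biased / balanced.
    Pairs with a member missing from the matrix are skipped.
    """
    rows, index = [], []
    for ga, gd in pairs:
        if ga not in mat.counts.index or gd not in mat.counts.index:
            continue
        ka = int(mat.counts.loc[ga].sum())
        kd = int(mat.counts.loc[gd].sum())
        la, ld = float(mat.gene_length[ga]), float(mat.gene_length[gd])
        p0 = la / (la + ld)
        p = _binom_p(ka, ka + kd, p0)
        ratio = math.log2(((ka + 1) / la) / ((kd + 1) / ld))
        rows.append((ka, kd, ratio, p))
        index.append((ga, gd))
    if not rows:
        return pd.DataFrame(columns=["at_count", "dt_count", "log2_ratio",
                                     "p_value", "fdr", "call"])
    df = pd.DataFrame(rows, columns=["at_count", "dt_count", "log2_ratio", "p_value"],
                      index=pd.MultiIndex.from_tuples(index, names=["gene_at", "gene_dt"]))
    df["fdr"] = _bh_fdr(df["p_value"].to_numpy())
    sig = (df["fdr"] <= fdr_max) & (df["log2_ratio"].abs() >= min_abs_log2)
    df["call"] = "balanced"
    df.loc[sig & (df["log2_ratio"] >= min_abs_log2), "call"] = "At_biased"
    df.loc[sig & (df["log2_ratio"] <= -min_abs_log2), "call"] = "Dt_biased"
    return df


def ltr_expression_contrast(mat: ExpressionMatrix, flags: dict[str, bool],
                            n_perm: int = 10_000, seed: int = 0,
                            ) -> tuple[float, float, float]:
    """Mean RPKM of LTR-proximal vs LTR-free genes.

    Returns (mean_flagged, mean_unflagged, permutation p) where p is the
    two-sided tail probability of the observed |mean difference| under
    ``n_perm`` random reassignments of the flags.
    """
    expr = rpkm(mat).mean(axis=1)
    flag_vec = np.array([bool(flags.get(g, False)) for g in expr.index])
    if flag_vec.all() or not flag_vec.any():
        raise InvalidDesign("both strata (flagged / unflagged) must be non-empty")
    vals = expr.to_numpy()
    m1, m0 = vals[flag_vec].mean(), vals[~flag_vec].mean()
    obs = abs(m1 - m0)
    rng = np.random.default_rng(seed)
    n_flag = int(flag_vec.sum())
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(vals))[:n_flag]
        sel = np.zeros(len(vals), dtype=bool)
        sel[perm] = True
        d = abs(vals[sel].mean() - vals[~sel].mean())
        if d >= obs:
            hits += 1
    pval = (hits + 1) / (n_perm + 1)
    return float(m1), float(m0), float(pval)


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_counts_tsv(mat: ExpressionMatrix, path) -> None:
    mat.counts.to_csv(path, sep="\t")
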