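"""Expression-side analyses: normalization, ancestral levels, ratio tests,
gametologue balance and tissue specificity.

Ratios are log2 with a 0.1 TPM pseudocount.  "Different from a distribution
with fixed median m" is operationalized as a one-sample Wilcoxon signed-rank
test of (ratios - m) against zero; Benjamini-Hochberg correction is applied
across the family of (tissue x reference-median) tests of one analysis run.
A tissue's dosage-compensation call follows the two fixed references 0
(balanced male/female expression) and -1 (halved male expression):
rejecting only -1 is BALANCED, rejecting only 0 is UNCOMPENSATED, rejecting
both is INTERMEDIATE (partial compensation), rejecting neither is
INCONCLUSIVE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError

PSEUDOCOUNT_TPM = 0.1
EXPRESSION_FLOOR_TPM = 1.0
TSI_SPECIFIC_THRESHOLD = 0.7

BALANCED = "BALANCED"
UNCOMPENSATED = "UNCOMPENSATED"
INTERMEDIATE = "INTERMEDIATE"
INCONCLUSIVE = "INCONCLUSIVE"


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM with sample (sex, tissue, species) and gene
    (chromosome class, orthogroup) metadata."""

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_meta: pd.DataFrame

    def __post_init__(self):
        if (self.values.to_numpy() < 0).any():
            raise ConfigurationError("TPM values must be >= 0")
        missing = set(self.values.columns) - set(self.sample_meta.index)
        if missing:
            raise ConfigurationError(f"samples without metadata: {sorted(missing)}")

    def samples(self, sex: str | None = None, tissue: str | None = None) -> list[str]:
        meta = self.sample_meta
        keep = pd.Series(True, index=meta.index)
        if sex is not None:
            keep &= meta["sex"] == sex
        if tissue is not None:
            keep &= meta["tissue"] == tissue
        return [s for s in self.values.columns if keep.get(s, False)]

    def genes_of_class(self, chrom_class: str) -> list[str]:
        return list(self.gene_meta.index[self.gene_meta["chrom_class"] == chrom_class])

    def to_tsv(self, values_path, sample_meta_path, gene_meta_path):
        self.values.rename_axis("gene_id").to_csv(values_path, sep="\t")
        self.sample_meta.rename_axis("sample_id").to_csv(sample_meta_path, sep="\t")
        self.gene_meta.rename_axis("gene_id").to_csv(gene_meta_path, sep="\t")

    @classmethod
    def from_tsv(cls, values_path, sample_meta_path, gene_meta_path):
        return cls(
            pd.read_csv(values_path, sep="\t", index_col=0),
            pd.read_csv(sample_meta_path, sep="\t", index_col=0),
            pd.read_csv(gene_meta_path, sep="\t", index_col=0),
        )


def median_scale_normalize(matrix: ExpressionMatrix, shared_orthologues) -> ExpressionMatrix:
    """Scale each sample so the median TPM of the shared one-to-one orthologue
    set equals the across-sample grand median of those medians."""
    shared = [g for g in shared_orthologues]
    if not shared:
        raise ConfigurationError("empty shared orthologue set")
    sub = matrix.values.loc[shared]
    if (sub <= 0).any().any():
        raise ConfigurationError(
            "shared orthologues must be expressed (TPM > 0) in every sample"
        )
    medians = sub.median(axis=0)
    grand = medians.median()
    scaled = matrix.values * (grand / medians)
    return ExpressionMatrix(scaled, matrix.sample_meta.copy(), matrix.gene_meta.copy())


def infer_ancestral_expression(orthologue_tpms_by_outgroup) -> tuple[pd.Series, list[str]]:
    """Per-allele ancestral expression: the median across outgroup orthologue
    TPMs, divided by 2 (one gene copy).  Genes without outgroup data are
    flagged and must be excluded from current/ancestral ratios."""
    if isinstance(orthologue_tpms_by_outgroup, pd.DataFrame):
        table = orthologue_tpms_by_outgroup
        medians = table.median(axis=1, skipna=True)
        flagged = list(medians.index[medians.isna()])
        return medians / 2.0, flagged
    out, flagged = {}, []
    for gene, vals in orthologue_tpms_by_outgroup.items():
        vals = [v for v in np.atleast_1d(vals) if np.isfinite(v)]
        if not vals:
            flagged.append(gene)
            out[gene] = np.nan
        else:
            out[gene] = float(np.median(vals)) / 2.0
    return pd.Series(out), flagged


def log2_ratios(
    numerator: pd.Series,
    denominator: pd.Series,
    pseudocount: float = PSEUDOCOUNT_TPM,
    floor: float = EXPRESSION_FLOOR_TPM,
) -> pd.Series:
    """Per-gene log2 ratio with pseudocount; genes below the expression floor
    in both series are excluded (not informative for dosage)."""
    num, den = numerator.align(denominator, join="inner")
    keep = (num >= floor) | (den >= floor)
    num, den = num[keep], den[keep]
    return np.log2((num + pseudocount) / (den + pseudocount))


def ratio_test(ratios, fixed_median: float, alpha: float = 0.05) -> dict:
    """One-sample Wilcoxon signed-rank of (ratios - fixed_median) against 0."""
    arr = np.asarray(ratios, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 5:
        raise ConfigurationError("need at least 5 finite ratios")
    shifted = arr - fixed_median
    if np.all(shifted == 0):
        p = 1.0
    else:
        p = float(stats.wilcoxon(shifted, zero_method="wilcox").pvalue)
    return {
        "n_genes": int(arr.size),
        "median_log2_ratio": float(np.median(arr)),
        "fixed_median": fixed_median,
        "p_raw": p,
        "alpha": alpha,
    }


def _call(reject0: bool, reject_m1: bool) -> str:
    if reject0 and reject_m1:
        return INTERMEDIATE
    if reject0:
        return UNCOMPENSATED
    if reject_m1:
        return BALANCED
    return INCONCLUSIVE


@dataclass
class RatioTestResult:
    tissue: str
    n_genes: int
    median_log2_ratio: float
    p_vs_0: float
    p_vs_minus1: float
    call: str


@dataclass
class DosageResults:
    """Per-tissue male/female dosage-compensation calls with BH-adjusted
    p-values against the fixed medians 0 and -1."""

    results: list[RatioTestResult]
    alpha: float

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(tissue=r.tissue, n_genes=r.n_genes,
                     median_log2_ratio=r.median_log2_ratio,
                     p_vs_0=r.p_vs_0, p_vs_minus1=r.p_vs_minus1, call=r.call)
                for r in self.results
            ]
        )

    def calls(self) -> dict[str, str]:
        return {r.tissue: r.call for r in self.results}


class DosageCompensationAnalysis:
    """Male/female expression-ratio tests for X-linked genes, per tissue.

    Model-fit style entry point: construct from an :class:`ExpressionMatrix`,
    call :meth:`fit`, inspect the returned results object.
    """

    def __init__(self, matrix: ExpressionMatrix, chrom_class: str = "X",
                 references: tuple[float, ...] = (0.0, -1.0)):
        self.matrix = matrix
        self.chrom_class = chrom_class
        self.references = references

    def fit(self, alpha: float = 0.05) -> DosageResults:
        matrix = self.matrix
        genes = matrix.genes_of_class(self.chrom_class)
        if not genes:
            raise ConfigurationError(f"no genes of class {self.chrom_class!r}")
        tissues = sorted(matrix.sample_meta["tissue"].unique())
        fragments = []
        for tissue in tissues:
            males = matrix.samples(sex="male", tissue=tissue)
            females = matrix.samples(sex="female", tissue=tissue)
            if not males or not females:
                continue
            m = matrix.values.loc[genes, males].mean(axis=1)
            f = matrix.values.loc[genes, females].mean(axis=1)
            ratios = log2_ratios(m, f)
            frag = {"tissue": tissue, "ratios": ratios}
            for ref in self.references:
                frag[ref] = ratio_test(ratios, ref, alpha=alpha)
            fragments.append(frag)
        if not fragments:
            raise ConfigurationError("no tissue with both male and female samples")
        raw = [frag[ref]["p_raw"] for frag in fragments for ref in self.references]
        adjusted = multipletests(raw, method="fdr_bh")[1]
        results = []
        i = 0
        for frag in fragments:
            adj = {}
            for ref in self.references:
                adj[ref] = float(adjusted[i])
                i += 1
            results.append(RatioTestResult(
                tissue=frag["tissue"],
                n_genes=frag[self.references[0]]["n_genes"],
                median_log2_ratio=frag[self.references[0]]["median_log2_ratio"],
                p_vs_0=adj.get(0.0, float("nan")),
                p_vs_minus1=adj.get(-1.0, float("nan")),
                call=_call(adj.get(0.0, 1.0) < alpha, adj.get(-1.0, 1.0) < alpha),
            ))
        return DosageResults(results=results, alpha=alpha)


def gametologue_balance(x_male, y_male, x_female,
                        pseudocount: float = PSEUDOCOUNT_TPM):
    """log2((X_male + Y_male) / X_female): near 0 when the added male
    gametologue expression matches the female X output."""
    x_male = np.asarray(x_male, dtype=float)
    y_male = np.asarray(y_male, dtype=float)
    x_female = np.asarray(x_female, dtype=float)
    return np.log2((x_male + y_male + pseudocount) / (x_female + pseudocount))


def tsi(expression_by_tissue) -> float:
    """Tissue-specificity index: the highest tissue TPM divided by the summed
    TPM over all tissues; range [1/T, 1].  NaN (flagged) for all-zero genes."""
    vals = np.asarray(list(expression_by_tissue), dtype=float)
    if vals.size < 2:
        raise ConfigurationError("TSI needs expression in at least 2 tissues")
    if (vals < 0).any():
        raise ConfigurationError("TPM values must be >= 0")
    total = vals.sum()
    if total == 0:
        return float("nan")
    return float(vals.max() / total)


def tsi_table(matrix: ExpressionMatrix, sex: str) -> pd.Series:
    """Per-gene TSI over the tissues of one sex (mean TPM per tissue first)."""
    tissues = sorted(matrix.sample_meta["tissue"].unique())
    per_tissue = pd.DataFrame({
        t: matrix.values[matrix.samples(sex=sex, tissue=t)].mean(axis=1) for t in tissues
    })
    totals = per_tissue.sum(axis=1)
    out = per_tissue.max(axis=1) / totals.where(totals > 0)
    return out
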