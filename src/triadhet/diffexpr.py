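"""Negative-binomial differential expression for F1/parent triads.

Counts are normalized with median-of-ratios size factors, per-gene NB
dispersions are estimated by the method of moments, and each pairwise
contrast (hybrid vs. each parent, parent vs. parent) is tested with a Wald
test on the log of the fitted group means.  A gene is called differentially
expressed when p < ``p_threshold`` (strict) and |log2FC| >= ``lfc_threshold``
(inclusive) — the screening rule applied throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

GENOTYPE_ROLES = ("parent1", "parent2", "hybrid")

#: canonical triad contrasts as (reference group A, group B); log2FC is
#: log2(mean_B / mean_A), so e.g. F1vsP1 > 0 means the hybrid is higher.
TRIAD_CONTRASTS = {
    "F1vsP1": ("parent1", "hybrid"),
    "F1vsP2": ("parent2", "hybrid"),
    "P1vsP2": ("parent2", "parent1"),
}

DISPERSION_FLOOR = 1e-8


@dataclass
class ExpressionMatrix:
    """Gene x sample count matrix with a triad sample design.

    Parameters
    ----------
    counts
        DataFrame of non-negative integer counts, genes as rows (index =
        gene ids), samples as columns.
    design
        DataFrame indexed by sample id with columns ``genotype`` (one of
        ``parent1``/``parent2``/``hybrid``) and ``replicate``.
    """

    counts: pd.DataFrame
    design: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate gene ids in count matrix")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids in count matrix")
        if set(self.counts.columns) != set(self.design.index):
            raise ValueError("count matrix samples and design sheet disagree")
        bad = set(self.design["genotype"]) - set(GENOTYPE_ROLES)
        if bad:
            raise ValueError(f"unknown genotype roles in design: {sorted(bad)}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")
        # keep design in column order of the matrix
        self.design = self.design.loc[self.counts.columns]
        self.design.index.name = "sample_id"

    @property
    def genes(self) -> pd.Index:
        return self.counts.index

    def samples_for(self, role: str) -> list[str]:
        return list(self.design.index[self.design["genotype"] == role])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.counts.loc[genes], self.design.copy())


@dataclass
class DEConfig:
    """Screening thresholds for differential expression calls."""

    p_threshold: float = 0.05
    lfc_threshold: float = 2.0
    use_adjusted: bool = False  # screen on padj instead of raw p
    pseudocount: float = 1.0  # for the displayed log2 fold change only

    def __post_init__(self) -> None:
        if self.p_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValueError("thresholds must be positive")


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_design_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = "sample_id"
    return df


def size_factors(matrix: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, rescaled to geometric mean 1.

    Genes containing any zero count are excluded from the reference
    geometric mean.  If no gene is expressed in every sample, total-count
    factors are used instead (with a warning).
    """
    counts = matrix.counts.to_numpy(dtype=float)
    all_pos = (counts > 0).all(axis=1)
    if not all_pos.any():
        warnings.warn(
            "no gene expressed in all samples; falling back to total-count "
            "size factors",
            RuntimeWarning,
            stacklevel=2,
        )
        totals = counts.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        ref = counts[all_pos]
        log_geo = np.mean(np.log(ref), axis=1)  # per-gene reference
        ratios = np.log(ref) - log_geo[:, None]
        factors = np.exp(np.median(ratios, axis=0))
        factors = factors / np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=matrix.counts.columns, name="size_factor")


def _group_indices(matrix: ExpressionMatrix) -> dict[str, np.ndarray]:
    cols = matrix.counts.columns
    out = {}
    for role in GENOTYPE_ROLES:
        idx = np.flatnonzero((matrix.design["genotype"] == role).to_numpy())
        if idx.size:
            out[role] = idx
    return out


def residual_df(matrix: ExpressionMatrix) -> int:
    """Pooled within-group degrees of freedom (sum of n_g - 1)."""
    return int(sum(len(ix) - 1 for ix in _group_indices(matrix).values()))


def estimate_dispersion(
    matrix: ExpressionMatrix, factors: pd.Series | None = None
) -> pd.Series:
    """Per-gene method-of-moments NB dispersion from within-group moments.

    For each genotype group, phi_g = (s^2 - m) / m^2 on normalized counts;
    the per-gene estimate pools groups weighted by their residual df and is
    floored at 1e-8 (genes with variance <= mean get the floor).
    """
    if factors is None:
        factors = size_factors(matrix)
    norm = matrix.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    num = np.zeros(norm.shape[0])
    den = 0.0
    for role, idx in _group_indices(matrix).items():
        if idx.size < 2:
            continue
        sub = norm[:, idx]
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        w = idx.size - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            phi_g = np.where(m > 0, (v - m) / np.square(m), 0.0)
        num += w * phi_g
        den += w
    if den == 0:
        raise ValueError("dispersion estimation requires >=2 replicates per group")
    phi = np.maximum(num / den, DISPERSION_FLOOR)
    return pd.Series(phi, index=matrix.genes, name="dispersion")


def bh(p: np.ndarray) -> np.ndarray:
    return multipletests(p, method="fdr_bh")[1]


def test_contrast(
    matrix: ExpressionMatrix,
    group_a: str,
    group_b: str,
    config: DEConfig | None = None,
    factors: pd.Series | None = None,
    dispersions: pd.Series | None = None,
    df: int | None = None,
) -> pd.DataFrame:
    """NB Wald test of mean equality between two genotype groups.

    The statistic is log(mu_B) - log(mu_A) over its delta-method standard
    error sqrt((1/mu_A + phi)/n_A + (1/mu_B + phi)/n_B); with few replicates
    the plug-in dispersion has little information, so the reference
    distribution is a t with the pooled residual df rather than a normal.
    Returns a DataFrame indexed by gene with columns baseMeanA, baseMeanB,
    log2FC, p, padj, significant.
    """
    if config is None:
        config = DEConfig()
    if factors is None:
        factors = size_factors(matrix)
    if dispersions is None:
        dispersions = estimate_dispersion(matrix, factors)
    if df is None:
        df = residual_df(matrix)
    groups = _group_indices(matrix)
    for role in (group_a, group_b):
        if role not in groups or len(groups[role]) < 2:
            raise ValueError(f"group {role!r} absent or unreplicated")

    norm = matrix.counts.to_numpy(dtype=float) / factors.to_numpy()[None, :]
    ia, ib = groups[group_a], groups[group_b]
    mu_a = norm[:, ia].mean(axis=1)
    mu_b = norm[:, ib].mean(axis=1)
    phi = dispersions.to_numpy()

    pc = config.pseudocount
    log2fc = np.log2((mu_b + pc) / (mu_a + pc))

    # Wald on fitted means; a 0.5 continuity floor keeps one-sided-zero
    # genes finite without dominating expressed genes.
    both_zero = (mu_a == 0) & (mu_b == 0)
    ta = np.where(mu_a > 0, mu_a, 0.5)
    tb = np.where(mu_b > 0, mu_b, 0.5)
    delta = np.log(tb) - np.log(ta)
    se = np.sqrt((1.0 / ta + phi) / len(ia) + (1.0 / tb + phi) / len(ib))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = delta / se
    p = 2.0 * stats.t.sf(np.abs(wald), df)
    p = np.clip(p, 0.0, 1.0)
    p[both_zero] = 1.0
    log2fc[both_zero] = 0.0

    padj = bh(p)
    screen_p = padj if config.use_adjusted else p
    significant = (screen_p < config.p_threshold) & (
        np.abs(log2fc) >= config.lfc_threshold
    )
    return pd.DataFrame(
        {
            "baseMeanA": mu_a,
            "baseMeanB": mu_b,
            "log2FC": log2fc,
            "p": p,
            "padj": padj,
            "significant": significant,
        },
        index=matrix.genes,
    )


def detection_filter(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Keep genes detected (nonzero mean) in every genotype group."""
    counts = matrix.counts.to_numpy(dtype=float)
    keep = np.ones(counts.shape[0], dtype=bool)
    for role, idx in _group_indices(matrix).items():
        keep &= counts[:, idx].mean(axis=1) > 0
    return matrix.subset_genes(matrix.genes[keep])


def triad_de(
    matrix: ExpressionMatrix,
    config: DEConfig | None = None,
    prefilter: bool = True,
) -> dict[str, pd.DataFrame]:
    """Run the three triad contrasts with shared size factors and dispersions.

    Genes are first restricted to those detected in all three genotypes
    (the triad intersection); set ``prefilter=False`` to test every gene.
    """
    if config is None:
        config = DEConfig()
    if prefilter:
        matrix = detection_filter(matrix)
    factors = size_factors(matrix)
    dispersions = estimate_dispersion(matrix, factors)
    df = residual_df(matrix)
    return {
        name: test_contrast(matrix, a, b, config, factors, dispersions, df)
        for name, (a, b) in TRIAD_CONTRASTS.items()
    }


def deg_set(result: pd.DataFrame) -> set[str]:
    return set(result.index[result["significant"]])


def venn_counts(set_a: set, set_b: set, set_c: set) -> dict[str, int]:
    """Seven-region counts of a three-set Venn diagram."""
    a, b, c = set(set_a), set(set_b), set(set_c)
    abc = a & b & c
    ab = (a & b) - abc
    ac = (a & c) - abc
    bc = (b & c) - abc
    return {
        "A_only": len(a - b - c),
        "B_only": len(b - a - c),
        "C_only": len(c - a - b),
        "AB": len(ab),
        "AC": len(ac),
        "BC": len(bc),
        "ABC": len(abc),
    }
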