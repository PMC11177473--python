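"""2^-ddCt relative quantification and RNA-seq concordance.

Relative expression of a target gene in a genotype, against a reference
gene and a calibrator genotype, is 2**(-ddCt) with
dCt = Ct_target - Ct_reference (replicate-averaged per genotype) and
ddCt = dCt_genotype - dCt_calibrator.  Amplification efficiency is fixed at
2 per the method's definition; no efficiency correction is applied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


def read_ct_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def ddct(
    table: pd.DataFrame,
    calibrator: str,
    reference_gene: str | None = None,
) -> pd.DataFrame:
    """Relative expression 2^-ddCt per (gene, genotype).

    ``table`` needs columns gene, genotype, replicate, Ct and either an
    ``is_reference`` boolean column or an explicit ``reference_gene``.
    Replicate Cts are averaged before dCt.  The calibrator genotype maps to
    exactly 1.0 for every gene.  Returns columns gene, genotype, ddCt, fold.
    """
    table = table.copy()
    if reference_gene is None:
        if "is_reference" not in table.columns:
            raise ValueError("provide reference_gene or an is_reference column")
        refs = set(table.loc[table["is_reference"].astype(bool), "gene"])
        if len(refs) != 1:
            raise ValueError(f"expected exactly one reference gene, found {sorted(refs)}")
        (reference_gene,) = refs
    mean_ct = table.groupby(["gene", "genotype"])["Ct"].mean()
    genotypes = sorted(table["genotype"].unique())
    if calibrator not in genotypes:
        raise ValueError(f"calibrator genotype {calibrator!r} not in table")
    for gt in genotypes:
        if (reference_gene, gt) not in mean_ct.index:
            raise ValueError(f"reference gene Ct missing for sample {gt!r}")

    rows = []
    targets = [g for g in table["gene"].unique() if g != reference_gene]
    for gene in targets:
        if (gene, calibrator) not in mean_ct.index:
            raise ValueError(f"calibrator Ct missing for gene {gene!r}")
        dct_cal = mean_ct[(gene, calibrator)] - mean_ct[(reference_gene, calibrator)]
        for gt in genotypes:
            if (gene, gt) not in mean_ct.index:
                continue
            dct = mean_ct[(gene, gt)] - mean_ct[(reference_gene, gt)]
            dd = dct - dct_cal
            rows.append((gene, gt, dd, 2.0 ** (-dd)))
    return pd.DataFrame(rows, columns=["gene", "genotype", "ddCt", "fold"])


def concordance(
    qpcr_folds: dict[str, float], rnaseq_folds: dict[str, float]
) -> tuple[float, float]:
    """Direction agreement and Spearman correlation of two fold maps.

    Folds are relative to the same calibrator; direction is the sign of the
    log2 fold.  Requires >= 3 shared genes.  Returns (agreement fraction,
    Spearman rho of log2 folds).
    """
    shared = sorted(set(qpcr_folds) & set(rnaseq_folds))
    if len(shared) < 3:
        raise ValueError(f"need >=3 shared genes, got {len(shared)}")
    a = np.log2([qpcr_folds[g] for g in shared])
    b = np.log2([rnaseq_folds[g] for g in shared])
    agreement = float(np.mean(np.sign(a) == np.sign(b)))
    rho = float(stats.spearmanr(a, b).statistic)
    return agreement, rho
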