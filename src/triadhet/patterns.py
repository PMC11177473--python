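"""Classification of triad DEGs into the 12 expression patterns.

The F1 expression level of a differentially expressed gene is placed
relative to its two parents using the three triad contrasts:

* additive (P1-P2): parents differ, the F1 differs from both and sits
  strictly between the parental means (mid-parent expression);
* dominant (P3-P6): parents differ and the F1 is statistically
  indistinguishable from exactly one parent (expression-level dominance);
* overdominant down (P7-P9): F1 significantly below both parents;
* overdominant up (P10-P12): F1 significantly above both parents
  (transgressive expression).

"Significantly different" means the corresponding contrast passes the DE
screen (p and |log2FC| thresholds), so classification uses exactly the same
machinery as the DEG calls.  Sub-codes within a category record the
parental relationship: whether parent1 is below (P10/P7), indistinguishable
from (P11/P8) or above (P12/P9) parent2, and for dominance which parent is
matched and whether it is the high or the low parent.  The sub-code
numbering is this package's convention; swapping the parent labels maps
P1<->P2, P3<->P4, P5<->P6, P7<->P9, P10<->P12 and fixes P8/P11.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

PATTERN_CODES = tuple(f"P{i}" for i in range(1, 13)) + ("UNCLASSIFIED",)

CATEGORY_OF = {
    "P1": "additive",
    "P2": "additive",
    "P3": "dominant",
    "P4": "dominant",
    "P5": "dominant",
    "P6": "dominant",
    "P7": "overdominant_down",
    "P8": "overdominant_down",
    "P9": "overdominant_down",
    "P10": "overdominant_up",
    "P11": "overdominant_up",
    "P12": "overdominant_up",
    "UNCLASSIFIED": "unclassified",
}

CATEGORIES = ("additive", "dominant", "overdominant_down", "overdominant_up")

#: code image under exchanging the two parent labels
PARENT_SWAP = {
    "P1": "P2", "P2": "P1",
    "P3": "P4", "P4": "P3",
    "P5": "P6", "P6": "P5",
    "P7": "P9", "P8": "P8", "P9": "P7",
    "P10": "P12", "P11": "P11", "P12": "P10",
    "UNCLASSIFIED": "UNCLASSIFIED",
}


@dataclass(frozen=True)
class TriadCalls:
    """Per-gene significance calls and genotype means for one gene.

    ``*_sig`` flags come from the DE screen; ``*_up`` is the sign of the
    contrast's log2FC (F1vsP1 up means F1 > parent1; P1vsP2 up means
    parent1 > parent2) and is only meaningful when the flag is set.
    """

    f1p1_sig: bool
    f1p1_up: bool
    f1p2_sig: bool
    f1p2_up: bool
    p1p2_sig: bool
    p1p2_up: bool
    mean_p1: float
    mean_f1: float
    mean_p2: float


def classify_gene(calls: TriadCalls) -> str:
    """Assign the expression-pattern code for one DEG.

    Genes with no significant contrast are UNCLASSIFIED (they would not be
    DEGs in the first place).
    """
    c = calls
    if c.f1p1_sig and c.f1p2_sig and c.f1p1_up and c.f1p2_up:
        # F1 above both parents: up-regulated overdominance
        if not c.p1p2_sig:
            return "P11"
        return "P12" if c.p1p2_up else "P10"
    if c.f1p1_sig and c.f1p2_sig and not c.f1p1_up and not c.f1p2_up:
        # F1 below both parents: down-regulated overdominance
        if not c.p1p2_sig:
            return "P8"
        return "P9" if c.p1p2_up else "P7"
    if c.p1p2_sig and (c.f1p1_sig != c.f1p2_sig):
        # expression-level dominance: F1 matches exactly one parent
        matched_p1 = not c.f1p1_sig
        p1_high = c.p1p2_up
        if matched_p1:
            return "P3" if p1_high else "P5"
        return "P6" if p1_high else "P4"
    if (
        c.p1p2_sig
        and c.f1p1_sig
        and c.f1p2_sig
        and min(c.mean_p1, c.mean_p2) < c.mean_f1 < max(c.mean_p1, c.mean_p2)
    ):
        # mid-parent (additive) expression
        return "P1" if c.mean_p1 > c.mean_p2 else "P2"
    return "UNCLASSIFIED"


def triad_calls_table(
    de_results: dict[str, pd.DataFrame], deg_policy: str = "union"
) -> pd.DataFrame:
    """Assemble per-gene calls from the three contrast result tables.

    ``deg_policy`` selects which genes are classified: ``"union"`` (default)
    classifies every gene significant in at least one contrast;
    ``"hybrid"`` restricts to genes significant in a hybrid-vs-parent
    contrast.
    """
    f1p1, f1p2, p1p2 = (
        de_results["F1vsP1"],
        de_results["F1vsP2"],
        de_results["P1vsP2"],
    )
    genes = f1p1.index
    if not (genes.equals(f1p2.index) and genes.equals(p1p2.index)):
        raise ValueError("contrast tables must share the same gene index")
    tbl = pd.DataFrame(
        {
            "f1p1_sig": f1p1["significant"],
            "f1p1_up": f1p1["log2FC"] > 0,
            "f1p2_sig": f1p2["significant"],
            "f1p2_up": f1p2["log2FC"] > 0,
            "p1p2_sig": p1p2["significant"],
            "p1p2_up": p1p2["log2FC"] > 0,
            "mean_p1": f1p1["baseMeanA"],
            "mean_f1": f1p1["baseMeanB"],
            "mean_p2": f1p2["baseMeanA"],
        },
        index=genes,
    )
    if deg_policy == "union":
        keep = tbl["f1p1_sig"] | tbl["f1p2_sig"] | tbl["p1p2_sig"]
    elif deg_policy == "hybrid":
        keep = tbl["f1p1_sig"] | tbl["f1p2_sig"]
    else:
        raise ValueError(f"unknown deg_policy {deg_policy!r}")
    return tbl[keep]


def classify_table(
    de_results: dict[str, pd.DataFrame], deg_policy: str = "union"
) -> pd.DataFrame:
    """Classify every DEG; returns columns ``code`` and ``category``."""
    tbl = triad_calls_table(de_results, deg_policy)
    codes = _classify_vectorized(tbl)
    return pd.DataFrame(
        {"code": codes, "category": [CATEGORY_OF[c] for c in codes]},
        index=tbl.index,
    )


def _classify_vectorized(tbl: pd.DataFrame) -> np.ndarray:
    """Vectorized equivalent of :func:`classify_gene` over a calls table."""
    s1 = tbl["f1p1_sig"].to_numpy()
    u1 = tbl["f1p1_up"].to_numpy()
    s2 = tbl["f1p2_sig"].to_numpy()
    u2 = tbl["f1p2_up"].to_numpy()
    sp = tbl["p1p2_sig"].to_numpy()
    up = tbl["p1p2_up"].to_numpy()
    mp1 = tbl["mean_p1"].to_numpy()
    mf1 = tbl["mean_f1"].to_numpy()
    mp2 = tbl["mean_p2"].to_numpy()

    out = np.full(len(tbl), "UNCLASSIFIED", dtype=object)
    od_up = s1 & s2 & u1 & u2
    od_dn = s1 & s2 & ~u1 & ~u2
    out[od_up & ~sp] = "P11"
    out[od_up & sp & up] = "P12"
    out[od_up & sp & ~up] = "P10"
    out[od_dn & ~sp] = "P8"
    out[od_dn & sp & up] = "P9"
    out[od_dn & sp & ~up] = "P7"
    dom = ~od_up & ~od_dn & sp & (s1 != s2)
    out[dom & ~s1 & up] = "P3"
    out[dom & ~s1 & ~up] = "P5"
    out[dom & s1 & up] = "P6"
    out[dom & s1 & ~up] = "P4"
    between = (np.minimum(mp1, mp2) < mf1) & (mf1 < np.maximum(mp1, mp2))
    add = ~od_up & ~od_dn & sp & s1 & s2 & between
    out[add & (mp1 > mp2)] = "P1"
    out[add & (mp1 <= mp2) & (mp1 != mp2)] = "P2"
    return out


@dataclass
class PatternSummary:
    """Counts and percentages per code and per category over classified DEGs."""

    by_code: pd.DataFrame
    by_category: pd.DataFrame
    n_classified: int
    n_unclassified: int


def summarize_patterns(codes: pd.Series) -> PatternSummary:
    """Tally pattern codes; percentages are over classified genes only."""
    if len(codes) == 0:
        raise ValueError("no pattern codes to summarize")
    codes = pd.Series(codes)
    n_uncl = int((codes == "UNCLASSIFIED").sum())
    classified = codes[codes != "UNCLASSIFIED"]
    n_cls = len(classified)

    code_counts = classified.value_counts().reindex(
        [c for c in PATTERN_CODES if c != "UNCLASSIFIED"], fill_value=0
    )
    by_code = pd.DataFrame(
        {
            "count": code_counts,
            "pct": 100.0 * code_counts / n_cls if n_cls else 0.0,
        }
    )
    cat = classified.map(CATEGORY_OF)
    cat_counts = cat.value_counts().reindex(CATEGORIES, fill_value=0)
    by_category = pd.DataFrame(
        {
            "count": cat_counts,
            "pct": 100.0 * cat_counts / n_cls if n_cls else 0.0,
        }
    )
    return PatternSummary(by_code, by_category, n_cls, n_uncl)
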