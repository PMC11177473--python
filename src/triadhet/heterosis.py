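"""Mid-parent heterosis and Duncan multiple-range letters for trait tables.

Mid-parent heterosis of a hybrid is MPH(%) = ((F1 - MP) / MP) x 100, where
F1 is the hybrid trait mean and MP the average of its two parents' means.
The module computes MPH time series from long-format trait tables, the
consecutive-interval trend deltas that locate the key period of heterosis
formation, and Duncan's new multiple-range-test letter groupings across
varieties at a given timepoint.  The same machinery serves any replicated
trait (leaf dry-weight biomass, net photosynthetic rate, stomatal
conductance, ...): the trait is a column, not a type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

TRAIT_COLUMNS = ["variety", "parent1", "parent2", "day", "replicate", "value"]


def read_trait_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    df["parent1"] = df["parent1"].astype(str)
    df["parent2"] = df["parent2"].astype(str)
    return df


def _maybe_filter_trait(table: pd.DataFrame, trait: str | None) -> pd.DataFrame:
    if trait is not None and "trait" in table.columns:
        table = table[table["trait"] == trait]
        if table.empty:
            raise ValueError(f"no rows for trait {trait!r}")
    return table


def mph(f1: float, mp: float) -> float:
    """Mid-parent heterosis in percent: ((F1 - MP) / MP) x 100."""
    if mp <= 0:
        raise ValueError(f"mid-parent value must be positive, got {mp}")
    return (f1 - mp) / mp * 100.0


def mph_series(table: pd.DataFrame, trait: str | None = None) -> pd.DataFrame:
    """One heterosis record per hybrid x day.

    F1 and the parental values entering MP are replicate means.  A hybrid
    whose parent is missing at a day is skipped with a logged warning.
    Returns columns hybrid, day, F1, MP, MPH_pct.
    """
    table = _maybe_filter_trait(table, trait)
    means = table.groupby(["variety", "day"])["value"].mean()
    is_hybrid = (table["parent1"].astype(str) != "") & (
        table["parent2"].astype(str) != ""
    )
    pairs = (
        table[is_hybrid]
        .drop_duplicates("variety")
        .set_index("variety")[["parent1", "parent2"]]
    )
    rows = []
    for hyb, (p1, p2) in pairs.iterrows():
        days = sorted(table.loc[table["variety"] == hyb, "day"].unique())
        for day in days:
            if (p1, day) not in means.index or (p2, day) not in means.index:
                logger.warning(
                    "skipping %s at day %s: parent measurement missing", hyb, day
                )
                continue
            f1 = means[(hyb, day)]
            mp = 0.5 * (means[(p1, day)] + means[(p2, day)])
            rows.append((hyb, day, f1, mp, mph(f1, mp)))
    return pd.DataFrame(rows, columns=["hybrid", "day", "F1", "MP", "MPH_pct"])


def trend_deltas(series: pd.DataFrame) -> pd.DataFrame:
    """Consecutive-interval changes in MPH, flagging each hybrid's key period.

    Returns columns hybrid, day_from, day_to, delta_points, key_period.
    The key period is the interval of maximum MPH increase (earliest
    interval on exact ties); if no interval shows an increase, none is
    flagged.  Hybrids with a single timepoint yield no rows.
    """
    rows = []
    for hyb, grp in series.groupby("hybrid", sort=False):
        grp = grp.sort_values("day")
        if len(grp) < 2:
            continue
        days = grp["day"].to_numpy()
        vals = grp["MPH_pct"].to_numpy()
        deltas = np.diff(vals)
        key_idx = -1
        if (deltas > 0).any():
            key_idx = int(np.argmax(deltas))  # argmax takes the earliest tie
        for i, d in enumerate(deltas):
            rows.append((hyb, days[i], days[i + 1], d, i == key_idx))
    return pd.DataFrame(
        rows, columns=["hybrid", "day_from", "day_to", "delta_points", "key_period"]
    )


def mean_trend_deltas(series: pd.DataFrame) -> pd.DataFrame:
    """Across-hybrid mean MPH per day and mean consecutive deltas."""
    mean_series = (
        series.groupby("day")["MPH_pct"].mean().reset_index().assign(hybrid="ALL")
    )
    mean_series["F1"] = np.nan
    mean_series["MP"] = np.nan
    return trend_deltas(mean_series)


# ---------------------------------------------------------------------------
# Duncan's new multiple range test
# ---------------------------------------------------------------------------


@dataclass
class LetterGrouping:
    """Compact letter display: varieties sharing no letter differ at alpha."""

    letters: dict[str, str]
    means: dict[str, float]
    alpha: float


def _duncan_lsr(p: int, df: int, alpha: float, se: float) -> float:
    """Least significant range for a stretch of p ordered means.

    Duncan's protection level alpha_p = 1 - (1 - alpha)^(p - 1) applied to
    the studentized range distribution.
    """
    q = stats.studentized_range.ppf((1.0 - alpha) ** (p - 1), p, df)
    return float(q) * se


def duncan_letters(
    table: pd.DataFrame,
    day: int | None = None,
    alpha: float = 0.05,
    trait: str | None = None,
    group_col: str = "variety",
    value_col: str = "value",
) -> LetterGrouping:
    """Duncan multiple-range-test letters across varieties at one timepoint.

    One-way ANOVA supplies the pooled error mean square; means are sorted
    descending and a stretch of p means is homogeneous when its range does
    not exceed LSR_p = q'(p, df, alpha) * sqrt(MSE/n) (harmonic-mean n for
    unbalanced groups).  Once a stretch is declared homogeneous no stretch
    inside it is split — the standard range-test protection rule.  The
    variety with the largest mean always holds letter "a".
    """
    table = _maybe_filter_trait(table, trait)
    if day is not None:
        table = table[table["day"] == day]
    groups = {g: sub[value_col].to_numpy(dtype=float) for g, sub in table.groupby(group_col)}
    if len(groups) < 2:
        raise ValueError("need at least two varieties")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("need >=2 replicates per variety")

    names = sorted(groups, key=lambda g: -np.mean(groups[g]))
    means = np.array([np.mean(groups[g]) for g in names])
    ns = np.array([len(groups[g]) for g in names])
    df = int(ns.sum() - len(names))
    sse = sum(((groups[g] - np.mean(groups[g])) ** 2).sum() for g in names)
    mse = sse / df
    n_h = len(ns) / np.sum(1.0 / ns)  # harmonic mean group size
    se = np.sqrt(mse / n_h)

    k = len(names)
    # homogeneous[i][j]: stretch i..j declared not significantly different
    homogeneous = np.zeros((k, k), dtype=bool)
    np.fill_diagonal(homogeneous, True)
    for p in range(k, 1, -1):
        lsr = _duncan_lsr(p, df, alpha, se) if mse > 0 else 0.0
        for i in range(0, k - p + 1):
            j = i + p - 1
            if homogeneous[i, j]:
                continue
            inside = any(
                homogeneous[a, b]
                for a in range(0, i + 1)
                for b in range(j, k)
                if (a, b) != (i, j) and b - a >= p
            )
            if inside:
                homogeneous[i, j] = True
                continue
            if means[i] - means[j] <= lsr:
                homogeneous[i, j] = True
    # reach[i]: furthest j with stretch i..j homogeneous (interval property)
    reach = np.arange(k)
    for i in range(k):
        for j in range(k - 1, i, -1):
            if homogeneous[i, j]:
                reach[i] = j
                break

    letters = {name: "" for name in names}
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letter_i = 0
    prev_end = -1
    for i in range(k):
        j = int(reach[i])
        if j <= prev_end and i > 0:
            continue  # interval contained in an already-lettered one
        symbol = alphabet[letter_i % 26] * (letter_i // 26 + 1)
        for m in range(i, j + 1):
            letters[names[m]] += symbol
        letter_i += 1
        prev_end = j
    return LetterGrouping(
        letters=letters,
        means={name: float(np.mean(groups[name])) for name in names},
        alpha=alpha,
    )
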