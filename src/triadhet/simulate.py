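"""Synthetic triad RNA-seq counts and multi-variety trait time courses.

Every downstream stage of the package is testable without external
downloads: :func:`simulate_triad` draws a negative-binomial count matrix
for a parent1/parent2/hybrid triad in which each gene realizes a known
expression pattern (additive, dominant, overdominant up/down, or flat), and
:func:`simulate_biomass` draws replicate trait measurements for a panel of
parents and hybrids whose mid-parent heterosis follows a designed schedule.

The defaults emulate the study conditions the package targets: a triad with
three biological replicates, 13,587 genes detected in all three genotypes,
a DEG compartment whose category shares are 0.13% additive / 23.18%
dominant / 76.69% overdominant, and a panel of five parents crossed into
six hybrids whose leaf biomass is measured at 38-66 days after
transplanting with a heterosis peak forming over days 45-52.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import ExpressionMatrix
from .patterns import CATEGORY_OF, PATTERN_CODES

# ---------------------------------------------------------------------------
# triad count simulation
# ---------------------------------------------------------------------------

#: DEG category shares among classified genes (additive, dominant,
#: overdominant) used by the default pattern proportions.
DEFAULT_CATEGORY_SHARES = {"additive": 0.0013, "dominant": 0.2318, "overdominant": 0.7669}

DEFAULT_N_GENES = 13587


def default_pattern_proportions(deg_fraction: float = 0.30) -> dict[str, float]:
    """Pattern proportions with paper-like category shares among DEGs.

    ``deg_fraction`` of genes carry a designed pattern (split across the
    P1-P12 codes with additive/dominant/overdominant shares of
    0.13/23.18/76.69% and equal weight within each category); the rest are
    flat (UNCLASSIFIED).
    """
    if not 0 < deg_fraction <= 1:
        raise ValueError("deg_fraction must be in (0, 1]")
    s = DEFAULT_CATEGORY_SHARES
    props: dict[str, float] = {}
    for code in ("P1", "P2"):
        props[code] = deg_fraction * s["additive"] / 2
    for code in ("P3", "P4", "P5", "P6"):
        props[code] = deg_fraction * s["dominant"] / 4
    for code in ("P7", "P8", "P9", "P10", "P11", "P12"):
        props[code] = deg_fraction * s["overdominant"] / 6
    props["UNCLASSIFIED"] = 1.0 - sum(props.values())
    return props


@dataclass
class TriadSimConfig:
    """Design of a synthetic triad count matrix.

    ``effect_log2fc`` is the designed log2 separation between "different"
    expression states; ``dispersion`` the global NB dispersion phi in
    Var = mu + phi mu^2; ``base_mean_log_range`` the natural-log range from
    which baseline gene abundances are drawn.
    """

    n_genes: int = DEFAULT_N_GENES
    n_reps: int = 3
    pattern_proportions: dict[str, float] = field(
        default_factory=default_pattern_proportions
    )
    base_mean_log_range: tuple[float, float] = (math.log(50.0), math.log(5000.0))
    effect_log2fc: float = 3.0
    dispersion: float = 0.05
    libsize_factors: np.ndarray | None = None  # per-sample, default all 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if self.n_reps < 2:
            raise ValueError("n_reps must be >= 2 (DE testing needs replication)")
        if self.effect_log2fc <= 0:
            raise ValueError("effect_log2fc must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        unknown = set(self.pattern_proportions) - set(PATTERN_CODES)
        if unknown:
            raise ValueError(f"unknown pattern codes: {sorted(unknown)}")
        total = sum(self.pattern_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern_proportions sum to {total}, not 1")
        if self.libsize_factors is not None:
            lf = np.asarray(self.libsize_factors, dtype=float)
            if lf.shape != (3 * self.n_reps,) or (lf <= 0).any():
                raise ValueError(
                    "libsize_factors must be positive with one entry per sample"
                )
            self.libsize_factors = lf


def lognormal_libsize_factors(
    n_samples: int, sigma: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Log-normal(0, sigma) library-size factors (exercises normalization)."""
    return np.random.default_rng(seed).lognormal(0.0, sigma, n_samples)


@dataclass
class SyntheticTriad:
    counts: ExpressionMatrix
    truth: pd.Series  # gene -> pattern code


def _pattern_counts(proportions: dict[str, float], n_genes: int) -> dict[str, int]:
    """Largest-remainder apportionment of genes to patterns."""
    items = [(code, proportions[code]) for code in PATTERN_CODES if code in proportions]
    raw = [(code, p * n_genes) for code, p in items]
    base = {code: int(math.floor(x)) for code, x in raw}
    short = n_genes - sum(base.values())
    remainders = sorted(raw, key=lambda cx: (cx[1] - math.floor(cx[1]), cx[0]), reverse=True)
    for code, _ in remainders[:short]:
        base[code] += 1
    return base


def _pattern_means(code: str, base: float, fold: float) -> tuple[float, float, float]:
    """Designed (mu_P1, mu_F1, mu_P2) for one gene.

    ``fold`` = 2**effect_log2fc.  Dominant F1 means equal the matched
    parental mean exactly; additive F1 means are the arithmetic mid-parent;
    overdominant F1 means exceed (or undercut) both parents by ``fold``.
    """
    b, e = base, fold
    if code == "P1":  # additive, parent1 high
        return b * e, (b * e + b) / 2.0, b
    if code == "P2":
        return b, (b * e + b) / 2.0, b * e
    if code == "P3":  # dominance toward parent1, parent1 high
        return b * e, b * e, b
    if code == "P4":  # toward parent2, parent2 high
        return b, b * e, b * e
    if code == "P5":  # toward parent1, parent1 low
        return b, b, b * e
    if code == "P6":  # toward parent2, parent2 low
        return b * e, b, b
    if code == "P7":  # down-overdominant, parent1 < parent2
        return b, b / e, b * e
    if code == "P8":
        return b, b / e, b
    if code == "P9":
        return b * e, b / e, b
    if code == "P10":  # up-overdominant, parent1 < parent2
        return b, b * e * e, b * e
    if code == "P11":
        return b, b * e, b
    if code == "P12":
        return b * e, b * e * e, b
    return b, b, b  # UNCLASSIFIED: flat


def designed_means(config: TriadSimConfig) -> tuple[pd.DataFrame, pd.Series]:
    """Per-gene designed genotype means and truth labels (deterministic)."""
    rng = np.random.default_rng(config.seed)
    counts_per = _pattern_counts(config.pattern_proportions, config.n_genes)
    codes: list[str] = []
    for code in PATTERN_CODES:
        codes.extend([code] * counts_per.get(code, 0))
    lo, hi = config.base_mean_log_range
    base = np.exp(rng.uniform(lo, hi, config.n_genes))
    fold = 2.0 ** config.effect_log2fc
    mus = np.array(
        [_pattern_means(c, b, fold) for c, b in zip(codes, base)], dtype=float
    )
    genes = pd.Index([f"gene{i:05d}" for i in range(config.n_genes)], name="gene_id")
    means = pd.DataFrame(mus, index=genes, columns=["parent1", "hybrid", "parent2"])
    truth = pd.Series(codes, index=genes, name="pattern_code")
    return means, truth


def simulate_triad(config: TriadSimConfig) -> SyntheticTriad:
    """Draw NB counts realizing each gene's assigned expression pattern.

    Replicate counts are NB(mean = mu * libsize_factor, dispersion phi);
    identical seeds give identical output.
    """
    means, truth = designed_means(config)
    rng = np.random.default_rng(config.seed)
    rng.uniform(size=config.n_genes)  # consume the base-mean draw stream

    roles = ["parent1", "parent2", "hybrid"]
    sample_ids = [
        f"{role}_r{r + 1}" for role in roles for r in range(config.n_reps)
    ]
    lf = (
        np.ones(len(sample_ids))
        if config.libsize_factors is None
        else config.libsize_factors
    )
    mu = np.column_stack(
        [means[role].to_numpy() for role in roles for _ in range(config.n_reps)]
    )
    mu = mu * lf[None, :]
    phi = config.dispersion
    r = 1.0 / phi
    p = 1.0 / (1.0 + phi * mu)
    counts = rng.negative_binomial(r, p)

    counts_df = pd.DataFrame(counts, index=means.index, columns=sample_ids)
    design = pd.DataFrame(
        {
            "genotype": [role for role in roles for _ in range(config.n_reps)],
            "replicate": [r + 1 for _ in roles for r in range(config.n_reps)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    return SyntheticTriad(ExpressionMatrix(counts_df, design), truth)


# ---------------------------------------------------------------------------
# trait time-course simulation
# ---------------------------------------------------------------------------

DEFAULT_TIMEPOINTS = (38, 45, 52, 59, 66)


@dataclass
class BiomassSimConfig:
    """Design of a multi-variety trait time course with scheduled heterosis.

    Parent means follow logistic growth curves value(t) =
    asymptote / (1 + exp(-rate (t - midpoint))); each hybrid mean equals
    the mid-parent value scaled by (1 + MPH/100) from ``mph_schedule``.
    Replicates carry multiplicative log-normal noise with coefficient of
    variation ``noise_cv`` (mean exactly 1, so designed MPH is unbiased).
    """

    parents: dict[str, tuple[float, float, float]]  # name -> (asym, rate, mid)
    hybrids: dict[str, tuple[str, str]]  # name -> (parent1, parent2)
    mph_schedule: dict[tuple[str, int], float]  # (hybrid, day) -> MPH %
    timepoints_days: tuple[int, ...] = DEFAULT_TIMEPOINTS
    noise_cv: float = 0.05
    n_reps: int = 3
    trait: str = "biomass"
    seed: int = 0

    def __post_init__(self) -> None:
        tp = tuple(self.timepoints_days)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise ValueError("timepoints must be strictly increasing")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        for hyb, (p1, p2) in self.hybrids.items():
            for p in (p1, p2):
                if p not in self.parents:
                    raise ValueError(f"hybrid {hyb!r} references unknown parent {p!r}")


def _logistic(t: float, asym: float, rate: float, mid: float) -> float:
    return asym / (1.0 + math.exp(-rate * (t - mid)))


def simulate_biomass(config: BiomassSimConfig) -> pd.DataFrame:
    """Long-format trait table (variety, parent1, parent2, day, replicate, value)."""
    rng = np.random.default_rng(config.seed)
    cv = config.noise_cv
    sigma = math.sqrt(math.log(1.0 + cv * cv)) if cv > 0 else 0.0

    rows = []
    parent_means: dict[tuple[str, int], float] = {}
    for name, (asym, rate, mid) in config.parents.items():
        for day in config.timepoints_days:
            parent_means[(name, day)] = _logistic(day, asym, rate, mid)
    for name in config.parents:
        for day in config.timepoints_days:
            m = parent_means[(name, day)]
            for rep in range(1, config.n_reps + 1):
                noise = rng.lognormal(-0.5 * sigma * sigma, sigma) if sigma else 1.0
                rows.append((name, "", "", day, rep, m * noise))
    for name, (p1, p2) in config.hybrids.items():
        for day in config.timepoints_days:
            mp = 0.5 * (parent_means[(p1, day)] + parent_means[(p2, day)])
            mph = config.mph_schedule.get((name, day), 0.0)
            m = mp * (1.0 + mph / 100.0)
            for rep in range(1, config.n_reps + 1):
                noise = rng.lognormal(-0.5 * sigma * sigma, sigma) if sigma else 1.0
                rows.append((name, p1, p2, day, rep, m * noise))
    df = pd.DataFrame(
        rows, columns=["variety", "parent1", "parent2", "day", "replicate", "value"]
    )
    df.insert(0, "trait", config.trait)
    return df


def default_biomass_config(seed: int = 0, noise_cv: float = 0.05) -> BiomassSimConfig:
    """Study-condition panel: 5 parents, 6 hybrids, days 38-66.

    The flagship hybrid Va116xGDH94 carries the designed schedule
    {38: 15.00, 45: 22.50, 52: 37.49, 59: 24.59, 66: 30.27}%, i.e. a 22.50%
    mid-parent heterosis at 45 days and consecutive trend deltas of +7.50,
    +14.99, -12.90 and +5.68 percentage points, with its maximum rise (the
    key period) over days 45-52.  The other five hybrids peak lower.
    """
    parents = {
        # grams leaf dry weight per plant: (asymptote, rate/day, midpoint day)
        "K326": (85.0, 0.12, 55.0),
        "Va116": (70.0, 0.11, 54.0),
        "GDH94": (95.0, 0.13, 56.0),
        "JCP2": (80.0, 0.12, 53.0),
        "GDH88": (65.0, 0.10, 52.0),
    }
    hybrids = {
        "Va116xGDH94": ("Va116", "GDH94"),
        "Va116xJCP2": ("Va116", "JCP2"),
        "Va116xGDH88": ("Va116", "GDH88"),
        "K326xGDH94": ("K326", "GDH94"),
        "K326xJCP2": ("K326", "JCP2"),
        "K326xGDH88": ("K326", "GDH88"),
    }
    days = DEFAULT_TIMEPOINTS
    schedule: dict[tuple[str, int], float] = {}
    flagship = {38: 15.00, 45: 22.50, 52: 37.49, 59: 24.59, 66: 30.27}
    for day, v in flagship.items():
        schedule[("Va116xGDH94", day)] = v
    # remaining hybrids: lower 45-day heterosis, same qualitative shape
    base45 = {
        "Va116xJCP2": 18.0,
        "Va116xGDH88": 15.5,
        "K326xGDH94": 12.5,
        "K326xJCP2": 9.5,
        "K326xGDH88": 7.0,
    }
    shape = {38: -6.0, 45: 0.0, 52: 9.0, 59: 1.5, 66: 4.5}
    for hyb, b in base45.items():
        for day in days:
            schedule[(hyb, day)] = b + shape[day]
    return BiomassSimConfig(
        parents=parents,
        hybrids=hybrids,
        mph_schedule=schedule,
        timepoints_days=days,
        noise_cv=noise_cv,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# synthetic annotation
# ---------------------------------------------------------------------------


def simulate_term_map(
    truth: pd.Series,
    n_terms: int = 40,
    term_size: int = 120,
    enriched_fraction: float = 0.6,
    seed: int = 0,
) -> dict[str, set[str]]:
    """Synthetic flat gene->term annotation with designed enrichment.

    Two designated terms ("photosynthesis-like" and "TCA-like") draw
    ``enriched_fraction`` of their members from the overdominant-up and
    overdominant-down truth sets respectively; the remaining terms sample
    genes uniformly, giving a null background for enrichment tests.
    """
    rng = np.random.default_rng(seed)
    genes = np.asarray(truth.index)
    cat = truth.map(CATEGORY_OF)
    up = np.asarray(truth.index[cat == "overdominant_up"])
    down = np.asarray(truth.index[cat == "overdominant_down"])

    terms: dict[str, set[str]] = {}

    def biased(pool: np.ndarray) -> set[str]:
        k_bias = min(int(term_size * enriched_fraction), len(pool))
        chosen = set(rng.choice(pool, k_bias, replace=False))
        rest = rng.choice(genes, term_size, replace=False)
        for g in rest:
            if len(chosen) >= term_size:
                break
            chosen.add(g)
        return chosen

    if len(up):
        terms["TERM_PHOTOSYNTHESIS"] = biased(up)
    if len(down):
        terms["TERM_TCA_CYCLE"] = biased(down)
    for i in range(n_terms - len(terms)):
        terms[f"TERM{i:03d}"] = set(rng.choice(genes, term_size, replace=False))
    return terms


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_counts_tsv(triad: SyntheticTriad, path) -> None:
    triad.counts.counts.to_csv(path, sep="\t")


def write_design_tsv(triad: SyntheticTriad, path) -> None:
    triad.counts.design.to_csv(path, sep="\t")


def write_truth_tsv(triad: SyntheticTriad, path) -> None:
    triad.truth.to_frame().to_csv(path, sep="\t")


def write_trait_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)
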