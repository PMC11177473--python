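"""End-to-end orchestration: simulate/ingest -> DE -> patterns -> enrichment
-> heterosis -> qPCR, with seeded determinism and TSV/JSON reporting.

A single :class:`PipelineConfig` (optionally loaded from a YAML document)
names either on-disk inputs (counts + design, trait table, annotation, Ct
table) or simulation blocks; :func:`run` executes every applicable stage,
writes each stage's table under the output directory with a provenance
header (version, seed, config hash), and assembles a summary report of DEG
counts, Venn regions, pattern shares, enriched terms, per-pathway
overdominant tallies and the heterosis time course with its key period.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .diffexpr import DEConfig, ExpressionMatrix, deg_set, read_counts_tsv, read_design_tsv, triad_de, venn_counts
from .enrichment import enrich, read_term_map_tsv
from .heterosis import mean_trend_deltas, mph_series, read_trait_tsv, trend_deltas
from .patterns import CATEGORY_OF, classify_table, summarize_patterns
from .qpcr import concordance, ddct, read_ct_tsv
from .simulate import (
    BiomassSimConfig,
    TriadSimConfig,
    default_biomass_config,
    simulate_biomass,
    simulate_term_map,
    simulate_triad,
)

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "triadhet_out"
    seed: int = 0
    # real inputs (paths); when absent the corresponding simulation runs
    counts_path: str | None = None
    design_path: str | None = None
    trait_path: str | None = None
    annotation_path: str | None = None
    qpcr_path: str | None = None
    qpcr_calibrator: str | None = None
    qpcr_reference: str | None = None
    # simulation blocks
    triad_sim: TriadSimConfig | None = None
    biomass_sim: BiomassSimConfig | None = None
    de: DEConfig = field(default_factory=DEConfig)
    enrichment_alpha: float = 0.05
    deg_policy: str = "union"
    plots: bool = False
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        have_real = self.counts_path is not None and self.design_path is not None
        if not have_real and self.triad_sim is None:
            # simulation with defaults is the fallback
            self.triad_sim = TriadSimConfig(seed=self.seed)
        if self.trait_path is None and self.biomass_sim is None:
            self.biomass_sim = default_biomass_config(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(doc)
        if "triad_sim" in kwargs and kwargs["triad_sim"] is not None:
            kwargs["triad_sim"] = TriadSimConfig(**kwargs["triad_sim"])
        if "biomass_sim" in kwargs and kwargs["biomass_sim"] is not None:
            bs = dict(kwargs["biomass_sim"])
            if "hybrids" in bs:
                bs["hybrids"] = {k: tuple(v) for k, v in bs["hybrids"].items()}
            if "parents" in bs:
                bs["parents"] = {k: tuple(v) for k, v in bs["parents"].items()}
            if "mph_schedule" in bs:
                bs["mph_schedule"] = {
                    (h, int(d)): float(v)
                    for h, per_day in bs["mph_schedule"].items()
                    for d, v in per_day.items()
                }
            kwargs["biomass_sim"] = BiomassSimConfig(**bs)
        if "de" in kwargs and kwargs["de"] is not None:
            kwargs["de"] = DEConfig(**kwargs["de"])
        return cls(**kwargs)

    def digest(self) -> str:
        return hashlib.sha1(repr(self).encode()).hexdigest()[:12]


def write_tsv(df: pd.DataFrame, path: Path, meta: dict, index: bool = True) -> None:
    """Write a TSV with '# key: value' provenance header lines."""
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}: {val}\n")
        df.to_csv(fh, sep="\t", index=index)


def pathway_summary(
    patterns: pd.DataFrame, terms: dict[str, set[str]]
) -> pd.DataFrame:
    """Per-term tallies of overdominant pattern membership.

    ``patterns`` is the gene x (code, category) table; returns one row per
    term with counts of up- and down-overdominant members and the member
    gene lists (comma-joined, sorted).
    """
    rows = []
    for term, genes in sorted(terms.items()):
        members = patterns.loc[patterns.index.intersection(sorted(genes))]
        up = members.index[members["category"] == "overdominant_up"]
        down = members.index[members["category"] == "overdominant_down"]
        rows.append(
            (
                term,
                len(up),
                len(down),
                ",".join(sorted(up)),
                ",".join(sorted(down)),
            )
        )
    return pd.DataFrame(
        rows,
        columns=["term", "n_overdominant_up", "n_overdominant_down",
                 "up_genes", "down_genes"],
    ).set_index("term")


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except StageError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage-named rewrap
                raise StageError(name, exc) from exc
        return wrapped
    return deco


def run(config: PipelineConfig) -> dict:
    """Execute every applicable stage; returns the summary report dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    meta = {"version": __version__, "seed": config.seed, "config": config.digest()}
    report: dict = {"seed": config.seed, "version": __version__}

    # ---- expression input -------------------------------------------------
    truth = None
    if config.counts_path and config.design_path:
        matrix = _stage("ingest")(
            lambda: ExpressionMatrix(
                read_counts_tsv(config.counts_path),
                read_design_tsv(config.design_path),
            )
        )()
    else:
        def _sim():
            triad = simulate_triad(config.triad_sim)
            write_tsv(triad.counts.counts, outdir / "counts.tsv", meta)
            write_tsv(triad.counts.design, outdir / "design.tsv", meta)
            write_tsv(triad.truth.to_frame(), outdir / "truth.tsv", meta)
            return triad
        triad = _stage("simulate")(_sim)()
        matrix, truth = triad.counts, triad.truth

    # ---- differential expression -----------------------------------------
    def _de():
        results = triad_de(matrix, config.de)
        for name, res in results.items():
            write_tsv(res, outdir / f"de_{name}.tsv", meta)
        return results
    de_results = _stage("diffexpr")(_de)()
    deg_sets = {name: deg_set(res) for name, res in de_results.items()}
    report["deg_counts"] = {
        name: {
            "up": int((res["significant"] & (res["log2FC"] > 0)).sum()),
            "down": int((res["significant"] & (res["log2FC"] < 0)).sum()),
        }
        for name, res in de_results.items()
    }
    venn = venn_counts(deg_sets["F1vsP1"], deg_sets["F1vsP2"], deg_sets["P1vsP2"])
    report["venn"] = venn
    write_tsv(pd.DataFrame([venn]), outdir / "venn.tsv", meta, index=False)

    # ---- pattern classification -------------------------------------------
    def _classify():
        patterns = classify_table(de_results, config.deg_policy)
        write_tsv(patterns, outdir / "patterns.tsv", meta)
        return patterns
    patterns = _stage("patterns")(_classify)()
    summary = summarize_patterns(patterns["code"])
    write_tsv(summary.by_code, outdir / "pattern_summary_codes.tsv", meta)
    write_tsv(summary.by_category, outdir / "pattern_summary_categories.tsv", meta)
    report["patterns"] = {
        "n_classified": summary.n_classified,
        "n_unclassified": summary.n_unclassified,
        "category_pct": {
            cat: float(summary.by_category.loc[cat, "pct"])
            for cat in summary.by_category.index
        },
    }
    if truth is not None:
        common = patterns.index
        truth_cat = truth.loc[common].map(CATEGORY_OF)
        agree = (patterns["category"] == truth_cat) & (truth_cat != "unclassified")
        denom = int((truth_cat != "unclassified").sum())
        report["truth_category_recovery_pct"] = (
            100.0 * float(agree.sum()) / denom if denom else float("nan")
        )

    # ---- enrichment & pathway summary --------------------------------------
    if config.annotation_path:
        terms = _stage("enrichment")(read_term_map_tsv)(config.annotation_path)
    elif truth is not None:
        terms = simulate_term_map(truth, seed=config.seed)
        ann = pd.DataFrame(
            [(g, t) for t, gs in sorted(terms.items()) for g in sorted(gs)],
            columns=["gene_id", "term_id"],
        )
        write_tsv(ann, outdir / "annotation.tsv", meta, index=False)
    else:
        terms = None
    if terms:
        background = set(de_results["F1vsP1"].index)
        def _enrich():
            out = {}
            for cat in ("overdominant_up", "overdominant_down"):
                query = set(patterns.index[patterns["category"] == cat]) & background
                res = enrich(query, background, terms, alpha=config.enrichment_alpha)
                write_tsv(res, outdir / f"enrichment_{cat}.tsv", meta, index=False)
                out[cat] = res
            return out
        enr = _stage("enrichment")(_enrich)()
        report["enrichment"] = {
            cat: {
                "n_significant": int(res["significant"].sum()),
                "top_terms": res.head(3)["term"].tolist(),
            }
            for cat, res in enr.items()
        }
        psum = pathway_summary(patterns, terms)
        write_tsv(psum, outdir / "pathway_summary.tsv", meta)
        report["pathway_tallies"] = {
            term: {
                "overdominant_up": int(row["n_overdominant_up"]),
                "overdominant_down": int(row["n_overdominant_down"]),
            }
            for term, row in psum.iterrows()
            if row["n_overdominant_up"] or row["n_overdominant_down"]
        }

    # ---- heterosis ---------------------------------------------------------
    if config.trait_path:
        trait_table = _stage("heterosis")(read_trait_tsv)(config.trait_path)
    else:
        trait_table = simulate_biomass(config.biomass_sim)
        write_tsv(trait_table, outdir / "trait.tsv", meta, index=False)
    def _het():
        series = mph_series(trait_table)
        deltas = trend_deltas(series)
        write_tsv(series, outdir / "heterosis.tsv", meta, index=False)
        write_tsv(deltas, outdir / "heterosis_deltas.tsv", meta, index=False)
        write_tsv(mean_trend_deltas(series), outdir / "heterosis_deltas_mean.tsv",
                  meta, index=False)
        return series, deltas
    series, deltas = _stage("heterosis")(_het)()
    key = deltas[deltas["key_period"]]
    report["heterosis"] = {
        "n_hybrids": int(series["hybrid"].nunique()),
        "max_mph_pct": float(series["MPH_pct"].max()),
        "key_periods": {
            row["hybrid"]: [int(row["day_from"]), int(row["day_to"])]
            for _, row in key.iterrows()
        },
    }

    # ---- qPCR --------------------------------------------------------------
    if config.qpcr_path and config.qpcr_calibrator:
        def _qpcr():
            ct = read_ct_tsv(config.qpcr_path)
            folds = ddct(ct, config.qpcr_calibrator, config.qpcr_reference)
            write_tsv(folds, outdir / "qpcr_folds.tsv", meta, index=False)
            return folds
        _stage("qpcr")(_qpcr)()

    if config.plots:
        _stage("plots")(_plots)(summary, series, outdir)

    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report


def _plots(summary, series, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    summary.by_category["pct"].plot.bar(ax=axes[0], color="tab:blue")
    axes[0].set_ylabel("% of classified DEGs")
    for hyb, grp in series.groupby("hybrid"):
        axes[1].plot(grp["day"], grp["MPH_pct"], marker="o", label=hyb)
    axes[1].set_xlabel("days after transplanting")
    axes[1].set_ylabel("MPH (%)")
    axes[1].legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(outdir / "summary.png", dpi=120)
    plt.close(fig)
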