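"""Config-driven orchestration of the full enrichment cascade.

Stage order: normalize → flag filter → three-list DE selection → Venn
combination → hierarchical clustering → per-cluster GO over-representation →
per-cluster promoter motif enrichment → PWM→TF mapping → miRNA target
aggregation → empirical functional enrichment → final candidate report.

Every stage logs input/output counts into the run provenance; an empty
intermediate set terminates the cascade with a structured report (stage name
recorded) instead of raising.  Identical config+seed reproduces byte-identical
output files: no wall-clock values are written to reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clustering import hierarchical_cluster
from .diffexpr import SelectionCriteria, combine_lists, select_de_genes
from .expression import ExpressionMatrix, flag_filter, percentile_shift_normalize, read_expression
from .go_enrichment import GOAnnotation, enrich, read_gmt, read_go_tsv
from .mirna_rank import (
    TargetTable,
    aggregate_targets,
    annotate_top_candidates,
    fame_empirical_p,
    read_target_tables,
)
from .promoter_motif import (
    PromoterSet,
    hit_table,
    motif_enrichment_from_hits,
    read_jaspar,
    read_promoters_fasta,
)
from .synthetic_data import SimConfig, SyntheticDataset, generate_dataset

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All knobs of one cascade run.  Exactly one of ``sim`` / ``inputs`` is set.

    ``inputs`` maps names (expression, flags, samples, go, promoters, pwms,
    pwm_tf_map, targets) to file paths; ``sim`` generates the same objects
    with planted truth.
    """

    sim: SimConfig | None = None
    inputs: dict[str, str] | None = None
    duration: str = "24h"
    criteria1: SelectionCriteria = field(default_factory=SelectionCriteria)
    criteria2: SelectionCriteria = field(default_factory=SelectionCriteria)
    criteria3: SelectionCriteria = field(default_factory=lambda: SelectionCriteria(test="anova"))
    combine_rule: str = "union_all"
    anova_factors: tuple[str, str] = ("strain", "treatment")
    anova_p_factor: str = "strain"
    cluster_k: int = 2
    linkage: str = "average"
    distance: str = "one_minus_pearson"
    min_informative_flags: int = 1
    go_min_term_size: int = 2
    go_max_term_size: int = 500
    go_p_threshold: float = 0.05
    motif_threshold_frac: float = 0.85
    motif_background: str = "promoters"
    motif_p_threshold: float = 0.05
    fame_B: int = 1000
    fame_p_threshold: float = 0.05
    fame_top_k: int = 10
    family_map: dict[str, str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.inputs is None):
            raise ValueError("exactly one of sim / inputs must be set")
        if not (0 < self.motif_threshold_frac <= 1):
            raise ValueError("motif_threshold_frac must be in (0, 1]")
        for name in ("go_p_threshold", "motif_p_threshold", "fame_p_threshold"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")
        if self.fame_B < 100:
            raise ValueError("fame_B must be >= 100")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "sim" in kwargs and kwargs["sim"] is not None:
            sim = dict(kwargs["sim"])
            for key in ("strains", "treatments", "durations", "go_term_size_range",
                        "pwm_length_range", "planted_pwm_ids"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            kwargs["sim"] = SimConfig(**sim)
        for key in ("criteria1", "criteria2", "criteria3"):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = SelectionCriteria(**kwargs[key])
        if "anova_factors" in kwargs:
            kwargs["anova_factors"] = tuple(kwargs["anova_factors"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class PipelineResult:
    provenance: dict
    reports: dict[str, pd.DataFrame]
    summary: dict
    terminated_at: str | None = None
    truth: object = None  # SyntheticTruth when simulating


def _load_inputs(paths: dict[str, str]):
    required = {"expression", "samples", "go", "promoters", "pwms", "pwm_tf_map", "targets"}
    missing = required - set(paths)
    if missing:
        raise ValueError(f"input paths missing: {sorted(missing)}")
    expr = read_expression(paths["expression"], paths["samples"], paths.get("flags"))
    go_path = paths["go"]
    if str(go_path).endswith(".gmt"):
        go = read_gmt(go_path)
    else:
        go = read_go_tsv(go_path)
    promoters = read_promoters_fasta(paths["promoters"])
    pwms = read_jaspar(paths["pwms"])
    tf_map_df = pd.read_csv(paths["pwm_tf_map"], sep="\t", dtype=str)
    pwm_tf_map = dict(zip(tf_map_df["pwm_id"], tf_map_df["tf_gene"]))
    tables = read_target_tables(paths["targets"])
    return expr, go, promoters, pwms, pwm_tf_map, tables


def run_pipeline(
    config: PipelineConfig, outdir=None, dry_run: bool = False
) -> PipelineResult:
    """Execute the cascade; optionally write all stage reports under ``outdir``."""
    provenance: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": _jsonable(config.to_dict()),
        "stages": [],
    }
    reports: dict[str, pd.DataFrame] = {}
    summary: dict = {}

    def stage(name: str, n_in: int, n_out: int) -> None:
        provenance["stages"].append(
            {"stage": name, "n_in": n_in, "n_out": n_out, "dropped": n_in - n_out}
        )
        log.info("stage %-18s in=%d out=%d", name, n_in, n_out)

    def terminate(at: str, reason: str) -> PipelineResult:
        summary["terminated_at"] = at
        summary["reason"] = reason
        log.warning("cascade terminated at stage %s: %s", at, reason)
        result = PipelineResult(
            provenance=provenance, reports=reports, summary=summary,
            terminated_at=at, truth=truth,
        )
        if outdir is not None:
            _write_outputs(result, outdir)
        return result

    truth = None
    if config.sim is not None:
        ds: SyntheticDataset = generate_dataset(config.sim)
        expr, go, promoters, pwms = ds.expression, ds.go, ds.promoters, ds.pwms
        pwm_tf_map, tables, truth = ds.pwm_tf_map, ds.target_tables, ds.truth
    else:
        expr, go, promoters, pwms, pwm_tf_map, tables = _load_inputs(config.inputs)

    if dry_run:
        summary["dry_run"] = True
        summary["n_genes"] = len(expr.gene_ids)
        summary["n_samples"] = len(expr.sample_ids)
        summary["n_terms"] = len(go.terms)
        summary["n_pwms"] = len(pwms)
        return PipelineResult(provenance=provenance, reports={}, summary=summary, truth=truth)

    # 1. normalize ------------------------------------------------------------
    norm, norm_report = percentile_shift_normalize(expr)
    stage("normalize", len(expr.gene_ids), len(norm.gene_ids))

    # 2. flag filter ----------------------------------------------------------
    universe = flag_filter(norm, config.min_informative_flags)
    stage("flag_filter", len(norm.gene_ids), len(universe))
    if not universe:
        return terminate("flag_filter", "no gene passed the detection-flag filter")
    norm_u = norm.subset_genes(universe)

    # 3. DE selection ---------------------------------------------------------
    selection = select_de_genes(
        norm_u,
        duration=config.duration,
        criteria1=config.criteria1,
        criteria2=config.criteria2,
        criteria3=config.criteria3,
        anova_factors=config.anova_factors,
        anova_p_factor=config.anova_p_factor,
    )
    for name in ("list1", "list2", "list3"):
        reports[f"de_{name}"] = selection.results[name]
    provenance["de"] = selection.provenance
    stage("select_de_genes", len(universe),
          sum(len(s) for s in selection.lists.values()))

    # 4. combine --------------------------------------------------------------
    venn = combine_lists(
        selection.lists["list1"], selection.lists["list2"], selection.lists["list3"],
        rule=config.combine_rule,
    )
    combined = venn.combined_set
    summary["venn"] = {"region_counts": venn.region_counts, "rule": venn.rule,
                       "combined_size": len(combined)}
    stage("combine_lists", sum(len(s) for s in selection.lists.values()), len(combined))
    if not combined:
        return terminate("combine_lists", "no differentially expressed genes selected")

    # 5. cluster --------------------------------------------------------------
    if len(combined) < config.cluster_k:
        return terminate(
            "hierarchical_cluster",
            f"{len(combined)} genes < k={config.cluster_k}",
        )
    clusters = hierarchical_cluster(
        norm_u, combined, linkage=config.linkage, distance=config.distance,
        k=config.cluster_k,
    )
    reports["clusters"] = clusters.to_frame()
    stage("hierarchical_cluster", len(combined), len(clusters.labels))

    # 6. per-cluster GO enrichment -------------------------------------------
    go_u = go.restrict(universe)
    go_frames = []
    for c in clusters.clusters:
        members = clusters.members(c)
        try:
            df = enrich(members, go_u, config.go_min_term_size, config.go_max_term_size)
        except ValueError:
            continue
        df.insert(0, "cluster", c)
        go_frames.append(df)
    go_all = (
        pd.concat(go_frames, ignore_index=True)
        if go_frames
        else pd.DataFrame(columns=["cluster", "term", "p", "p_adj"])
    )
    reports["go_enrichment"] = go_all
    sig_terms = sorted(set(go_all.loc[go_all["p_adj"] < config.go_p_threshold, "term"]))
    stage("go_enrichment", len(go_u.terms), len(sig_terms))

    # 7. per-cluster motif enrichment ----------------------------------------
    prom_universe = {g for g in universe if g in promoters}
    bg_prom = promoters.subset(sorted(prom_universe))
    bg_hits = hit_table(
        bg_prom, pwms,
        background_model=config.motif_background,
        threshold_frac=config.motif_threshold_frac,
    )
    motif_frames = []
    enriched_pwms: set[str] = set()
    for c in clusters.clusters:
        members = sorted(clusters.members(c) & prom_universe)
        if not members:
            continue
        df = motif_enrichment_from_hits(bg_hits, set(members), pwms)
        df.insert(0, "cluster", c)
        motif_frames.append(df)
        enriched_pwms |= set(df.loc[df["p_adj"] < config.motif_p_threshold, "pwm_id"])
    motif_all = (
        pd.concat(motif_frames, ignore_index=True)
        if motif_frames
        else pd.DataFrame(columns=["cluster", "pwm_id", "p", "p_adj", "EF"])
    )
    reports["motif_enrichment"] = motif_all
    stage("motif_enrichment", len(pwms), len(enriched_pwms))
    if not enriched_pwms:
        return terminate("motif_enrichment", "no PWM passed the enrichment threshold")

    # 8. map enriched PWMs to TF genes ---------------------------------------
    unmapped = sorted(p for p in enriched_pwms if p not in pwm_tf_map)
    if unmapped:
        log.warning("enriched PWMs without TF mapping dropped: %s", unmapped)
    enriched_tfs = {pwm_tf_map[p] for p in enriched_pwms if p in pwm_tf_map}
    summary["enriched_pwms"] = sorted(enriched_pwms)
    summary["enriched_tfs"] = sorted(enriched_tfs)
    stage("pwm_tf_map", len(enriched_pwms), len(enriched_tfs))
    if not enriched_tfs:
        return terminate("pwm_tf_map", "no enriched PWM could be mapped to a TF gene")

    # 9. aggregate miRNA targets ----------------------------------------------
    ranking = aggregate_targets(enriched_tfs, tables, family_map=config.family_map)
    stage("aggregate_targets",
          len(set().union(*[set(t.targets) for t in tables], set())), len(ranking))
    if len(ranking) == 0:
        reports["mirna_ranking"] = ranking
        return terminate("aggregate_targets", "no miRNA targets any enriched TF")

    # 10. empirical functional enrichment (FAME-style) ------------------------
    fame_records = []
    fame_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 982451653]))
    top = ranking.head(config.fame_top_k)
    target_by_mirna = {
        m: set().union(*[t.targets.get(m, set()) for t in tables]) & universe
        for m in top["mirna"]
    }
    for mirna in top["mirna"]:
        targets = target_by_mirna[mirna]
        if not targets:
            continue
        for term in sig_terms:
            term_genes = go_u.terms[term] & universe
            sub_seed = int(fame_rng.integers(0, 2**31 - 1))
            fame_records.append(
                fame_empirical_p(
                    targets, term_genes, universe, B=config.fame_B,
                    seed=sub_seed, mirna=mirna, term=term,
                )
            )
    stage("fame_empirical_p", len(top) * max(len(sig_terms), 1), len(fame_records))

    # 11. final report ---------------------------------------------------------
    final = annotate_top_candidates(ranking, fame_records, config.fame_p_threshold)
    reports["mirna_ranking"] = final
    summary["top_candidate"] = str(final.iloc[0]["mirna"])
    summary["top_sum"] = int(final.iloc[0]["sum"])
    summary["n_candidates"] = int(len(final))
    if truth is not None:
        summary["planted_mirna"] = truth.mirna_truth[0]
        summary["planted_recovered_at_rank_1"] = bool(
            summary["top_candidate"] == truth.mirna_truth[0]
        )
    stage("annotate_top_candidates", len(final), len(final))

    result = PipelineResult(
        provenance=provenance, reports=reports, summary=summary, truth=truth
    )
    if outdir is not None:
        _write_outputs(result, outdir)
    return result


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_jsonable(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _write_outputs(result: PipelineResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in result.reports.items():
        df.to_csv(outdir / f"{name}.tsv", sep="\t", float_format="%.10g")
    with open(outdir / "summary.json", "w") as fh:
        json.dump(_jsonable(result.summary), fh, indent=1, sort_keys=True)
        fh.write("\n")
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(_jsonable(result.provenance), fh, indent=1, sort_keys=True)
        fh.write("\n")
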