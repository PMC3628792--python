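"""Synthetic two-strain LPS-stimulation dataset with planted ground truth.

Generates every input the enrichment cascade consumes: a raw-scale expression
matrix over strains × {control, LPS} × durations × replicates with detection
flags, a GO annotation with terms enriched in the planted gene clusters,
promoter sequences with motif occurrences planted in one cluster, a PWM
library, a PWM→TF-gene map, and two miRNA target-prediction tables with one
planted true regulator.  The returned :class:`SyntheticTruth` records the
planted structure so every downstream stage has a known acceptance surface.

Intensities are generated on the log2 scale (Gaussian noise) and exponentiated
for the raw-scale matrix, so planted effects are interpretable directly as
log2 fold changes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .expression import ExpressionMatrix, write_expression
from .go_enrichment import GOAnnotation, write_go_tsv, write_gmt
from .mirna_rank import TargetTable, write_target_tables
from .promoter_motif import BASES, PWM, PromoterSet, write_jaspar, write_promoters_fasta


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic dataset.

    Defaults describe a desk-scale version of a two-strain bead-array
    experiment: 2 strains × {control, LPS} × {24h, 48h} with 3 replicate
    arrays per condition, planted strain-differential and LPS-responsive genes
    at log2 effect 1.5 against log2-scale noise SD 0.4.
    """

    n_genes: int = 1000
    n_replicates_per_condition: int = 3
    strains: tuple[str, str] = ("LEW", "PVG")
    treatments: tuple[str, ...] = ("control", "LPS")
    durations: tuple[str, ...] = ("24h", "48h")
    frac_strain_de: float = 0.05
    frac_lps_de: float = 0.05
    log2_effect_strain: float = 1.5
    log2_effect_lps: float = 1.5
    noise_sd_log2: float = 0.4
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    flag_absent_quantile: float = 0.05
    n_go_terms: int = 50
    go_term_size_range: tuple[int, int] = (10, 40)
    planted_go_enrichment_frac: float = 0.6
    promoter_length: int = 3000
    n_pwms: int = 15
    n_planted_pwms: int = 5
    planted_pwm_ids: tuple[str, ...] | None = None
    pwm_length_range: tuple[int, int] = (8, 12)
    motif_plant_rate: float = 0.6
    n_mirnas: int = 30
    true_mirna_target_coverage: float = 0.8
    decoy_target_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        fractions = {
            "frac_strain_de": self.frac_strain_de,
            "frac_lps_de": self.frac_lps_de,
            "flag_absent_quantile": self.flag_absent_quantile,
            "planted_go_enrichment_frac": self.planted_go_enrichment_frac,
            "motif_plant_rate": self.motif_plant_rate,
            "true_mirna_target_coverage": self.true_mirna_target_coverage,
            "decoy_target_rate": self.decoy_target_rate,
        }
        for name, v in fractions.items():
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} must be in [0, 1]")
        counts = {
            "n_genes": self.n_genes,
            "n_replicates_per_condition": self.n_replicates_per_condition,
            "n_go_terms": self.n_go_terms,
            "promoter_length": self.promoter_length,
            "n_pwms": self.n_pwms,
            "n_mirnas": self.n_mirnas,
        }
        for name, v in counts.items():
            if v < 1:
                raise ValueError(f"{name}={v} must be positive")
        if self.n_replicates_per_condition < 2:
            raise ValueError(
                "n_replicates_per_condition must be >= 2 (rank tests and the "
                "replicated ANOVA are degenerate with one array per cell)"
            )
        if not self.treatments or not self.durations:
            raise ValueError("treatments and durations must be nonempty")
        if len(self.strains) != 2:
            raise ValueError("exactly two strains are required")
        for name in ("log2_effect_strain", "log2_effect_lps", "noise_sd_log2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd_log2 < 0:
            raise ValueError("noise_sd_log2 must be >= 0")
        if self.frac_strain_de + self.frac_lps_de > 1:
            raise ValueError(
                "frac_strain_de + frac_lps_de > 1: planted gene sets are "
                "disjoint and cannot exceed the gene count"
            )
        if self.n_planted_pwms > self.n_pwms:
            raise ValueError("n_planted_pwms exceeds n_pwms")
        lo, hi = self.pwm_length_range
        if lo < 4 or hi < lo:
            raise ValueError("pwm_length_range must satisfy 4 <= lo <= hi")
        if hi > self.promoter_length:
            raise ValueError("motif longer than promoter")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]


@dataclass
class MotifInsertion:
    gene: str
    pwm_id: str
    position: int
    strand: str
    site: str


@dataclass
class SyntheticTruth:
    """Planted structure of one generated dataset."""

    strain_de: dict[str, float]  # gene -> signed log2 effect (strain[0] minus strain[1])
    lps_de: dict[str, dict[str, float]]  # gene -> strain -> signed log2 effect
    cluster_assignment: dict[str, str]  # gene -> "strain" | "lps"
    planted_terms: dict[str, str]  # GO term -> cluster label
    planted_pwms: dict[str, str]  # pwm id -> cluster label
    pwm_tf_map: dict[str, str]  # pwm id -> TF gene id
    mirna_truth: tuple[str, tuple[str, ...]]  # (planted miRNA, its intended TF set)
    motif_insertions: list[MotifInsertion] = field(default_factory=list)
    seed: int = 0

    @property
    def tf_set(self) -> set[str]:
        return set(self.mirna_truth[1])


@dataclass
class SyntheticDataset:
    expression: ExpressionMatrix  # raw scale, with flags
    go: GOAnnotation
    promoters: PromoterSet
    pwms: list[PWM]
    pwm_tf_map: dict[str, str]
    target_tables: list[TargetTable]
    truth: SyntheticTruth
    config: SimConfig


_COMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def generate_expression(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Raw-scale expression matrix with flags, plus the planted DE truth.

    Strain-DE genes carry a signed log2 effect on the first strain; LPS genes
    carry a common signed effect under LPS in both strains.  Flags threshold
    raw intensity at the per-sample ``flag_absent_quantile`` with an M band of
    ±2% around the threshold.
    """
    config.validate()
    rng = rng or np.random.default_rng(config.seed)
    genes = config.gene_ids
    n = config.n_genes
    n_strain = int(round(config.frac_strain_de * n))
    n_lps = int(round(config.frac_lps_de * n))
    perm = rng.permutation(n)
    strain_genes = [genes[i] for i in sorted(perm[:n_strain])]
    lps_genes = [genes[i] for i in sorted(perm[n_strain : n_strain + n_lps])]
    strain_sign = rng.choice([-1.0, 1.0], size=n_strain)
    lps_sign = rng.choice([-1.0, 1.0], size=n_lps)

    samples, design_rows = [], []
    for strain in config.strains:
        for trt in config.treatments:
            for dur in config.durations:
                for rep in range(1, config.n_replicates_per_condition + 1):
                    samples.append(f"{strain}_{trt}_{dur}_r{rep}")
                    design_rows.append((strain, trt, dur))
    design = pd.DataFrame(design_rows, columns=["strain", "treatment", "duration"],
                          index=samples)

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    means = np.tile(baseline[:, None], (1, len(samples)))
    gene_pos = {g: i for i, g in enumerate(genes)}
    is_first_strain = (design["strain"] == config.strains[0]).to_numpy()
    is_lps = (design["treatment"] == "LPS").to_numpy()
    for g, s in zip(strain_genes, strain_sign):
        means[gene_pos[g], is_first_strain] += s * config.log2_effect_strain
    for g, s in zip(lps_genes, lps_sign):
        means[gene_pos[g], is_lps] += s * config.log2_effect_lps

    log2_vals = means + rng.normal(0.0, config.noise_sd_log2, size=means.shape)
    raw = np.power(2.0, log2_vals)

    flags = np.full(raw.shape, "P", dtype="U1")
    q = config.flag_absent_quantile
    if q > 0:
        thresh = np.quantile(raw, q, axis=0)
        flags[raw < 0.98 * thresh[None, :]] = "A"
        band = (raw >= 0.98 * thresh[None, :]) & (raw <= 1.02 * thresh[None, :])
        flags[band] = "M"

    expr = ExpressionMatrix(
        values=pd.DataFrame(raw, index=genes, columns=samples),
        flags=pd.DataFrame(flags, index=genes, columns=samples),
        design=design,
        scale="raw",
    )
    truth = SyntheticTruth(
        strain_de={g: float(s * config.log2_effect_strain)
                   for g, s in zip(strain_genes, strain_sign)},
        lps_de={g: {strain: float(s * config.log2_effect_lps)
                    for strain in config.strains}
                for g, s in zip(lps_genes, lps_sign)},
        cluster_assignment={**{g: "strain" for g in strain_genes},
                            **{g: "lps" for g in lps_genes}},
        planted_terms={},
        planted_pwms={},
        pwm_tf_map={},
        mirna_truth=("", ()),
        seed=config.seed,
    )
    return expr, truth


def generate_go_annotation(
    config: SimConfig, truth: SyntheticTruth, rng: np.random.Generator
) -> GOAnnotation:
    """Random GO terms plus one planted term per cluster.

    The planted term draws ``planted_go_enrichment_frac`` of its members from
    the cluster; terms are sampled without forced disjointness.
    """
    genes = config.gene_ids
    lo, hi = config.go_term_size_range
    terms: dict[str, set[str]] = {}
    clusters = sorted(set(truth.cluster_assignment.values()))
    term_ids = [f"GO:{i + 1:07d}" for i in range(config.n_go_terms)]
    planted = {}
    for i, cluster in enumerate(clusters):
        if i >= config.n_go_terms:
            break
        tid = term_ids[i]
        members = sorted(g for g, c in truth.cluster_assignment.items() if c == cluster)
        size = int(rng.integers(lo, hi + 1))
        n_from_cluster = min(len(members), math.ceil(config.planted_go_enrichment_frac * size))
        chosen = list(rng.choice(members, size=n_from_cluster, replace=False))
        others = sorted(set(genes) - set(members))
        n_rest = max(size - n_from_cluster, 0)
        chosen += list(rng.choice(others, size=min(n_rest, len(others)), replace=False))
        terms[tid] = set(chosen)
        planted[tid] = cluster
    for tid in term_ids[len(planted):]:
        size = int(rng.integers(lo, hi + 1))
        terms[tid] = set(rng.choice(genes, size=size, replace=False))
    truth.planted_terms = planted
    return GOAnnotation(terms=terms, universe=set(genes))


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_promoters(config: SimConfig, rng: np.random.Generator) -> PromoterSet:
    """Uniform-random ACGT promoters of ``promoter_length`` for every gene."""
    seqs = {}
    for g in config.gene_ids:
        codes = rng.integers(0, 4, size=config.promoter_length)
        seqs[g] = _BASE_BYTES[codes].tobytes().decode("ascii")
    return PromoterSet(seqs)


def generate_pwms(config: SimConfig, rng: np.random.Generator) -> list[PWM]:
    """Random informative PWMs with consensus-dominated columns.

    Each column concentrates 0.85–0.97 of its mass on one base (drawn
    uniformly), emulating the sharp core positions of curated TF binding-site
    matrices so that sites sampled from the matrix are recoverable by scanning.
    """
    pwms = []
    ids = (
        list(config.planted_pwm_ids)
        if config.planted_pwm_ids is not None
        else [f"M{i + 1:05d}" for i in range(config.n_planted_pwms)]
    )
    ids += [f"M{i + 1:05d}" for i in range(config.n_planted_pwms, config.n_pwms)]
    lo, hi = config.pwm_length_range
    for i, pwm_id in enumerate(ids[: config.n_pwms]):
        L = int(rng.integers(lo, hi + 1))
        cols = np.empty((4, L))
        for j in range(L):
            dominant = int(rng.integers(0, 4))
            q = rng.uniform(0.85, 0.97)
            rest = rng.dirichlet(np.ones(3)) * (1 - q)
            col = np.insert(rest, dominant, q)
            cols[:, j] = col
        pwms.append(PWM.from_counts(id=pwm_id, counts=cols * 1000,
                                    tf_name=f"TF{i + 1:02d}"))
    return pwms


def plant_motifs(
    promoters: PromoterSet,
    pwm: PWM,
    genes: set[str],
    rate: float,
    seed: int | np.random.Generator,
) -> tuple[PromoterSet, list[MotifInsertion]]:
    """Write one PWM-sampled site into ceil(rate·|genes|) promoters.

    Position uniform, strand uniform (minus strand inserts the reverse
    complement).  Untouched promoters are passed through; insertion records
    are returned alongside the new set.
    """
    if not (0 <= rate <= 1):
        raise ValueError("rate must be in [0, 1]")
    missing = [g for g in genes if g not in promoters]
    if missing:
        raise ValueError(f"genes without promoters: {sorted(missing)[:5]}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ordered = sorted(genes)
    n_plant = math.ceil(rate * len(ordered))
    chosen = list(rng.choice(ordered, size=n_plant, replace=False)) if n_plant else []
    new_seqs = dict(promoters.sequences)
    insertions = []
    for g in chosen:
        seq = new_seqs[g]
        if pwm.length > len(seq):
            raise ValueError(
                f"motif {pwm.id} (length {pwm.length}) longer than promoter of {g!r}"
            )
        site = pwm.sample(rng)
        strand = "+" if rng.random() < 0.5 else "-"
        written = site if strand == "+" else _revcomp(site)
        pos = int(rng.integers(0, len(seq) - pwm.length + 1))
        new_seqs[g] = seq[:pos] + written + seq[pos + pwm.length:]
        insertions.append(
            MotifInsertion(gene=g, pwm_id=pwm.id, position=pos, strand=strand, site=site)
        )
    return PromoterSet(new_seqs), insertions


def generate_target_tables(
    truth: SyntheticTruth,
    mirnas: list[str],
    coverage: float,
    decoy_rate: float,
    universe: list[str],
    seed: int | np.random.Generator,
    algorithms: tuple[str, str] = ("targetscan", "miranda"),
) -> list[TargetTable]:
    """Two prediction tables: the planted miRNA covers ceil(coverage·|TF set|)
    of the truth TF set per table (independently sampled); decoy miRNAs target
    universe genes uniformly at ``decoy_rate``."""
    if not mirnas:
        raise ValueError("miRNA list is empty")
    if not (0 <= coverage <= 1) or not (0 <= decoy_rate <= 1):
        raise ValueError("coverage and decoy_rate must be in [0, 1]")
    planted_mirna, tf_tuple = truth.mirna_truth
    if not planted_mirna:
        raise ValueError("truth.mirna_truth is not set")
    tf_list = sorted(tf_tuple)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    universe = list(universe)
    n_cover = math.ceil(coverage * len(tf_list))
    tables = []
    for alg in algorithms:
        targets: dict[str, set[str]] = {}
        for mirna in mirnas:
            if mirna == planted_mirna:
                targets[mirna] = (
                    set(rng.choice(tf_list, size=n_cover, replace=False))
                    if n_cover
                    else set()
                )
            else:
                mask = rng.random(len(universe)) < decoy_rate
                targets[mirna] = {g for g, m in zip(universe, mask) if m}
        tables.append(TargetTable(algorithm=alg, targets=targets))
    return tables


def generate_dataset(config: SimConfig) -> SyntheticDataset:
    """Generate every cascade input with planted structure (seed-deterministic)."""
    config.validate()
    master = np.random.default_rng(config.seed)
    # independent child streams so sub-generators stay reproducible in isolation
    streams = master.spawn(6)
    expr, truth = generate_expression(config, streams[0])
    go = generate_go_annotation(config, truth, streams[1])
    promoters = generate_promoters(config, streams[2])
    pwms = generate_pwms(config, streams[3])

    strain_cluster = {g for g, c in truth.cluster_assignment.items() if c == "strain"}
    planted = pwms[: config.n_planted_pwms]
    insertions: list[MotifInsertion] = []
    for pwm in planted:
        promoters, ins = plant_motifs(
            promoters, pwm, strain_cluster, config.motif_plant_rate, streams[4]
        )
        insertions.extend(ins)
    truth.planted_pwms = {p.id: "strain" for p in planted}
    truth.motif_insertions = insertions

    # map every PWM to a distinct TF gene outside the planted clusters
    cluster_genes = set(truth.cluster_assignment)
    candidates = sorted(set(config.gene_ids) - cluster_genes)
    tf_genes = [str(g) for g in streams[5].choice(candidates, size=len(pwms), replace=False)]
    truth.pwm_tf_map = {p.id: g for p, g in zip(pwms, tf_genes)}

    mirna_ids = [f"miR-{i + 1:03d}" for i in range(config.n_mirnas)]
    planted_mirna = mirna_ids[int(streams[5].integers(0, config.n_mirnas))]
    truth_tfs = tuple(sorted(str(truth.pwm_tf_map[p.id]) for p in planted))
    truth.mirna_truth = (planted_mirna, truth_tfs)
    tables = generate_target_tables(
        truth,
        mirna_ids,
        config.true_mirna_target_coverage,
        config.decoy_target_rate,
        config.gene_ids,
        streams[5],
    )
    return SyntheticDataset(
        expression=expr,
        go=go,
        promoters=promoters,
        pwms=pwms,
        pwm_tf_map=truth.pwm_tf_map,
        target_tables=tables,
        truth=truth,
        config=config,
    )


def write_dataset(ds: SyntheticDataset, outdir) -> dict[str, str]:
    """Write every input file form the pipeline can read back; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": outdir / "expression.tsv",
        "flags": outdir / "flags.tsv",
        "samples": outdir / "samples.tsv",
        "go_tsv": outdir / "go_map.tsv",
        "go_gmt": outdir / "go_terms.gmt",
        "promoters": outdir / "promoters.fasta",
        "pwms": outdir / "pwms.jaspar",
        "pwm_tf_map": outdir / "pwm_tf_map.tsv",
        "targets": outdir / "target_tables.tsv",
        "truth": outdir / "truth.json",
    }
    write_expression(ds.expression, paths["expression"], paths["flags"], paths["samples"])
    write_go_tsv(ds.go, paths["go_tsv"])
    write_gmt(ds.go, paths["go_gmt"])
    write_promoters_fasta(ds.promoters, paths["promoters"])
    write_jaspar(ds.pwms, paths["pwms"])
    pd.DataFrame(
        sorted(ds.pwm_tf_map.items()), columns=["pwm_id", "tf_gene"]
    ).to_csv(paths["pwm_tf_map"], sep="\t", index=False)
    write_target_tables(ds.target_tables, paths["targets"])
    truth_dict = asdict(ds.truth)
    truth_dict["mirna_truth"] = list(truth_dict["mirna_truth"])
    with open(paths["truth"], "w") as fh:
        json.dump(truth_dict, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
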