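"""Candidate-miRNA ranking over an enriched-TF set, with empirical functional
enrichment p-values.

Two (or more) target-prediction tables — each mapping miRNA → predicted target
genes — are intersected with the set of transcription factors whose binding
motifs were enriched in a cluster's promoters.  Per-algorithm counts are
summed; miRNAs are ranked by the sum.  For top candidates, an empirical
over-representation p-value against a GO gene group is computed by uniform
resampling of equal-size target sets from the universe (add-one rule:
p = (1 + #{resamples with overlap >= observed}) / (1 + B)).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class TargetTable:
    """One prediction algorithm's miRNA → target-gene sets."""

    algorithm: str
    targets: dict[str, set[str]]

    def __post_init__(self) -> None:
        self.targets = {m: set(g) for m, g in self.targets.items()}


def read_target_tables(path) -> list[TargetTable]:
    """TSV with columns algorithm, mirna, gene; one table per algorithm label.

    Duplicate (algorithm, mirna) rows are merged (a warning counts them).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"algorithm", "mirna", "gene"}
    if not required <= set(df.columns):
        raise ValueError(f"target table needs columns {sorted(required)}")
    n_dup = int(df.duplicated().sum())
    if n_dup:
        log.warning("%d duplicate target rows merged", n_dup)
    tables = []
    for alg in sorted(df["algorithm"].unique()):
        sub = df[df["algorithm"] == alg]
        targets: dict[str, set[str]] = {}
        for mirna, gene in zip(sub["mirna"], sub["gene"]):
            targets.setdefault(mirna, set()).add(gene)
        tables.append(TargetTable(algorithm=alg, targets=targets))
    return tables


def write_target_tables(tables: list[TargetTable], path) -> None:
    rows = [
        (t.algorithm, m, g)
        for t in tables
        for m in sorted(t.targets)
        for g in sorted(t.targets[m])
    ]
    pd.DataFrame(rows, columns=["algorithm", "mirna", "gene"]).to_csv(
        path, sep="\t", index=False
    )


def aggregate_targets(
    enriched_tfs: set[str],
    tables: list[TargetTable],
    family_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Count enriched-TF targets per miRNA per algorithm; rank by the sum.

    Tie-break for equal sums: more algorithms with a nonzero count, then larger
    minimum per-algorithm count, then lexicographic miRNA id.  miRNAs with
    sum 0 are excluded from the report (their number is logged).  An optional
    family map collapses miRNA ids to families (max count per family and
    algorithm; associated TFs are unioned over members).
    """
    enriched_tfs = set(enriched_tfs)
    if not enriched_tfs:
        raise ValueError("enriched TF set is empty")
    if not tables:
        raise ValueError("need at least one target table")
    algs = [t.algorithm for t in tables]
    if len(set(algs)) != len(algs):
        raise ValueError(f"algorithm labels must be distinct: {algs}")

    mirnas = sorted(set().union(*[set(t.targets) for t in tables]))
    counts: dict[str, dict[str, int]] = {}
    assoc: dict[str, set[str]] = {}
    for mirna in mirnas:
        counts[mirna] = {}
        assoc[mirna] = set()
        for t in tables:
            hit = t.targets.get(mirna, set()) & enriched_tfs
            counts[mirna][t.algorithm] = len(hit)
            assoc[mirna] |= hit

    if family_map:
        fam_counts: dict[str, dict[str, int]] = {}
        fam_assoc: dict[str, set[str]] = {}
        for mirna in mirnas:
            fam = family_map.get(mirna, mirna)
            fc = fam_counts.setdefault(fam, {a: 0 for a in algs})
            for a in algs:
                fc[a] = max(fc[a], counts[mirna][a])
            fam_assoc.setdefault(fam, set()).update(assoc[mirna])
        counts, assoc = fam_counts, fam_assoc
        mirnas = sorted(counts)

    rows = []
    for mirna in mirnas:
        per_alg = counts[mirna]
        total = sum(per_alg.values())
        rows.append(
            {
                "mirna": mirna,
                **{f"n_{a}": per_alg[a] for a in algs},
                "sum": total,
                "n_algorithms_hit": sum(v > 0 for v in per_alg.values()),
                "min_count": min(per_alg.values()),
                "associated_tfs": ";".join(sorted(assoc[mirna])),
            }
        )
    df = pd.DataFrame(rows)
    n_zero = int((df["sum"] == 0).sum()) if len(df) else 0
    if n_zero:
        log.info("%d candidate miRNAs with zero enriched-TF targets excluded", n_zero)
    df = df[df["sum"] > 0].copy() if len(df) else df
    if len(df) == 0:
        cols = ["mirna", *[f"n_{a}" for a in algs], "sum", "rank", "associated_tfs"]
        empty = pd.DataFrame(columns=cols)
        empty.attrs["n_zero_candidates"] = n_zero
        return empty
    df = df.sort_values(
        ["sum", "n_algorithms_hit", "min_count", "mirna"],
        ascending=[False, False, False, True],
        kind="mergesort",
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df = df[["mirna", *[f"n_{a}" for a in algs], "sum", "rank", "associated_tfs"]]
    df.attrs["n_zero_candidates"] = n_zero
    return df


@dataclass
class FameRecord:
    """Empirical enrichment of a miRNA target set in one GO gene group."""

    mirna: str
    term: str
    observed: int
    p: float
    B: int
    seed: int

    def __post_init__(self) -> None:
        if not (0 < self.p <= 1):
            raise ValueError(f"empirical p must be in (0, 1], got {self.p}")


def fame_empirical_p(
    targets: set[str],
    term_genes: set[str],
    universe: set[str],
    B: int = 1000,
    seed: int = 0,
    mirna: str = "",
    term: str = "",
) -> FameRecord:
    """Permutation p-value for the overlap of a target set with a gene group.

    B resamples of |targets| genes are drawn uniformly without replacement from
    the universe; p = (1 + #{overlap >= observed}) / (1 + B).  Deterministic
    under ``seed``.
    """
    targets = set(targets)
    term_genes = set(term_genes)
    universe_list = sorted(universe)
    if not targets <= set(universe_list) or not term_genes <= set(universe_list):
        raise ValueError("targets and term genes must be subsets of the universe")
    if len(targets) > len(universe_list):
        raise ValueError("target set larger than universe")
    if B < 100:
        raise ValueError("B must be >= 100")
    observed = len(targets & term_genes)
    rng = np.random.default_rng(seed)
    N, s = len(universe_list), len(targets)
    term_mask = np.array([g in term_genes for g in universe_list])
    if s == 0:
        count_ge = B if observed == 0 else 0
    else:
        # B draws without replacement: first-s columns of random argpartitions
        keys = rng.random((B, N))
        idx = np.argpartition(keys, s - 1, axis=1)[:, :s]
        overlaps = term_mask[idx].sum(axis=1)
        count_ge = int((overlaps >= observed).sum())
    p = (1 + count_ge) / (1 + B)
    return FameRecord(mirna=mirna, term=term, observed=observed, p=p, B=B, seed=seed)


def annotate_top_candidates(
    records: pd.DataFrame,
    fame_results: list[FameRecord],
    p_threshold: float = 0.05,
) -> pd.DataFrame:
    """Join the miRNA ranking with significant empirical GO associations.

    Empirical p-values are BH-adjusted across all tested (miRNA, term) pairs;
    pairs below ``p_threshold`` after adjustment appear in the
    ``significant_terms`` column (empty for candidates with none, as for
    lower-ranked rows of a typical report).
    """
    if "rank" not in records.columns:
        raise ValueError("records must be a ranked aggregate_targets table")
    out = records.copy()
    out["significant_terms"] = ""
    out["fame_p"] = ""
    if fame_results:
        fame_df = pd.DataFrame(
            [
                {"mirna": r.mirna, "term": r.term, "observed": r.observed, "p": r.p}
                for r in fame_results
            ]
        )
        fame_df["p_adj"] = bh_adjust(fame_df["p"].to_numpy())
        sig = fame_df[fame_df["p_adj"] < p_threshold]
        for mirna, grp in sig.groupby("mirna"):
            grp = grp.sort_values(["p_adj", "p", "term"], kind="mergesort")
            mask = out["mirna"] == mirna
            out.loc[mask, "significant_terms"] = ";".join(grp["term"])
            out.loc[mask, "fame_p"] = ";".join(f"{v:.4g}" for v in grp["p"])
    return out
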