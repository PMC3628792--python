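"""Differential-expression selection: rank test, two-way ANOVA, fold change, and the
three-list combination that yields the candidate gene set.

Three selection lists mirror the study design for a two-strain (e.g. LEW vs PVG)
LPS-stimulation experiment:

* List 1 — strain contrast under LPS at one duration: Mann–Whitney U with BH
  correction, plus a raw-scale fold-change threshold.
* List 2 — LPS response within either strain: fold-change threshold alone
  ("at least one condition").
* List 3 — two-way ANOVA across the factorial design, BH-adjusted p of a chosen
  main effect.

Lists are combined either as the full union or as genes shared by at least two
of the three lists; both rules are reported with the 7-region Venn partition.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionMatrix

log = logging.getLogger(__name__)


@dataclass
class SelectionCriteria:
    """Thresholds for one selection list.

    fc_threshold is a raw-scale ratio (>= 1); p_threshold applies to BH-adjusted
    p-values.  The permissive p_threshold=0.5 used in less-stringent screening is
    flagged in logs because it is unusually lax.
    """

    fc_threshold: float = 1.5
    p_threshold: float = 0.05
    test: str = "mann_whitney"
    correction: str = "BH"

    def __post_init__(self) -> None:
        if self.fc_threshold < 1:
            raise ValueError("fc_threshold must be >= 1 (direction-free ratio)")
        if not (0 < self.p_threshold <= 1):
            raise ValueError("p_threshold must be in (0, 1]")
        if self.test not in ("mann_whitney", "anova"):
            raise ValueError(f"unknown test {self.test!r}")
        if self.correction != "BH":
            raise ValueError("only BH correction is supported")
        if self.p_threshold > 0.2:
            log.warning(
                "p_threshold=%.3g is unusually permissive (less-stringent mode)",
                self.p_threshold,
            )


@dataclass
class VennPartition:
    """Counts for the 7 regions of three gene sets plus the combined set."""

    region_counts: dict[str, int]
    combined_set: set[str]
    rule: str

    def __post_init__(self) -> None:
        if self.rule not in ("union_all", "shared_by_2_of_3"):
            raise ValueError(f"unknown combination rule {self.rule!r}")


def mann_whitney_u(
    group_a, group_b, alternative: str = "two-sided"
) -> tuple[float, float, str]:
    """Mann–Whitney U with midrank ties.

    Exact p by full enumeration when n1+n2 <= 12 and the pooled data is
    tie-free; otherwise the normal approximation with tie correction (and
    continuity correction).  Returns ``(U, p, method)`` where U is the statistic
    of the first group.  Accepts 2-D arrays (last axis = observations) for
    vectorized per-gene testing.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    n1, n2 = a.shape[-1], b.shape[-1]
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"each group needs >= 2 observations (got {n1} and {n2})"
        )
    pooled = np.concatenate([a, b], axis=-1)
    has_ties = bool(
        (np.sort(pooled, axis=-1)[..., 1:] == np.sort(pooled, axis=-1)[..., :-1]).any()
    )
    method = "exact" if (n1 + n2 <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method, axis=-1)
    return res.statistic, res.pvalue, method


def two_way_anova(
    values,
    factor_a,
    factor_b,
    replicated: bool = True,
    factor_names: tuple[str, str] = ("A", "B"),
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Balanced two-factor ANOVA, vectorized over genes.

    ``values`` is (genes × samples) or 1-D; ``factor_a``/``factor_b`` give the
    per-sample levels.  With ``replicated=True`` the full model with interaction
    is fit; otherwise the additive model (residual = interaction cell).  Returns
    a dict mapping factor name (and ``"interaction"`` when fitted) to (F, p)
    arrays.

    Noiseless planted effects produce zero residual mean square; these are
    guarded: F=inf with p=0 for factors with positive effect SS, p=1 otherwise.
    """
    X = np.atleast_2d(np.asarray(values, dtype=float))
    fa = np.asarray(factor_a)
    fb = np.asarray(factor_b)
    n = X.shape[1]
    if fa.shape[0] != n or fb.shape[0] != n:
        raise ValueError("factor length does not match sample count")
    levels_a, ia = np.unique(fa, return_inverse=True)
    levels_b, ib = np.unique(fb, return_inverse=True)
    A, B = len(levels_a), len(levels_b)
    if A < 2 or B < 2:
        raise ValueError("each factor needs >= 2 levels")
    cell = ia * B + ib
    counts = np.bincount(cell, minlength=A * B)
    if (counts == 0).any():
        empty = [(levels_a[c // B], levels_b[c % B]) for c in np.where(counts == 0)[0]]
        raise ValueError(f"empty design cells: {empty}")
    if len(set(counts)) != 1:
        raise ValueError(f"unbalanced design (cell counts {sorted(set(counts))})")
    r = int(counts[0])
    if replicated and r < 2:
        raise ValueError("replicated model needs >= 2 observations per cell")

    grand = X.mean(axis=1, keepdims=True)
    centered = X - grand

    def _group_means(idx, n_levels):
        sums = np.zeros((X.shape[0], n_levels))
        np.add.at(sums.T, idx, centered.T)
        return sums / np.bincount(idx, minlength=n_levels)

    ma = _group_means(ia, A)  # deviations of factor-A level means
    mb = _group_means(ib, B)
    mcell = _group_means(cell, A * B)
    na = np.bincount(ia, minlength=A)
    nb = np.bincount(ib, minlength=B)
    ss_a = (na * ma**2).sum(axis=1)
    ss_b = (nb * mb**2).sum(axis=1)
    ss_cells = (counts * mcell**2).sum(axis=1)
    ss_ab = ss_cells - ss_a - ss_b
    ss_t = (centered**2).sum(axis=1)

    df_a, df_b, df_ab = A - 1, B - 1, (A - 1) * (B - 1)
    if replicated:
        ss_e = ss_t - ss_cells
        df_e = n - A * B
    else:
        ss_e = ss_t - ss_a - ss_b
        df_e = df_ab
    if df_e <= 0:
        raise ValueError("zero residual degrees of freedom")
    ss_e = np.maximum(ss_e, 0.0)
    ms_e = ss_e / df_e

    def _ftest(ss, df):
        ms = ss / df
        F = np.full_like(ms, np.nan)
        p = np.ones_like(ms)
        pos = ms_e > 0
        F[pos] = ms[pos] / ms_e[pos]
        p[pos] = stats.f.sf(F[pos], df, df_e)
        degenerate = ~pos & (ms > 0)  # zero noise, nonzero effect
        F[degenerate] = np.inf
        p[degenerate] = 0.0
        return F, p

    out = {factor_names[0]: _ftest(ss_a, df_a), factor_names[1]: _ftest(ss_b, df_b)}
    if replicated:
        out["interaction"] = _ftest(ss_ab, df_ab)
    return out


def fold_change(
    m: ExpressionMatrix, group1: list[str], group2: list[str]
) -> pd.DataFrame:
    """Per-gene raw-scale fold change between two sample groups.

    The matrix must be log2-normalized; the ratio of anti-logged group means is
    reported direction-free (``fold_change = max(r, 1/r)``) with a ``direction``
    sign (+1 when group1 > group2).
    """
    if m.scale != "log2":
        raise ValueError("fold_change expects a log2-normalized matrix")
    for grp, name in ((group1, "group1"), (group2, "group2")):
        if not grp:
            raise ValueError(f"{name} is empty")
        unknown = [s for s in grp if s not in m.sample_ids]
        if unknown:
            raise ValueError(f"{name} samples not in matrix: {unknown}")
    mean1 = m.values[list(group1)].mean(axis=1)
    mean2 = m.values[list(group2)].mean(axis=1)
    log2_diff = mean1 - mean2
    ratio = np.power(2.0, log2_diff)
    fc = np.maximum(ratio, 1.0 / ratio)
    return pd.DataFrame(
        {
            "log2_diff": log2_diff,
            "ratio": ratio,
            "fold_change": fc,
            "direction": np.sign(log2_diff).astype(int),
        },
        index=m.gene_ids,
    )


def bh_adjust(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (capped at 1, ties preserved)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        bad = p[~((p >= 0) & (p <= 1))]
        raise ValueError(f"p-values outside [0, 1]: {bad[:5]}")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DESelection:
    """The three selected gene lists and their per-gene statistics tables."""

    lists: dict[str, set[str]]
    results: dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)


def select_de_genes(
    m: ExpressionMatrix,
    universe: set[str] | None = None,
    duration: str = "24h",
    criteria1: SelectionCriteria | None = None,
    criteria2: SelectionCriteria | None = None,
    criteria3: SelectionCriteria | None = None,
    anova_factors: tuple[str, str] = ("strain", "treatment"),
    anova_p_factor: str = "strain",
    lps_label: str = "LPS",
    control_label: str = "control",
) -> DESelection:
    """Apply the three selection criteria to a normalized matrix.

    List 1: rank test (BH-adjusted p < threshold) AND fold change >= threshold
    for the strain contrast under LPS at ``duration``.
    List 2: fold change >= threshold between LPS and control within either strain.
    List 3: two-way ANOVA over ``anova_factors``; BH-adjusted p of
    ``anova_p_factor`` < threshold (factor choice logged).
    """
    criteria1 = criteria1 or SelectionCriteria()
    criteria2 = criteria2 or SelectionCriteria()
    criteria3 = criteria3 or SelectionCriteria(test="anova")
    if m.scale != "log2":
        raise ValueError("select_de_genes expects a log2-normalized matrix")
    if universe is not None:
        m = m.subset_genes(universe)
    strains = sorted(m.design["strain"].unique())
    if len(strains) != 2:
        raise ValueError(f"expected exactly 2 strains, found {strains}")
    s1, s2 = strains
    genes = m.gene_ids

    # --- List 1: strain contrast under LPS ------------------------------------
    g1 = m.samples_where(strain=s1, treatment=lps_label, duration=duration)
    g2 = m.samples_where(strain=s2, treatment=lps_label, duration=duration)
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError(
            f"strain contrast under {lps_label} at {duration} needs >= 2 samples "
            f"per group (got {len(g1)} and {len(g2)})"
        )
    U, p1, method1 = mann_whitney_u(m.values[g1].to_numpy(), m.values[g2].to_numpy())
    padj1 = bh_adjust(p1)
    fc1 = fold_change(m, g1, g2)
    res1 = pd.DataFrame(
        {
            "statistic": U,
            "p": p1,
            "p_adj": padj1,
            "log2_fc": fc1["log2_diff"],
            "fold_change": fc1["fold_change"],
            "contrast": f"{s1}-{lps_label} vs {s2}-{lps_label} ({duration})",
        },
        index=genes,
    )
    list1 = set(
        genes[(padj1 < criteria1.p_threshold) & (fc1["fold_change"] >= criteria1.fc_threshold)]
    )

    # --- List 2: LPS response within either strain ----------------------------
    frames = []
    in_any = np.zeros(len(genes), dtype=bool)
    for strain in strains:
        trt = m.samples_where(strain=strain, treatment=lps_label, duration=duration)
        ctl = m.samples_where(strain=strain, treatment=control_label, duration=duration)
        if not trt or not ctl:
            raise ValueError(
                f"strain {strain!r} lacks {lps_label} or {control_label} samples "
                f"at {duration}"
            )
        fc = fold_change(m, trt, ctl)
        fc["contrast"] = f"{strain}: {lps_label} vs {control_label} ({duration})"
        frames.append(fc)
        in_any |= (fc["fold_change"] >= criteria2.fc_threshold).to_numpy()
    res2 = pd.concat(frames, keys=strains, names=["strain", "gene"])
    list2 = set(genes[in_any])

    # --- List 3: two-way ANOVA ------------------------------------------------
    fa = m.design[anova_factors[0]].to_numpy()
    fb = m.design[anova_factors[1]].to_numpy()
    anova = two_way_anova(
        m.values.to_numpy(), fa, fb, replicated=True, factor_names=anova_factors
    )
    if anova_p_factor not in anova:
        raise ValueError(
            f"anova_p_factor {anova_p_factor!r} not among fitted factors {list(anova)}"
        )
    F3, p3 = anova[anova_p_factor]
    padj3 = bh_adjust(p3)
    res3 = pd.DataFrame(
        {
            "statistic": F3,
            "p": p3,
            "p_adj": padj3,
            "contrast": f"ANOVA {anova_factors[0]}x{anova_factors[1]}: {anova_p_factor}",
        },
        index=genes,
    )
    list3 = set(genes[padj3 < criteria3.p_threshold])
    log.info(
        "List3 thresholds BH-adjusted ANOVA p of the %r main effect "
        "(factors %s)", anova_p_factor, anova_factors
    )

    return DESelection(
        lists={"list1": list1, "list2": list2, "list3": list3},
        results={"list1": res1, "list2": res2, "list3": res3},
        provenance={
            "n_genes_tested": len(genes),
            "duration": duration,
            "mann_whitney_method": method1,
            "anova_factors": list(anova_factors),
            "anova_p_factor": anova_p_factor,
            "list_sizes": {"list1": len(list1), "list2": len(list2), "list3": len(list3)},
        },
    )


def combine_lists(
    a: set[str], b: set[str], c: set[str], rule: str = "union_all"
) -> VennPartition:
    """Combine three gene lists; compute the 7-region Venn partition.

    ``union_all`` keeps every gene in any list; ``shared_by_2_of_3`` keeps genes
    in at least two lists.  Region keys are membership patterns "abc" in
    {0,1}^3, e.g. "110" = in A and B only.
    """
    a, b, c = set(a), set(b), set(c)
    regions: dict[str, int] = {}
    union = a | b | c
    for pat in ("100", "010", "001", "110", "101", "011", "111"):
        sel = union
        for flag, s in zip(pat, (a, b, c)):
            sel = sel & s if flag == "1" else sel - s
        regions[pat] = len(sel)
    if rule == "union_all":
        combined = union
    elif rule == "shared_by_2_of_3":
        combined = (a & b) | (a & c) | (b & c)
    else:
        raise ValueError(f"unknown combination rule {rule!r}")
    return VennPartition(region_counts=regions, combined_set=combined, rule=rule)
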