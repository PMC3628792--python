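"""Model-free GO over-representation analysis against a declared gene universe.

Each term is scored with the hypergeometric upper tail P(X >= k) for k query
genes among K term members in a universe of N, with BH correction across
exactly the tested terms.  Annotations are flat term→gene sets (no ontology
graph propagation); terms outside a configurable size band are excluded from
the BH family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class GOAnnotation:
    """Term→gene-set map with a declared universe and optional term names."""

    terms: dict[str, set[str]]
    universe: set[str]
    names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.terms = {t: set(g) for t, g in self.terms.items()}
        self.universe = set(self.universe)
        stray = set().union(*self.terms.values(), set()) - self.universe
        if stray:
            raise ValueError(
                f"{len(stray)} annotated genes are outside the universe "
                f"(e.g. {sorted(stray)[:5]}); restrict() the annotation first"
            )

    def restrict(self, universe: set[str]) -> "GOAnnotation":
        """Intersect every term (and the universe) with a new universe."""
        universe = set(universe)
        return GOAnnotation(
            terms={t: g & universe for t, g in self.terms.items()},
            universe=self.universe & universe,
            names=dict(self.names),
        )


def read_go_tsv(path, universe: set[str] | None = None) -> GOAnnotation:
    """Two-column TSV (gene, term); universe defaults to the annotated genes."""
    df = pd.read_csv(path, sep="\t", header=0, names=["gene", "term"], dtype=str)
    terms: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        terms.setdefault(term, set()).add(gene)
    ann_genes = set(df["gene"])
    ann = GOAnnotation(terms=terms, universe=ann_genes)
    return ann if universe is None else ann.restrict(universe)


def read_gmt(path, universe: set[str] | None = None) -> GOAnnotation:
    """GMT: one term per line — term, description, then member genes."""
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            terms[parts[0]] = set(parts[2:])
            names[parts[0]] = parts[1]
    all_genes = set().union(*terms.values(), set())
    ann = GOAnnotation(terms=terms, universe=all_genes, names=names)
    return ann if universe is None else ann.restrict(universe)


def write_go_tsv(ann: GOAnnotation, path) -> None:
    rows = [(g, t) for t in sorted(ann.terms) for g in sorted(ann.terms[t])]
    pd.DataFrame(rows, columns=["gene", "term"]).to_csv(path, sep="\t", index=False)


def write_gmt(ann: GOAnnotation, path) -> None:
    with open(path, "w") as fh:
        for t in sorted(ann.terms):
            name = ann.names.get(t, t)
            fh.write("\t".join([t, name, *sorted(ann.terms[t])]) + "\n")


def hypergeometric_p(k: int, n: int, K: int, N: int) -> float:
    """Upper tail P(X >= k) for X ~ Hypergeometric(N population, K marked, n drawn).

    Computed with log-gamma-stabilized exact summation (scipy survival
    function).  P(X >= 0) = 1 by convention.
    """
    k, n, K, N = int(k), int(n), int(K), int(N)
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"inconsistent counts: k={k}, n={n}, K={K}")
    if n > N or K > N:
        raise ValueError(f"n={n} and K={K} must not exceed N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: set[str],
    ann: GOAnnotation,
    min_term_size: int = 2,
    max_term_size: int = 500,
) -> pd.DataFrame:
    """Test every annotation term within the size band for over-representation.

    Query genes outside the universe are dropped with a logged warning.  BH
    correction spans exactly the tested terms.  Result is sorted by (p_adj, p)
    and carries the overlap gene list per term.
    """
    query = set(query)
    dropped = query - ann.universe
    if dropped:
        log.warning(
            "%d query genes outside the universe were dropped (e.g. %s)",
            len(dropped),
            sorted(dropped)[:5],
        )
    query &= ann.universe
    if not query:
        raise ValueError("query is empty after intersecting with the universe")
    N = len(ann.universe)
    n = len(query)
    rows = []
    for term in sorted(ann.terms):
        members = ann.terms[term] & ann.universe
        K = len(members)
        if not (min_term_size <= K <= max_term_size):
            continue
        overlap = members & query
        k = len(overlap)
        rows.append(
            {
                "term": term,
                "name": ann.names.get(term, term),
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": hypergeometric_p(k, n, K, N),
                "genes": ";".join(sorted(overlap)),
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=["term", "name", "k", "n", "K", "N", "p", "p_adj", "genes"]
        )
    df = pd.DataFrame(rows)
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df = df.sort_values(["p_adj", "p", "term"], kind="mergesort").reset_index(drop=True)
    return df[["term", "name", "k", "n", "K", "N", "p", "p_adj", "genes"]]
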