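"""Expression-matrix data model, percentile-shift normalization, and detection-flag filtering.

The central container is :class:`ExpressionMatrix`: a genes × samples matrix of
bead-array intensities (raw or log2-normalized), a parallel matrix of detection
flags (P present / M marginal / A absent), and a per-sample design sheet with
the three experimental factors (strain, treatment, duration).

Normalization follows the percentile-shift scheme used for bead arrays: log2
transform, subtract the per-sample 75th percentile, then subtract the per-gene
median across samples.  Both centering vectors are returned in a
:class:`NormalizationReport` so the exact convention (linear-interpolation
percentile) is auditable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

REQUIRED_FACTORS = ("strain", "treatment", "duration")
VALID_FLAGS = frozenset({"P", "M", "A"})


@dataclass
class ExpressionMatrix:
    """Genes × samples expression values with detection flags and a design sheet.

    Parameters
    ----------
    values
        DataFrame indexed by gene id, columns are sample ids.
    flags
        Same shape as ``values``; entries in {P, M, A}.
    design
        DataFrame indexed by sample id with columns strain, treatment, duration.
    scale
        ``"raw"`` (positive intensities) or ``"log2"`` (normalized).
    """

    values: pd.DataFrame
    flags: pd.DataFrame
    design: pd.DataFrame
    scale: str = "raw"

    def __post_init__(self) -> None:
        if self.scale not in ("raw", "log2"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:10]}")
        vals = self.values.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            bad = [
                (g, s)
                for g, row in self.values.iterrows()
                for s, v in row.items()
                if not isinstance(v, (int, float, np.number))
            ]
            raise ValueError(f"non-numeric cells at {bad[:10]}")
        if not np.isfinite(vals).all():
            gi, si = np.argwhere(~np.isfinite(vals))[0]
            raise ValueError(
                f"non-finite value at gene {self.values.index[gi]!r}, "
                f"sample {self.values.columns[si]!r}"
            )
        if self.flags.shape != self.values.shape:
            raise ValueError(
                f"flags shape {self.flags.shape} != values shape {self.values.shape}"
            )
        if not self.flags.index.equals(self.values.index) or not self.flags.columns.equals(
            self.values.columns
        ):
            self.flags = self.flags.reindex(index=self.values.index, columns=self.values.columns)
        bad_flags = set(np.unique(self.flags.to_numpy().astype(str))) - VALID_FLAGS
        if bad_flags:
            raise ValueError(f"invalid detection flags: {sorted(bad_flags)}")
        missing = [s for s in self.values.columns if s not in self.design.index]
        if missing:
            raise ValueError(f"samples missing from design sheet: {missing}")
        for col in REQUIRED_FACTORS:
            if col not in self.design.columns:
                raise ValueError(f"design sheet lacks required factor {col!r}")
        self.design = self.design.loc[self.values.columns, list(REQUIRED_FACTORS)]

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def samples_where(self, **factors: str) -> list[str]:
        """Sample ids whose design row matches every given factor=level pair."""
        for f, level in factors.items():
            if f not in self.design.columns:
                raise ValueError(f"unknown design factor {f!r}")
            if level not in set(self.design[f]):
                raise ValueError(f"factor {f!r} has no level {level!r}")
        mask = pd.Series(True, index=self.design.index)
        for f, level in factors.items():
            mask &= self.design[f] == level
        return list(self.design.index[mask])

    def subset_genes(self, genes) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(
            values=self.values.loc[keep],
            flags=self.flags.loc[keep],
            design=self.design.copy(),
            scale=self.scale,
        )


@dataclass
class NormalizationReport:
    """Record of the centering vectors applied by percentile-shift normalization."""

    per_sample_p75: pd.Series
    per_gene_median: pd.Series
    scale_before: str = "raw"
    scale_after: str = "log2"
    percentile_rule: str = "linear interpolation between order statistics"

    def __post_init__(self) -> None:
        if self.per_sample_p75.isna().any() or self.per_gene_median.isna().any():
            raise ValueError("normalization centers contain NaN")


def read_expression(
    matrix_path, samplesheet_path, flags_path=None, scale: str = "raw"
) -> ExpressionMatrix:
    """Read an expression TSV (first column gene id), sample sheet, and optional flags TSV.

    Missing flags default to P with a logged warning.
    """
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric cells in {matrix_path}: {exc}") from exc
    design = pd.read_csv(samplesheet_path, sep="\t", index_col=0)
    missing = [s for s in values.columns if s not in design.index]
    if missing:
        raise ValueError(
            f"sample sheet {samplesheet_path} missing matrix columns: {missing}"
        )
    if flags_path is not None:
        flags = pd.read_csv(flags_path, sep="\t", index_col=0)
    else:
        log.warning("no flags file given; defaulting every flag to P (present)")
        flags = pd.DataFrame("P", index=values.index, columns=values.columns)
    return ExpressionMatrix(values=values, flags=flags, design=design, scale=scale)


def write_expression(m: ExpressionMatrix, matrix_path, flags_path, samplesheet_path) -> None:
    """Write the three-file on-disk form read back by :func:`read_expression`."""
    m.values.to_csv(matrix_path, sep="\t", index_label="gene_id")
    m.flags.to_csv(flags_path, sep="\t", index_label="gene_id")
    m.design.to_csv(samplesheet_path, sep="\t", index_label="sample_id")


def percentile_shift_normalize(
    m: ExpressionMatrix,
) -> tuple[ExpressionMatrix, NormalizationReport]:
    """Log2-transform, center each sample at its 75th percentile, each gene at its median.

    Input must be on the raw (strictly positive) scale.  After the first step the
    per-sample 75th percentile of log2 values is exactly 0; after the second the
    per-gene median is exactly 0.  "Divide by" the percentile/median on the raw
    scale becomes subtraction after log2.
    """
    if m.scale != "raw":
        raise ValueError("percentile_shift_normalize expects a raw-scale matrix")
    vals = m.values.to_numpy(dtype=float)
    if (vals <= 0).any():
        gi, si = np.argwhere(vals <= 0)[0]
        raise ValueError(
            f"non-positive raw value at gene {m.values.index[gi]!r}, "
            f"sample {m.values.columns[si]!r}: log2 undefined"
        )
    log2v = np.log2(vals)
    p75 = np.percentile(log2v, 75.0, axis=0)  # linear interpolation (numpy default)
    step1 = log2v - p75[None, :]
    med = np.median(step1, axis=1)
    out = step1 - med[:, None]
    norm = ExpressionMatrix(
        values=pd.DataFrame(out, index=m.values.index, columns=m.values.columns),
        flags=m.flags.copy(),
        design=m.design.copy(),
        scale="log2",
    )
    report = NormalizationReport(
        per_sample_p75=pd.Series(p75, index=m.values.columns),
        per_gene_median=pd.Series(med, index=m.values.index),
    )
    return norm, report


def flag_filter(m: ExpressionMatrix, min_informative: int = 1) -> set[str]:
    """Genes with at least ``min_informative`` P-or-M flags across all samples.

    This set is the default analysis universe for every downstream stage.
    """
    n_samples = len(m.sample_ids)
    if min_informative > n_samples:
        raise ValueError(
            f"min_informative={min_informative} exceeds sample count {n_samples}"
        )
    if min_informative < 1:
        raise ValueError("min_informative must be >= 1")
    informative = m.flags.isin(["P", "M"]).sum(axis=1)
    return set(informative.index[informative >= min_informative])
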