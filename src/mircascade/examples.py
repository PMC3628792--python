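"""Bundled worked example: a published-style candidate-miRNA table.

The packaged fixture reproduces the shape of a printed report in which 16
candidate miRNAs were scored against 9 promoter-enriched transcription
factors by two target-prediction algorithms (TargetScan 5.1 and miRanda).
``load_worked_example`` returns the 9-TF set and the two prediction tables so
:func:`mircascade.mirna_rank.aggregate_targets` can recompute the per-miRNA
sums and ranks from them.
"""

from __future__ import annotations

from importlib import resources

from .mirna_rank import TargetTable, read_target_tables


def load_worked_example() -> tuple[set[str], list[TargetTable]]:
    """Return (enriched TF set, target tables) for the bundled worked example."""
    data = resources.files("mircascade") / "data"
    tfs = set((data / "worked_example_enriched_tfs.txt").read_text().split())
    with resources.as_file(data / "worked_example_targets.tsv") as path:
        tables = read_target_tables(path)
    return tfs, tables
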