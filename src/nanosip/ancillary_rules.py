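"""Standalone filtering rules: proteomics detection/specificity and genome
pathway completeness.

Both thresholds are inclusive (>=). The proteomics filter is unit-agnostic:
"counts" may be spectral counts or peptide detections.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PathwayDefinition",
    "protein_passes_filter",
    "proteomics_detection_filter",
    "pathway_completeness",
]

#: Required columns of the long-format detection table.
DETECTION_COLUMNS = ("protein", "culture", "bio_rep", "tech_rep", "correct_sample", "count")


@dataclass(frozen=True)
class PathwayDefinition:
    """A pathway as a list of required steps.

    Each step is either a single gene name or a frozenset of alternate genes
    (an OR-group, satisfied if any variant is present).
    """

    pathway_id: str
    required: tuple
    genes_present: frozenset

    def __post_init__(self) -> None:
        if not self.required:
            raise ValueError("required gene set must be non-empty")


def protein_passes_filter(runs: pd.DataFrame) -> bool:
    """Apply both detection rules to one protein's runs.

    Rule 1: detected (count > 0) in both technical replicates of at least
    one (culture, biological replicate) pair.
    Rule 2: at least 80% of the protein's total counts fall in runs flagged
    as the correct sample (inclusive boundary). Zero total counts fail.
    """
    by_bio = runs.groupby(["culture", "bio_rep"])["count"]
    rule1 = bool(((by_bio.min() > 0) & (by_bio.count() >= 2)).any())

    total = runs["count"].sum()
    if total <= 0:
        return False
    correct = runs.loc[runs["correct_sample"], "count"].sum()
    rule2 = bool(correct / total >= 0.80)
    return rule1 and rule2


def proteomics_detection_filter(table: pd.DataFrame) -> list:
    """Retained proteins from a long-format detection table.

    The table has one row per (protein, run) with columns
    ``protein, culture, bio_rep, tech_rep, correct_sample, count``.
    """
    missing = [c for c in DETECTION_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"detection table missing columns: {missing}")
    if (table["count"] < 0).any():
        raise ValueError("detection counts must be non-negative")
    return [
        protein
        for protein, runs in table.groupby("protein", sort=True)
        if protein_passes_filter(runs)
    ]


def pathway_completeness(
    defn: PathwayDefinition, threshold: float = 0.75
) -> tuple[float, bool]:
    """Fraction of required steps present and the completeness verdict.

    A step is satisfied if its gene (or any alternate in an OR-group) is in
    ``genes_present``; the pathway is functionally complete when the
    satisfied fraction is >= threshold (inclusive).
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be a fraction")
    satisfied = 0
    for step in defn.required:
        alternates = step if isinstance(step, (set, frozenset, tuple, list)) else (step,)
        if any(g in defn.genes_present for g in alternates):
            satisfied += 1
    completeness = satisfied / len(defn.required)
    return completeness, completeness >= threshold
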