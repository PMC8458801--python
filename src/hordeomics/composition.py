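"""Amino-acid composition shift estimation and residue-rich classification.

The compositional-shift statistic compares the mean percent amino-acid
composition of the proteins that went up in a contrast against the mean
composition of those that went down: per residue, the ratio of set means
(up / down). The mean is an unweighted arithmetic mean over proteins — it
deliberately does not weight by protein abundance, so it indicates the
compositional direction of the proteome change rather than its mass
balance. A protein is called residue-rich (for K, M, W or any residue)
when its own percent content is at least 1.5x the mean content of a
background proteome; the boundary is inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import AMINO_ACIDS, ProteinRecord
from .differential import bh_adjust


@dataclass(frozen=True)
class CompositionProfile:
    """Percent composition over the 20 standard residues (X excluded)."""

    percent: dict[str, float]

    def __post_init__(self) -> None:
        total = sum(self.percent.values())
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"composition must sum to 100, got {total!r}")

    def __getitem__(self, residue: str) -> float:
        return self.percent[residue]


@dataclass(frozen=True)
class ResidueShift:
    residue: str
    mean_percent_up: float
    mean_percent_down: float
    ratio: float | None          # None when the down-set mean is zero
    p_value: float
    q_value: float


@dataclass(frozen=True)
class ResidueRichCall:
    protein_id: str
    residue: str
    protein_percent: float
    background_percent: float
    enrichment_factor: float
    rich: bool


def aa_percent(sequence: str) -> CompositionProfile:
    """Percent of each standard residue; X is excluded from the denominator."""
    counts = {aa: 0 for aa in AMINO_ACIDS}
    n = 0
    for c in sequence:
        if c in counts:
            counts[c] += 1
            n += 1
        elif c != "X":
            raise ValueError(f"illegal residue {c!r}")
    if n == 0:
        raise ValueError("sequence contains no standard residues")
    return CompositionProfile({aa: 100.0 * counts[aa] / n for aa in AMINO_ACIDS})


def set_mean_composition(profiles: list[CompositionProfile]) -> CompositionProfile:
    """Unweighted arithmetic mean per residue over a protein set."""
    if not profiles:
        raise ValueError("cannot average an empty set of profiles")
    return CompositionProfile(
        {aa: float(np.mean([p[aa] for p in profiles])) for aa in AMINO_ACIDS}
    )


def background_composition(reference: list[ProteinRecord]) -> CompositionProfile:
    """Mean composition of a reference proteome (same estimator as set means)."""
    if not reference:
        raise ValueError("reference proteome is empty")
    return set_mean_composition([aa_percent(r.sequence) for r in reference])


def composition_shift(
    up_proteins: list[ProteinRecord],
    down_proteins: list[ProteinRecord],
) -> list[ResidueShift]:
    """Per-residue up/down set-mean ratio with Mann-Whitney significance.

    The direction test compares per-protein residue percentages between the
    two sets with a two-sided Mann-Whitney U test, BH-adjusted across the
    20 residues. A residue absent from the down set yields an undefined
    (None) ratio rather than infinity.
    """
    if not up_proteins or not down_proteins:
        raise ValueError("both the up and the down set must be non-empty")
    up_prof = [aa_percent(r.sequence) for r in up_proteins]
    down_prof = [aa_percent(r.sequence) for r in down_proteins]
    up_mean = set_mean_composition(up_prof)
    down_mean = set_mean_composition(down_prof)
    pvals = []
    for aa in AMINO_ACIDS:
        u = [p[aa] for p in up_prof]
        d = [p[aa] for p in down_prof]
        if np.ptp(u + d) == 0:
            pvals.append(1.0)
        else:
            pvals.append(float(stats.mannwhitneyu(u, d, alternative="two-sided").pvalue))
    qvals = bh_adjust(np.array(pvals))
    shifts = []
    for aa, p, q in zip(AMINO_ACIDS, pvals, qvals):
        down_val = down_mean[aa]
        ratio = (up_mean[aa] / down_val) if down_val > 0 else None
        shifts.append(ResidueShift(aa, up_mean[aa], down_val, ratio, p, float(q)))
    return shifts


def classify_residue_rich(
    protein: ProteinRecord,
    residue: str,
    background: CompositionProfile,
    factor: float = 1.5,
) -> ResidueRichCall:
    """Rich iff protein percent / background percent >= factor (inclusive)."""
    if residue not in AMINO_ACIDS:
        raise ValueError(f"unknown residue {residue!r}")
    bg = background[residue]
    if bg <= 0:
        raise ValueError(f"background percent for {residue} is zero; enrichment undefined")
    pct = aa_percent(protein.sequence)[residue]
    enrichment = pct / bg
    return ResidueRichCall(protein.protein_id, residue, pct, bg, enrichment, enrichment >= factor)


def residue_rich_table(
    proteins: list[ProteinRecord],
    background: CompositionProfile,
    residues: tuple[str, ...] = ("K", "M", "W"),
    factor: float = 1.5,
) -> pd.DataFrame:
    rows = []
    for rec in proteins:
        for aa in residues:
            call = classify_residue_rich(rec, aa, background, factor)
            rows.append(
                {
                    "protein_id": call.protein_id,
                    "residue": call.residue,
                    "protein_percent": call.protein_percent,
                    "background_percent": call.background_percent,
                    "enrichment_factor": call.enrichment_factor,
                    "rich": call.rich,
                }
            )
    return pd.DataFrame(rows)


def shift_frame(shifts: list[ResidueShift]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "residue": [s.residue for s in shifts],
            "mean_percent_up": [s.mean_percent_up for s in shifts],
            "mean_percent_down": [s.mean_percent_down for s in shifts],
            "ratio": [s.ratio if s.ratio is not None else np.nan for s in shifts],
            "p_value": [s.p_value for s in shifts],
            "q_value": [s.q_value for s in shifts],
        }
    )
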