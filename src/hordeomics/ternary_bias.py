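"""Ternary abundance-bias categorization.

Each protein's mean abundance in three chosen lines is normalized to a
point on the 2-simplex and assigned to the nearest of seven ideal points
by Euclidean distance: the three corners (single-line dominance), the
three edge midpoints (two-line enrichment) and the centre (balanced).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io_core import AbundanceMatrix, logger

#: The seven ideal points of the corner/edge/centre scheme, in tie-break order.
IDEAL_POINTS: tuple[tuple[str, tuple[float, float, float]], ...] = (
    ("A-dominant", (1.0, 0.0, 0.0)),
    ("B-dominant", (0.0, 1.0, 0.0)),
    ("C-dominant", (0.0, 0.0, 1.0)),
    ("A+B-enriched", (0.5, 0.5, 0.0)),
    ("A+C-enriched", (0.5, 0.0, 0.5)),
    ("B+C-enriched", (0.0, 0.5, 0.5)),
    ("balanced", (1 / 3, 1 / 3, 1 / 3)),
)


@dataclass(frozen=True)
class TernaryPoint:
    protein_id: str
    fractions: tuple[float, float, float]
    category: str
    distance: float


def normalize_triplet(a: float, b: float, c: float) -> tuple[float, float, float]:
    """(a, b, c) / (a + b + c); requires a positive total."""
    total = a + b + c
    if total <= 0:
        raise ValueError("cannot normalize an all-zero abundance triplet")
    return (a / total, b / total, c / total)


def assign_category(
    fractions: Sequence[float],
    ideal_points: tuple[tuple[str, tuple[float, float, float]], ...] = IDEAL_POINTS,
) -> tuple[str, float]:
    """Nearest ideal point by Euclidean distance; ties break in listed order."""
    f = np.asarray(fractions, dtype=float)
    best_label, best_d = None, np.inf
    for label, point in ideal_points:
        d = float(np.linalg.norm(f - np.asarray(point)))
        if d < best_d - 1e-15:
            best_label, best_d = label, d
    return best_label, best_d


def ternary_panel(
    matrix: AbundanceMatrix,
    genotypes: tuple[str, str, str],
    log_scale: bool = False,
) -> list[TernaryPoint]:
    """One ternary point per protein for a three-genotype panel.

    Coordinates use per-genotype replicate means of raw abundances
    (``log_scale`` switches to log10 means). All-zero proteins are excluded
    with a log entry.
    """
    means = []
    for g in genotypes:
        m = matrix.genotype_means(g)
        means.append(np.log10(np.maximum(m, 1e-12)) if log_scale else m)
    triplets = np.column_stack(means)
    points: list[TernaryPoint] = []
    n_excluded = 0
    for pid, (a, b, c) in zip(matrix.protein_ids, triplets):
        total = a + b + c
        if not total > 0 or np.isnan(total):
            n_excluded += 1
            continue
        frac = normalize_triplet(float(a), float(b), float(c))
        category, dist = assign_category(frac)
        points.append(TernaryPoint(pid, frac, category, dist))
    if n_excluded:
        logger.info("ternary panel %s: excluded %d all-zero/missing proteins", genotypes, n_excluded)
    return points


def panel_frame(points: list[TernaryPoint], panel: tuple[str, str, str]) -> pd.DataFrame:
    """Tabular panel with plotting-ready Cartesian coordinates
    (x = b + c/2, y = sqrt(3)/2 * c)."""
    rows = []
    for p in points:
        a, b, c = p.fractions
        rows.append(
            {
                "protein_id": p.protein_id,
                "panel": "-".join(panel),
                "frac_a": a,
                "frac_b": b,
                "frac_c": c,
                "category": p.category,
                "distance": p.distance,
                "plot_x": b + c / 2.0,
                "plot_y": np.sqrt(3.0) / 2.0 * c,
            }
        )
    return pd.DataFrame(rows)
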