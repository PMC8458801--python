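"""Trait statistics: percent change vs wild type, one-way ANOVA with
Tukey's HSD, and compact letter displays.

Because published trait tables usually print only group summaries
(mean, sd, n), Tukey's test is offered in a summary-statistic mode that
reconstructs the pooled mean squared error as
``MSE = sum_i (n_i - 1) s_i^2 / sum_i (n_i - 1)`` and refers the
studentized range statistic ``q = |m_i - m_j| / sqrt(MSE/2 * (1/n_i + 1/n_j))``
to the studentized range distribution with ``k`` groups and
``sum_i (n_i - 1)`` error degrees of freedom. With raw replicate values the
same computation is applied to the observed summaries, which for balanced
one-way layouts coincides with the classical Tukey HSD procedure.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .io_core import PhenotypeGroup, PhenotypeTable, logger

ALPHA = 0.05


@dataclass(frozen=True)
class TraitComparison:
    trait: str
    genotype: str
    mean: float
    sd: float
    n: int
    percent_change_vs_wt: float
    tukey_p_vs_wt: float
    significant: bool


def percent_change(mutant_mean: float, wt_mean: float) -> float:
    """(mutant - wt) / wt x 100. Output tables round to one decimal."""
    if wt_mean == 0:
        raise ValueError("percent change undefined for a zero wild-type mean")
    return (mutant_mean - wt_mean) / wt_mean * 100.0


GroupSummary = tuple[str, float, float, int]  # (name, mean, sd, n)


def _summaries(
    groups: Sequence[tuple[str, Sequence[float]] | GroupSummary]
) -> list[GroupSummary]:
    out: list[GroupSummary] = []
    for g in groups:
        if len(g) == 4 and np.isscalar(g[1]):
            name, mean, sd, n = g
            out.append((str(name), float(mean), float(sd), int(n)))
        else:
            name, values = g[0], np.asarray(g[1], dtype=float)
            out.append((str(name), float(np.mean(values)), float(np.std(values, ddof=1)), len(values)))
    return out


def anova_tukey(
    groups: Sequence[tuple[str, Sequence[float]] | GroupSummary]
) -> dict[tuple[str, str], float]:
    """Tukey HSD adjusted p-values for every unordered group pair.

    Groups may be (name, replicate values) or (name, mean, sd, n) summary
    tuples. Requires >=2 groups with n >= 2 each.
    """
    summ = _summaries(groups)
    if len(summ) < 2:
        raise ValueError("Tukey's test needs at least two groups")
    if any(n < 2 for _, _, _, n in summ):
        raise ValueError("every group needs n >= 2")
    k = len(summ)
    df_err = sum(n - 1 for _, _, _, n in summ)
    mse = sum((n - 1) * sd**2 for _, _, sd, n in summ) / df_err
    pvals: dict[tuple[str, str], float] = {}
    if mse == 0.0:
        means = {name for name, m, _, _ in summ}
        if len({m for _, m, _, _ in summ}) > 1:
            logger.warning("zero within-group variance with unequal means; p reported as 0")
        for a in range(k):
            for b in range(a + 1, k):
                na, nb = summ[a][0], summ[b][0]
                pvals[(na, nb)] = 1.0 if summ[a][1] == summ[b][1] else 0.0
        return pvals
    for a in range(k):
        for b in range(a + 1, k):
            name_a, mean_a, _, n_a = summ[a]
            name_b, mean_b, _, n_b = summ[b]
            se = np.sqrt(mse / 2.0 * (1.0 / n_a + 1.0 / n_b))
            q = abs(mean_a - mean_b) / se
            pvals[(name_a, name_b)] = float(stats.studentized_range.sf(q, k, df_err))
    return pvals


def anova_f_p(
    groups: Sequence[tuple[str, Sequence[float]] | GroupSummary]
) -> tuple[float, float]:
    """One-way ANOVA (F, p) from group summaries or raw replicate values."""
    summ = _summaries(groups)
    k = len(summ)
    if k < 2:
        raise ValueError("ANOVA needs at least two groups")
    n_total = sum(n for _, _, _, n in summ)
    grand = sum(n * m for _, m, _, n in summ) / n_total
    ss_between = sum(n * (m - grand) ** 2 for _, m, _, n in summ)
    df_err = n_total - k
    mse = sum((n - 1) * sd**2 for _, _, sd, n in summ) / df_err
    if mse == 0:
        return (0.0, 1.0) if ss_between == 0 else (np.inf, 0.0)
    f = (ss_between / (k - 1)) / mse
    return float(f), float(stats.f.sf(f, k - 1, df_err))


def pair_p(pvals: Mapping[tuple[str, str], float], a: str, b: str) -> float:
    """Symmetric lookup into an unordered-pair p-value map."""
    if (a, b) in pvals:
        return pvals[(a, b)]
    return pvals[(b, a)]


def compact_letter_display(
    pvals: Mapping[tuple[str, str], float],
    alpha: float = ALPHA,
) -> dict[str, str]:
    """Insert-absorb compact letter display.

    Two groups share at least one letter iff they are NOT significantly
    different at ``alpha``. Intransitive patterns are handled by letting a
    group carry several letters; redundant (absorbed) letter columns are
    removed and letters assigned in group order.
    """
    names = sorted({n for pair in pvals for n in pair})
    sig = {
        (a, b)
        for a in names
        for b in names
        if a != b and pair_p(pvals, a, b) < alpha
    }
    # columns: sets of mutually non-significant groups
    columns: list[set[str]] = [set(names[:1])] if names else []
    for g in names[1:]:
        placed = False
        new_cols: list[set[str]] = []
        for col in columns:
            conflicts = {h for h in col if (g, h) in sig}
            if not conflicts:
                col.add(g)
                placed = True
            else:
                ok = col - conflicts
                if ok:
                    new_cols.append(ok | {g})
        columns.extend(new_cols)
        if not placed and not new_cols:
            columns.append({g})
        # absorb: drop columns contained in another
        columns = [
            c for i, c in enumerate(columns)
            if not any(i != j and c < d or (c == d and i > j) for j, d in enumerate(columns))
        ]
    # ensure every non-significant pair shares a column (absorb may have been
    # too eager for odd patterns); add minimal pair columns if needed
    def shares(a: str, b: str) -> bool:
        return any(a in c and b in c for c in columns)

    for a in names:
        for b in names:
            if a < b and (a, b) not in sig and not shares(a, b):
                columns.append({a, b})
    letters = "abcdefghijklmnopqrstuvwxyz"
    assignment = {n: "" for n in names}
    for i, col in enumerate(columns):
        for n in names:
            if n in col:
                assignment[n] += letters[i % len(letters)]
    return assignment


def compare_trait(
    table: PhenotypeTable, trait: str, reference: str = "WT", alpha: float = ALPHA
) -> list[TraitComparison]:
    """Full Table-style comparison of every genotype against the reference."""
    groups = table.trait_groups(trait)
    if reference not in groups:
        raise ValueError(f"reference genotype {reference!r} absent for trait {trait!r}")
    summaries: list[GroupSummary] = [
        (g.genotype, g.mean, g.sd, g.n) for g in groups.values()
    ]
    pvals = anova_tukey(summaries)
    wt = groups[reference]
    out = []
    for g in groups.values():
        if g.genotype == reference:
            continue
        p = pair_p(pvals, g.genotype, reference)
        out.append(
            TraitComparison(
                trait=trait,
                genotype=g.genotype,
                mean=g.mean,
                sd=g.sd,
                n=g.n,
                percent_change_vs_wt=percent_change(g.mean, wt.mean),
                tukey_p_vs_wt=p,
                significant=p < alpha,
            )
        )
    return out


def phenotype_report(table: PhenotypeTable, reference: str = "WT") -> "pd.DataFrame":
    import pandas as pd

    rows = []
    for trait in table.traits:
        for c in compare_trait(table, trait, reference):
            rows.append(
                {
                    "trait": c.trait,
                    "genotype": c.genotype,
                    "mean": c.mean,
                    "sd": c.sd,
                    "n": c.n,
                    "percent_change_vs_wt": round(c.percent_change_vs_wt, 1),
                    "tukey_p_vs_wt": c.tukey_p_vs_wt,
                    "significant": c.significant,
                }
            )
    return pd.DataFrame(rows)
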