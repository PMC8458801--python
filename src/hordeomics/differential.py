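"""Differential abundance and multivariate structure.

The quantitative workflow: log10 transformation with row mean-centring;
per-protein Welch t-tests on log2 values for each mutant-vs-reference
contrast, with Benjamini-Hochberg adjustment within the contrast and
volcano classification (fold change > 2 or < 0.5 plus a significance
gate); PCA of the normalized sample profiles; and PLS-DA with VIP
(variable importance in projection) scores for supervised feature
selection between two sample classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cross_decomposition import PLSRegression
from statsmodels.stats.multitest import multipletests

from .io_core import AbundanceMatrix, Config, logger


@dataclass(frozen=True)
class DifferentialResult:
    protein_id: str
    contrast: tuple[str, str]          # (mutant, reference)
    mean_log2_ratio: float
    p_value: float
    q_value: float
    status: str                        # up | down | unchanged


@dataclass(frozen=True)
class PcaSummary:
    sample_ids: list[str]
    scores: np.ndarray                 # samples x components
    variance_fraction: np.ndarray
    loadings: np.ndarray | None = None  # components x proteins
    sample_mean: np.ndarray | None = None


@dataclass(frozen=True)
class VipRanking:
    protein_ids: list[str]
    vip: np.ndarray
    selected: np.ndarray               # boolean, vip > threshold capped at top_n


def impute_half_minimum(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """Replace zeros and missing values by half the protein's smallest
    positive value, so the subsequent log transform is defined. Proteins
    with no positive value at all are left untouched (and excluded later).
    """
    values = matrix.values.copy()
    n_imputed = 0
    for i in range(values.shape[0]):
        row = values[i]
        bad = ~(row > 0)
        if bad.any():
            positive = row[row > 0]
            if positive.size:
                row[bad] = positive.min() / 2.0
                n_imputed += int(bad.sum())
    if n_imputed:
        logger.info("imputed %d zero/missing abundance cells at half row minimum", n_imputed)
    return AbundanceMatrix(matrix.protein_ids, matrix.design, values)


def normalize(matrix: AbundanceMatrix) -> AbundanceMatrix:
    """log10 transform then centre each protein row across samples."""
    values = matrix.values
    if np.nanmin(values) <= 0:
        raise ValueError(
            "normalize requires strictly positive values; impute zeros first "
            "(see impute_half_minimum)"
        )
    logged = np.log10(values)
    centred = logged - np.nanmean(logged, axis=1, keepdims=True)
    out = AbundanceMatrix.__new__(AbundanceMatrix)
    out.protein_ids = list(matrix.protein_ids)
    out.design = list(matrix.design)
    out.values = centred  # centred values may be negative; bypass the ctor check
    return out


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_status(
    log2_ratio: float, p: float, q: float, config: Config, use_q: bool = False
) -> str:
    gate = (q if use_q else p) <= (config.q_threshold if use_q else config.p_threshold)
    lfc = np.log2(config.fold_change)
    if gate and log2_ratio > lfc:
        return "up"
    if gate and log2_ratio < -lfc:
        return "down"
    return "unchanged"


def contrast_test(
    matrix: AbundanceMatrix,
    mutant: str,
    reference: str,
    config: Config | None = None,
    use_q_gate: bool = False,
) -> list[DifferentialResult]:
    """Two-sample t-test on log2 abundances, mutant vs reference replicates.

    The default is the pooled-variance (Student) test: at triplicate group
    sizes the Welch/Satterthwaite correction is markedly conservative
    (empirical size well below nominal), while the pooled test stays near
    the nominal level; ``config.ttest = "welch"`` switches to the
    unequal-variance form. Proteins with any missing (NaN) or non-positive
    value in either group are excluded from the contrast, with a logged
    count.
    """
    config = config or Config()
    mut = matrix.genotype_values(mutant)
    ref = matrix.genotype_values(reference)
    if mut.shape[1] < 2 or ref.shape[1] < 2:
        raise ValueError("both genotypes need >= 2 replicates")
    results: list[DifferentialResult] = []
    n_excluded = 0
    raw_p: list[float] = []
    rows: list[tuple[str, float]] = []
    for i, pid in enumerate(matrix.protein_ids):
        a, b = mut[i], ref[i]
        if np.any(~(a > 0)) or np.any(~(b > 0)):
            n_excluded += 1
            continue
        la, lb = np.log2(a), np.log2(b)
        ratio = float(np.mean(la) - np.mean(lb))
        if np.var(la) == 0 and np.var(lb) == 0:
            p = 1.0 if np.mean(la) == np.mean(lb) else 0.0
        else:
            p = float(
                stats.ttest_ind(la, lb, equal_var=(config.ttest == "student")).pvalue
            )
        rows.append((pid, ratio))
        raw_p.append(p)
    if n_excluded:
        logger.info(
            "contrast %s vs %s: excluded %d proteins with missing/non-positive values",
            mutant, reference, n_excluded,
        )
    q = bh_adjust(np.array(raw_p))
    for (pid, ratio), p, qv in zip(rows, raw_p, q):
        status = classify_status(ratio, p, qv, config, use_q=use_q_gate)
        results.append(DifferentialResult(pid, (mutant, reference), ratio, p, float(qv), status))
    logger.info(
        "contrast %s vs %s: %d tested, %d up, %d down (FC>%.1f, %s<=%.2g)",
        mutant, reference, len(results),
        sum(r.status == "up" for r in results),
        sum(r.status == "down" for r in results),
        config.fold_change,
        "q" if use_q_gate else "p",
        config.q_threshold if use_q_gate else config.p_threshold,
    )
    return results


def summarize_counts(results: list[DifferentialResult], n_quantified: int | None = None):
    """(n_up, n_down, n_changed, percent changed of quantified, one decimal)."""
    n_up = sum(r.status == "up" for r in results)
    n_down = sum(r.status == "down" for r in results)
    n_changed = n_up + n_down
    total = n_quantified if n_quantified is not None else len(results)
    fraction = round(100.0 * n_changed / total, 1) if total else 0.0
    return n_up, n_down, n_changed, fraction


def count_percent(n_changed: int, n_quantified: int) -> float:
    """Count-to-percent conversion as printed in results text, one decimal."""
    return round(100.0 * n_changed / n_quantified, 1)


def results_frame(results: list[DifferentialResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "protein_id": [r.protein_id for r in results],
            "mutant": [r.contrast[0] for r in results],
            "reference": [r.contrast[1] for r in results],
            "log2FC": [r.mean_log2_ratio for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
            "neg_log10_p": [-np.log10(r.p_value) if r.p_value > 0 else np.inf for r in results],
            "status": [r.status for r in results],
        }
    )


def pca(normalized: AbundanceMatrix, n_components: int = 3) -> PcaSummary:
    """PCA of samples in protein space via SVD of the centred data.

    Sign convention: within each component the loading of largest magnitude
    is made positive, so scores are reproducible across runs.
    """
    X = normalized.values.T  # samples x proteins
    n_samples = X.shape[0]
    if n_samples < 2:
        raise ValueError("PCA needs at least two samples")
    if n_components > n_samples - 1:
        logger.warning(
            "requested %d components but only %d available; truncating",
            n_components, n_samples - 1,
        )
        n_components = n_samples - 1
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for a in range(Vt.shape[0]):
        j = np.argmax(np.abs(Vt[a]))
        if Vt[a, j] < 0:
            Vt[a] *= -1
            U[:, a] *= -1
    scores = U * S
    var = S**2 / (n_samples - 1)
    total_var = np.sum(np.var(Xc, axis=0, ddof=1))
    frac = var / total_var if total_var > 0 else np.zeros_like(var)
    return PcaSummary(
        sample_ids=normalized.sample_ids,
        scores=scores[:, :n_components],
        variance_fraction=frac[:n_components],
        loadings=Vt[:n_components],
        sample_mean=X.mean(axis=0),
    )


def plsda_vip(
    normalized: AbundanceMatrix,
    class_labels: dict[str, int] | list[int],
    config: Config | None = None,
) -> VipRanking:
    """Two-class PLS-DA with VIP scores.

    The response is coded +/-1 per sample class; a NIPALS PLS regression
    with ``config.n_pls_components`` components is fitted and
    ``VIP_j = sqrt(P * sum_a w_aj^2 SSY_a / sum_a SSY_a)`` computed from the
    normalized x-weights ``w_a`` and the response variance ``SSY_a``
    explained by each component. Selection keeps VIP above the threshold,
    truncated to the ``vip_top_n`` highest scores.
    """
    config = config or Config()
    if isinstance(class_labels, dict):
        y = np.array([class_labels[s] for s in normalized.sample_ids], dtype=float)
    else:
        y = np.asarray(class_labels, dtype=float)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("PLS-DA here is two-class; got classes " + str(classes))
    y = np.where(y == classes[0], -1.0, 1.0)
    for c in (-1.0, 1.0):
        if np.sum(y == c) < 2:
            raise ValueError("each class needs >= 2 samples")
    X = normalized.values.T  # samples x proteins
    n_comp = min(config.n_pls_components, X.shape[0] - 1)
    pls = PLSRegression(n_components=n_comp, scale=False)
    pls.fit(X, y)
    W = pls.x_weights_                  # (P, A), unit-norm columns
    T = pls.x_scores_                   # (N, A)
    Q = pls.y_loadings_                 # (1, A)
    ssy = (Q[0] ** 2) * np.einsum("na,na->a", T, T)   # response SS per component
    P = X.shape[1]
    denom = ssy.sum()
    if denom == 0:
        vip = np.zeros(P)
    else:
        vip = np.sqrt(P * (W**2 @ ssy) / denom)
    order = np.argsort(-vip, kind="stable")
    selected = vip > config.vip_threshold
    if selected.sum() > config.vip_top_n:
        keep = np.zeros(P, dtype=bool)
        keep[order[: config.vip_top_n]] = True
        selected &= keep
    return VipRanking(list(normalized.protein_ids), vip, selected)
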