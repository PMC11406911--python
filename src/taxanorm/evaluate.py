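"""Downstream evaluation of normalization quality.

Differential-abundance (DA) calling on normalized values: per-taxon
two-sided Wilcoxon rank-sum tests between two sample groups, Benjamini–
Hochberg adjustment, and power/false-discovery-rate bookkeeping against
simulation truth; plus per-taxon log-fold-change summaries and simple
scaling baselines (total-sum scaling and simplified TMM/CSS-like scalers)
for comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EvalReport",
    "wilcoxon_da",
    "bh_adjust",
    "power_fdr",
    "lfc_summary",
    "evaluate_calls",
    "evaluate_simulation",
    "tss_normalize",
    "tmm_factors",
    "css_factors",
]


@dataclass(frozen=True)
class EvalReport:
    power: float
    fdr: float
    n_called: int
    q_values: np.ndarray
    lfc_mean: float = np.nan
    lfc_sd: float = np.nan
    lfc_min: float = np.nan
    lfc_max: float = np.nan


def wilcoxon_da(values: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Two-sided Wilcoxon rank-sum p-value per taxon (row).

    Ties are handled by midranks with the tie-corrected normal
    approximation.  A taxon constant across all samples gets p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.ndim != 2:
        raise ValueError("values must be taxa x samples")
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups are required")
    g0 = groups == labels[0]
    g1 = groups == labels[1]
    if g0.sum() < 2 or g1.sum() < 2:
        raise ValueError("each group needs at least 2 samples")
    pvals = np.ones(values.shape[0])
    for i, row in enumerate(values):
        if np.ptp(row) == 0:
            warnings.warn(f"taxon row {i} is constant; p-value set to 1")
            continue
        pvals[i] = stats.mannwhitneyu(row[g0], row[g1], alternative="two-sided",
                                      method="asymptotic").pvalue
    return pvals


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def power_fdr(q: np.ndarray, is_da: np.ndarray, alpha: float = 0.05):
    """Empirical power and FDR of the calls {q <= alpha} against truth.

    power = TP / (TP + FN); fdr = FP / (TP + FP), with 0/0 counted as 0
    (no calls means no false discoveries).
    """
    q = np.asarray(q, dtype=float)
    is_da = np.asarray(is_da, dtype=bool)
    called = q <= alpha
    tp = int(np.sum(called & is_da))
    fp = int(np.sum(called & ~is_da))
    fn = int(np.sum(~called & is_da))
    power = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    fdr = fp / (tp + fp) if (tp + fp) > 0 else 0.0
    return power, fdr, int(called.sum())


def evaluate_calls(values: np.ndarray, groups: np.ndarray, is_da: np.ndarray,
                   alpha: float = 0.05) -> EvalReport:
    """Wilcoxon + BH + power/FDR in one pass, with log-fold-change summary."""
    q = bh_adjust(wilcoxon_da(values, groups))
    power, fdr, n_called = power_fdr(q, is_da, alpha)
    mean, sd, lo, hi = lfc_summary(values, groups)
    return EvalReport(power=power, fdr=fdr, n_called=n_called, q_values=q,
                      lfc_mean=mean, lfc_sd=sd, lfc_min=lo, lfc_max=hi)


def evaluate_simulation(sim, fit_config=None, seed: int = 0,
                        alpha: float = 0.05, min_nonzero_samples: int = 10,
                        use_true_depths: bool = False) -> EvalReport:
    """Full pipeline on one simulated dataset: filter, fit, quantile-residual
    normalize, Wilcoxon + BH, power/FDR against the simulation truth.

    By default the fit uses the tool's own depth definition (log column
    sums); ``use_true_depths`` substitutes the generating library sizes.
    """
    from .em import FitConfig, fit_matrix
    from .io import filter_taxa
    from .normalize import normalize_matrix

    fit_config = fit_config or FitConfig()
    kept, _, _ = filter_taxa(sim.counts, min_nonzero_samples)
    depth = sim.depths if use_true_depths else None
    fits = fit_matrix(kept, fit_config, depth=depth)
    norm = normalize_matrix(kept, fits, seed=seed)
    truth = sim.truth.set_index("taxon_id").loc[kept.taxon_ids, "is_da"].to_numpy()
    return evaluate_calls(norm.values, sim.groups, truth, alpha=alpha)


def lfc_summary(values: np.ndarray, groups: np.ndarray):
    """Per-taxon group-mean difference of (normalized) values, summarized.

    On quantile-residual output the values are already on an additive scale
    (residuals can be negative, so a ratio is undefined); the per-taxon
    "log fold-change" is therefore the difference of group means.  Returns
    (mean, sd, min, max) across taxa.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if labels.size != 2:
        raise ValueError("exactly two groups are required")
    d = values[:, groups == labels[1]].mean(axis=1) - values[:, groups == labels[0]].mean(axis=1)
    return float(d.mean()), float(d.std(ddof=1)) if d.size > 1 else 0.0, float(d.min()), float(d.max())


def tss_normalize(counts: np.ndarray) -> np.ndarray:
    """Total-sum scaling: each column divided by its library size."""
    counts = np.asarray(counts, dtype=float)
    colsum = counts.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("TSS undefined for empty samples")
    return counts / colsum


def tmm_factors(counts: np.ndarray, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Simplified trimmed-mean-of-M-values size factors.

    Formula-level re-implementation (reference column = the one whose upper
    quartile is closest to the mean upper quartile; doubly trimmed mean of
    log-ratios over taxa positive in both columns), not a claim of
    equivalence to edgeR's released implementation.
    """
    counts = np.asarray(counts, dtype=float)
    colsum = counts.sum(axis=0)
    props = counts / colsum
    uq = np.array([np.quantile(c[c > 0], 0.75) if np.any(c > 0) else 0.0 for c in props.T])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.ones(counts.shape[1])
    pr = props[:, ref]
    for j in range(counts.shape[1]):
        pj = props[:, j]
        both = (pj > 0) & (pr > 0)
        if both.sum() < 2:
            continue
        m = np.log2(pj[both] / pr[both])
        a = 0.5 * np.log2(pj[both] * pr[both])
        keep = (
            (m >= np.quantile(m, trim_m)) & (m <= np.quantile(m, 1 - trim_m))
            & (a >= np.quantile(a, trim_a)) & (a <= np.quantile(a, 1 - trim_a))
        )
        if keep.any():
            factors[j] = 2.0 ** np.mean(m[keep])
    factors /= np.exp(np.mean(np.log(factors)))
    return factors * colsum / np.exp(np.mean(np.log(colsum)))


def css_factors(counts: np.ndarray, quantile: float = 0.5) -> np.ndarray:
    """Simplified cumulative-sum-scaling size factors.

    Sum of each column's counts up to its own ``quantile`` of positive
    counts, rescaled to geometric mean 1; a formula-level simplification of
    metagenomeSeq's CSS (which chooses the quantile adaptively).
    """
    counts = np.asarray(counts, dtype=float)
    factors = np.empty(counts.shape[1])
    for j, c in enumerate(counts.T):
        pos = c[c > 0]
        if pos.size == 0:
            factors[j] = 1.0
            continue
        ql = np.quantile(pos, quantile)
        factors[j] = c[c <= ql].sum() or 1.0
    return factors / np.exp(np.mean(np.log(factors)))
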