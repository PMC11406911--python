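"""Model-diagnosis likelihood-ratio tests for the depth effect.

Two nested-model tests, each comparing the full varying-dispersion model
against a constrained null per taxon and summing the per-taxon statistics:

* **prevalence** — H0: beta1_i = kappa1_i = 0 for every taxon, i.e. sequencing
  depth affects neither the mean nor the dispersion of any taxon.  The null
  fit is an intercept-only, fixed-dispersion (ZI)NB regression.
* **equivalence** — H0: beta1_i = 1 and kappa1_i = 0 for every taxon, the
  assumption under which a single sample-level size factor (scaling
  normalization) would suffice.  The null pins the depth coefficient at 1 via
  a mean offset and fixes the dispersion.

Each taxon contributes 2 * (loglik_full - loglik_null) with 2 degrees of
freedom; the global statistic is the sum, asymptotically chi-squared with
2p degrees of freedom.  Taxa whose full or null fit failed to converge are
excluded from the global sum with a warning (df reduced accordingly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .em import FitConfig, TaxonFit, fit_matrix
from .zinb import CountMatrix

__all__ = ["TestResult", "PerTaxonTest", "prevalence_test", "equivalence_test", "lrt_from_fits"]


@dataclass(frozen=True)
class PerTaxonTest:
    taxon_id: str
    statistic: float
    df: int
    p_value: float
    q_value: float
    converged: bool


@dataclass(frozen=True)
class TestResult:
    """Global LRT with its per-taxon decomposition."""

    test_name: str
    statistic: float
    df: int
    p_value: float
    per_taxon: list[PerTaxonTest] = field(repr=False)
    n_excluded: int = 0

    def reject(self, alpha: float = 0.05) -> bool:
        return self.p_value <= alpha


def lrt_from_fits(full: list[TaxonFit], null: list[TaxonFit],
                  test_name: str) -> TestResult:
    """Assemble the global and per-taxon LRT from matched fit lists.

    Per-taxon statistics are clamped at 0 (nested models; tiny negative
    values can arise from optimizer tolerance).
    """
    if len(full) != len(null):
        raise ValueError("full and null fit lists must align")
    stats_raw, ok_flags, ids = [], [], []
    for f, g in zip(full, null):
        if f.taxon_id != g.taxon_id:
            raise ValueError("full/null fits are not aligned by taxon")
        ids.append(f.taxon_id or "")
        ok = f.converged and g.converged and np.isfinite(f.loglik) and np.isfinite(g.loglik)
        stat = max(0.0, 2.0 * (f.loglik - g.loglik)) if ok else np.nan
        stats_raw.append(stat)
        ok_flags.append(ok)
    stats_arr = np.asarray(stats_raw)
    ok_arr = np.asarray(ok_flags)
    p_taxon = np.where(ok_arr, stats.chi2.sf(stats_arr, 2), np.nan)
    q_taxon = np.full_like(p_taxon, np.nan)
    if ok_arr.any():
        q_taxon[ok_arr] = multipletests(p_taxon[ok_arr], method="fdr_bh")[1]
    n_excluded = int((~ok_arr).sum())
    if n_excluded:
        warnings.warn(f"{test_name} test: {n_excluded} taxa excluded "
                      "from the global statistic (non-converged fits)")
    global_stat = float(np.nansum(stats_arr[ok_arr])) if ok_arr.any() else 0.0
    df = 2 * int(ok_arr.sum())
    p_global = float(stats.chi2.sf(global_stat, df)) if df > 0 else 1.0
    per_taxon = [
        PerTaxonTest(tid, float(s), 2, float(p), float(q), bool(ok))
        for tid, s, p, q, ok in zip(ids, stats_arr, p_taxon, q_taxon, ok_arr)
    ]
    return TestResult(test_name=test_name, statistic=global_stat, df=df,
                      p_value=p_global, per_taxon=per_taxon,
                      n_excluded=n_excluded)


def _run_test(counts: CountMatrix, config: FitConfig | None,
              null_constraint: str, name: str,
              depth: np.ndarray | None = None,
              full_fits: list[TaxonFit] | None = None) -> TestResult:
    config = config or FitConfig()
    if full_fits is None:
        full_fits = fit_matrix(counts, config, "full", depth=depth)
    null_fits = fit_matrix(counts, config, null_constraint, depth=depth)
    return lrt_from_fits(full_fits, null_fits, name)


def prevalence_test(counts: CountMatrix, config: FitConfig | None = None,
                    depth: np.ndarray | None = None,
                    full_fits: list[TaxonFit] | None = None) -> TestResult:
    """LRT of 'no depth effect on any taxon' (mean or dispersion)."""
    return _run_test(counts, config, "prevalence-null", "prevalence",
                     depth=depth, full_fits=full_fits)


def equivalence_test(counts: CountMatrix, config: FitConfig | None = None,
                     depth: np.ndarray | None = None,
                     full_fits: list[TaxonFit] | None = None) -> TestResult:
    """LRT of 'every taxon has depth coefficient 1 and fixed dispersion'."""
    return _run_test(counts, config, "equivalence-null", "equivalence",
                     depth=depth, full_fits=full_fits)
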