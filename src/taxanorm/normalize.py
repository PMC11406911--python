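"""Randomized quantile-residual normalization.

Given a fitted per-taxon model, the normalized value of count ``y`` is

    r = Phi^{-1}( F(y - 1) + u * f(y) )

with ``F``/``f`` the fitted ZINB (or NB) cdf/pmf at that cell, ``u`` a
uniform(0,1) draw, and ``Phi^{-1}`` the standard-normal quantile.  If the
model is correct, ``F(Y-1) + U f(Y)`` is uniform, so the residuals are
standard normal and independent of sequencing depth; positive residuals mean
more abundance than expected at that taxon's typical abundance and that
sample's depth, negative residuals less.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .em import TaxonFit
from .zinb import CountMatrix, ZinbPointParams

__all__ = ["NormalizedMatrix", "quantile_residual", "normalize_matrix"]

# keep Phi^{-1} finite for extreme tail counts
_CLAMP_LO = 1e-12
_CLAMP_HI = 1.0 - 1e-12


@dataclass(frozen=True)
class NormalizedMatrix:
    """Real-valued quantile residuals with the input's labels."""

    values: np.ndarray
    taxon_ids: list[str]
    sample_ids: list[str]
    seed: int | None

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match id lists")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("normalized values must be finite")


def _residual_args(y: np.ndarray, mu: np.ndarray, theta: np.ndarray,
                   pi: float, u: np.ndarray) -> np.ndarray:
    """F(y-1) + u*f(y) for the (possibly zero-inflated) NB, vectorized."""
    p_nb = theta / (theta + mu)
    nb_cdf_m1 = np.where(y > 0, stats.nbinom.cdf(y - 1, theta, p_nb), 0.0)
    nb_pmf = stats.nbinom.pmf(y, theta, p_nb)
    cdf_m1 = np.where(y > 0, pi + (1.0 - pi) * nb_cdf_m1, 0.0)
    pmf = (1.0 - pi) * nb_pmf + pi * (y == 0)
    return cdf_m1 + u * pmf


def quantile_residual(y: int, point: ZinbPointParams, u: float) -> float:
    """Randomized quantile residual of a single count.

    ``u`` must lie strictly inside (0, 1); the probability handed to the
    normal quantile is clamped to [1e-12, 1-1e-12] so the residual is finite.
    """
    if not 0.0 < u < 1.0:
        raise ValueError("u must be strictly inside (0, 1)")
    arg = _residual_args(np.asarray([float(y)]), np.asarray([point.mu]),
                         np.asarray([point.theta]), point.pi,
                         np.asarray([u]))[0]
    return float(stats.norm.ppf(np.clip(arg, _CLAMP_LO, _CLAMP_HI)))


def normalize_matrix(counts: CountMatrix, fits: list[TaxonFit],
                     seed: int | None = 0,
                     randomized: bool = True) -> NormalizedMatrix:
    """Quantile-residual normalization of a whole matrix.

    One uniform draw per cell, generated row-major (taxon-, then
    sample-order) from ``seed``, so the same seed reproduces the output
    bit for bit.  ``randomized=False`` uses the deterministic mid-quantile
    residual (u = 1/2) instead.  NB-class taxa use the plain NB cdf/pmf.
    """
    if len(fits) != counts.n_taxa:
        raise ValueError("one fit per retained taxon is required")
    for i, fit in enumerate(fits):
        if fit.taxon_id is not None and fit.taxon_id != counts.taxon_ids[i]:
            raise ValueError(
                f"fit {i} is for taxon {fit.taxon_id!r}, "
                f"matrix row is {counts.taxon_ids[i]!r}")
    p, n = counts.counts.shape
    if randomized:
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=(p, n))
    else:
        u = np.full((p, n), 0.5)
    values = np.empty((p, n))
    for i, fit in enumerate(fits):
        y = counts.counts[i].astype(float)
        pi = fit.pi if fit.model_class == "ZINB" else 0.0
        arg = _residual_args(y, fit.mu, fit.theta, pi, u[i])
        values[i] = stats.norm.ppf(np.clip(arg, _CLAMP_LO, _CLAMP_HI))
    return NormalizedMatrix(values=values, taxon_ids=list(counts.taxon_ids),
                            sample_ids=list(counts.sample_ids),
                            seed=seed if randomized else None)
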