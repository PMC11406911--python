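"""Synthetic microbiome count matrices from the depth-dependent ZINB model.

The generator emulates the study design used to validate the method:

* per-sample sequencing depths uniform on ``[a, b]`` (the covariate is the
  natural log of depth), with an optional multiplier for group 2 to create a
  depth-confounded, no-differential-abundance scenario;
* per-taxon coefficients drawn from documented ranges (a stand-in for
  templates estimated from real stool samples), or loaded from a TSV file;
* optional two-group design in which a chosen fraction of taxa receive a
  group log-fold-change ``beta2`` (half up-, half down-regulated, fold
  changes uniform on a configurable range);
* an equal-efficiency switch forcing ``beta1 = 1`` and ``kappa1 = 0`` for all
  taxa — the regime where a single size factor per sample would suffice.

Counts are drawn from the ZINB at the linked parameters via the
gamma–Poisson representation of the NB.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .zinb import CountMatrix, TaxonParams

__all__ = [
    "SimConfig",
    "SimResult",
    "make_template",
    "constrain_template",
    "simulate_counts",
    "write_template",
    "read_template",
]

# documented default coefficient ranges for the synthetic template: wide
# intercepts (very rare to dominant taxa), heterogeneous positive depth
# effects on the mean, mild depth effects on dispersion, moderate zero mass
TEMPLATE_RANGES: dict[str, tuple[float, float]] = {
    "beta0": (-12.0, 2.0),
    "beta1": (0.3, 1.6),
    "kappa0": (-1.0, 2.0),
    "kappa1": (-0.2, 0.5),
    "gamma": (-3.0, 1.0),
}

_MAX_POISSON_LAM = 1e15


@dataclass(frozen=True)
class SimConfig:
    """Design of one simulated dataset."""

    n_samples: int = 100
    n_taxa: int = 50
    depth_range: tuple[float, float] = (1e4, 1e5)  # raw library-size range [a, b]
    template: tuple[TaxonParams, ...] | None = None
    da_fraction: float = 0.0
    fold_range: tuple[float, float] = (2.0, 4.0)
    group_depth_multiplier: float = 1.0   # 3.0 reproduces the no-DA 3x depth shift
    equal_efficiency: bool = False
    two_groups: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = self.depth_range
        if not (0 < a < b):
            raise ValueError("depth_range must satisfy 0 < a < b")
        lo, hi = self.fold_range
        if not (1.0 < lo < hi):
            raise ValueError("fold_range must satisfy 1 < lo < hi")
        if not 0.0 <= self.da_fraction <= 1.0:
            raise ValueError("da_fraction must be in [0, 1]")
        if self.group_depth_multiplier <= 0:
            raise ValueError("group_depth_multiplier must be positive")
        if self.n_samples < 2 or self.n_taxa < 1:
            raise ValueError("need n_samples >= 2 and n_taxa >= 1")


@dataclass(frozen=True)
class SimResult:
    counts: CountMatrix
    depths: np.ndarray           # the generating library sizes (not column sums)
    log_depths: np.ndarray
    groups: np.ndarray           # 0/1 per sample
    truth: pd.DataFrame          # taxon_id, is_da, beta2
    template: tuple[TaxonParams, ...]
    config: SimConfig


# structural zeros are a rare-taxon phenomenon: community members that are
# conditionally absent are the low-abundance ones, while dominant taxa are
# present in every sample.  The zero-mass logit is tapered with expected
# abundance accordingly (slope/pivot below), so a taxon averaging ~30 counts
# at the central depth can carry substantial zero mass while one averaging
# thousands effectively cannot.
ZERO_MASS_TAPER_SLOPE = 8.0
ZERO_MASS_TAPER_PIVOT = np.log(30.0)


def make_template(
    n_taxa: int,
    rng: np.random.Generator,
    ranges: dict[str, tuple[float, float]] | None = None,
    x_center: float = 10.35,  # log depth at the centre of the default range
) -> list[TaxonParams]:
    """Draw a plausible per-taxon coefficient template."""
    if n_taxa < 1:
        raise ValueError("n_taxa must be >= 1")
    r = dict(TEMPLATE_RANGES)
    if ranges:
        r.update(ranges)
    draws = {k: rng.uniform(*r[k], size=n_taxa) for k in TEMPLATE_RANGES}
    eta_center = draws["beta0"] + draws["beta1"] * x_center
    draws["gamma"] = draws["gamma"] - ZERO_MASS_TAPER_SLOPE * np.maximum(
        0.0, eta_center - ZERO_MASS_TAPER_PIVOT)
    draws["gamma"] = np.maximum(draws["gamma"], -30.0)
    return [
        TaxonParams(draws["beta0"][i], draws["beta1"][i], draws["kappa0"][i],
                    draws["kappa1"][i], draws["gamma"][i])
        for i in range(n_taxa)
    ]


def constrain_template(
    template: list[TaxonParams] | tuple[TaxonParams, ...],
    x_center: float,
    beta1: float | None = None,
    kappa1: float | None = None,
    subset: np.ndarray | list[int] | None = None,
    preserve_center: bool = True,
) -> list[TaxonParams]:
    """Pin depth coefficients of (a subset of) taxa.

    With ``preserve_center`` (default) the corresponding intercept is shifted
    by ``(old - new) * x_center`` so the mean (or dispersion) at the centre
    log depth is unchanged — appropriate when pinning ``beta1`` at 1, where
    the taxon should stay as abundant as before.  With
    ``preserve_center=False`` the intercepts are left untouched, the
    convention of no-depth-effect null scenarios where slopes are simply
    zeroed and all other coefficients kept as drawn.
    """
    idx = set(range(len(template))) if subset is None else set(int(i) for i in subset)
    out = []
    for i, t in enumerate(template):
        if i not in idx:
            out.append(t)
            continue
        b0, b1, k0, k1, g = t.beta0, t.beta1, t.kappa0, t.kappa1, t.gamma
        eta_old = b0 + b1 * x_center
        if beta1 is not None:
            if preserve_center:
                b0 += (b1 - beta1) * x_center
            b1 = beta1
        if kappa1 is not None:
            if preserve_center:
                k0 += (k1 - kappa1) * x_center
            k1 = kappa1
        # the prevalence-abundance coupling of make_template must hold for
        # the *realized* abundance: a taxon made more abundant by pinning
        # beta1 loses zero mass accordingly (never regained when made rarer)
        eta_new = b0 + b1 * x_center
        extra = (max(0.0, eta_new - ZERO_MASS_TAPER_PIVOT)
                 - max(0.0, eta_old - ZERO_MASS_TAPER_PIVOT))
        if extra > 0:
            g = max(g - ZERO_MASS_TAPER_SLOPE * extra, -30.0)
        out.append(replace(t, beta0=b0, beta1=b1, kappa0=k0, kappa1=k1, gamma=g))
    return out


def _draw_zinb(rng: np.random.Generator, mu: np.ndarray, theta: np.ndarray,
               pi: np.ndarray) -> np.ndarray:
    lam = rng.gamma(shape=theta, scale=mu / theta)
    y = rng.poisson(np.minimum(lam, _MAX_POISSON_LAM))
    zero = rng.uniform(size=mu.shape) < pi
    return np.where(zero, 0, y).astype(np.int64)


def simulate_counts(config: SimConfig) -> SimResult:
    """Generate one dataset; identical config (incl. seed) gives identical output."""
    rng = np.random.default_rng(config.seed)
    n, p = config.n_samples, config.n_taxa
    a, b = config.depth_range
    x_center = np.log(np.sqrt(a * b))
    template = (list(config.template) if config.template is not None
                else make_template(p, rng, x_center=x_center))
    if len(template) != p:
        raise ValueError("template length does not match n_taxa")
    if config.equal_efficiency:
        template = constrain_template(template, x_center, beta1=1.0, kappa1=0.0)

    two_groups = config.two_groups or config.da_fraction > 0 or config.group_depth_multiplier != 1.0
    groups = np.zeros(n, dtype=int)
    if two_groups:
        perm = rng.permutation(n)
        groups[perm[: n // 2]] = 1

    m = config.group_depth_multiplier
    depths = rng.uniform(a, b, size=n)
    depths = np.where(groups == 1, depths * m, depths)
    x = np.log(depths)

    # DA assignment: floor of each 50/50 half of da_fraction * p
    n_half = int(np.floor(config.da_fraction * p / 2.0))
    beta2 = np.zeros(p)
    if n_half > 0:
        lo, hi = config.fold_range
        da_idx = rng.choice(p, size=2 * n_half, replace=False)
        up, down = da_idx[:n_half], da_idx[n_half:]
        beta2[up] = np.log(rng.uniform(lo, hi, size=n_half))
        beta2[down] = -np.log(rng.uniform(lo, hi, size=n_half))
    template = [replace(t, beta2=float(b2)) for t, b2 in zip(template, beta2)]

    def _draw_columns(cols: np.ndarray) -> np.ndarray:
        out = np.empty((p, cols.size), dtype=np.int64)
        for i, t in enumerate(template):
            eta_mu = np.clip(t.beta0 + t.beta1 * x[cols] + t.beta2 * groups[cols],
                             -30.0, 30.0)
            eta_th = np.clip(t.kappa0 + t.kappa1 * x[cols], -30.0, 30.0)
            pi = 1.0 / (1.0 + np.exp(-t.gamma))
            out[i] = _draw_zinb(rng, np.exp(eta_mu), np.exp(eta_th),
                                np.full(cols.size, pi))
        return out

    counts = _draw_columns(np.arange(n))
    # a sample with zero total reads would never enter a dataset; such
    # columns (possible only for tiny/sparse templates) are redrawn
    for _ in range(100):
        empty = np.flatnonzero(counts.sum(axis=0) == 0)
        if empty.size == 0:
            break
        counts[:, empty] = _draw_columns(empty)
    else:
        raise RuntimeError("template cannot produce non-empty samples")

    taxon_ids = [f"taxon_{i:04d}" for i in range(p)]
    sample_ids = [f"sample_{j:04d}" for j in range(n)]
    cm = CountMatrix(counts=counts, taxon_ids=taxon_ids, sample_ids=sample_ids)
    truth = pd.DataFrame({
        "taxon_id": taxon_ids,
        "is_da": beta2 != 0.0,
        "beta2": beta2,
    })
    return SimResult(counts=cm, depths=depths, log_depths=x, groups=groups,
                     truth=truth, template=tuple(template), config=config)


_TEMPLATE_COLS = ["taxon_id", "beta0", "beta1", "kappa0", "kappa1", "gamma", "beta2"]


def write_template(path, template: list[TaxonParams] | tuple[TaxonParams, ...]) -> None:
    rows = [{"taxon_id": f"taxon_{i:04d}", **{k: getattr(t, k) for k in _TEMPLATE_COLS[1:]}}
            for i, t in enumerate(template)]
    pd.DataFrame(rows, columns=_TEMPLATE_COLS).to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_template(path) -> list[TaxonParams]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = set(_TEMPLATE_COLS[1:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"template file missing columns: {sorted(missing)}")
    if "beta2" not in df.columns:
        df["beta2"] = 0.0
    return [TaxonParams(r.beta0, r.beta1, r.kappa0, r.kappa1, r.gamma, r.beta2)
            for r in df.itertuples()]
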