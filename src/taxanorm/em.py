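"""Per-taxon maximum-likelihood fitting of the depth-dependent ZINB model.

Each taxon is fit independently by an EM algorithm that treats the zero-mass
membership as the latent variable.  The E-step is the closed-form posterior
probability that an observed zero came from the point mass; the M-step splits
into a closed-form update of the zero-mass logit (``pi_hat = mean(w)``, since
``pi`` is intercept-only) and a quasi-Newton maximization of the
weight-downweighted NB log-likelihood over the mean/dispersion coefficients,
warm-started at the previous iterate with an analytic gradient (digamma
terms).  Convergence is declared on the relative change of the EM objective Q.

Taxa with a zero fraction below ``FitConfig.nb_zero_threshold`` are fit as a
plain varying-dispersion NB regression (no zero inflation): a ZINB fit on
nearly zero-free data cannot separate structural zeros from sampling zeros.

Constrained fits back the two diagnosis tests:

* ``prevalence-null`` — intercept-only, fixed dispersion (beta1 = kappa1 = 0);
* ``equivalence-null`` — depth coefficient pinned at the scaling-method value
  (beta1 = 1, implemented as a mean offset) with fixed dispersion (kappa1 = 0).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .zinb import CountMatrix, TaxonParams, depth_vector, nb_logpmf, taxon_loglik

__all__ = [
    "FitConfig",
    "TaxonFit",
    "CONSTRAINTS",
    "initialize",
    "e_step",
    "m_step",
    "fit_taxon",
    "fit_matrix",
]

# named constraint sets: fixed values for (beta1, kappa1)
CONSTRAINTS: dict[str, dict[str, float]] = {
    "full": {},
    "fixed-dispersion": {"kappa1": 0.0},
    "prevalence-null": {"beta1": 0.0, "kappa1": 0.0},
    "equivalence-null": {"beta1": 1.0, "kappa1": 0.0},
}

_PARAM_ORDER = ("beta0", "beta1", "kappa0", "kappa1")
# admissible coefficient box (centered covariate).  The dispersion bounds are
# deliberately much tighter than the mean bounds: depth effects on dispersion
# beyond |kappa1| ~ 1 are never seen in data, and unbounded kappa1 lets the
# likelihood chase individual outliers with extreme dispersion slopes
_BOUNDS = {"beta0": (-40.0, 40.0), "beta1": (-15.0, 15.0),
           "kappa0": (-10.0, 15.0), "kappa1": (-3.0, 3.0)}
_PI_EPS = 1e-10


@dataclass(frozen=True)
class FitConfig:
    """Tuning knobs of the per-taxon EM fit."""

    epsilon: float = 1e-5          # relative-Q convergence threshold
    max_iter: int = 200            # EM iteration cap
    nb_zero_threshold: float = 0.05  # zero fraction below which plain NB is used
    optimizer_tol: float = 1e-8    # gtol/ftol handed to the inner quasi-Newton

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.max_iter < 1:
            raise ValueError("epsilon must be > 0 and max_iter >= 1")
        if not 0.0 <= self.nb_zero_threshold <= 1.0:
            raise ValueError("nb_zero_threshold must be in [0, 1]")


@dataclass
class TaxonFit:
    """Result of fitting one taxon."""

    params: TaxonParams
    weights: np.ndarray            # posterior zero-mass membership, 0 where y > 0
    loglik: float                  # observed-data log-likelihood at params
    q_trace: np.ndarray            # EM objective per iteration (convergence rule)
    ll_trace: np.ndarray           # observed log-likelihood per iteration (ascent)
    converged: bool
    n_iter: int
    model_class: str               # "ZINB" or "NB"
    mu: np.ndarray                 # fitted per-sample NB mean
    theta: np.ndarray              # fitted per-sample NB dispersion
    pi: float                      # fitted zero-mass probability (0.0 for NB class)
    constraint: str = "full"
    taxon_id: str | None = None


def _logit(p: float) -> float:
    return float(np.log(p) - np.log1p(-p))


def initialize(y: np.ndarray, x: np.ndarray, config: FitConfig | None = None,
               constraint: str = "full") -> TaxonParams:
    """Starting values for the EM.

    (beta0, beta1, kappa0) come from a fixed-dispersion ZINB fit (kappa1
    constrained to 0, run as a short EM pass of the same machinery); gamma
    starts at the logit of the observed zero fraction (an intercept-only
    logistic regression of the zero indicator), with a (k+0.5)/(n+1)
    continuity correction when the zero fraction is 0 or 1.
    """
    config = config or FitConfig()
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if not np.any(y > 0):
        raise ValueError("all-zero taxon: filter before fitting")
    gamma0 = _init_gamma(y)
    # centered covariate: intercept and slope are near-orthogonal, so the
    # quasi-Newton steps stay off the kappa0/kappa1 ridge
    x_bar = float(np.mean(x))
    xc = x - x_bar
    crude = _crude_start(y, xc, CONSTRAINTS[constraint])
    fixed = dict(CONSTRAINTS[constraint])
    fixed.setdefault("kappa1", 0.0)
    params, *_ = _em_loop(
        y, xc, crude, gamma0, fixed,
        FitConfig(epsilon=max(config.epsilon, 1e-4), max_iter=8,
                  nb_zero_threshold=config.nb_zero_threshold,
                  optimizer_tol=config.optimizer_tol),
    )
    return TaxonParams(params.beta0 - params.beta1 * x_bar, params.beta1,
                       params.kappa0, 0.0, gamma0)


def _init_gamma(y: np.ndarray) -> float:
    n = y.size
    k = int(np.sum(y == 0))
    if k == 0 or k == n:
        return _logit((k + 0.5) / (n + 1))
    return _logit(k / n)


def _crude_start(y: np.ndarray, x: np.ndarray, fixed: dict[str, float]) -> dict[str, float]:
    """Cheap moment-style start: log-linear regression on positive counts."""
    pos = y > 0
    start = {"beta0": 0.0, "beta1": 1.0, "kappa0": 0.0, "kappa1": 0.0}
    logy = np.log(y[pos])
    if "beta1" in fixed:
        start["beta1"] = fixed["beta1"]
        start["beta0"] = float(np.mean(logy) - start["beta1"] * np.mean(x[pos]))
    elif pos.sum() >= 3 and np.ptp(x[pos]) > 0:
        b1, b0 = np.polyfit(x[pos], logy, 1)
        start["beta0"], start["beta1"] = float(b0), float(b1)
    else:
        start["beta0"] = float(np.mean(logy))
        start["beta1"] = 0.0
    start.update(fixed)
    return start


def e_step(y: np.ndarray, mu: np.ndarray, theta: np.ndarray, pi: float) -> np.ndarray:
    """Posterior probability that each observation came from the zero mass."""
    y = np.asarray(y, dtype=float)
    w = np.zeros_like(y)
    if pi <= 0.0:
        return w
    z = y == 0
    if np.any(z):
        mu_z = np.broadcast_to(mu, y.shape)[z]
        th_z = np.broadcast_to(theta, y.shape)[z]
        log_nb0 = nb_logpmf(0.0, mu_z, th_z)
        # w = pi / (pi + (1-pi) * nb0), computed in log space
        log_num = np.log(pi)
        log_den = np.logaddexp(log_num, np.log1p(-pi) + log_nb0)
        w[z] = np.exp(log_num - log_den)
    return w


def _to_vec(values: dict[str, float]) -> np.ndarray:
    return np.array([values[k] for k in _PARAM_ORDER])


def _to_dict(vec: np.ndarray) -> dict[str, float]:
    return {k: float(v) for k, v in zip(_PARAM_ORDER, vec)}


def _wnb_negloglik(theta_free: np.ndarray, base: np.ndarray, free_idx: np.ndarray,
                   y: np.ndarray, x: np.ndarray, c: np.ndarray,
                   lgam_y1: np.ndarray):
    """Negative (1-w)-weighted NB log-likelihood and gradient over free coefs.

    ``base`` is the full (beta0, beta1, kappa0, kappa1) vector; ``free_idx``
    selects the entries being optimized.
    """
    b = base.copy()
    b[free_idx] = theta_free
    eta_mu = np.clip(b[0] + b[1] * x, -30.0, 30.0)
    eta_th = np.clip(b[2] + b[3] * x, -30.0, 30.0)
    mu = np.exp(eta_mu)
    th = np.exp(eta_th)
    denom = th + mu
    log_denom = np.log(denom)
    ll = c * (
        special.gammaln(y + th) - special.gammaln(th) - lgam_y1
        + y * (eta_mu - log_denom) + th * (eta_th - log_denom)
    )
    g_mu = c * (y - mu * (y + th) / denom)
    g_th = c * th * (
        special.digamma(y + th) - special.digamma(th)
        + eta_th + 1.0 - log_denom - (y + th) / denom
    )
    grad = np.array([g_mu.sum(), g_mu @ x, g_th.sum(), g_th @ x])
    return -ll.sum(), -grad[free_idx]


def _maximize_wnb(y, x, c, start: dict[str, float], fixed: dict[str, float],
                  tol: float, lgam_y1=None, maxiter: int = 120):
    """Quasi-Newton ascent of the weighted NB log-likelihood; simplex fallback."""
    free = [k for k in _PARAM_ORDER if k not in fixed]
    base = _to_vec({**start, **fixed})
    free_idx = np.array([_PARAM_ORDER.index(k) for k in free])
    if lgam_y1 is None:
        lgam_y1 = special.gammaln(y + 1.0)
    x0 = base[free_idx]
    bounds = [_BOUNDS[k] for k in free]
    res = optimize.minimize(
        _wnb_negloglik, x0, args=(base, free_idx, y, x, c, lgam_y1),
        method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": maxiter, "ftol": tol, "gtol": 1e-7},
    )
    ok = res.success or res.status == 1  # status 1: iteration cap, iterate usable
    if not np.isfinite(res.fun):
        res = optimize.minimize(
            lambda v: _wnb_negloglik(v, base, free_idx, y, x, c, lgam_y1)[0],
            x0, method="Nelder-Mead", options={"maxiter": 400, "fatol": 1e-8})
        ok = res.success
    out = base.copy()
    out[free_idx] = res.x
    return _to_dict(out), -float(res.fun), ok


def _q_value(wnb_ll: float, w: np.ndarray, pi: float) -> float:
    """EM objective Q = Bernoulli part + weighted NB part."""
    pi = min(max(pi, _PI_EPS), 1.0 - _PI_EPS)
    bern = float(np.sum(w) * np.log(pi) + np.sum(1.0 - w) * np.log1p(-pi))
    return bern + wnb_ll


def _obs_negloglik(v: np.ndarray, base: np.ndarray, free_idx: np.ndarray,
                   y: np.ndarray, x: np.ndarray, lgam_y1: np.ndarray):
    """Negative observed-data ZINB log-likelihood and gradient.

    ``v`` is the free (beta, kappa) subvector with gamma appended.  The
    gradient w.r.t. (beta, kappa) is the E-step-weighted complete-data
    gradient evaluated at the same parameters (a standard EM identity), and
    w.r.t. gamma it is sum(w) - n*pi.
    """
    b = base.copy()
    b[free_idx] = v[:-1]
    gamma = v[-1]
    eta_mu = np.clip(b[0] + b[1] * x, -30.0, 30.0)
    eta_th = np.clip(b[2] + b[3] * x, -30.0, 30.0)
    mu = np.exp(eta_mu)
    th = np.exp(eta_th)
    denom = th + mu
    log_denom = np.log(denom)
    nb_ll = (special.gammaln(y + th) - special.gammaln(th) - lgam_y1
             + y * (eta_mu - log_denom) + th * (eta_th - log_denom))
    pi = float(special.expit(gamma))
    pi = min(max(pi, _PI_EPS), 1.0 - _PI_EPS)
    log_pi, log1m = np.log(pi), np.log1p(-pi)
    is_zero = y == 0
    ll = np.where(is_zero, np.logaddexp(log_pi, log1m + nb_ll), log1m + nb_ll)
    w = np.where(is_zero, np.exp(np.minimum(log_pi - ll, 0.0)), 0.0)
    c = 1.0 - w
    g_mu = c * (y - mu * (y + th) / denom)
    g_th = c * th * (
        special.digamma(y + th) - special.digamma(th)
        + eta_th + 1.0 - log_denom - (y + th) / denom
    )
    grad = np.array([g_mu.sum(), g_mu @ x, g_th.sum(), g_th @ x])
    g_gamma = float(np.sum(w) - y.size * pi)
    return -ll.sum(), -np.concatenate([grad[free_idx], [g_gamma]])


def _polish(y, x, vals: dict[str, float], gamma: float,
            fixed: dict[str, float], tol: float, lgam_y1):
    """Quasi-Newton refinement of the observed log-likelihood after EM."""
    free = [k for k in _PARAM_ORDER if k not in fixed]
    base = _to_vec({**vals, **fixed})
    free_idx = np.array([_PARAM_ORDER.index(k) for k in free])
    v0 = np.concatenate([base[free_idx], [np.clip(gamma, -29.0, 29.0)]])
    bounds = [_BOUNDS[k] for k in free] + [(-30.0, 30.0)]
    res = optimize.minimize(
        _obs_negloglik, v0, args=(base, free_idx, y, x, lgam_y1),
        method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": 200, "ftol": tol, "gtol": 1e-8},
    )
    f0 = _obs_negloglik(v0, base, free_idx, y, x, lgam_y1)[0]
    if not np.isfinite(res.fun) or res.fun > f0:
        return vals, gamma, -float(f0), True
    out = base.copy()
    out[free_idx] = res.x[:-1]
    return _to_dict(out), float(res.x[-1]), -float(res.fun), bool(res.success or res.status == 1)


def m_step(y: np.ndarray, x: np.ndarray, weights: np.ndarray,
           params_current: TaxonParams, constraint: str = "full",
           config: FitConfig | None = None) -> TaxonParams:
    """One M-step: closed-form gamma update plus weighted-NB maximization."""
    config = config or FitConfig()
    fixed = CONSTRAINTS[constraint]
    pi_new = float(np.clip(np.mean(weights), _PI_EPS, 1.0 - _PI_EPS))
    start = {k: getattr(params_current, k) for k in _PARAM_ORDER}
    start.update(fixed)
    y = np.asarray(y, dtype=float)
    vals, _, _ = _maximize_wnb(y, np.asarray(x, dtype=float),
                               1.0 - weights, start, fixed, config.optimizer_tol)
    return TaxonParams(vals["beta0"], vals["beta1"], vals["kappa0"],
                       vals["kappa1"], _logit(pi_new))


def _em_loop(y, x, start_vals: dict[str, float], gamma0: float,
             fixed: dict[str, float], config: FitConfig):
    """Run EM to convergence; returns (params, weights, q_trace, ll_trace, converged, n_iter)."""
    lgam_y1 = special.gammaln(y + 1.0)
    vals = dict(start_vals)
    gamma = gamma0
    all_idx = np.arange(4)
    q_trace: list[float] = []
    ll_trace: list[float] = []
    converged = False
    n_iter = 0
    for n_iter in range(1, config.max_iter + 1):
        eta_mu = np.clip(vals["beta0"] + vals["beta1"] * x, -30.0, 30.0)
        eta_th = np.clip(vals["kappa0"] + vals["kappa1"] * x, -30.0, 30.0)
        mu, th = np.exp(eta_mu), np.exp(eta_th)
        pi = float(special.expit(gamma))
        pi_c = min(max(pi, _PI_EPS), 1.0 - _PI_EPS)
        nb_ll = nb_logpmf(y, mu, th)
        ll_trace.append(float(np.sum(np.where(
            y == 0, np.logaddexp(np.log(pi_c), np.log1p(-pi_c) + nb_ll),
            np.log1p(-pi_c) + nb_ll))))
        w = e_step(y, mu, th, pi)
        c = 1.0 - w
        # Q at current parameters under the fresh weights
        vec = _to_vec(vals)
        q_old = _q_value(-_wnb_negloglik(vec, vec, all_idx, y, x, c, lgam_y1)[0],
                         w, pi)
        pi_new = float(np.clip(np.mean(w), _PI_EPS, 1.0 - _PI_EPS))
        gamma = _logit(pi_new)
        # after the first sweep the warm-started inner ascent is capped:
        # partial M-steps still increase Q (generalized EM)
        vals, wnb_ll, _ = _maximize_wnb(y, x, c, vals, fixed,
                                        config.optimizer_tol, lgam_y1,
                                        maxiter=120 if n_iter == 1 else 15)
        q_new = _q_value(wnb_ll, w, pi_new)
        q_trace.append(q_new)
        if abs(q_new - q_old) / max(abs(q_old), 1e-12) < config.epsilon:
            converged = True
            break
    params = TaxonParams(vals["beta0"], vals["beta1"], vals["kappa0"],
                         vals["kappa1"], gamma)
    pi = float(special.expit(gamma))
    eta_mu = np.clip(vals["beta0"] + vals["beta1"] * x, -30.0, 30.0)
    eta_th = np.clip(vals["kappa0"] + vals["kappa1"] * x, -30.0, 30.0)
    w = e_step(y, np.exp(eta_mu), np.exp(eta_th), pi)
    return params, w, np.array(q_trace), np.array(ll_trace), converged, n_iter


def fit_taxon(y: np.ndarray, x: np.ndarray, config: FitConfig | None = None,
              constraint: str = "full", model_class: str | None = None,
              taxon_id: str | None = None) -> TaxonFit:
    """Fit one taxon, choosing ZINB vs plain NB by its zero fraction.

    ``constraint`` is one of ``full``, ``fixed-dispersion``,
    ``prevalence-null``, ``equivalence-null``.
    """
    config = config or FitConfig()
    if constraint not in CONSTRAINTS:
        raise ValueError(f"unknown constraint {constraint!r}")
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    if y.shape != x.shape:
        raise ValueError("y and x length mismatch")
    if not np.any(y > 0):
        raise ValueError("all-zero taxon: filter before fitting")
    zero_frac = float(np.mean(y == 0))
    if model_class is None:
        model_class = "NB" if zero_frac < config.nb_zero_threshold else "ZINB"
    fixed = CONSTRAINTS[constraint]
    # optimize on the centered covariate (near-orthogonal intercept/slope);
    # slopes are centering-invariant so fixed beta1/kappa1 values carry over
    x_bar = float(np.mean(x))
    xc = x - x_bar

    def _uncenter(vals: dict[str, float]) -> dict[str, float]:
        out = dict(vals)
        out["beta0"] = vals["beta0"] - vals["beta1"] * x_bar
        out["kappa0"] = vals["kappa0"] - vals["kappa1"] * x_bar
        return out

    if model_class == "NB":
        start = _crude_start(y, xc, fixed)
        starts = [start, dict(start, kappa0=-1.0), dict(start, kappa0=3.0)]
        if "kappa1" not in fixed:
            starts += [dict(start, kappa0=1.0, kappa1=s) for s in (-0.5, 0.5)]
        vals, ll, ok = None, -np.inf, False
        for s0 in starts:
            v_, ll_, ok_ = _maximize_wnb(y, xc, np.ones_like(y), s0, fixed,
                                         config.optimizer_tol)
            if ll_ > ll:
                vals, ll, ok = v_, ll_, ok_
        mu = np.exp(np.clip(vals["beta0"] + vals["beta1"] * xc, -30.0, 30.0))
        th = np.exp(np.clip(vals["kappa0"] + vals["kappa1"] * xc, -30.0, 30.0))
        vals = _uncenter(vals)
        params = TaxonParams(vals["beta0"], vals["beta1"], vals["kappa0"],
                             vals["kappa1"], _logit(_PI_EPS))
        return TaxonFit(params=params, weights=np.zeros_like(y), loglik=ll,
                        q_trace=np.array([ll]), ll_trace=np.array([ll]),
                        converged=ok, n_iter=1, model_class="NB", mu=mu,
                        theta=th, pi=0.0, constraint=constraint,
                        taxon_id=taxon_id)

    gamma0 = _init_gamma(y)
    if "kappa1" in fixed:
        start = _crude_start(y, xc, fixed)
    else:
        # fixed-dispersion ZINB pre-fit supplies (beta0, beta1, kappa0)
        init = initialize(y, x, config, constraint)
        start = {"beta0": init.beta0 + init.beta1 * x_bar, "beta1": init.beta1,
                 "kappa0": init.kappa0, "kappa1": 0.0}
        start.update(fixed)
    lgam_y1 = special.gammaln(y + 1.0)

    def _run(start_vals, gamma_start):
        pc, w_, qt, lt, conv, it = _em_loop(y, xc, start_vals, gamma_start,
                                            fixed, config)
        vals_ = {k: getattr(pc, k) for k in _PARAM_ORDER}
        vals_, gam, ll_, ok = _polish(y, xc, vals_, pc.gamma, fixed,
                                      config.optimizer_tol, lgam_y1)
        return vals_, gam, ll_, qt, lt, conv and ok, it

    vals, gamma, ll_c, q_trace, ll_trace, converged, n_iter = _run(start, gamma0)
    if vals["kappa0"] >= 8.0:
        # ended on the near-Poisson dispersion ridge; retry from a
        # heavy-tailed start, which can sit in a separate basin
        alt_start = dict(start, kappa0=0.0, kappa1=fixed.get("kappa1", 0.0))
        vals2, gamma2, ll2, qt2, lt2, conv2, it2 = _run(alt_start, gamma0)
        if ll2 > ll_c:
            vals, gamma, ll_c, q_trace, ll_trace, converged, n_iter = (
                vals2, gamma2, ll2, qt2, lt2, conv2, it2)
    # cheap multi-start guard against secondary modes: direct quasi-Newton
    # refinement of the observed likelihood from a few diverse starts
    candidates = [(dict(start, kappa0=0.0), gamma0), (dict(vals), -8.0)]
    if "kappa1" not in fixed:
        candidates += [(dict(start, kappa0=1.0, kappa1=s), gamma0)
                       for s in (-1.0, 1.0)]
    for cand_vals, cand_gamma in candidates:
        v2, g2, ll2, ok2 = _polish(y, xc, cand_vals, cand_gamma, fixed,
                                   config.optimizer_tol, lgam_y1)
        if ll2 > ll_c + 1e-10:
            vals, gamma, ll_c = v2, g2, ll2
            converged = converged or ok2
    params_c = TaxonParams(vals["beta0"], vals["beta1"], vals["kappa0"],
                           vals["kappa1"], gamma)
    params = TaxonParams(params_c.beta0 - params_c.beta1 * x_bar,
                         params_c.beta1,
                         params_c.kappa0 - params_c.kappa1 * x_bar,
                         params_c.kappa1, params_c.gamma)
    pi = float(special.expit(params.gamma))
    from .zinb import link_arrays  # local import avoids cycle at module load

    mu, th, _ = link_arrays(params_c, xc)
    w = e_step(y, mu, th, pi)
    ll = taxon_loglik(params, y, x)
    ll_trace = np.append(ll_trace, ll)
    return TaxonFit(params=params, weights=w, loglik=ll, q_trace=q_trace,
                    ll_trace=ll_trace, converged=converged, n_iter=n_iter,
                    model_class="ZINB", mu=mu, theta=th, pi=pi,
                    constraint=constraint, taxon_id=taxon_id)


def fit_matrix(counts: CountMatrix, config: FitConfig | None = None,
               constraint: str = "full",
               depth: np.ndarray | None = None) -> list[TaxonFit]:
    """Fit every taxon of a count matrix independently.

    ``depth`` optionally supplies known per-sample library sizes (e.g. the
    generating depths of a simulation); by default the covariate is the log
    of the unfiltered column sums.
    """
    config = config or FitConfig()
    x = depth_vector(counts) if depth is None else np.log(np.asarray(depth, dtype=float))
    fits: list[TaxonFit] = []
    for i, tid in enumerate(counts.taxon_ids):
        y = counts.counts[i].astype(float)
        try:
            fits.append(fit_taxon(y, x, config, constraint, taxon_id=tid))
        except ValueError:
            raise
        except Exception as exc:  # numerical failure: flag, keep going
            warnings.warn(f"fit failed for taxon {tid}: {exc}")
            params = TaxonParams(0.0, 0.0, 0.0, 0.0, _init_gamma(y))
            fits.append(TaxonFit(params=params, weights=np.zeros_like(y),
                                 loglik=np.nan, q_trace=np.array([]),
                                 ll_trace=np.array([]), converged=False,
                                 n_iter=0, model_class="ZINB",
                                 mu=np.ones_like(y), theta=np.ones_like(y),
                                 pi=float(special.expit(params.gamma)),
                                 constraint=constraint, taxon_id=tid))
    return fits
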