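"""Gaussian-Gamma mixture thresholding of component z-maps.

A component's z-values are modelled as a two-class mixture: a Gaussian
background (noise) class and a positive Gamma activation class (optionally a
third, negative-tail Gamma).  Voxels whose posterior probability of the
activation class exceeds 0.5 form the network's support — voxels more likely
to belong to background noise are excluded.

Fitting is plain EM.  The Gamma M-step is the weighted maximum-likelihood
update (Newton on the shape), so the observed-data log-likelihood is
non-decreasing across iterations; a degenerate Gamma class triggers a
fallback to a two-Gaussian mixture with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln, polygamma
from scipy.stats import norm

from .grids import BrainMap, ValidationError

logger = logging.getLogger(__name__)

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - np.log(sd) - _LOG_SQRT_2PI


def _gamma_logpdf(x, shape, rate, loc):
    """log density of loc + Gamma(shape, rate); -inf at or below loc."""
    out = np.full_like(x, -np.inf, dtype=float)
    pos = x > loc
    z = x[pos] - loc
    out[pos] = shape * np.log(rate) + (shape - 1) * np.log(z) - rate * z - gammaln(shape)
    return out


def _solve_gamma_shape(s: float, max_iter: int = 50) -> float:
    """Solve log(shape) - digamma(shape) = s (s > 0) by Newton iteration."""
    # standard starting approximation
    a = (3 - s + np.sqrt((s - 3) ** 2 + 24 * s)) / (12 * s)
    a = max(a, 1e-3)
    for _ in range(max_iter):
        f = np.log(a) - digamma(a) - s
        fp = 1.0 / a - polygamma(1, a)
        step = f / fp
        a_new = a - step
        if a_new <= 0:
            a_new = a / 2.0
        if abs(a_new - a) < 1e-12 * max(1.0, a):
            a = a_new
            break
        a = a_new
    return float(max(a, 1e-6))


@dataclass
class GaussianClass:
    mean: float
    sd: float
    weight: float


@dataclass
class GammaClass:
    shape: float
    rate: float
    weight: float
    loc: float = 0.0


@dataclass
class MixtureFit:
    component: int
    background: GaussianClass
    activation: GammaClass | GaussianClass
    negative: GammaClass | None
    loglik_trace: np.ndarray
    posterior: np.ndarray        # per-voxel probability of the activation class
    converged: bool
    fallback_gaussian: bool = False
    grid: object = None
    domain: str = "brain"

    @property
    def n_iter(self) -> int:
        return len(self.loglik_trace)


@dataclass
class LCNMap:
    """Mixture-posterior map of one lesion covariance network."""

    posterior: BrainMap
    support: np.ndarray          # boolean over domain voxels
    threshold: float = 0.5

    @property
    def n_voxels(self) -> int:
        return int(self.support.sum())


def fit_mixture(
    z_map: BrainMap,
    max_iter: int = 500,
    tol: float = 1e-6,
    negative_tail: bool = False,
    component: int = 0,
) -> MixtureFit:
    """Fit the background-Gaussian / activation-Gamma mixture to a z-map by EM.

    Initialization: the Gaussian from the trimmed mean/sd of the central 90%
    of values; the Gamma by method of moments on the top decile.  EM stops
    when the log-likelihood improves by less than ``tol`` or at ``max_iter``.
    """
    x = np.asarray(z_map.values, dtype=float)
    if x.size < 1000:
        logger.warning("mixture fit on only %d voxels; >=1000 recommended", x.size)

    lo, hi = np.percentile(x, [5, 95])
    central = x[(x >= lo) & (x <= hi)]
    mu0, sd0 = float(np.mean(central)), float(max(np.std(central), 1e-6))

    top = x[x >= np.percentile(x, 90)]
    g_shape, g_rate = _mom_gamma(top, loc=0.0)
    classes_neg = None
    if negative_tail:
        bot = -x[x <= np.percentile(x, 10)]
        n_shape, n_rate = _mom_gamma(bot, loc=0.0)
        classes_neg = GammaClass(n_shape, n_rate, 0.05)

    bg = GaussianClass(mu0, sd0, 0.9 if not negative_tail else 0.85)
    act = GammaClass(g_shape, g_rate, 0.1 if not negative_tail else 0.10)

    try:
        return _em(x, bg, act, classes_neg, max_iter, tol, component, z_map)
    except _DegenerateGamma:
        logger.warning("degenerate Gamma class; falling back to Gaussian/Gaussian mixture")
        return _em_gauss_fallback(x, max_iter, tol, component, z_map)


def _mom_gamma(v: np.ndarray, loc: float) -> tuple[float, float]:
    v = v[v > loc] - loc
    if v.size < 2:
        return 2.0, 1.0
    m, var = float(np.mean(v)), float(max(np.var(v), 1e-12))
    return max(m * m / var, 1e-2), max(m / var, 1e-6)


class _DegenerateGamma(Exception):
    pass


def _em(x, bg, act, neg, max_iter, tol, component, z_map) -> MixtureFit:
    n = x.size
    trace = []
    converged = False
    for it in range(max_iter):
        # E-step
        log_p = [np.log(bg.weight) + _norm_logpdf(x, bg.mean, bg.sd),
                 np.log(max(act.weight, 1e-300)) + _gamma_logpdf(x, act.shape, act.rate, act.loc)]
        if neg is not None:
            log_p.append(np.log(max(neg.weight, 1e-300))
                         + _gamma_logpdf(-x, neg.shape, neg.rate, neg.loc))
        L = np.vstack(log_p)
        m = L.max(axis=0)
        lse = m + np.log(np.exp(L - m).sum(axis=0))
        ll = float(lse.sum())
        trace.append(ll)
        R = np.exp(L - lse)  # responsibilities, classes x voxels

        if it > 0 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break

        # M-step
        w = R.sum(axis=1) / n
        if w[1] < 1e-8 or not np.isfinite(w).all():
            raise _DegenerateGamma
        r0, r1 = R[0], R[1]
        bg = GaussianClass(
            float(np.sum(r0 * x) / max(r0.sum(), 1e-12)),
            float(max(np.sqrt(np.sum(r0 * (x - np.sum(r0 * x) / max(r0.sum(), 1e-12)) ** 2)
                              / max(r0.sum(), 1e-12)), 1e-6)),
            float(w[0]),
        )
        act = _gamma_mstep(x, r1, act.loc, float(w[1]))
        if neg is not None:
            if w[2] < 1e-8:
                neg = GammaClass(neg.shape, neg.rate, float(w[2]))
            else:
                neg = _gamma_mstep(-x, R[2], neg.loc, float(w[2]))

    posterior = R[1]
    return MixtureFit(component, bg, act, neg, np.asarray(trace), posterior,
                      converged, False, z_map.grid, z_map.domain)


def _gamma_mstep(x, r, loc, weight) -> GammaClass:
    pos = x > loc
    rw = r[pos]
    z = x[pos] - loc
    tot = rw.sum()
    if tot < 1e-8:
        raise _DegenerateGamma
    wm = float(np.sum(rw * z) / tot)
    wml = float(np.sum(rw * np.log(z)) / tot)
    s = np.log(wm) - wml
    if not np.isfinite(s) or s <= 0:
        raise _DegenerateGamma
    shape = _solve_gamma_shape(s)
    return GammaClass(shape, shape / wm, weight, loc)


def _em_gauss_fallback(x, max_iter, tol, component, z_map) -> MixtureFit:
    """Two-Gaussian EM used when the Gamma class degenerates."""
    mu = np.array([float(np.percentile(x, 40)), float(np.percentile(x, 95))])
    sd = np.array([float(np.std(x)), float(np.std(x))])
    w = np.array([0.9, 0.1])
    trace = []
    converged = False
    R = np.full((2, x.size), 0.5)
    for it in range(max_iter):
        L = np.vstack([np.log(w[c]) + _norm_logpdf(x, mu[c], sd[c]) for c in range(2)])
        m = L.max(axis=0)
        lse = m + np.log(np.exp(L - m).sum(axis=0))
        trace.append(float(lse.sum()))
        R = np.exp(L - lse)
        if it > 0 and abs(trace[-1] - trace[-2]) < tol:
            converged = True
            break
        for c in range(2):
            tot = max(R[c].sum(), 1e-12)
            mu[c] = np.sum(R[c] * x) / tot
            sd[c] = max(np.sqrt(np.sum(R[c] * (x - mu[c]) ** 2) / tot), 1e-6)
            w[c] = tot / x.size
    # the higher-mean class plays the activation role
    hi = int(np.argmax(mu))
    fit = MixtureFit(
        component,
        GaussianClass(float(mu[1 - hi]), float(sd[1 - hi]), float(w[1 - hi])),
        GaussianClass(float(mu[hi]), float(sd[hi]), float(w[hi])),
        None,
        np.asarray(trace),
        R[hi],
        converged,
        fallback_gaussian=True,
        grid=z_map.grid,
        domain=z_map.domain,
    )
    return fit


def threshold(fit: MixtureFit, level: float = 0.5) -> LCNMap:
    """Binary network support: voxels whose activation posterior strictly
    exceeds ``level`` (default 0.5); only the positive-activation class counts."""
    if not 0 < level < 1:
        raise ValidationError("threshold level must be in (0, 1)")
    support = fit.posterior > level
    if not support.any():
        logger.warning("empty LCN support at posterior threshold %g", level)
    pmap = BrainMap(fit.grid, fit.domain, fit.posterior)
    return LCNMap(pmap, support, level)
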