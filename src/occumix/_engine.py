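"""Compiled whole-dataset likelihood used by the MCMC sampler.

This mirrors :func:`occumix.model_core.site_marginal_loglik` exactly (the
test suite asserts agreement) but evaluates all sites in one pass, with the
group-size marginalization done in tight loops.  ``numba`` is used when
available; otherwise the same code runs as plain Python (slow but correct).
"""

from __future__ import annotations

import math

import numpy as np

from .data_io import SiteSet, StudyDataset
from .model_core import ModelVariant, N_MAX_DEFAULT

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(f):
            return f

        return wrap


@njit(cache=True)
def _logaddexp(a, b):
    if a == -np.inf:
        return b
    if b == -np.inf:
        return a
    if a > b:
        return a + math.log1p(math.exp(b - a))
    return b + math.log1p(math.exp(a - b))


@njit(cache=True)
def _cond_count_lp(y, lam, d):
    """log P(Y=y | occupied, available), N ~ ZTPois(lam) marginalized.

    The infinite sum over N collapses: thinning a Poisson leaves Y ~
    Poisson(lam*d) up to the zero-truncation normalizer of N, so
    P(y) = e^{-lam d} (lam d)^y / (y! (1 - e^{-lam})) for y >= 1 and
    P(0) = (e^{-lam d} - e^{-lam}) / (1 - e^{-lam}).
    """
    if d <= 0.0:
        return 0.0 if y == 0 else -np.inf
    lnorm = math.log(-math.expm1(-lam))  # log(1 - e^-lam)
    if d >= 1.0:
        if y < 1:
            return -np.inf
        return y * math.log(lam) - lam - math.lgamma(y + 1.0) - lnorm
    if y == 0:
        return -lam * d + math.log(-math.expm1(-lam * (1.0 - d))) - lnorm
    ld = lam * d
    return y * math.log(ld) - ld - math.lgamma(y + 1.0) - lnorm


@njit(cache=True)
def _open_count_lp(y, psi, p, lam, d):
    """log P(Y=y) with latent occupancy and availability."""
    la = -np.inf
    if psi * p > 0.0:
        la = math.log(psi * p) + _cond_count_lp(y, lam, d)
    if y == 0:
        absent = (1.0 - psi) + psi * (1.0 - p)
        if absent > 0.0:
            la = _logaddexp(la, math.log(absent))
    return la


@njit(cache=True)
def _study_logliks(
    set_code, y1, y2, y3, dist, tree1, tree2, work, eps,
    c, c2, g1, g2, g3, set2_linear,
    alpha, b1, b2, b3, b4, b5, b6, b7, p, d,
):
    n = set_code.shape[0]
    out = np.zeros(n)
    for i in range(n):
        w = work[i]
        e = eps[i]
        ll = 0.0
        if set_code[i] == 3:
            eta2 = alpha + b3 + (b4 + b5) * w + e
            ll += _cond_count_lp(y2[i], math.exp(eta2), d)
            if y3[i] >= 0:
                lam3 = math.exp(eta2 + b6 * w + b7)
                ll += _cond_count_lp(y3[i], lam3, d)
            out[i] = ll
            continue
        base = alpha + b1 * dist[i] + e
        if y1[i] >= 0:
            lam1 = math.exp(base + b2 * tree1[i] + b5 * w)
            ll += _cond_count_lp(y1[i], lam1, d)
        if y2[i] >= 0:
            if set_code[i] == 1:
                eta = c + g1 * dist[i] + g2 * tree2[i] + g3 * w
            else:
                eta = c2
                if set2_linear:
                    eta += g1 * dist[i] + g2 * tree2[i] + g3 * w
            psi = 1.0 / (1.0 + math.exp(-eta))
            lam2 = math.exp(base + b2 * tree2[i] + b3 + (b4 + b5) * w)
            ll += _open_count_lp(y2[i], psi, p, lam2, d)
        if y3[i] >= 0:
            lam3 = math.exp(
                base + b2 * tree2[i] + b3 + (b4 + b5 + b6) * w + b7
            )
            ll += _cond_count_lp(y3[i], lam3, d)
        out[i] = ll
    return out


@njit(cache=True)
def _det_logliks(counts, lgam, lam, p, d, n_max):
    """Per-site marginal log-likelihood of the repeat-count calibration data.

    Visits share one latent N (closure within the season), so the N sum
    does not collapse; it is truncated at ``n_max`` like the reference
    implementation.
    """
    n_sites, n_visits = counts.shape
    out = np.empty(n_sites)
    log_lam = math.log(lam)
    lnorm = math.log(-math.expm1(-lam))
    logp = math.log(p) if p > 0.0 else -np.inf
    log1mp = math.log1p(-p) if p < 1.0 else -np.inf
    logd = math.log(d) if d > 0.0 else -np.inf
    log1md = math.log1p(-d) if d < 1.0 else -np.inf
    for i in range(n_sites):
        lo = 1
        for j in range(n_visits):
            if counts[i, j] > lo:
                lo = counts[i, j]
        m = -np.inf
        s = 0.0
        for n in range(lo, n_max + 1):
            t = n * log_lam - lam - lgam[n] - lnorm
            for j in range(n_visits):
                y = counts[i, j]
                if y == 0:
                    if d >= 1.0:
                        la = log1mp  # available group of n>=1 cannot yield 0
                    else:
                        la = _logaddexp(log1mp, logp + n * log1md)
                else:
                    lbin = lgam[n] - lgam[y] - lgam[n - y] \
                        + y * logd + (n - y) * log1md if d < 1.0 else (
                            0.0 if y == n else -np.inf)
                    la = logp + lbin
                t += la
                if t == -np.inf:
                    break
            if t == -np.inf:
                continue
            if t > m:
                s = s * math.exp(m - t) + 1.0
                m = t
            else:
                s += math.exp(t - m)
        out[i] = m + math.log(s) if m > -np.inf else -np.inf
    return out


_SET_CODE = {SiteSet.SET1: 1, SiteSet.SET2: 2, SiteSet.SET3: 3}


class LikelihoodEngine:
    """Whole-dataset marginal likelihood with per-site granularity.

    Parameters enter as a plain ``dict`` of scalars (keys as in
    :class:`occumix.model_core.ParameterSet`) plus a site-effect vector, so
    the sampler can mutate values cheaply.
    """

    def __init__(
        self,
        dataset: StudyDataset,
        variant: ModelVariant,
        n_max: int = N_MAX_DEFAULT,
    ):
        self.variant = variant
        self.n_max = int(n_max)
        sites = dataset.sites
        self.n_sites = len(sites)
        self.site_ids = [s.site_id for s in sites]

        def miss(v):
            return -1 if v is None else int(v)

        self.set_code = np.array([_SET_CODE[s.set] for s in sites], dtype=np.int64)
        self.y1 = np.array([miss(s.y_1995) for s in sites], dtype=np.int64)
        self.y2 = np.array([miss(s.y_2008) for s in sites], dtype=np.int64)
        self.y3 = np.array([miss(s.y_2009) for s in sites], dtype=np.int64)
        self.dist = np.zeros(self.n_sites)
        self.tree1 = np.zeros(self.n_sites)
        self.tree2 = np.zeros(self.n_sites)
        for i, s in enumerate(sites):
            if s.set is not SiteSet.SET3:
                self.dist[i] = dataset.scaled_dist(s)
                self.tree1[i] = dataset.scaled_tree(s, 1995)
                self.tree2[i] = dataset.scaled_tree(s, 2008)
        self.work = np.array([float(s.work) for s in sites])
        ymax = 0
        for arr in (self.y1, self.y2, self.y3):
            if arr.size:
                ymax = max(ymax, int(arr.max()))
        self.det_counts = np.array(
            [list(rec.counts) for rec in dataset.detection], dtype=np.int64
        ).reshape(len(dataset.detection), 4 if dataset.detection else 0)
        if self.det_counts.size:
            ymax = max(ymax, int(self.det_counts.max()))
        if ymax > self.n_max:
            raise ValueError(f"n_max={self.n_max} below observed count {ymax}")
        self.n_det = self.det_counts.shape[0]
        # lgam[k] = log(k!)
        self._lgam = np.array(
            [math.lgamma(k + 1.0) for k in range(self.n_max + 1)]
        )

    def study_logliks(self, theta: dict, eps: np.ndarray) -> np.ndarray:
        b5 = theta.get("beta5", 0.0) if self.variant.include_beta5 else 0.0
        return _study_logliks(
            self.set_code, self.y1, self.y2, self.y3,
            self.dist, self.tree1, self.tree2, self.work, eps,
            theta["c"], theta["c_set2"],
            theta["gamma1"], theta["gamma2"], theta["gamma3"],
            self.variant.set2_occupancy_linear,
            theta["alpha"], theta["beta1"], theta["beta2"], theta["beta3"],
            theta["beta4"], b5, theta["beta6"], theta["beta7"],
            theta["p"], theta["d"],
        )

    def det_logliks(self, theta: dict) -> np.ndarray:
        if self.n_det == 0:
            return np.zeros(0)
        lam = math.exp(theta["alpha"] + theta["beta3"])
        return _det_logliks(
            self.det_counts, self._lgam, lam, theta["p"], theta["d"], self.n_max
        )

    def total_loglik(self, theta: dict, eps: np.ndarray) -> float:
        total = float(np.sum(self.study_logliks(theta, eps)))
        if self.n_det:
            total += float(np.sum(self.det_logliks(theta)))
        return total
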