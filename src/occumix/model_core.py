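"""Mathematical core: distributions, linear predictors, priors, marginal likelihood.

The state process is site occupancy Z ~ Bernoulli(psi) with, conditional on
occupancy, a zero-truncated Poisson group size N with log-linear mean
``lambda``.  Observation happens in two layers: the whole group is available
at the site with probability ``p`` (A ~ Bernoulli(p Z)) and each bird of an
available group is counted with probability ``d`` (Y ~ Binomial(N, d A)).
Only false negatives are modelled.

Everything here is a pure function of parameters; sampling lives in
:mod:`occumix.inference` and data generation in :mod:`occumix.synthetic_data`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import asdict, dataclass, replace
from typing import Iterable, Mapping

import numpy as np
from scipy.special import gammaln, logsumexp, expit

from .data_io import SiteRecord, SiteSet, StudyDataset, MissingCovariateError

__all__ = [
    "ParameterSet",
    "ModelVariant",
    "LatentState",
    "ztpois_logpmf",
    "ztpois_mean",
    "occupancy_probability",
    "group_size_mean",
    "observation_logprob",
    "site_marginal_loglik",
    "detection_site_loglik",
    "log_prior",
    "conditional_deviance",
]

#: default truncation for exact marginalization over group size.  Observed
#: groups never exceed 10 and the zero-truncated Poisson tail beyond 50 is
#: negligible for any lambda <= 15.
N_MAX_DEFAULT = 50

NORMAL_PRIOR_SD = 100.0
CAUCHY_INTERCEPT_SCALE = 10.0
CAUCHY_SLOPE_SCALE = 2.5
SIGMA_EPS_UPPER = 10.0


@dataclass(frozen=True)
class ModelVariant:
    """A member of the model family.

    All variants share the state/observation structure; they differ in
    whether a site random effect is present, whether a pre-existing
    restoration baseline term (beta5) enters the group-size predictors, and
    whether the second stratum's occupancy uses the full linear model or an
    intercept only.
    """

    name: str
    include_beta5: bool
    set2_occupancy_linear: bool
    site_random_effect: bool

    @classmethod
    def from_name(cls, name: str) -> "ModelVariant":
        try:
            return _VARIANTS[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown variant {name!r}; choose from {sorted(_VARIANTS)}"
            ) from None


_VARIANTS = {
    # no site random effect, used as the deviance-comparison baseline
    "M1": ModelVariant("M1", include_beta5=False, set2_occupancy_linear=False,
                       site_random_effect=False),
    "M2": ModelVariant("M2", include_beta5=False, set2_occupancy_linear=False,
                       site_random_effect=True),
    "M4": ModelVariant("M4", include_beta5=True, set2_occupancy_linear=False,
                       site_random_effect=True),
    "M6": ModelVariant("M6", include_beta5=False, set2_occupancy_linear=True,
                       site_random_effect=True),
}


@dataclass(frozen=True)
class ParameterSet:
    """All model unknowns (site effects ``eps`` optional).

    Occupancy submodel (logit scale): intercepts ``c`` (stratum 1) and
    ``c_set2`` (stratum 2), slopes ``gamma1`` (distance), ``gamma2`` (large
    trees), ``gamma3`` (restoration works).

    Group-size submodel (log scale): intercept ``alpha`` (1995 mean log
    group size), ``beta1`` distance, ``beta2`` large trees, ``beta3`` time
    1995->2008, ``beta4`` restoration x time, ``beta5`` restoration
    baseline (variant M4 only), ``beta6`` restoration x 2008->2009,
    ``beta7`` time 2008->2009; ``sigma_eps`` is the SD of the site random
    effect.

    Observation: ``p`` group availability, ``d`` per-bird detection.
    """

    c: float = 0.0
    c_set2: float = 0.0
    gamma1: float = 0.0
    gamma2: float = 0.0
    gamma3: float = 0.0
    alpha: float = 0.0
    beta1: float = 0.0
    beta2: float = 0.0
    beta3: float = 0.0
    beta4: float = 0.0
    beta5: float = 0.0
    beta6: float = 0.0
    beta7: float = 0.0
    sigma_eps: float = 0.0
    p: float = 1.0
    d: float = 1.0
    eps: np.ndarray | None = None

    def __post_init__(self):
        if not (0.0 <= self.p <= 1.0 and 0.0 <= self.d <= 1.0):
            raise ValueError("p and d must lie in [0, 1]")
        if self.sigma_eps < 0.0:
            raise ValueError("sigma_eps must be non-negative")

    def to_dict(self) -> dict:
        out = asdict(self)
        eps = out.pop("eps")
        if eps is not None:
            out["eps"] = list(np.asarray(eps, dtype=float))
        return out

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        d = dict(d)
        eps = d.pop("eps", None)
        if eps is not None:
            eps = np.asarray(eps, dtype=float)
        return cls(eps=eps, **d)

    def with_(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


@dataclass
class LatentState:
    """Per site-year latent states: occupancy Z, availability A, group size N.

    Arrays are indexed (site, year-slot); entries for years a site was not
    surveyed are -1.  ``A <= Z`` always; ``N >= 1`` wherever ``Z == 1``.
    """

    site_ids: list[str]
    Z: np.ndarray
    A: np.ndarray
    N: np.ndarray
    eps: np.ndarray

    def validate(self) -> None:
        mask = self.Z >= 0
        if np.any(self.A[mask] > self.Z[mask]):
            raise ValueError("availability A may not exceed occupancy Z")
        occ = mask & (self.Z == 1)
        if np.any(self.N[occ] < 1):
            raise ValueError("occupied site-years must have N >= 1")


# ---------------------------------------------------------------------------
# distributions
# ---------------------------------------------------------------------------


def ztpois_logpmf(n, lam) -> np.ndarray | float:
    """Log pmf of the zero-truncated Poisson at ``n >= 1``.

    ``log[ lam^n e^(-lam) / (n! (1 - e^(-lam))) ]``, stable for extreme
    ``lam`` (the normalizer uses ``log(-expm1(-lam))``).
    """
    n_arr = np.asarray(n)
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(n_arr < 1):
        raise ValueError("zero-truncated Poisson support starts at n = 1")
    if np.any(lam_arr <= 0):
        raise ValueError("lambda must be positive")
    out = (
        n_arr * np.log(lam_arr)
        - lam_arr
        - gammaln(n_arr + 1.0)
        - np.log(-np.expm1(-lam_arr))
    )
    return float(out) if np.isscalar(n) and np.isscalar(lam) else out


def ztpois_mean(lam) -> float | np.ndarray:
    """Mean of the zero-truncated Poisson: ``lam / (1 - e^(-lam))``."""
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("lambda must be positive")
    out = lam_arr / (-np.expm1(-lam_arr))
    return float(out) if np.isscalar(lam) else out


def occupancy_probability(
    params: ParameterSet,
    dist_s: float,
    tree_s: float,
    work: int,
    site_set: SiteSet,
    variant: ModelVariant | None = None,
) -> float:
    """Occupancy probability for the 2008 survey on the logit-linear scale.

    Stratum 1 and stratum 2 share the slopes and differ only in the
    intercept; under variants without ``set2_occupancy_linear`` the stratum-2
    model is intercept-only.
    """
    if site_set is SiteSet.SET1:
        eta = params.c + params.gamma1 * dist_s + params.gamma2 * tree_s \
            + params.gamma3 * work
    elif site_set is SiteSet.SET2:
        eta = params.c_set2
        if variant is not None and variant.set2_occupancy_linear:
            eta += params.gamma1 * dist_s + params.gamma2 * tree_s \
                + params.gamma3 * work
    else:
        raise ValueError("occupancy is modelled only for strata 1 and 2")
    return float(expit(eta))


def group_size_mean(
    params: ParameterSet,
    variant: ModelVariant,
    year: int,
    work: int,
    dist_s: float | None = None,
    tree_s: float | None = None,
    site_set: SiteSet = SiteSet.SET1,
    eps: float = 0.0,
) -> float:
    """Expected (untruncated) group size ``lambda`` for one site-year.

    For covariate-bearing sites::

        lam_1995 = exp(alpha + b1*dist + b2*tree95        [+ b5*w] + eps)
        lam_2008 = exp(alpha + b1*dist + b2*tree08 + b3 + (b4 [+ b5])*w + eps)
        lam_2009 = exp(... + b3 + (b4 [+ b5] + b6)*w + b7 + eps)

    Covariate-free (stratum 3) sites drop the dist/tree terms; their 2009
    mean is the 2008 mean times ``exp(b6*w + b7)``.  ``b5`` enters only
    under variants with ``include_beta5``.
    """
    b5 = params.beta5 if variant.include_beta5 else 0.0
    if site_set is SiteSet.SET3:
        if year == 1995:
            raise ValueError("stratum-3 sites have no 1995 survey")
        eta = params.alpha + params.beta3 + (params.beta4 + b5) * work + eps
        if year == 2009:
            eta += params.beta6 * work + params.beta7
        return math.exp(eta)

    if dist_s is None or tree_s is None:
        raise MissingCovariateError(
            "dist and tree covariates required for covariate-bearing sites"
        )
    eta = params.alpha + params.beta1 * dist_s + params.beta2 * tree_s
    if year == 1995:
        eta += b5 * work
    elif year == 2008:
        eta += params.beta3 + (params.beta4 + b5) * work
    elif year == 2009:
        eta += params.beta3 + (params.beta4 + b5 + params.beta6) * work + params.beta7
    else:
        raise ValueError(f"unknown survey year {year!r}")
    return math.exp(eta + eps)


def observation_logprob(y: int, n: int, a: int, d: float) -> float:
    """Log-probability of counting ``y`` of ``n`` birds: Binomial(n, d*a).

    An unavailable group (``a = 0``) yields a point mass at ``y = 0``.
    """
    if n < 1:
        raise ValueError("group size must be >= 1")
    if not 0 <= y <= n:
        raise ValueError(f"count y={y} outside [0, N={n}]")
    prob = d * a
    if prob <= 0.0:
        return 0.0 if y == 0 else -math.inf
    if prob >= 1.0:
        return 0.0 if y == n else -math.inf
    return float(
        gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
        + y * math.log(prob) + (n - y) * math.log1p(-prob)
    )


# ---------------------------------------------------------------------------
# exact single-site marginal likelihood (reference implementation)
# ---------------------------------------------------------------------------


def _count_logprob_given_available(y: int, lam: float, d: float, n_max: int) -> float:
    """log P(Y=y | Z=1, A=1) = log sum_N ZTPois(N; lam) Binomial(y; N, d)."""
    ns = np.arange(max(1, y), n_max + 1)
    if ns.size == 0:
        return -math.inf
    terms = ztpois_logpmf(ns, lam) + np.array(
        [observation_logprob(y, int(n), 1, d) for n in ns]
    )
    return float(logsumexp(terms))


def _count_logprob_open(
    y: int, psi: float, p: float, lam: float, d: float, n_max: int
) -> float:
    """log P(Y=y) for an un-conditioned site-year (Z and A both latent)."""
    parts = [math.log(psi * p) + _count_logprob_given_available(y, lam, d, n_max)] \
        if psi * p > 0 else []
    if y == 0:
        absent = (1.0 - psi) + psi * (1.0 - p)
        if absent > 0:
            parts.append(math.log(absent))
    if not parts:
        return -math.inf
    return float(logsumexp(parts))


def site_marginal_loglik(
    site: SiteRecord,
    dataset: StudyDataset,
    params: ParameterSet,
    variant: ModelVariant,
    eps: float = 0.0,
    n_max: int = N_MAX_DEFAULT,
) -> float:
    """Exact log-likelihood of one site's counts, marginalizing Z, A and N.

    Conditioning encoded by the design: stratum-1 sites are occupied and
    available in 1995 (Z1 = A1 = 1); stratum-3 sites are occupied and
    available in both their survey years; any 2009 survey is targeted, so
    A3 = 1 given occupancy.  Group size is drawn independently each year
    given the site effect ``eps``.
    """
    for y in (site.y_1995, site.y_2008, site.y_2009):
        if y is not None and y > n_max:
            raise ValueError(f"n_max={n_max} below observed count {y}")
    ll = 0.0
    if site.set is SiteSet.SET3:
        lam2 = group_size_mean(params, variant, 2008, site.work,
                               site_set=SiteSet.SET3, eps=eps)
        lam3 = group_size_mean(params, variant, 2009, site.work,
                               site_set=SiteSet.SET3, eps=eps)
        ll += _count_logprob_given_available(site.y_2008, lam2, params.d, n_max)
        ll += _count_logprob_given_available(site.y_2009, lam3, params.d, n_max)
        return ll

    dist_s = dataset.scaled_dist(site)
    tree1_s = dataset.scaled_tree(site, 1995)
    tree2_s = dataset.scaled_tree(site, 2008)

    if site.set is SiteSet.SET1 and site.y_1995 is not None:
        lam1 = group_size_mean(params, variant, 1995, site.work, dist_s, tree1_s,
                               eps=eps)
        ll += _count_logprob_given_available(site.y_1995, lam1, params.d, n_max)
    if site.y_2008 is not None:
        psi = occupancy_probability(params, dist_s, tree2_s, site.work, site.set,
                                    variant)
        lam2 = group_size_mean(params, variant, 2008, site.work, dist_s, tree2_s,
                               eps=eps)
        ll += _count_logprob_open(site.y_2008, psi, params.p, lam2, params.d, n_max)
    if site.y_2009 is not None:
        lam3 = group_size_mean(params, variant, 2009, site.work, dist_s, tree2_s,
                               eps=eps)
        ll += _count_logprob_given_available(site.y_2009, lam3, params.d, n_max)
    return ll


def detection_site_loglik(
    counts: Iterable[int],
    lam: float,
    p: float,
    d: float,
    n_max: int = N_MAX_DEFAULT,
) -> float:
    """Marginal log-likelihood of one calibration site's repeat counts.

    One latent N persists across visits (closure within the season); each
    visit has its own availability draw.
    """
    counts = [int(y) for y in counts]
    lo = max(1, max(counts))
    ns = np.arange(lo, n_max + 1)
    total = ztpois_logpmf(ns, lam).astype(float)
    for y in counts:
        visit = np.empty(ns.size)
        for i, n in enumerate(ns):
            avail = math.log(p) + observation_logprob(y, int(n), 1, d) \
                if p > 0 else -math.inf
            if y == 0 and p < 1.0:
                visit[i] = logsumexp([math.log1p(-p), avail])
            else:
                visit[i] = avail
        total += visit
    return float(logsumexp(total))


# ---------------------------------------------------------------------------
# priors and deviance
# ---------------------------------------------------------------------------


def _log_normal_pdf(x: float, sd: float) -> float:
    return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


def _log_cauchy_pdf(x: float, scale: float) -> float:
    return -math.log(math.pi * scale * (1.0 + (x / scale) ** 2))


def log_prior(params: ParameterSet, variant: ModelVariant) -> float:
    """Joint log prior density.

    Vague Normal(0, sd 100) on all regression coefficients except the
    stratum-1 occupancy submodel, which gets weakly informative Cauchy
    priors (scale 10 on the intercept, 2.5 on the slopes).  The random-
    effect SD is Uniform(0, 10); availability and detection probabilities
    are Uniform(0, 1); site effects are Normal(0, sigma_eps).
    """
    lp = _log_cauchy_pdf(params.c, CAUCHY_INTERCEPT_SCALE)
    for g in (params.gamma1, params.gamma2, params.gamma3):
        lp += _log_cauchy_pdf(g, CAUCHY_SLOPE_SCALE)
    coeffs = [params.c_set2, params.alpha, params.beta1, params.beta2,
              params.beta3, params.beta4, params.beta6, params.beta7]
    if variant.include_beta5:
        coeffs.append(params.beta5)
    for b in coeffs:
        lp += _log_normal_pdf(b, NORMAL_PRIOR_SD)
    if not (0.0 < params.p < 1.0) or not (0.0 < params.d < 1.0):
        return -math.inf
    if variant.site_random_effect:
        if not (0.0 < params.sigma_eps < SIGMA_EPS_UPPER):
            return -math.inf
        if params.eps is not None:
            eps = np.asarray(params.eps, dtype=float)
            lp += float(
                np.sum(-0.5 * (eps / params.sigma_eps) ** 2)
                - eps.size * (math.log(params.sigma_eps)
                              + 0.5 * math.log(2.0 * math.pi))
            )
    return lp


def conditional_deviance(
    observations: Iterable[tuple[int, int, int]],
    d: float,
) -> float:
    """-2 x log-likelihood of observed counts given current latent (N, A).

    ``observations`` yields ``(y, N, A)`` triples, one per observed count.
    This is the quantity whose posterior mean compares model variants.
    """
    total = 0.0
    for y, n, a in observations:
        if a == 0 and y > 0:
            raise ValueError("latent states inconsistent with data: A=0 but y>0")
        total += observation_logprob(y, n, a, d)
    return -2.0 * total
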