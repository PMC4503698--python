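"""Posterior sampling, convergence diagnostics, and model comparison.

The sampler is an adaptive Metropolis-within-Gibbs scheme on the
likelihood with the discrete latent states (occupancy, availability, group
size) marginalized out exactly; only the continuous unknowns (regression
coefficients, detection probabilities, random-effect SD and the per-site
effects) are sampled.  Proposal scales adapt during burn-in only, so the
retained chain is a valid Markov chain.  Latent states can be re-imputed
from their exact conditionals afterwards (for the conditional deviance used
in model comparison).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .data_io import SiteSet, StudyDataset
from .model_core import (
    CAUCHY_INTERCEPT_SCALE,
    CAUCHY_SLOPE_SCALE,
    N_MAX_DEFAULT,
    NORMAL_PRIOR_SD,
    SIGMA_EPS_UPPER,
    ModelVariant,
    ParameterSet,
    conditional_deviance,
    ztpois_logpmf,
)
from ._engine import LikelihoodEngine

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "ConfigurationError",
    "fit",
    "rhat",
    "summarize",
    "compare_models",
    "sample_latent_states",
]


class ConfigurationError(ValueError):
    """The fit request violates an identifiability or validity contract."""


@dataclass(frozen=True)
class MCMCConfig:
    """Chain-length and convergence settings (defaults follow the published
    protocol: 3 chains, 2,000 burn-in, 100,000 retained samples)."""

    n_chains: int = 3
    n_burnin: int = 2_000
    n_samples: int = 100_000
    thin: int = 1
    seed: int | None = None
    rhat_threshold: float = 1.1

    def __post_init__(self):
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.n_burnin < 0 or self.n_samples < 1 or self.thin < 1:
            raise ValueError("chain lengths must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


# parameter -> (log prior density fn, support check)
def _prior_logpdf(name: str, x: float) -> float:
    if name == "c":
        s = CAUCHY_INTERCEPT_SCALE
        return -math.log(math.pi * s * (1.0 + (x / s) ** 2))
    if name in ("gamma1", "gamma2", "gamma3"):
        s = CAUCHY_SLOPE_SCALE
        return -math.log(math.pi * s * (1.0 + (x / s) ** 2))
    if name in ("p", "d"):
        return 0.0 if 0.0 < x < 1.0 else -math.inf
    if name == "sigma_eps":
        return (
            -math.log(SIGMA_EPS_UPPER) if 0.0 < x < SIGMA_EPS_UPPER else -math.inf
        )
    # all remaining regression coefficients share the vague normal prior
    sd = NORMAL_PRIOR_SD
    return -0.5 * (x / sd) ** 2 - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


_SCALARS = [
    "c", "c_set2", "gamma1", "gamma2", "gamma3",
    "alpha", "beta1", "beta2", "beta3", "beta4", "beta5", "beta6", "beta7",
    "sigma_eps", "p", "d",
]

#: parameters whose update changes the detection-panel likelihood
_TOUCHES_DET = {"alpha", "beta3", "p", "d"}
#: parameters with no data likelihood at all (prior/random-effect only)
_NO_DATA = {"sigma_eps"}


def _free_parameter_names(variant: ModelVariant, fixed: dict) -> list[str]:
    names = [n for n in _SCALARS if n not in fixed]
    if not variant.include_beta5 and "beta5" in names:
        names.remove("beta5")
    if not variant.site_random_effect and "sigma_eps" in names:
        names.remove("sigma_eps")
    return names


@dataclass
class PosteriorSamples:
    """Rectangular posterior draws: (chain, iteration, parameter)."""

    names: list[str]
    draws: np.ndarray  # (n_chains, n_draws, n_params)
    variant: ModelVariant
    config: MCMCConfig
    site_ids: list[str] = field(default_factory=list)
    fixed: dict = field(default_factory=dict)
    eps_draws: np.ndarray | None = None  # (n_chains, n_draws, n_sites)
    dataset_fingerprint: str = ""
    max_rhat: float | None = None
    converged: bool | None = None

    def __post_init__(self):
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must be (chains, iterations, parameters)")

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    @property
    def n_draws(self) -> int:
        return self.draws.shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws of one parameter, shape (chains, iterations)."""
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown parameter {name!r}") from None
        return self.draws[:, :, j]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    def to_dataframe(self, include_eps: bool = False) -> pd.DataFrame:
        n_c, n_d, _ = self.draws.shape
        cols = {
            "chain": np.repeat(np.arange(n_c), n_d),
            "iteration": np.tile(np.arange(n_d), n_c),
        }
        for j, name in enumerate(self.names):
            cols[name] = self.draws[:, :, j].reshape(-1)
        if include_eps and self.eps_draws is not None:
            for k, sid in enumerate(self.site_ids):
                cols[f"eps[{sid}]"] = self.eps_draws[:, :, k].reshape(-1)
        return pd.DataFrame(cols)

    def parameter_set(self, chain: int, iteration: int) -> ParameterSet:
        kw = dict(self.fixed)
        kw.update(
            {n: float(self.draws[chain, iteration, j])
             for j, n in enumerate(self.names)}
        )
        eps = None
        if self.eps_draws is not None:
            eps = self.eps_draws[chain, iteration].copy()
        return ParameterSet(
            **{k: v for k, v in kw.items() if k in ParameterSet.__dataclass_fields__},
            eps=eps,
        )


def dataset_fingerprint(dataset: StudyDataset | None) -> str:
    if dataset is None:
        return "prior-only"
    h = hashlib.sha256()
    for s in dataset.sites:
        h.update(repr((s.site_id, s.set.value, s.work, s.dist, s.tree_1995,
                       s.tree_2008, s.y_1995, s.y_2008, s.y_2009)).encode())
    for r in dataset.detection:
        h.update(repr((r.site_id, r.counts)).encode())
    return h.hexdigest()[:16]


def _initial_values(names: list[str], fixed: dict,
                    rng: np.random.Generator) -> dict:
    theta = {
        "c": 0.0, "c_set2": 0.5, "gamma1": 0.0, "gamma2": 0.0, "gamma3": 0.0,
        "alpha": 1.2, "beta1": 0.0, "beta2": 0.0, "beta3": 0.0, "beta4": 0.0,
        "beta5": 0.0, "beta6": 0.0, "beta7": 0.0,
        "sigma_eps": 0.5, "p": 0.7, "d": 0.8,
    }
    for n in names:
        if n in ("p", "d"):
            theta[n] = float(rng.uniform(0.4, 0.9))
        elif n == "sigma_eps":
            theta[n] = float(rng.uniform(0.2, 0.8))
        else:
            theta[n] = theta[n] + float(rng.normal(0.0, 0.3))
    theta.update(fixed)
    return theta


class _MWGSampler:
    """Adaptive Metropolis-within-Gibbs kernel over (theta, eps).

    One :meth:`sweep` updates every free scalar and the whole site-effect
    vector (element-wise, valid because sites are conditionally independent
    given the globals).  Proposal scales adapt only while ``adapting=True``
    is passed, so the post-burn-in kernel satisfies detailed balance.
    """

    ADAPT_BLOCK = 25

    def __init__(
        self,
        engine: LikelihoodEngine | None,
        variant: ModelVariant,
        names: list[str],
        fixed: dict,
        rng: np.random.Generator,
        theta: dict | None = None,
        eps: np.ndarray | None = None,
    ):
        self.engine = engine
        self.names = names
        self.rng = rng
        self.theta = theta if theta is not None else _initial_values(
            names, fixed, rng)
        self.n_sites = engine.n_sites if engine is not None else 0
        self.use_eps = variant.site_random_effect and self.n_sites > 0
        if eps is not None:
            self.eps = np.asarray(eps, dtype=float).copy()
        elif self.use_eps:
            self.eps = rng.normal(0.0, 0.1, size=self.n_sites)
        else:
            self.eps = np.zeros(self.n_sites)
        self.have_data = engine is not None and (
            self.n_sites > 0 or engine.n_det > 0
        )
        self.scales = {n: 0.25 for n in names}
        for n in ("p", "d"):
            if n in self.scales:
                self.scales[n] = 0.1
        self._acc = {n: 0 for n in names}
        self.eps_scales = np.full(self.n_sites, 0.5)
        self._eps_acc = np.zeros(self.n_sites)
        self._n_sweeps = 0
        self._refresh_loglik()

    def _refresh_loglik(self) -> None:
        """Recompute cached likelihoods (call after replacing the engine)."""
        if self.have_data:
            self.study_ll = self.engine.study_logliks(self.theta, self.eps)
            self.det_ll = self.engine.det_logliks(self.theta)
        else:
            self.study_ll = np.zeros(0)
            self.det_ll = np.zeros(0)
        self.study_sum = float(self.study_ll.sum())
        self.det_sum = float(self.det_ll.sum())

    def set_engine(self, engine: LikelihoodEngine) -> None:
        self.engine = engine
        self.have_data = engine.n_sites > 0 or engine.n_det > 0
        self._refresh_loglik()

    def sweep(self, adapting: bool = False) -> None:
        rng = self.rng
        theta = self.theta
        engine = self.engine
        for name in self.names:
            cur = theta[name]
            prop = cur + self.scales[name] * rng.normal()
            lp_new = _prior_logpdf(name, prop)
            if lp_new == -math.inf:
                continue
            delta = lp_new - _prior_logpdf(name, cur)
            new_study = new_det = None
            new_study_sum = 0.0
            if name == "sigma_eps" and self.use_eps:
                # site effects' density is the only data-side term
                sse = float(np.dot(self.eps, self.eps))
                delta += (
                    -0.5 * sse / prop**2 - self.n_sites * math.log(prop)
                ) - (
                    -0.5 * sse / cur**2 - self.n_sites * math.log(cur)
                )
            elif self.have_data and name not in _NO_DATA:
                theta[name] = prop
                new_study = engine.study_logliks(theta, self.eps)
                new_study_sum = float(new_study.sum())
                delta += new_study_sum - self.study_sum
                if engine.n_det and name in _TOUCHES_DET:
                    new_det = engine.det_logliks(theta)
                    delta += float(new_det.sum()) - self.det_sum
                theta[name] = cur
            if delta >= 0 or rng.uniform() < math.exp(delta):
                theta[name] = prop
                self._acc[name] += 1
                if new_study is not None:
                    self.study_ll = new_study
                    self.study_sum = new_study_sum
                if new_det is not None:
                    self.det_ll = new_det
                    self.det_sum = float(new_det.sum())

        if self.use_eps:
            prop_eps = self.eps + self.eps_scales * rng.normal(size=self.n_sites)
            new_study = engine.study_logliks(theta, prop_eps)
            sig = theta["sigma_eps"]
            delta_vec = (
                new_study - self.study_ll
                - 0.5 * (prop_eps**2 - self.eps**2) / sig**2
            )
            accept = np.log(rng.uniform(size=self.n_sites)) < delta_vec
            self.eps = np.where(accept, prop_eps, self.eps)
            self.study_ll = np.where(accept, new_study, self.study_ll)
            self.study_sum = float(self.study_ll.sum())
            self._eps_acc += accept

        self._n_sweeps += 1
        if adapting and self._n_sweeps % self.ADAPT_BLOCK == 0:
            gain = min(0.5, 2.0 / math.sqrt(self._n_sweeps / self.ADAPT_BLOCK))
            for name in self.names:
                rate = self._acc[name] / self.ADAPT_BLOCK
                self.scales[name] *= math.exp(gain * (rate - 0.44))
                self._acc[name] = 0
            rates = self._eps_acc / self.ADAPT_BLOCK
            self.eps_scales *= np.exp(gain * (rates - 0.44))
            self._eps_acc[:] = 0.0


def _run_chain(
    engine: LikelihoodEngine | None,
    variant: ModelVariant,
    names: list[str],
    fixed: dict,
    n_burnin: int,
    n_keep: int,
    thin: int,
    rng: np.random.Generator,
):
    """One adaptive MWG chain; adaptation happens during burn-in only."""
    sampler = _MWGSampler(engine, variant, names, fixed, rng)
    draws = np.empty((n_keep, len(names)))
    eps_out = np.empty((n_keep, sampler.n_sites)) if sampler.use_eps else None

    keep_idx = 0
    for it in range(n_burnin + n_keep * thin):
        adapting = it < n_burnin
        sampler.sweep(adapting=adapting)
        if not adapting and (it - n_burnin) % thin == 0:
            draws[keep_idx] = [sampler.theta[n] for n in names]
            if sampler.use_eps:
                eps_out[keep_idx] = sampler.eps
            keep_idx += 1
    return draws, eps_out


def fit(
    dataset: StudyDataset | None,
    variant: ModelVariant | str,
    config: MCMCConfig,
    rng: np.random.Generator | None = None,
    fixed: dict | None = None,
    n_max: int = N_MAX_DEFAULT,
) -> PosteriorSamples:
    """Sample the posterior (or, with ``dataset=None``, the prior).

    The detection-calibration panel must be present whenever both ``p`` and
    ``d`` are free: single visits per site-year cannot separate them.  Pass
    ``fixed={"p": ..., ...}`` to pin parameters.  Non-convergence (max PSRF
    above the configured threshold) is flagged on the result, not raised.
    """
    if isinstance(variant, str):
        variant = ModelVariant.from_name(variant)
    fixed = dict(fixed or {})
    if dataset is not None and dataset.n_sites == 0 and not dataset.detection:
        raise ConfigurationError(
            "dataset has no sites; pass dataset=None to sample the prior"
        )
    if dataset is not None and not dataset.detection:
        if "p" not in fixed and "d" not in fixed:
            raise ConfigurationError(
                "p and d are jointly unidentifiable without repeat-count "
                "detection data; supply a detection panel or fix one of them"
            )
    names = _free_parameter_names(variant, fixed)
    engine = LikelihoodEngine(dataset, variant, n_max) if dataset is not None else None

    if rng is None:
        rng = np.random.default_rng(config.seed)
    seeds = rng.spawn(config.n_chains)

    per_chain = int(math.ceil(config.n_samples / config.n_chains))
    all_draws = []
    all_eps = []
    for chain_rng in seeds:
        d, e = _run_chain(
            engine, variant, names, fixed,
            config.n_burnin, per_chain, config.thin, chain_rng,
        )
        all_draws.append(d)
        all_eps.append(e)
    draws = np.stack(all_draws)
    eps_draws = np.stack(all_eps) if all_eps[0] is not None else None

    samples = PosteriorSamples(
        names=names,
        draws=draws,
        variant=variant,
        config=config,
        site_ids=engine.site_ids if engine is not None else [],
        fixed=fixed,
        eps_draws=eps_draws,
        dataset_fingerprint=dataset_fingerprint(dataset),
    )
    if config.n_chains >= 2:
        rh = rhat(samples)
        samples.max_rhat = max(rh.values()) if rh else 1.0
        samples.converged = samples.max_rhat <= config.rhat_threshold
    return samples


# ---------------------------------------------------------------------------
# diagnostics and summaries
# ---------------------------------------------------------------------------


def rhat(samples: PosteriorSamples) -> dict[str, float]:
    """Gelman-Rubin potential scale reduction factor per parameter."""
    if samples.n_chains < 2:
        raise ValueError("PSRF requires at least 2 chains")
    out = {}
    for name in samples.names:
        out[name] = _psrf(samples.get(name))
    return out


def _psrf(chains: np.ndarray) -> float:
    m, n = chains.shape
    means = chains.mean(axis=1)
    w = float(np.mean(chains.var(axis=1, ddof=1)))
    b_over_n = float(np.var(means, ddof=1))
    if w <= 0.0:
        return 1.0
    var_plus = (n - 1) / n * w + b_over_n
    return math.sqrt(var_plus / w)


def summarize(
    samples: PosteriorSamples, parameter: str
) -> tuple[float, float, float]:
    """Posterior median and equal-tailed 95% credible interval."""
    x = samples.flat(parameter)
    lo, med, hi = np.quantile(x, [0.025, 0.5, 0.975])
    return float(med), float(lo), float(hi)


# ---------------------------------------------------------------------------
# latent-state re-imputation and model comparison
# ---------------------------------------------------------------------------


def _sample_n_given_count(y, lam, d, n_max, rng, available=True):
    """Draw N | Y=y from the enumerated conditional (available group)."""
    ns = np.arange(max(1, y), n_max + 1)
    logw = ztpois_logpmf(ns, lam)
    if available:
        if d <= 0.0:
            logw = np.where(ns >= 1, logw, -np.inf) if y == 0 else logw - np.inf
        elif d >= 1.0:
            logw = np.where(ns == y, 0.0, -np.inf) + logw
        else:
            from scipy.special import gammaln

            logw = logw + (
                gammaln(ns + 1) - gammaln(y + 1) - gammaln(ns - y + 1)
                + y * math.log(d) + (ns - y) * math.log1p(-d)
            )
    w = np.exp(logw - logw.max())
    w /= w.sum()
    return int(rng.choice(ns, p=w))


def sample_latent_states(
    dataset: StudyDataset,
    params: ParameterSet,
    variant: ModelVariant,
    rng: np.random.Generator,
    n_max: int = N_MAX_DEFAULT,
) -> list[tuple[int, int, int]]:
    """Impute (Z, A, N) from their exact conditionals given data and params.

    Returns one ``(y, N, A)`` triple per *observed* count (study surveys
    followed by detection-panel visits), ready for
    :func:`occumix.model_core.conditional_deviance`.
    """
    from .model_core import group_size_mean, occupancy_probability

    obs: list[tuple[int, int, int]] = []
    p, d = params.p, params.d
    eps_arr = params.eps
    for i, site in enumerate(dataset.sites):
        e = float(eps_arr[i]) if eps_arr is not None else 0.0
        if site.set is SiteSet.SET3:
            lam2 = group_size_mean(params, variant, 2008, site.work,
                                   site_set=SiteSet.SET3, eps=e)
            lam3 = group_size_mean(params, variant, 2009, site.work,
                                   site_set=SiteSet.SET3, eps=e)
            obs.append((site.y_2008,
                        _sample_n_given_count(site.y_2008, lam2, d, n_max, rng), 1))
            obs.append((site.y_2009,
                        _sample_n_given_count(site.y_2009, lam3, d, n_max, rng), 1))
            continue
        dist_s = dataset.scaled_dist(site)
        tree1_s = dataset.scaled_tree(site, 1995)
        tree2_s = dataset.scaled_tree(site, 2008)
        if site.set is SiteSet.SET1 and site.y_1995 is not None:
            lam1 = group_size_mean(params, variant, 1995, site.work, dist_s,
                                   tree1_s, eps=e)
            obs.append((site.y_1995,
                        _sample_n_given_count(site.y_1995, lam1, d, n_max, rng), 1))
        if site.y_2008 is not None:
            psi = occupancy_probability(params, dist_s, tree2_s, site.work,
                                        site.set, variant)
            lam2 = group_size_mean(params, variant, 2008, site.work, dist_s,
                                   tree2_s, eps=e)
            y = site.y_2008
            if y > 0:
                obs.append((y, _sample_n_given_count(y, lam2, d, n_max, rng), 1))
            else:
                # categories: unoccupied / occupied-unavailable / occupied-available
                ns = np.arange(1, n_max + 1)
                s0 = float(np.exp(ztpois_logpmf(ns, lam2)) @
                           np.exp(ns * math.log1p(-d)) if d < 1.0 else 0.0)
                w_cat = np.array([1.0 - psi, psi * (1.0 - p), psi * p * s0])
                w_cat /= w_cat.sum()
                cat = rng.choice(3, p=w_cat)
                if cat == 0:
                    obs.append((0, 1, 0))  # unoccupied: no group; A=0 forces y=0
                elif cat == 1:
                    obs.append((0, _sample_n_given_count(0, lam2, d, n_max, rng,
                                                         available=False), 0))
                else:
                    obs.append((0, _sample_n_given_count(0, lam2, d, n_max, rng), 1))
        if site.y_2009 is not None:
            lam3 = group_size_mean(params, variant, 2009, site.work, dist_s,
                                   tree2_s, eps=e)
            obs.append((site.y_2009,
                        _sample_n_given_count(site.y_2009, lam3, d, n_max, rng), 1))

    lam_det = math.exp(params.alpha + params.beta3)
    for rec in dataset.detection:
        counts = rec.counts
        ns = np.arange(max(1, max(counts)), n_max + 1)
        logw = ztpois_logpmf(ns, lam_det)
        for y in counts:
            visit = np.full(ns.size, -np.inf)
            for k, n in enumerate(ns):
                la = -math.inf
                if p > 0 and 0 <= y <= n:
                    from .model_core import observation_logprob

                    la = math.log(p) + observation_logprob(y, int(n), 1, d)
                if y == 0 and p < 1.0:
                    la = np.logaddexp(la, math.log1p(-p))
                visit[k] = la
            logw = logw + visit
        w = np.exp(logw - logw.max())
        w /= w.sum()
        n_latent = int(rng.choice(ns, p=w))
        for y in counts:
            if y > 0:
                obs.append((y, n_latent, 1))
            else:
                pr_unavail = (1.0 - p)
                pr_avail0 = p * math.exp(n_latent * math.log1p(-d)) if d < 1.0 else 0.0
                tot = pr_unavail + pr_avail0
                a = 1 if (tot > 0 and rng.uniform() < pr_avail0 / tot) else 0
                obs.append((y, n_latent, a))
    return obs


def posterior_deviance(
    dataset: StudyDataset,
    samples: PosteriorSamples,
    rng: np.random.Generator,
    max_draws: int = 400,
    n_max: int = N_MAX_DEFAULT,
) -> np.ndarray:
    """Conditional deviance evaluated over (a thinned subset of) the draws."""
    n_total = samples.n_chains * samples.n_draws
    step = max(1, n_total // max_draws)
    out = []
    for flat_idx in range(0, n_total, step):
        chain, it = divmod(flat_idx, samples.n_draws)
        params = samples.parameter_set(chain, it)
        obs = sample_latent_states(dataset, params, samples.variant, rng, n_max)
        out.append(conditional_deviance(obs, params.d))
    return np.asarray(out)


def compare_models(
    dataset: StudyDataset,
    variants: list[ModelVariant | str],
    config: MCMCConfig,
    rng: np.random.Generator | None = None,
    fixed: dict | None = None,
    max_deviance_draws: int = 400,
) -> pd.DataFrame:
    """Fit each variant and tabulate posterior mean +/- SD of the conditional
    deviance, sorted ascending by mean."""
    if len(variants) < 2:
        raise ValueError("need at least 2 variants to compare")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    rows = []
    for v in variants:
        v = ModelVariant.from_name(v) if isinstance(v, str) else v
        samples = fit(dataset, v, config, rng=rng.spawn(1)[0], fixed=fixed)
        dev = posterior_deviance(dataset, samples, rng.spawn(1)[0],
                                 max_draws=max_deviance_draws)
        rows.append(
            {
                "variant": v.name,
                "deviance_mean": float(dev.mean()),
                "deviance_sd": float(dev.std(ddof=1)),
                "max_rhat": samples.max_rhat,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("deviance_mean", ignore_index=True)
    )
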