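"""Maximum-likelihood fitting and MCMC posteriors for demographic models.

Free parameters (join times, branch sizes) are optimized on a transformed
scale: sizes on log scale, join times as positive increments above the
latest event on either child lineage, which keeps every in-bounds vector
consistent with the tree ordering.  Maximization is derivative-free
(Nelder-Mead with perturbed restarts); posteriors come from random-walk
Metropolis with proposal scales adapted during burn-in and frozen
afterwards.  Priors are flat on the transformed scale within bounds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .corecoal import histogram_loglikelihood
from .model import DemographyModel, ParameterMap, UnitScale, validate_model
from .patterns import PatternHistogram

__all__ = [
    "FitResult",
    "PosteriorSample",
    "maximize",
    "mcmc",
    "add_population",
    "random_walk_metropolis",
    "natural_parameters",
]


@dataclass
class FitResult:
    parameters: dict  # natural-scale values (absolute join times, sizes)
    loglik: float
    converged: bool
    n_evaluations: int
    model: DemographyModel
    x: np.ndarray = field(repr=False, default=None)
    pmap: ParameterMap = field(repr=False, default=None)


@dataclass
class PosteriorSample:
    names: list
    chain: np.ndarray  # (steps, n_params) transformed scale
    logliks: np.ndarray
    acceptance_rate: float
    burn_in: int
    summaries: dict  # name -> {median, q10, q90} on the natural scale
    natural_chain: np.ndarray  # (steps, n_params) natural scale


def natural_parameters(pmap: ParameterMap, x) -> dict:
    """Natural-scale values (absolute join times, plain sizes) for vector x."""
    m = pmap.unpack(x)
    sj = m.sorted_joins()
    out = {}
    for name, (kind, idx) in zip(pmap.names, pmap._slots):
        if kind == "time":
            out[name] = sj[idx].time
        elif kind == "lambda_tip":
            out[name] = m.branches[idx].lam
        else:
            out[name] = sj[idx].lambda_after
    return out


def _make_loglik(pmap, h, u, conditional=False):
    def loglik(x):
        if not pmap.in_bounds(x):
            return -math.inf
        m = pmap.unpack(x)
        if validate_model(m):
            return -math.inf
        try:
            return histogram_loglikelihood(m, h, u, conditional=conditional)
        except (ValueError, RuntimeError):
            return -math.inf

    return loglik


def maximize(
    template: DemographyModel,
    free: ParameterMap | list,
    h: PatternHistogram,
    u: UnitScale | None = None,
    seed: int = 0,
    improvement_tol: float = 1e-4,
    max_restarts: int = 3,
    maxfev: int | None = None,
) -> FitResult:
    """Nelder-Mead maximization of the composite likelihood.

    Restarts from a perturbed best point until the improvement drops below
    `improvement_tol` log-units; deterministic given `seed`.
    """
    pmap = free if isinstance(free, ParameterMap) else ParameterMap(template, free)
    loglik = _make_loglik(pmap, h, u)
    if len(pmap) == 0:
        ll = histogram_loglikelihood(template, h, u)
        return FitResult({}, ll, True, 1, template.copy(), np.zeros(0), pmap)

    rng = np.random.default_rng(seed)
    n_eval = 0

    def objective(x):
        nonlocal n_eval
        n_eval += 1
        return -loglik(x)

    x_best = pmap.pack(template)
    f_best = objective(x_best)
    if not math.isfinite(f_best):
        raise ValueError("template model has non-finite likelihood")
    converged = False
    for attempt in range(max_restarts + 1):
        x0 = x_best if attempt == 0 else x_best + rng.normal(0, 0.05, len(x_best))
        res = minimize(
            objective,
            x0,
            method="Nelder-Mead",
            options={
                "xatol": 1e-5,
                "fatol": improvement_tol / 10,
                "maxfev": maxfev or 400 * len(pmap),
            },
        )
        if res.fun < f_best - improvement_tol:
            f_best, x_best = res.fun, res.x
        else:
            if res.fun < f_best:
                f_best, x_best = res.fun, res.x
            converged = True
            break
    model = pmap.unpack(x_best)
    return FitResult(
        parameters=natural_parameters(pmap, x_best),
        loglik=-f_best,
        converged=converged,
        n_evaluations=n_eval,
        model=model,
        x=np.asarray(x_best),
        pmap=pmap,
    )


def random_walk_metropolis(
    logpdf,
    x0,
    steps: int,
    seed: int = 0,
    scales=None,
    burn_in_frac: float = 0.2,
    target_rate: float = 0.3,
):
    """Generic random-walk Metropolis with burn-in proposal adaptation.

    During the first `burn_in_frac` of the chain the global proposal
    scale is tuned toward `target_rate` every 25 steps and, from halfway
    through burn-in, the proposal covariance is re-estimated from the
    chain history (adaptive Metropolis); both are frozen after burn-in,
    so the post-burn-in chain is a standard Markov chain.  Returns
    (chain, logpdfs, acceptance_rate_after_burnin, burn_in).
    """
    if steps <= 0:
        raise ValueError("chain length must be positive")
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    d = len(x0)
    rng = np.random.default_rng(seed)
    scales = np.full(d, 0.1) if scales is None else np.asarray(scales, dtype=float)
    sigma = 1.0
    chol = np.diag(scales)
    burn_in = int(burn_in_frac * steps)
    chain = np.empty((steps, d))
    lps = np.empty(steps)
    x = x0.copy()
    lp = logpdf(x)
    if not math.isfinite(lp):
        raise ValueError("starting point has zero posterior density")
    accepted_post = 0
    accepted_window = 0
    for i in range(steps):
        prop = x + sigma * (chol @ rng.normal(size=d))
        lp_prop = logpdf(prop)
        if math.log(rng.random()) < lp_prop - lp:
            x, lp = prop, lp_prop
            accepted_window += 1
            if i >= burn_in:
                accepted_post += 1
        chain[i] = x
        lps[i] = lp
        if i < burn_in and (i + 1) % 25 == 0:
            rate = accepted_window / 25
            sigma *= math.exp((rate - target_rate) * 0.7)
            accepted_window = 0
            if d > 1 and i + 1 >= max(burn_in // 2, 10 * d):
                cov = np.cov(chain[: i + 1].T) + 1e-10 * np.eye(d)
                try:
                    chol = np.linalg.cholesky(2.38**2 / d * cov)
                    sigma = 1.0
                except np.linalg.LinAlgError:
                    pass
    n_post = max(steps - burn_in, 1)
    return chain, lps, accepted_post / n_post, burn_in


def mcmc(
    template: DemographyModel,
    free: ParameterMap | list,
    h: PatternHistogram,
    u: UnitScale | None = None,
    steps: int = 2000,
    seed: int = 0,
    start: FitResult | np.ndarray | None = None,
    scales=None,
) -> PosteriorSample:
    """Random-walk Metropolis posterior for the free parameters.

    Proposals are adapted during the first 20% of the chain (burn-in) and
    frozen afterwards; summaries (median and central 80% interval) are
    reported on the natural scale from the post-burn-in samples.
    """
    pmap = free if isinstance(free, ParameterMap) else ParameterMap(template, free)
    loglik = _make_loglik(pmap, h, u)
    if isinstance(start, FitResult):
        x0 = start.x
    elif start is not None:
        x0 = np.asarray(start, dtype=float)
    else:
        x0 = pmap.pack(template)
    if scales is None:
        scales = np.asarray(
            [0.1 if k == "time" else 0.05 for k, _ in pmap._slots]
        )
        # scale time-increment proposals relative to their starting magnitude
        for i, (kind, _) in enumerate(pmap._slots):
            if kind == "time":
                scales[i] = max(abs(x0[i]) * 0.3, 1e-5)
    chain, lps, rate, burn_in = random_walk_metropolis(
        loglik, x0, steps, seed=seed, scales=scales
    )
    post = chain[burn_in:]
    natural = np.empty_like(chain)
    for i, x in enumerate(chain):
        vals = natural_parameters(pmap, x)
        natural[i] = [vals[n] for n in pmap.names]
    nat_post = natural[burn_in:]
    summaries = {}
    for j, name in enumerate(pmap.names):
        q10, med, q90 = np.quantile(nat_post[:, j], [0.1, 0.5, 0.9])
        summaries[name] = {"median": med, "q10": q10, "q90": q90}
    return PosteriorSample(
        names=list(pmap.names),
        chain=chain,
        logliks=lps,
        acceptance_rate=rate,
        burn_in=burn_in,
        summaries=summaries,
        natural_chain=natural,
    )


def add_population(
    fitted: DemographyModel,
    h: PatternHistogram,
    new_pop: str,
    candidate_branches: list,
    u: UnitScale | None = None,
    seed: int = 0,
    lambda_init: float = 1.0,
    **max_kwargs,
) -> list:
    """Graft `new_pop` onto each candidate branch, fit (attach time, size).

    `h` must contain a column for `new_pop` in addition to the fitted
    model's populations.  Returns FitResults sorted by log-likelihood,
    best first; the attachment branch is recorded in
    ``result.parameters['attached_to']``.
    """
    from .model import Branch, JoinEvent

    if not candidate_branches:
        raise ValueError("no candidate branches")
    n_new = h.config.sizes[h.config.index(new_pop)]
    results = []
    for cand in candidate_branches:
        template = fitted.copy()
        terminal = template.terminal_join_time(cand)
        hi = terminal if math.isfinite(terminal) else max(
            template.root_time() * 1.5, 0.01
        )
        t0 = 0.5 * hi
        template.branches.append(Branch(new_pop, lambda_init, n_new))
        template.joins.append(JoinEvent(t0, cand, new_pop))
        pmap = ParameterMap(
            template, [f"t_{cand}_{new_pop}", f"lambda_{new_pop}"]
        )
        try:
            fit = maximize(template, pmap, h, u, seed=seed, **max_kwargs)
        except (ValueError, RuntimeError):
            continue
        fit.parameters["attached_to"] = cand
        results.append(fit)
    if not results:
        raise RuntimeError("no candidate attachment converged")
    return sorted(results, key=lambda r: -r.loglik)
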