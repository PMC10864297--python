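"""Approximate adjusted fractional Bayes factors for informative hypotheses.

The engine works on a normal approximation to the posterior of a vector of
model parameters, ``g(gamma | data) ~ N(gamma_hat, Sigma)``.  From it an
*adjusted fractional prior* ``h(gamma) ~ N(0, Sigma / (f * b))`` is derived,
where ``b = J / n_eff`` (J independent constraint rows, n_eff the effective
sample size of the clustered data) and the fraction ``f`` (1, 2 or 3)
controls how conservative the prior is.

For each hypothesis the *fit* is the posterior probability (inequalities) or
density (equalities) of its constraints, and the *complexity* is the same
quantity under the prior.  Bayes factors against the unconstrained model are
``BF_iu = fit / complexity``; against the complement,
``BF_ic = (fit/complexity) / ((1-fit)/(1-complexity))`` on the
probability-valued inequality parts.  Posterior model probabilities
normalise the ``BF_iu`` over the evaluated hypothesis set.

Equality parts are evaluated in closed form (marginal normal density at the
constraint point); inequality parts by seeded Monte Carlo, conditioned
exactly on the equality constraints when both are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constraints import ConstraintSet, parse_hypothesis

__all__ = [
    "PosteriorApprox",
    "FractionalPrior",
    "EvidenceResult",
    "build_fractional_prior",
    "estimate_fit",
    "estimate_complexity",
    "evidence",
    "posterior_model_probabilities",
    "evaluate_hypotheses",
    "sensitivity_over_fractions",
    "evidence_table",
]

DEFAULT_DRAWS = 100_000
MIN_DRAWS = 10_000


@dataclass(frozen=True)
class PosteriorApprox:
    """Normal approximation N(gamma_hat, sigma) to a parameter posterior.

    ``n_eff`` is the effective sample size of the data behind the estimates
    (for clustered data, between the number of clusters and the number of
    observations).
    """

    gamma_hat: np.ndarray
    sigma: np.ndarray
    n_eff: float
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        gamma_hat = np.asarray(self.gamma_hat, dtype=float).reshape(-1)
        sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        G = gamma_hat.size
        if sigma.shape != (G, G):
            raise ValueError("sigma must be G x G for G parameters")
        if not np.allclose(sigma, sigma.T, atol=1e-10):
            raise ValueError("sigma must be symmetric")
        if np.linalg.eigvalsh(sigma).min() < -1e-10 * max(1.0, np.abs(sigma).max()):
            raise ValueError("sigma must be positive semi-definite")
        if not self.n_eff > 0:
            raise ValueError("n_eff must be positive")
        names = tuple(self.names) or tuple(f"g{i + 1}" for i in range(G))
        if len(names) != G:
            raise ValueError("names length must match gamma_hat")
        object.__setattr__(self, "gamma_hat", gamma_hat)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "names", names)

    @property
    def G(self) -> int:
        return self.gamma_hat.size


@dataclass(frozen=True)
class FractionalPrior:
    """Adjusted fractional prior N(mean, sigma/(f*b)) with b = J/n_eff."""

    mean: np.ndarray
    cov: np.ndarray
    fraction: float
    b: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float).reshape(-1))
        object.__setattr__(self, "cov", np.atleast_2d(np.asarray(self.cov, dtype=float)))
        if not self.b > 0 or not self.fraction > 0:
            raise ValueError("fraction and b must be positive")


@dataclass
class EvidenceResult:
    """Evidence for one hypothesis: fit, complexity, Bayes factors, PostP."""

    name: str
    fit: float
    complexity: float
    bf_iu: float
    bf_ic: float
    postp: float = np.nan
    mc_se: float = 0.0
    # probability-valued (inequality) parts, used for complements
    fit_prob: float = 1.0
    complexity_prob: float = 1.0
    fit_mc_se: float = 0.0
    complexity_mc_se: float = 0.0
    constraints: ConstraintSet | None = field(default=None, repr=False)

    @property
    def equality_only(self) -> bool:
        return self.constraints is not None and self.constraints.equality_only

    @property
    def pure_inequality(self) -> bool:
        return self.constraints is not None and self.constraints.q_e == 0


def build_fractional_prior(
    post: PosteriorApprox,
    cs: ConstraintSet,
    fraction: float = 2.0,
    J: int | None = None,
) -> FractionalPrior:
    """Derive the adjusted fractional prior from a posterior approximation.

    The prior mean sits at the constraint boundary, which for contrast
    constraints (r = 0) is the zero vector; non-zero boundary points are
    rejected rather than silently mis-centred.  ``J`` overrides the
    per-hypothesis constraint count when a shared fraction across a
    hypothesis set is wanted.
    """
    if fraction <= 0:
        raise ValueError("fraction must be positive")
    if np.any(cs.r_eq != 0) or np.any(cs.r_in != 0):
        raise ValueError(
            "adjusted fractional prior requires contrast constraints with "
            "boundary r = 0; got a non-zero constraint constant"
        )
    J_val = int(J) if J is not None else cs.J
    if J_val <= 0:
        raise ValueError("J must be at least 1")
    b = J_val / post.n_eff
    return FractionalPrior(
        mean=np.zeros(post.G), cov=post.sigma / (fraction * b), fraction=fraction, b=b
    )


def _constrained_measure(
    mean: np.ndarray,
    cov: np.ndarray,
    cs: ConstraintSet,
    draws: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Density x probability of a constraint set under N(mean, cov).

    Returns ``(value, mc_se)`` where value is the product of the equality
    part (closed-form marginal density at r_eq) and the inequality part
    (Monte-Carlo orthant probability, conditioned on the equalities when
    both blocks are present).  ``mc_se`` is 0 for purely closed-form values.
    """
    mean = np.asarray(mean, dtype=float).reshape(-1)
    cov = np.atleast_2d(cov)
    density = 1.0
    if cs.q_e:
        e_mean = cs.R_eq @ mean
        e_cov = cs.R_eq @ cov @ cs.R_eq.T
        sign, logdet = np.linalg.slogdet(e_cov)
        if sign <= 0 or not np.isfinite(logdet):
            raise np.linalg.LinAlgError(
                "singular transformed covariance for the equality density"
            )
        density = float(
            stats.multivariate_normal.pdf(cs.r_eq, mean=e_mean, cov=e_cov, allow_singular=False)
        )
    if not cs.q_in:
        return density, 0.0

    i_mean = cs.R_in @ mean
    i_cov = cs.R_in @ cov @ cs.R_in.T
    if cs.q_e:
        # exact conditioning of the inequality block on R_eq gamma = r_eq
        e_mean = cs.R_eq @ mean
        e_cov = cs.R_eq @ cov @ cs.R_eq.T
        cross = cs.R_in @ cov @ cs.R_eq.T
        solve = np.linalg.solve(e_cov, (cs.r_eq - e_mean))
        i_mean = i_mean + cross @ solve
        i_cov = i_cov - cross @ np.linalg.solve(e_cov, cross.T)
        i_cov = (i_cov + i_cov.T) / 2.0

    if draws < MIN_DRAWS:
        raise ValueError(f"draws must be at least {MIN_DRAWS} for sampled probabilities")
    # jitter-free sampling: use eigendecomposition for possibly singular i_cov
    vals, vecs = np.linalg.eigh(i_cov)
    vals = np.clip(vals, 0.0, None)
    root = vecs * np.sqrt(vals)
    z = rng.standard_normal((draws, i_cov.shape[0]))
    samples = i_mean + z @ root.T
    hits = np.all(samples > cs.r_in, axis=1)
    p = float(hits.mean())
    mc_se = float(np.sqrt(p * (1.0 - p) / draws))
    return density * p, mc_se


def estimate_fit(
    post: PosteriorApprox,
    cs: ConstraintSet,
    draws: int = DEFAULT_DRAWS,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Posterior fit of a hypothesis: P/density that its constraints hold."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _constrained_measure(post.gamma_hat, post.sigma, cs, draws, rng)


def estimate_complexity(
    prior: FractionalPrior,
    cs: ConstraintSet,
    draws: int = DEFAULT_DRAWS,
    seed: int | np.random.Generator = 0,
) -> tuple[float, float]:
    """Prior complexity of a hypothesis: P/density under the fractional prior."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _constrained_measure(prior.mean, prior.cov, cs, draws, rng)


def evidence(
    fit: float,
    complexity: float,
    equality_only: bool = False,
    fit_prob: float | None = None,
    complexity_prob: float | None = None,
) -> tuple[float, float]:
    """Bayes factors (BF_iu, BF_ic) from fit and complexity.

    ``BF_iu`` compares against the unconstrained model.  ``BF_ic`` compares
    against the complement and is formed from the probability-valued
    inequality parts (``fit_prob``/``complexity_prob``, defaulting to the
    totals); for equality-only hypotheses the complement of a measure-zero
    set is the unconstrained model itself, so ``BF_ic = BF_iu``.
    """
    if complexity <= 0:
        raise ValueError("complexity must be positive")
    bf_iu = fit / complexity
    if equality_only:
        return bf_iu, bf_iu
    p_f = fit if fit_prob is None else fit_prob
    p_c = complexity if complexity_prob is None else complexity_prob
    if np.isclose(p_c, 1.0) or np.isclose(p_f, 1.0):
        bf_ic = np.inf if p_f >= p_c else 0.0
        return bf_iu, bf_ic
    bf_ic = (p_f / p_c) / ((1.0 - p_f) / (1.0 - p_c))
    # hypotheses mixing equalities and inequalities carry the equality
    # density ratio through to the complement comparison as well
    if fit_prob is not None and (fit != p_f or complexity != p_c):
        dens_ratio = (fit / p_f) / (complexity / p_c)
        bf_ic *= dens_ratio
    return bf_iu, bf_ic


def complement_evidence(
    results: list[EvidenceResult], mc_tolerance: float = 3.0
) -> EvidenceResult:
    """Fail-safe hypothesis: complement of the union of inequality hypotheses.

    For mutually exclusive pure-inequality hypotheses the complement's fit
    and complexity are ``1 - sum`` of theirs (equality hypotheses are
    measure-zero in the union and contribute nothing).  Raises if either
    complement goes negative beyond ``mc_tolerance`` combined Monte-Carlo
    standard errors, which signals a non-exclusive hypothesis set.
    """
    ineq = [r for r in results if r.pure_inequality]
    fit_c = 1.0 - sum(r.fit_prob for r in ineq)
    com_c = 1.0 - sum(r.complexity_prob for r in ineq)
    tol = mc_tolerance * np.sqrt(sum(r.fit_mc_se**2 + r.complexity_mc_se**2 for r in ineq))
    if fit_c < -tol - 1e-9 or com_c < -tol - 1e-9:
        raise ValueError(
            "complement fit/complexity negative beyond Monte-Carlo error: "
            "the inequality hypotheses are not mutually exclusive"
        )
    fit_c = max(fit_c, 1e-12)
    com_c = max(com_c, 1e-12)
    mc_se = float(np.sqrt(sum(r.fit_mc_se**2 + r.complexity_mc_se**2 for r in ineq)))
    return EvidenceResult(
        name="Hc", fit=fit_c, complexity=com_c, bf_iu=fit_c / com_c, bf_ic=np.nan,
        mc_se=mc_se, fit_prob=fit_c, complexity_prob=com_c,
    )


def posterior_model_probabilities(
    results: list[EvidenceResult],
    include_failsafe: bool = False,
    prior_weights: np.ndarray | None = None,
    failsafe_mode: str = "complement",
) -> np.ndarray:
    """Posterior model probabilities over a hypothesis set.

    ``PostP_i`` is proportional to ``weight_i * BF_iu``.  With
    ``include_failsafe`` a fail-safe hypothesis is appended; in the default
    ``"complement"`` mode it is the complement of the union of the mutually
    exclusive inequality hypotheses (see :func:`complement_evidence`); in
    ``"unconstrained"`` mode it is the unconstrained model with ``BF = 1``.
    The returned vector (fail-safe entry last) sums to 1 and is written
    back onto ``results``.
    """
    if not results:
        raise ValueError("no hypotheses to compare")
    results = list(results)
    k = len(results)
    weights = np.full(k, 1.0 / k) if prior_weights is None else np.asarray(prior_weights, float)
    if weights.size != k:
        raise ValueError("prior_weights length must match results")

    if include_failsafe:
        if failsafe_mode == "unconstrained":
            fs = EvidenceResult(name="Hu", fit=1.0, complexity=1.0, bf_iu=1.0, bf_ic=np.nan)
        elif failsafe_mode == "complement":
            fs = complement_evidence(results)
        else:
            raise ValueError(f"unknown failsafe_mode {failsafe_mode!r}")
        # the fail-safe shares the uniform weight of an extra hypothesis
        weights = np.append(weights * k / (k + 1), 1.0 / (k + 1))
        results = results + [fs]

    bfs = np.asarray([r.bf_iu for r in results], dtype=float)
    if np.any(np.isinf(bfs)):
        post = np.where(np.isinf(bfs), 1.0, 0.0)
        post /= post.sum()
    else:
        unnorm = weights * bfs
        post = unnorm / unnorm.sum()
    for r, p in zip(results, post):
        r.postp = float(p)
    return post


def evaluate_hypotheses(
    post: PosteriorApprox,
    hypotheses: dict[str, str | ConstraintSet],
    fraction: float = 2.0,
    draws: int = DEFAULT_DRAWS,
    seed: int | np.random.SeedSequence = 0,
    include_failsafe: bool = True,
    failsafe_mode: str = "complement",
    shared_J: bool = False,
    prior_weights: np.ndarray | None = None,
) -> list[EvidenceResult]:
    """Evaluate a named set of informative hypotheses on one posterior.

    Each hypothesis gets its own fraction ``b_i = J_i / n_eff`` unless
    ``shared_J`` pools the maximum J over the set.  All Monte-Carlo parts
    derive from ``seed`` deterministically.
    """
    sets: dict[str, ConstraintSet] = {}
    for name, h in hypotheses.items():
        sets[name] = h if isinstance(h, ConstraintSet) else parse_hypothesis(h, post.names)
    J_shared = max(cs.J for cs in sets.values()) if shared_J else None

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    results: list[EvidenceResult] = []
    for child, (name, cs) in zip(ss.spawn(len(sets)), sets.items()):
        rng_fit, rng_com = (np.random.default_rng(s) for s in child.spawn(2))
        prior = build_fractional_prior(post, cs, fraction, J=J_shared)
        fit, fit_se = estimate_fit(post, cs, draws, rng_fit)
        com, com_se = estimate_complexity(prior, cs, draws, rng_com)
        # recover the probability-valued inequality parts for complements
        if cs.q_e and cs.q_in:
            eq_only = ConstraintSet(cs.names, cs.R_eq, cs.r_eq,
                                    np.empty((0, cs.G)), np.empty(0))
            fit_dens, _ = estimate_fit(post, eq_only, MIN_DRAWS, 0)
            com_dens, _ = estimate_complexity(prior, eq_only, MIN_DRAWS, 0)
            fit_prob, com_prob = fit / fit_dens, com / com_dens
        elif cs.q_e:
            fit_prob = com_prob = 1.0
        else:
            fit_prob, com_prob = fit, com
        bf_iu, bf_ic = evidence(fit, com, cs.equality_only, fit_prob, com_prob)
        results.append(
            EvidenceResult(
                name=name, fit=fit, complexity=com, bf_iu=bf_iu, bf_ic=bf_ic,
                mc_se=float(np.hypot(fit_se, com_se)),
                fit_prob=fit_prob, complexity_prob=com_prob,
                fit_mc_se=fit_se, complexity_mc_se=com_se, constraints=cs,
            )
        )
    if include_failsafe:
        if failsafe_mode == "complement":
            fs = complement_evidence(results)
        else:
            fs = EvidenceResult(name="Hu", fit=1.0, complexity=1.0, bf_iu=1.0, bf_ic=np.nan)
        all_results = results + [fs]
        k = len(results)
        base = np.full(k, 1.0 / k) if prior_weights is None else np.asarray(prior_weights, float)
        weights = np.append(base * k / (k + 1), 1.0 / (k + 1))
        posterior_model_probabilities(all_results, include_failsafe=False, prior_weights=weights)
        return all_results
    posterior_model_probabilities(results, include_failsafe=False, prior_weights=prior_weights)
    return results


def evidence_table(results: list[EvidenceResult]) -> pd.DataFrame:
    """Tidy evidence table (hypothesis, fit, complexity, BF_iu, BF_ic, PostP, mc_se)."""
    return pd.DataFrame(
        {
            "hypothesis": [r.name for r in results],
            "fit": [r.fit for r in results],
            "complexity": [r.complexity for r in results],
            "BF_iu": [r.bf_iu for r in results],
            "BF_ic": [r.bf_ic for r in results],
            "PostP": [r.postp for r in results],
            "mc_se": [r.mc_se for r in results],
        }
    )


def sensitivity_over_fractions(
    post: PosteriorApprox,
    hypotheses: dict[str, str | ConstraintSet],
    fractions: tuple[float, ...] = (1.0, 2.0, 3.0),
    draws: int = DEFAULT_DRAWS,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Evidence tables across prior fractions (same seeds per fraction)."""
    if not len(fractions) or any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive and non-empty")
    frames = []
    for f in fractions:
        res = evaluate_hypotheses(post, hypotheses, fraction=f, draws=draws,
                                  seed=seed, **kwargs)
        tab = evidence_table(res)
        tab.insert(0, "fraction", f)
        frames.append(tab)
    return pd.concat(frames, ignore_index=True)
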