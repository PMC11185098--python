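"""Marginal maximum likelihood estimation for the DLC-IRT family.

Optimization runs on an unconstrained reparameterization (log variance,
atanh correlation, logit guessing constant) with analytic gradients;
standard errors come from the numerically differentiated observed
information mapped back to the natural scale by the delta method.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logit
from scipy.stats import chi2, norm

from .model_core import (
    COVARIATE_NAMES,
    EncounterData,
    InvalidArgumentError,
    InvalidParameterError,
    ItemBank,
    ModelSpec,
    ParameterSet,
    QuadratureGrid,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "LRTestResult",
    "PosteriorClassification",
    "EstimationError",
    "count_parameters",
    "fit",
    "information_criteria",
    "lr_test",
    "select_item_intercepts",
    "posterior_class_prob",
    "entropy",
    "compare_models",
    "data_hash",
]

_LN2 = math.log(2.0)


class EstimationError(RuntimeError):
    """No optimization start produced a usable optimum."""


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    n_starts: int = 20
    n_final: int = 5
    nodes: int = 15
    seed: int = 0
    stage1_maxiter: int = 40
    final_maxiter: int = 600
    jitter_scale: float = 0.5
    compute_se: bool = True
    alpha: float = 0.05           # used by sequential intercept selection

    def escalated(self) -> "FitConfig":
        """More starts, analogous to raising the random-start budget."""
        return replace(self, n_starts=64, n_final=16)


@dataclass
class FitResult:
    spec: ModelSpec
    params: ParameterSet
    se: dict
    loglik: float
    n_free: int
    n_persons: int
    n_valid_encounters: int
    aic: float
    bic: float
    abic: float
    entropy: float | None
    converged: bool
    n_starts_used: int
    best_ll_replicated: bool
    seed: int
    data_hash: str | None = None
    start_logliks: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "params": self.params.to_dict(),
            "se": {k: (None if v is None or not np.isfinite(v) else float(v))
                   for k, v in self.se.items()},
            "loglik": float(self.loglik),
            "n_free": int(self.n_free),
            "n_persons": int(self.n_persons),
            "n_valid_encounters": int(self.n_valid_encounters),
            "aic": float(self.aic),
            "bic": float(self.bic),
            "abic": float(self.abic),
            "entropy": None if self.entropy is None else float(self.entropy),
            "converged": bool(self.converged),
            "n_starts_used": int(self.n_starts_used),
            "best_ll_replicated": bool(self.best_ll_replicated),
            "seed": int(self.seed),
            "data_hash": self.data_hash,
            "start_logliks": [float(v) for v in self.start_logliks],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(
            spec=ModelSpec.from_dict(d["spec"]),
            params=ParameterSet.from_dict(d["params"]),
            se={k: (None if v is None else float(v))
                for k, v in d["se"].items()},
            loglik=d["loglik"], n_free=d["n_free"],
            n_persons=d["n_persons"],
            n_valid_encounters=d["n_valid_encounters"],
            aic=d["aic"], bic=d["bic"], abic=d["abic"],
            entropy=d["entropy"], converged=d["converged"],
            n_starts_used=d["n_starts_used"],
            best_ll_replicated=d["best_ll_replicated"], seed=d["seed"],
            data_hash=d.get("data_hash"),
            start_logliks=list(d.get("start_logliks", [])),
        )

    @classmethod
    def from_json(cls, s: str) -> "FitResult":
        return cls.from_dict(json.loads(s))


@dataclass
class LRTestResult:
    delta_dev: float
    df: int
    p_value: float


@dataclass
class PosteriorClassification:
    person_ids: np.ndarray
    item_ids: np.ndarray
    p_solution: np.ndarray

    @property
    def hard_class(self) -> np.ndarray:
        return (self.p_solution >= 0.5).astype(int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "person_id": self.person_ids,
            "item_id": self.item_ids,
            "p_solution": self.p_solution,
            "hard_class": self.hard_class,
        })


# ---------------------------------------------------------------------------
# parameter counting and packing
# ---------------------------------------------------------------------------


def count_parameters(spec: ModelSpec) -> int:
    """Number of free parameters implied by a model specification."""
    k = spec.n_items                                  # item difficulties
    if spec.theta_variance_mode == "free":
        k += 1
    if spec.has_engagement_regression:
        k += 1 + len(spec.intercept_items)            # general + item intercepts
        k += len(spec.covariates) + len(spec.interactions)
    if spec.has_random_effect:
        k += 2                                        # var(psi), cov(psi, theta)
    if spec.z_mode == "equal_free":
        k += 1
    return k


def _param_names(spec: ModelSpec, bank: ItemBank) -> list:
    names = [f"beta[{j}]" for j in bank.item_ids]
    if spec.theta_variance_mode == "free":
        names.append("var_theta")
    if spec.has_engagement_regression:
        names += list(spec.eta_term_names())
    if spec.has_random_effect:
        names += ["sigma2_psi", "cov_psi_theta"]
    if spec.z_mode == "equal_free":
        names.append("z_free")
    return names


def _pack(spec: ModelSpec, params: ParameterSet, bank: ItemBank,
          enc=None) -> np.ndarray:
    """ParameterSet -> unconstrained optimization vector (centered design)."""
    x = [params.beta[j] for j in bank.item_ids]
    if spec.theta_variance_mode == "free":
        x.append(math.log(params.var_theta))
    if spec.has_engagement_regression:
        coefs = [params.alpha0]
        coefs += [params.alpha_item.get(j, 0.0) for j in spec.intercept_items]
        coefs += [params.gamma.get(c, 0.0) for c in spec.covariates]
        coefs += [params.gamma_int.get(p, 0.0) for p in spec.interactions]
        coefs = np.asarray(coefs, dtype=float)
        if enc is not None:
            coefs = enc.center_coefs(coefs)
        x += list(coefs)
    if spec.has_random_effect:
        s2 = max(params.sigma2_psi, 1e-8)
        rho = params.cov_psi_theta / math.sqrt(params.var_theta * s2)
        rho = min(max(rho, -0.999999), 0.999999)
        x += [math.log(s2), math.atanh(rho)]
    if spec.z_mode == "equal_free":
        x.append(logit(params.z_free if params.z_free is not None else 0.25))
    return np.asarray(x, dtype=float)


def _unpack(spec: ModelSpec, x: np.ndarray, bank: ItemBank,
            enc=None) -> ParameterSet:
    """Unconstrained optimization vector -> ParameterSet."""
    pos = bank.n_items
    beta = {j: float(v) for j, v in zip(bank.item_ids, x[:pos])}
    var_theta = 1.0
    if spec.theta_variance_mode == "free":
        var_theta = math.exp(x[pos]); pos += 1
    alpha0, alpha_item, gamma, gamma_int = 0.0, {}, {}, {}
    if spec.has_engagement_regression:
        p_eta = (1 + len(spec.intercept_items) + len(spec.covariates)
                 + len(spec.interactions))
        coefs = np.asarray(x[pos:pos + p_eta], dtype=float)
        pos += p_eta
        alpha0 = (enc.uncenter_intercept(coefs[0], coefs[1:])
                  if enc is not None else float(coefs[0]))
        k = 1
        for j in spec.intercept_items:
            alpha_item[j] = float(coefs[k]); k += 1
        for c in spec.covariates:
            gamma[c] = float(coefs[k]); k += 1
        for p in spec.interactions:
            gamma_int[p] = float(coefs[k]); k += 1
    sigma2_psi, cov = 0.0, 0.0
    if spec.has_random_effect:
        sigma2_psi = math.exp(x[pos])
        rho = math.tanh(x[pos + 1])
        cov = rho * math.sqrt(var_theta * sigma2_psi)
        pos += 2
    z_free = None
    if spec.z_mode == "equal_free":
        z_free = float(expit(x[pos])); pos += 1
    return ParameterSet(beta=beta, alpha0=alpha0, alpha_item=alpha_item,
                        gamma=gamma, gamma_int=gamma_int,
                        sigma2_psi=sigma2_psi, cov_psi_theta=cov,
                        var_theta=var_theta, z_free=z_free)


def _natural_vector(spec: ModelSpec, params: ParameterSet,
                    bank: ItemBank) -> np.ndarray:
    v = [params.beta[j] for j in bank.item_ids]
    if spec.theta_variance_mode == "free":
        v.append(params.var_theta)
    if spec.has_engagement_regression:
        v.append(params.alpha0)
        v += [params.alpha_item.get(j, 0.0) for j in spec.intercept_items]
        v += [params.gamma.get(c, 0.0) for c in spec.covariates]
        v += [params.gamma_int.get(p, 0.0) for p in spec.interactions]
    if spec.has_random_effect:
        v += [params.sigma2_psi, params.cov_psi_theta]
    if spec.z_mode == "equal_free":
        v.append(params.z_free)
    return np.asarray(v, dtype=float)


def _natural_from_unconstrained(spec: ModelSpec, x: np.ndarray,
                                bank: ItemBank, enc=None) -> np.ndarray:
    return _natural_vector(spec, _unpack(spec, x, bank, enc), bank)


# ---------------------------------------------------------------------------
# objective with analytic gradient
# ---------------------------------------------------------------------------


def _loglik_and_grad(x, spec: ModelSpec, data: EncounterData,
                     grid: QuadratureGrid, want_grad=True):
    n_items = data.bank.n_items
    pos = n_items
    beta_vec = x[:pos]
    u1 = grid.nodes[:, 0]
    if spec.theta_variance_mode == "free":
        sd_t = math.exp(0.5 * x[pos]); pos += 1
    else:
        sd_t = 1.0
    theta_nodes = sd_t * u1

    eta_coefs = None
    p_eta = 0
    if spec.has_engagement_regression:
        p_eta = (1 + len(spec.intercept_items) + len(spec.covariates)
                 + len(spec.interactions))
        eta_coefs = x[pos:pos + p_eta]; pos += p_eta

    psi_nodes = np.zeros_like(theta_nodes)
    if spec.has_random_effect:
        u2 = grid.nodes[:, 1]
        sd_p = math.exp(0.5 * x[pos])
        rho = math.tanh(x[pos + 1])
        w = math.sqrt(1.0 - rho ** 2)
        psi_nodes = sd_p * (rho * u1 + w * u2)
        pos += 2

    z_free = None
    if spec.z_mode == "equal_free":
        z_free = float(expit(x[pos])); pos += 1

    ll, g = data.loglik(theta_nodes, psi_nodes, grid.log_weights, beta_vec,
                        eta_coefs=eta_coefs, z_free=z_free,
                        want_grad=want_grad)
    if not want_grad:
        return ll, None

    grad = [g["g_beta"]]
    if spec.theta_variance_mode == "free":
        grad.append(np.array([0.5 * float(g["v_theta"] @ theta_nodes)]))
    if spec.has_engagement_regression:
        grad.append(g["g_eta"])
    if spec.has_random_effect:
        v_psi = g["v_psi"]
        g_sp = 0.5 * float(v_psi @ psi_nodes)
        dpsi_dr = sd_p * ((1.0 - rho ** 2) * u1 - rho * w * u2)
        g_r = float(v_psi @ dpsi_dr)
        grad.append(np.array([g_sp, g_r]))
    if spec.z_mode == "equal_free":
        grad.append(np.array([g["g_z"] * z_free * (1.0 - z_free)]))
    return ll, np.concatenate(grad)


def _neg_objective(x, spec, data, grid):
    ll, grad = _loglik_and_grad(x, spec, data, grid)
    if not np.isfinite(ll):
        return 1e12, np.zeros_like(x)
    return -ll, -grad


# ---------------------------------------------------------------------------
# starting values and multi-start optimization
# ---------------------------------------------------------------------------


def _default_start(spec: ModelSpec, data: EncounterData) -> np.ndarray:
    p_item = np.zeros(data.bank.n_items)
    n_item = np.zeros(data.bank.n_items)
    np.add.at(p_item, data.item_index, data.y)
    np.add.at(n_item, data.item_index, 1.0)
    prop = (p_item + 0.5) / (n_item + 1.0)
    beta0 = -logit(prop)
    x = list(beta0)
    if spec.theta_variance_mode == "free":
        x.append(0.0)                       # var_theta = 1
    if spec.has_engagement_regression:
        x.append(2.0)                       # alpha0
        x += [0.0] * len(spec.intercept_items)
        for c in spec.covariates:
            x.append(1.0 if c == "log_rt" else 0.0)
        x += [0.0] * len(spec.interactions)
    if spec.has_random_effect:
        x += [math.log(0.5), 0.0]           # sigma2_psi = 0.5, rho = 0
    if spec.z_mode == "equal_free":
        x.append(float(logit(0.25)))
    return np.asarray(x, dtype=float)


def _jitter(x0: np.ndarray, rng: np.random.Generator,
            scale: float) -> np.ndarray:
    return x0 + rng.normal(0.0, scale, size=x0.shape)


def _search_bounds(spec: ModelSpec, bank: ItemBank) -> list:
    """Box constraints for the unconstrained search.

    Wide enough for any plausible optimum; the correlation transform is
    capped at |atanh(rho)| = 3 (|rho| <= 0.995) because the score in that
    direction vanishes as rho -> +-1, which lets the line search run away
    and leaves a singular observed information.
    """
    b = [(-20.0, 20.0)] * bank.n_items
    if spec.theta_variance_mode == "free":
        b.append((-5.0, 3.0))
    if spec.has_engagement_regression:
        p_eta = (1 + len(spec.intercept_items) + len(spec.covariates)
                 + len(spec.interactions))
        b += [(-60.0, 60.0)] * p_eta
    if spec.has_random_effect:
        b += [(-12.0, 4.0), (-3.0, 3.0)]
    if spec.z_mode == "equal_free":
        b.append((-10.0, 10.0))
    return b


def fit(spec: ModelSpec, data, config: FitConfig | None = None,
        bank: ItemBank | None = None,
        start: ParameterSet | None = None) -> FitResult:
    """Fit a model by MML with multiple random starts.

    ``data`` may be a raw encounter table (DataFrame) together with ``bank``,
    or a prepared :class:`EncounterData`.  ``start`` warm-starts the first
    replication from a given parameter set (e.g. a nested model's optimum);
    remaining starts are jittered around it.
    """
    config = config or FitConfig()
    if isinstance(data, EncounterData):
        enc = data
        table = None
    else:
        if bank is None:
            raise InvalidArgumentError("an ItemBank is required with a table")
        enc = EncounterData.from_table(data, spec, bank)
        table = data
    if enc.n_persons < 2 or enc.bank.n_items < 2:
        raise EstimationError("need at least 2 persons and 2 items")

    dim = 2 if spec.has_random_effect else 1
    grid = QuadratureGrid.gauss_hermite(config.nodes, dim)
    rng = np.random.default_rng(config.seed)

    x0 = (_pack(spec, start, enc.bank, enc) if start is not None
          else _default_start(spec, enc))
    starts = [x0] + [_jitter(x0, rng, config.jitter_scale)
                     for _ in range(max(config.n_starts - 1, 0))]
    bounds = _search_bounds(spec, enc.bank)

    stage1 = []
    for xs in starts:
        try:
            res = optimize.minimize(
                _neg_objective, np.clip(xs, *zip(*bounds)),
                args=(spec, enc, grid), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": config.stage1_maxiter, "gtol": 1e-3})
            if np.isfinite(res.fun):
                stage1.append(res)
        except (FloatingPointError, ValueError):
            continue
    if not stage1:
        raise EstimationError("all optimization starts failed")

    stage1.sort(key=lambda r: r.fun)
    finals = []
    for res in stage1[:max(config.n_final, 1)]:
        try:
            res2 = optimize.minimize(
                _neg_objective, res.x, args=(spec, enc, grid), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": config.final_maxiter, "gtol": 1e-6,
                         "ftol": 1e-12})
            if np.isfinite(res2.fun):
                finals.append(res2)
        except (FloatingPointError, ValueError):
            continue
    if not finals:
        raise EstimationError("all polished starts failed")

    finals.sort(key=lambda r: r.fun)
    best = finals[0]
    lls = [-r.fun for r in finals]
    replicated = len(lls) >= 2 and (lls[0] - lls[1]) < 0.01
    params = _unpack(spec, best.x, enc.bank, enc)
    ll = -float(best.fun)

    se = {}
    names = _param_names(spec, enc.bank)
    if config.compute_se:
        se_vals = _standard_errors(spec, best.x, enc, grid)
        se = dict(zip(names, se_vals))
    else:
        se = {n: None for n in names}

    n_free = count_parameters(spec)
    assert n_free == len(best.x)
    aic, bic, abic = information_criteria(ll, n_free, enc.n_persons)

    ent = None
    if spec.has_engagement_regression:
        post = _posterior_from_arrays(spec, params, enc, grid)
        ent = entropy(post)

    return FitResult(
        spec=spec, params=params, se=se, loglik=ll, n_free=n_free,
        n_persons=enc.n_persons, n_valid_encounters=enc.n_valid,
        aic=aic, bic=bic, abic=abic, entropy=ent,
        converged=bool(best.success or np.max(np.abs(best.jac)) < 1e-3),
        n_starts_used=len(starts), best_ll_replicated=replicated,
        seed=config.seed,
        data_hash=None if table is None else data_hash(table),
        start_logliks=lls,
    )


# ---------------------------------------------------------------------------
# standard errors
# ---------------------------------------------------------------------------


def _standard_errors(spec, x_hat, enc, grid) -> np.ndarray:
    """Delta-method SEs on the natural scale from the observed information
    computed in the unconstrained space by differencing the analytic score."""
    n = len(x_hat)
    h = 1e-4 * np.maximum(1.0, np.abs(x_hat))
    H = np.zeros((n, n))
    for k in range(n):
        xp = x_hat.copy(); xp[k] += h[k]
        xm = x_hat.copy(); xm[k] -= h[k]
        _, gp = _loglik_and_grad(xp, spec, enc, grid)
        _, gm = _loglik_and_grad(xm, spec, enc, grid)
        H[k] = (gp - gm) / (2.0 * h[k])
    H = 0.5 * (H + H.T)
    try:
        cov_unc = np.linalg.inv(-H)
        if not np.all(np.isfinite(cov_unc)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        # near-singular information (e.g. a boundary solution): fall back
        # to the pseudo-inverse so the well-identified directions keep
        # finite standard errors
        from scipy.linalg import pinvh
        cov_unc = pinvh(-H, atol=1e-10 * max(1.0, float(np.abs(H).max())))
    # Jacobian of natural(x) by central differences of a trivial map
    J = np.zeros((n, n))
    for k in range(n):
        xp = x_hat.copy(); xp[k] += h[k]
        xm = x_hat.copy(); xm[k] -= h[k]
        J[:, k] = (_natural_from_unconstrained(spec, xp, enc.bank, enc)
                   - _natural_from_unconstrained(spec, xm, enc.bank, enc)) / (2 * h[k])
    cov_nat = J @ cov_unc @ J.T
    var = np.diag(cov_nat).copy()
    var[var < 0] = np.nan
    return np.sqrt(var)


# ---------------------------------------------------------------------------
# fit indices, tests, classification
# ---------------------------------------------------------------------------


def information_criteria(loglik: float, n_free: int,
                         n_persons: int) -> tuple:
    """AIC, BIC and sample-size adjusted BIC (N = persons)."""
    if n_persons < 1:
        raise InvalidArgumentError("n_persons must be >= 1")
    dev = -2.0 * loglik
    aic = dev + 2.0 * n_free
    bic = dev + n_free * math.log(n_persons)
    abic = dev + n_free * math.log((n_persons + 2.0) / 24.0)
    return aic, bic, abic


def lr_test(nested: FitResult, full: FitResult) -> LRTestResult:
    """Likelihood-ratio (deviance) test of nested against full."""
    if not nested.spec.is_restriction_of(full.spec):
        raise InvalidArgumentError("specs are not nested")
    df = full.n_free - nested.n_free
    if df < 1:
        raise InvalidArgumentError("full model has no extra parameters")
    delta = max(2.0 * (full.loglik - nested.loglik), 0.0)
    return LRTestResult(delta_dev=delta, df=df,
                        p_value=float(chi2.sf(delta, df)))


def _posterior_from_arrays(spec: ModelSpec, params: ParameterSet,
                           enc: EncounterData,
                           grid: QuadratureGrid) -> PosteriorClassification:
    from .model_core import eta_coefficients, transformed_nodes

    theta_nodes, psi_nodes = transformed_nodes(grid, params,
                                               spec.has_random_effect)
    beta_vec = np.asarray([params.beta[j] for j in enc.bank.item_ids])
    eta = (enc.center_coefs(eta_coefficients(spec, params))
           if spec.has_engagement_regression else None)
    z_free = params.z_free if spec.z_mode == "equal_free" else None
    W, Py, PI, zy, M = enc.posterior_node_weights(
        theta_nodes, psi_nodes, grid.log_weights, beta_vec,
        eta_coefs=eta, z_free=z_free)
    if PI is None:
        p = np.ones(enc.n_valid)
    else:
        frac = PI * Py / M
        p = (frac * W[enc.person_codes]).sum(axis=1)
        p = np.clip(p, 0.0, 1.0)
    item_ids = np.asarray(enc.bank.item_ids, dtype=object)[enc.item_index]
    return PosteriorClassification(person_ids=enc.person_ids,
                                   item_ids=item_ids, p_solution=p)


def posterior_class_prob(fit_result: FitResult, data,
                         bank: ItemBank | None = None,
                         nodes: int = 15) -> PosteriorClassification:
    """Posterior probability of solution behavior for each valid encounter.

    Marginalizes the person's latent variables over their posterior on the
    quadrature grid given the person's full response pattern.
    """
    if not fit_result.converged:
        raise InvalidArgumentError("fit did not converge")
    spec = fit_result.spec
    if isinstance(data, EncounterData):
        enc = data
    else:
        if bank is None:
            raise InvalidArgumentError("an ItemBank is required with a table")
        enc = EncounterData.from_table(data, spec, bank)
    grid = QuadratureGrid.gauss_hermite(
        nodes, 2 if spec.has_random_effect else 1)
    return _posterior_from_arrays(spec, fit_result.params, enc, grid)


def entropy(post: PosteriorClassification) -> float:
    """Normalized two-class classification entropy in [0, 1]."""
    p = np.asarray(post.p_solution, dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("no classified encounters")
    p = np.clip(p, 0.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = -np.where(p > 0, p * np.log(p), 0.0) \
            - np.where(p < 1, (1 - p) * np.log(1 - p), 0.0)
    return float(1.0 - h.sum() / (p.size * _LN2))


def select_item_intercepts(data, bank: ItemBank,
                           config: FitConfig | None = None,
                           base_spec: ModelSpec | None = None) -> tuple:
    """Sequential item-intercept selection against a base DLC model.

    Each item's single-intercept augmentation is fitted independently and
    compared with the same base fit by a df=1 likelihood-ratio test; items
    improving fit at ``config.alpha`` are retained.
    """
    config = config or FitConfig()
    if base_spec is None:
        base_spec = ModelSpec(family="dlc", n_items=bank.n_items,
                              covariates=("log_rt",))
    if base_spec.intercept_items:
        raise InvalidArgumentError("base spec must have no item intercepts")
    base_enc = (data if isinstance(data, EncounterData)
                else EncounterData.from_table(data, base_spec, bank))
    base_fit = fit(base_spec, base_enc,
                   replace(config, compute_se=False))
    retained = []
    for j in bank.item_ids:
        spec_j = replace(base_spec, intercept_items=(j,))
        enc_j = (EncounterData.from_table(data, spec_j, bank)
                 if not isinstance(data, EncounterData) else None)
        # rebuild the design for the augmented spec
        if enc_j is None:
            df = pd.DataFrame({
                "person_id": base_enc.person_ids,
                "item_id": np.asarray(bank.item_ids,
                                      dtype=object)[base_enc.item_index],
                "y": base_enc.y,
            })
            # reconstruct covariates from the base design columns
            for k, c in enumerate(base_spec.covariates):
                col = base_enc.X[:, 1 + k]
                df[c] = col
            enc_j = _encdata_from_valid_arrays(spec_j, bank, df)
        fit_j = fit(spec_j, enc_j, replace(config, compute_se=False),
                    start=base_fit.params)
        test = lr_test(base_fit, fit_j)
        if test.p_value < config.alpha:
            retained.append(j)
    return tuple(retained)


def _encdata_from_valid_arrays(spec: ModelSpec, bank: ItemBank,
                               df: pd.DataFrame) -> EncounterData:
    """Build EncounterData from already-valid rows carrying covariate values
    directly (log_rt on its log scale, indicators as 0/1)."""
    item_pos = {iid: k for k, iid in enumerate(bank.item_ids)}
    item_index = np.array([item_pos[i] for i in df["item_id"]], dtype=np.int64)
    X = None
    if spec.has_engagement_regression:
        cols = [np.ones(len(df))]
        for j in spec.intercept_items:
            cols.append((df["item_id"].to_numpy() == j).astype(float))
        for c in spec.covariates:
            cols.append(df[c].to_numpy(dtype=float))
        for a, b in spec.interactions:
            cols.append(df[a].to_numpy(dtype=float)
                        * df[b].to_numpy(dtype=float))
        X = np.column_stack(cols)
    return EncounterData(spec, bank,
                         person_ids=df["person_id"].to_numpy(),
                         item_index=item_index,
                         y=df["y"].to_numpy(dtype=np.int8),
                         X=X, n_total_encounters=len(df))


def compare_models(fits: Sequence[FitResult]) -> pd.DataFrame:
    """Model-comparison table: fit indices plus LR test vs the previous row."""
    if not fits:
        raise InvalidArgumentError("no fits to compare")
    hashes = {f.data_hash for f in fits if f.data_hash is not None}
    if len(hashes) > 1:
        raise InvalidArgumentError("fits come from different datasets")
    keys = {(f.n_persons, f.n_valid_encounters) for f in fits}
    if len({k[0] for k in keys}) > 1:
        raise InvalidArgumentError("fits come from different datasets")
    rows = []
    for i, f in enumerate(fits):
        row = {
            "model": _spec_label(f.spec),
            "n_par": f.n_free,
            "loglik": f.loglik,
            "aic": f.aic,
            "bic": f.bic,
            "abic": f.abic,
            "entropy": f.entropy,
            "delta_dev": None, "df": None, "p": None,
        }
        if i > 0 and fits[i - 1].spec.is_restriction_of(f.spec):
            t = lr_test(fits[i - 1], f)
            row.update(delta_dev=t.delta_dev, df=t.df, p=t.p_value)
        rows.append(row)
    table = pd.DataFrame(rows)
    table["df"] = table["df"].astype("Int64")
    return table


def _spec_label(spec: ModelSpec) -> str:
    if spec.family == "rasch":
        return "rasch"
    label = {"dlc": "dlc", "dlc_sl": "dlc-sl", "dlc_tl": "dlc-tl"}[spec.family]
    if len(spec.covariates) > 1:
        label += "-ext"
    if spec.interactions:
        label += "-int"
    return label


def wald_table(fit_result: FitResult) -> pd.DataFrame:
    """Estimate / SE / t / two-sided normal p for every free parameter."""
    names = list(fit_result.se.keys())
    est = []
    p = fit_result.params
    for n in names:
        if n.startswith("beta["):
            key = n[5:-1]
            try:
                key = int(key)
            except ValueError:
                pass
            est.append(p.beta[key])
        elif n == "var_theta":
            est.append(p.var_theta)
        elif n == "alpha0":
            est.append(p.alpha0)
        elif n.startswith("alpha["):
            key = n[6:-1]
            try:
                key = int(key)
            except ValueError:
                pass
            est.append(p.alpha_item.get(key, 0.0))
        elif n in COVARIATE_NAMES:
            est.append(p.gamma.get(n, 0.0))
        elif "*" in n:
            est.append(p.gamma_int.get(tuple(n.split("*")), 0.0))
        elif n == "sigma2_psi":
            est.append(p.sigma2_psi)
        elif n == "cov_psi_theta":
            est.append(p.cov_psi_theta)
        elif n == "z_free":
            est.append(p.z_free)
        else:
            est.append(np.nan)
    est = np.asarray(est, dtype=float)
    se = np.asarray([np.nan if fit_result.se[n] is None else fit_result.se[n]
                     for n in names], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
        pval = 2.0 * norm.sf(np.abs(t))
    return pd.DataFrame({"parameter": names, "estimate": est, "se": se,
                         "t": t, "p": pval})


def data_hash(table: pd.DataFrame) -> str:
    """Order-invariant hash of an encounter table, for comparison guards."""
    cols = [c for c in ("person_id", "item_id", "y", "rt_seconds",
                        "ac_count", "tr_count", "iv_count")
            if c in table.columns]
    canon = table[cols].sort_values(cols[:2]).reset_index(drop=True)
    payload = canon.to_csv(index=False).encode()
    return hashlib.sha256(payload).hexdigest()[:16]
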