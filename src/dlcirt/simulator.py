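"""Generative counterpart of the model family, for testing and recovery.

Simulates latent persons, lognormal response times, dichotomous engagement
indicators calibrated to target marginal rates, mixture responses with true
class labels, and (optionally) raw event logs whose extraction by
:mod:`dlcirt.process_indicators` reproduces the planted quantities exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .model_core import (
    InvalidArgumentError,
    InvalidParameterError,
    ItemBank,
    ModelSpec,
    ParameterSet,
)
from .process_indicators import LogEvent

__all__ = [
    "SimConfig",
    "SimOutput",
    "GenerationError",
    "simulate_persons",
    "simulate_covariates",
    "simulate_responses",
    "simulate_dataset",
    "simulate_event_log",
    "recovery_scenario",
    "realistic_scenario",
    "stress_scenario",
]


class GenerationError(RuntimeError):
    """A requested event-log plant is infeasible."""


@dataclass(frozen=True)
class SimConfig:
    """Everything needed to generate one synthetic dataset."""

    n_persons: int
    bank: ItemBank                      # carries true beta
    spec: ModelSpec
    params: ParameterSet
    mu_log_rt: tuple                    # per-item lognormal location
    rt_sigma: float = 0.5
    rt_psi_loading: float = 0.0         # slope of log RT on standardized psi
    ind_rates: Mapping = field(
        default_factory=lambda: {"ac": 0.14, "tr": 0.33, "iv": 0.07})
    ind_loadings: Mapping = field(
        default_factory=lambda: {"ac": 0.0, "tr": 0.0, "iv": 0.0})
    seed: int = 0

    def __post_init__(self):
        if self.rt_sigma <= 0:
            raise InvalidArgumentError("rt_sigma must be positive")
        for k, r in self.ind_rates.items():
            if not (0.0 < r < 1.0):
                raise InvalidArgumentError(f"target rate for {k} not in (0,1)")
        if len(self.mu_log_rt) != self.bank.n_items:
            raise InvalidArgumentError("mu_log_rt length mismatch")


@dataclass
class SimOutput:
    encounters: pd.DataFrame            # model-core encounter table
    latents: pd.DataFrame               # person_id, theta, psi
    true_class: pd.DataFrame            # person_id, item_id, c
    config: SimConfig


# ---------------------------------------------------------------------------
# latent persons and covariates
# ---------------------------------------------------------------------------


def simulate_persons(n: int, var_theta: float, sigma2_psi: float,
                     cov: float, seed: int) -> pd.DataFrame:
    """Bivariate-normal draws of (theta, psi), zero means."""
    sigma = np.array([[var_theta, cov], [cov, sigma2_psi]])
    eig = np.linalg.eigvalsh(sigma)
    if eig[0] < -1e-10:
        raise InvalidParameterError("latent covariance not PSD")
    rng = np.random.default_rng(seed)
    # explicit Cholesky-style factor that tolerates sigma2_psi == 0
    sd_t = math.sqrt(var_theta)
    c1 = cov / sd_t if sd_t > 0 else 0.0
    c2 = math.sqrt(max(sigma2_psi - c1 ** 2, 0.0))
    u = rng.standard_normal((n, 2))
    theta = sd_t * u[:, 0]
    psi = c1 * u[:, 0] + c2 * u[:, 1]
    return pd.DataFrame({"person_id": np.arange(1, n + 1),
                         "theta": theta, "psi": psi})


def _calibrated_intercept(rate: float, loading: float) -> float:
    """Intercept c with E[expit(c + loading * S)] = rate for S ~ N(0, 1)."""
    if loading == 0.0:
        return float(logit(rate))
    x, w = np.polynomial.hermite_e.hermegauss(41)
    w = w / w.sum()

    def gap(c):
        return float(expit(c + loading * x) @ w) - rate

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise GenerationError("target rate unattainable with this loading")
    return float(brentq(gap, lo, hi, xtol=1e-12))


def simulate_covariates(latents: pd.DataFrame,
                        config: SimConfig) -> pd.DataFrame:
    """Per-encounter response times and indicator flags.

    Log response times are normal around a per-item location, optionally
    shifted by the person's standardized engagement threshold; indicators
    are Bernoulli with intercepts solved so the marginal rates hit their
    targets given the loadings.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(latents)
    J = config.bank.n_items
    psi = latents["psi"].to_numpy()
    sd_psi = psi.std(ddof=0)
    if config.params.sigma2_psi > 0:
        psi_std = psi / math.sqrt(config.params.sigma2_psi)
    elif sd_psi > 0:
        psi_std = psi / sd_psi
    else:
        psi_std = rng.standard_normal(n)

    mu = np.asarray(config.mu_log_rt)
    log_rt = (mu[None, :]
              + config.rt_psi_loading * psi_std[:, None]
              + config.rt_sigma * rng.standard_normal((n, J)))
    rt = np.exp(log_rt)

    flags = {}
    for k in ("ac", "tr", "iv"):
        a = float(config.ind_loadings.get(k, 0.0))
        c = _calibrated_intercept(float(config.ind_rates[k]), a)
        p = expit(c + a * psi_std)[:, None] * np.ones((1, J))
        flags[k] = (rng.random((n, J)) < p).astype(int)

    pid = np.repeat(latents["person_id"].to_numpy(), J)
    iid = np.tile(np.asarray(config.bank.item_ids, dtype=object), n)
    return pd.DataFrame({
        "person_id": pid, "item_id": iid,
        "rt_seconds": rt.ravel(),
        "ac_count": flags["ac"].ravel(),
        "tr_count": flags["tr"].ravel(),
        "iv_count": flags["iv"].ravel(),
    })


# ---------------------------------------------------------------------------
# responses
# ---------------------------------------------------------------------------


def simulate_responses(latents: pd.DataFrame, covariates: pd.DataFrame,
                       spec: ModelSpec, params: ParameterSet,
                       bank: ItemBank, seed: int) -> pd.DataFrame:
    """Draw engagement classes and responses for every encounter.

    Returns the covariate table with added columns ``c`` (true class) and
    ``y`` (scored response).
    """
    rng = np.random.default_rng(seed + 2)
    df = covariates.merge(latents, on="person_id", how="left")
    theta = df["theta"].to_numpy()
    psi = df["psi"].to_numpy()
    item_pos = {iid: k for k, iid in enumerate(bank.item_ids)}
    item_idx = np.array([item_pos[i] for i in df["item_id"]])
    beta = np.asarray([params.beta[j] for j in bank.item_ids])[item_idx]

    if spec.has_engagement_regression:
        vals = {
            "log_rt": np.log(df["rt_seconds"].to_numpy(dtype=float)),
            "ac": (df["ac_count"].to_numpy(dtype=float) >= 1).astype(float),
            "tr": (df["tr_count"].to_numpy(dtype=float) >= 1).astype(float),
            "iv": (df["iv_count"].to_numpy(dtype=float) >= 1).astype(float),
        }
        eta = np.full(len(df), params.alpha0)
        for j, a in params.alpha_item.items():
            eta = eta + a * (df["item_id"].to_numpy() == j)
        for c in spec.covariates:
            eta = eta + params.gamma.get(c, 0.0) * vals[c]
        for a_, b_ in spec.interactions:
            eta = eta + params.gamma_int.get((a_, b_), 0.0) \
                * vals[a_] * vals[b_]
        if spec.has_random_effect:
            eta = eta + psi
        pi = expit(eta)
    else:
        pi = np.ones(len(df))

    z = (np.full(len(df), params.z_free) if spec.z_mode == "equal_free"
         else np.asarray(bank.z)[item_idx])
    c_true = (rng.random(len(df)) < pi).astype(int)
    p_sol = expit(theta - beta)
    p_correct = np.where(c_true == 1, p_sol, z)
    y = (rng.random(len(df)) < p_correct).astype(int)
    out = df[["person_id", "item_id", "rt_seconds",
              "ac_count", "tr_count", "iv_count"]].copy()
    out["c"] = c_true
    out["y"] = y
    return out


def simulate_dataset(config: SimConfig) -> SimOutput:
    """End-to-end generation of one dataset from a scenario config."""
    latents = simulate_persons(
        config.n_persons, config.params.var_theta,
        config.params.sigma2_psi, config.params.cov_psi_theta, config.seed)
    cov = simulate_covariates(latents, config)
    full = simulate_responses(latents, cov, config.spec, config.params,
                              config.bank, config.seed)
    enc = full[["person_id", "item_id", "y", "rt_seconds",
                "ac_count", "tr_count", "iv_count"]].copy()
    cls = full[["person_id", "item_id", "c"]].copy()
    return SimOutput(encounters=enc, latents=latents, true_class=cls,
                     config=config)


# ---------------------------------------------------------------------------
# raw event-log generation (round-trip oracle for the extraction pipeline)
# ---------------------------------------------------------------------------

_SEG_MIN_MS = 1200      # keeps real page visits above the navigation filter
_TEXT_DWELL_MS = 2000
_SIDE_DWELL_MS = 1500
_NOISE_DWELL_MS = 300


def _page(task: int, order: int) -> str:
    return f"T{task}.P{order:03d}"


def simulate_event_log(plants: pd.DataFrame, n_items: int,
                       noise_passthrough: int = 0,
                       seed: int = 0) -> list:
    """Emit raw events reproducing planted per-encounter quantities.

    ``plants`` columns: person_id, item_id (1..n_items), rt_seconds, ac, tr,
    iv.  Each person's session visits the planted items in order; text
    rereads bounce to the task's text page, item revisits bounce through a
    high-numbered filler item page, and answer changes alternate between two
    response options.  ``noise_passthrough = k`` makes the session open with
    a sub-threshold forward flip through the first k item pages (the
    canonical pass-through pattern the navigation filter removes).

    Raises :class:`GenerationError` when a plant cannot be realized, e.g.
    a response time too short for the number of required page visits.
    """
    events: list = []
    text_page = _page(1, 0)
    filler_page = _page(1, 900)
    end_page = _page(1, 990)

    for person_id, group in plants.groupby("person_id", sort=True):
        by_item = {int(r.item_id): r for r in group.itertuples(index=False)}
        items = sorted(by_item)
        if any(j < 1 or j > n_items for j in items):
            raise GenerationError("item id outside the page layout")
        k = min(noise_passthrough, len(items) - 1)
        if k > 0:
            order = [items[k]] + items[:k] + items[k + 1:]
        else:
            order = items

        t = 0
        seq = 0

        def emit(kind, page_order, page_kind, item_id=None, option_id=None):
            nonlocal seq
            seq += 1
            events.append(LogEvent(
                person_id=person_id, seq=seq, timestamp_ms=t, kind=kind,
                page_id=_page(1, page_order), page_kind=page_kind,
                task_id="T1", item_id=item_id, option_id=option_id))

        emit("navigate", 0, "text")
        t += _TEXT_DWELL_MS
        if k > 0:
            for j in items[:k]:
                emit("navigate", j * 10, "item", item_id=j)
                t += _NOISE_DWELL_MS

        for j in order:
            row = by_item[j]
            rt_ms = int(round(float(row.rt_seconds) * 1000))
            ac, tr, iv = int(row.ac), int(row.tr), int(row.iv)
            n_seg = 1 + tr + iv
            if rt_ms < n_seg * _SEG_MIN_MS:
                raise GenerationError(
                    f"rt of {rt_ms} ms cannot host {n_seg} page visits")
            seg = [rt_ms // n_seg] * n_seg
            seg[0] += rt_ms - sum(seg)
            if ac + 1 > (seg[0] - 200) // 100:
                raise GenerationError("first visit too short for selections")

            emit("navigate", j * 10, "item", item_id=j)
            t_open = t
            for s in range(ac + 1):
                t = t_open + 100 * (s + 1)
                emit("select_option", j * 10, "item", item_id=j,
                     option_id=("A", "B")[s % 2])
            t = t_open + seg[0]
            seg_idx = 1
            for _ in range(tr):
                emit("navigate", 0, "text")
                t += _SIDE_DWELL_MS
                emit("navigate", j * 10, "item", item_id=j)
                t += seg[seg_idx]; seg_idx += 1
            for _ in range(iv):
                emit("navigate", 900, "item", item_id="FILLER")
                t += _SIDE_DWELL_MS
                emit("navigate", j * 10, "item", item_id=j)
                t += seg[seg_idx]; seg_idx += 1

        emit("navigate", 990, "other")

    events.sort(key=lambda e: (str(e.person_id), e.timestamp_ms, e.seq))
    return events


# ---------------------------------------------------------------------------
# scenario factories
# ---------------------------------------------------------------------------

_MENU_INTERCEPT_ITEMS = (1, 2, 3, 7, 11, 14)


def _default_bank(n_items: int = 14) -> ItemBank:
    beta = np.linspace(-1.5, 1.5, n_items)
    return ItemBank.uniform(n_items, n_options=4, beta=beta)


def recovery_scenario(n_persons: int = 1000, seed: int = 0) -> SimConfig:
    """Moderate, well-conditioned truth for parameter-recovery studies.

    Covariates are generated independently of the latent variables so the
    fitted model is exactly the generating model.
    """
    bank = _default_bank()
    spec = ModelSpec(family="dlc_tl", n_items=bank.n_items,
                     intercept_items=_MENU_INTERCEPT_ITEMS,
                     covariates=("log_rt", "ac", "tr", "iv"))
    params = ParameterSet(
        beta={j: float(b) for j, b in zip(bank.item_ids, bank.beta)},
        alpha0=-1.7,
        alpha_item={j: -0.8 for j in _MENU_INTERCEPT_ITEMS},
        gamma={"log_rt": 1.0, "ac": 0.5, "tr": -0.8, "iv": 0.0},
        sigma2_psi=1.0, cov_psi_theta=0.5, var_theta=1.0)
    rt_sigma = 0.5
    # lognormal location set so item mean RTs span ~17-36 s
    mu = np.log(np.linspace(17.0, 36.0, bank.n_items)) - rt_sigma ** 2 / 2
    return SimConfig(n_persons=n_persons, bank=bank, spec=spec,
                     params=params, mu_log_rt=tuple(mu), rt_sigma=rt_sigma,
                     rt_psi_loading=0.0, seed=seed)


def realistic_scenario(n_persons: int = 1932, seed: int = 0) -> SimConfig:
    """Descriptively anchored scenario: indicator marginals near
    (0.14, 0.33, 0.07), item mean response times spanning ~17-36 s, and
    covariates mildly loaded on the engagement threshold."""
    cfg = recovery_scenario(n_persons=n_persons, seed=seed)
    return replace(cfg, rt_psi_loading=0.3,
                   ind_loadings={"ac": 0.3, "tr": 0.5, "iv": 0.3})


def stress_scenario(n_persons: int = 1932, seed: int = 0) -> SimConfig:
    """Stress scenario with extreme, near-boundary coefficients (strong
    class separation, near-perfect latent correlation); recovery is
    ill-conditioned here by construction."""
    cfg = realistic_scenario(n_persons=n_persons, seed=seed)
    params = ParameterSet(
        beta=cfg.params.beta,
        alpha0=-21.52,
        alpha_item={1: -6.34, 2: -9.83, 3: -13.93, 7: -8.43,
                    11: -13.17, 14: 3.92},
        gamma={"log_rt": 11.26, "ac": -0.76, "tr": -2.60, "iv": -1.43},
        sigma2_psi=7.26, cov_psi_theta=2.69, var_theta=1.0)
    return replace(cfg, params=params)
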