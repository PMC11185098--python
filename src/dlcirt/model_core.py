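"""Probability components and marginal likelihood of the DLC-IRT model family.

The family mixes, at the item-by-person encounter level, a Rasch
solution-behavior response process with a guessing process whose success
probability is the reciprocal of the number of response options.  Class
membership is governed by a logistic regression on the log response time,
optional dichotomous process-data indicators, optional item-specific
intercepts, and (in the two-level variant) a person random effect that is
allowed to covary with ability.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logsumexp

__all__ = [
    "COVARIATE_NAMES",
    "FAMILIES",
    "ItemBank",
    "PersonLatent",
    "EncounterRecord",
    "ModelSpec",
    "ParameterSet",
    "QuadratureGrid",
    "EncounterData",
    "rasch_prob",
    "guess_prob",
    "linear_predictor",
    "engagement_prob",
    "mixture_response_prob",
    "person_conditional_loglik",
    "marginal_loglik",
    "InvalidArgumentError",
    "InvalidParameterError",
]

COVARIATE_NAMES = ("log_rt", "ac", "tr", "iv")
FAMILIES = ("rasch", "dlc", "dlc_sl", "dlc_tl")

_PROB_FLOOR = 1e-12


class InvalidArgumentError(ValueError):
    """An operation received an argument outside its domain."""


class InvalidParameterError(ValueError):
    """A parameter set violates its constraints (e.g. non-PSD covariance)."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemBank:
    """Items with difficulties, option counts and guessing constants.

    ``z`` defaults to ``1 / n_options`` (the fixed-reciprocal convention);
    a shared free ``z`` is carried in :class:`ParameterSet` instead.
    """

    item_ids: tuple
    n_options: tuple
    beta: tuple | None = None
    z: tuple | None = None

    def __post_init__(self):
        if len(self.item_ids) != len(self.n_options):
            raise InvalidArgumentError("item_ids and n_options differ in length")
        if any(int(m) < 1 for m in self.n_options):
            raise InvalidArgumentError("n_options must be >= 1")
        if self.z is None:
            object.__setattr__(
                self, "z", tuple(1.0 / int(m) for m in self.n_options)
            )
        if any(not (0.0 < zj <= 1.0) for zj in self.z):
            raise InvalidArgumentError("z must lie in (0, 1]")
        if self.beta is not None and len(self.beta) != len(self.item_ids):
            raise InvalidArgumentError("beta length mismatch")

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def index_of(self, item_id) -> int:
        return self.item_ids.index(item_id)

    @classmethod
    def uniform(cls, n_items: int, n_options: int = 4, beta=None) -> "ItemBank":
        ids = tuple(range(1, n_items + 1))
        return cls(ids, (n_options,) * n_items,
                   beta=None if beta is None else tuple(beta))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ItemBank":
        return cls(tuple(df["item_id"]), tuple(int(m) for m in df["n_options"]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"item_id": self.item_ids, "n_options": self.n_options})


@dataclass(frozen=True)
class PersonLatent:
    """Latent draws for one person: ability and engagement threshold."""

    theta: float
    psi: float = 0.0


@dataclass
class EncounterRecord:
    """One person-by-item encounter.

    ``None`` encodes missingness.  When the response time is missing or
    non-positive, the log response time and all indicator flags are missing
    as well; such encounters never enter the likelihood.
    """

    person_id: object
    item_id: object
    y: int | None
    rt_seconds: float | None = None
    ac: int | None = None
    tr: int | None = None
    iv: int | None = None

    def __post_init__(self):
        if self.rt_seconds is not None and self.rt_seconds <= 0:
            self.rt_seconds = None
        if self.rt_seconds is None:
            self.ac = self.tr = self.iv = None

    @property
    def log_rt(self) -> float | None:
        return None if self.rt_seconds is None else math.log(self.rt_seconds)

    def covariate(self, name: str) -> float | None:
        if name == "log_rt":
            return self.log_rt
        return getattr(self, name)

    def is_valid(self, spec: "ModelSpec") -> bool:
        if self.y not in (0, 1):
            return False
        return all(self.covariate(c) is not None for c in spec.covariates)


def _norm_interactions(pairs) -> tuple:
    out = []
    for pair in pairs:
        a, b = sorted(pair, key=COVARIATE_NAMES.index)
        out.append((a, b))
    return tuple(sorted(out, key=lambda p: (COVARIATE_NAMES.index(p[0]),
                                            COVARIATE_NAMES.index(p[1]))))


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of one member of the model family."""

    family: str
    n_items: int
    intercept_items: tuple = ()
    covariates: tuple = ()
    interactions: tuple = ()
    z_mode: str = "fixed_reciprocal"
    theta_variance_mode: str = "free"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise InvalidArgumentError(f"unknown family {self.family!r}")
        if self.z_mode not in ("fixed_reciprocal", "equal_free"):
            raise InvalidArgumentError(f"unknown z_mode {self.z_mode!r}")
        if self.theta_variance_mode not in ("free", "fixed_1"):
            raise InvalidArgumentError(
                f"unknown theta_variance_mode {self.theta_variance_mode!r}")
        object.__setattr__(self, "intercept_items", tuple(self.intercept_items))
        object.__setattr__(self, "covariates", tuple(self.covariates))
        for c in self.covariates:
            if c not in COVARIATE_NAMES:
                raise InvalidArgumentError(f"unknown covariate {c!r}")
        object.__setattr__(self, "interactions",
                           _norm_interactions(self.interactions))
        if self.family == "rasch":
            if self.covariates or self.interactions or self.intercept_items:
                raise InvalidArgumentError(
                    "rasch family admits no engagement regression terms")
        for a, b in self.interactions:
            if a not in self.covariates or b not in self.covariates:
                raise InvalidArgumentError(
                    "interactions only between covariates present in the spec")

    @property
    def has_random_effect(self) -> bool:
        return self.family == "dlc_tl"

    @property
    def has_engagement_regression(self) -> bool:
        return self.family != "rasch"

    def eta_term_names(self) -> tuple:
        """Column names of the engagement-regression design, in order."""
        if not self.has_engagement_regression:
            return ()
        names = ["alpha0"]
        names += [f"alpha[{j}]" for j in self.intercept_items]
        names += list(self.covariates)
        names += [f"{a}*{b}" for a, b in self.interactions]
        return tuple(names)

    def is_restriction_of(self, full: "ModelSpec") -> bool:
        """Structural nesting check (used to validate LR tests)."""
        if self.n_items != full.n_items:
            return False
        order = {f: i for i, f in enumerate(FAMILIES)}
        if order[self.family] > order[full.family]:
            return False
        if not set(self.intercept_items) <= set(full.intercept_items):
            return False
        if not set(self.covariates) <= set(full.covariates):
            return False
        if not set(self.interactions) <= set(full.interactions):
            return False
        if self.z_mode == "equal_free" and full.z_mode != "equal_free":
            return False
        if (self.theta_variance_mode == "free"
                and full.theta_variance_mode != "free"):
            return False
        return True

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "n_items": self.n_items,
            "intercept_items": list(self.intercept_items),
            "covariates": list(self.covariates),
            "interactions": [list(p) for p in self.interactions],
            "z_mode": self.z_mode,
            "theta_variance_mode": self.theta_variance_mode,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            family=d["family"],
            n_items=int(d["n_items"]),
            intercept_items=tuple(d.get("intercept_items", ())),
            covariates=tuple(d.get("covariates", ())),
            interactions=tuple(tuple(p) for p in d.get("interactions", ())),
            z_mode=d.get("z_mode", "fixed_reciprocal"),
            theta_variance_mode=d.get("theta_variance_mode", "free"),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))


@dataclass
class ParameterSet:
    """All free parameters of one model, on their natural scales."""

    beta: dict
    alpha0: float = 0.0
    alpha_item: dict = field(default_factory=dict)
    gamma: dict = field(default_factory=dict)
    gamma_int: dict = field(default_factory=dict)
    sigma2_psi: float = 0.0
    cov_psi_theta: float = 0.0
    var_theta: float = 1.0
    z_free: float | None = None

    def validate(self) -> None:
        if self.var_theta <= 0:
            raise InvalidParameterError("var_theta must be positive")
        if self.sigma2_psi < 0:
            raise InvalidParameterError("sigma2_psi must be non-negative")
        if self.cov_psi_theta ** 2 > self.var_theta * self.sigma2_psi + 1e-12:
            raise InvalidParameterError(
                "(theta, psi) covariance matrix is not positive semidefinite")
        if self.z_free is not None and not (0.0 < self.z_free < 1.0):
            raise InvalidParameterError("z_free must lie in (0, 1)")

    def latent_covariance(self) -> np.ndarray:
        return np.array([[self.var_theta, self.cov_psi_theta],
                         [self.cov_psi_theta, self.sigma2_psi]])

    def to_dict(self) -> dict:
        d = {
            "beta": {str(k): float(v) for k, v in self.beta.items()},
            "alpha0": float(self.alpha0),
            "alpha_item": {str(k): float(v) for k, v in self.alpha_item.items()},
            "gamma": {k: float(v) for k, v in self.gamma.items()},
            "gamma_int": {f"{a}*{b}": float(v)
                          for (a, b), v in self.gamma_int.items()},
            "sigma2_psi": float(self.sigma2_psi),
            "cov_psi_theta": float(self.cov_psi_theta),
            "var_theta": float(self.var_theta),
            "z_free": None if self.z_free is None else float(self.z_free),
        }
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ParameterSet":
        def _key(k):
            try:
                return int(k)
            except (TypeError, ValueError):
                return k

        return cls(
            beta={_key(k): float(v) for k, v in d["beta"].items()},
            alpha0=float(d.get("alpha0", 0.0)),
            alpha_item={_key(k): float(v)
                        for k, v in d.get("alpha_item", {}).items()},
            gamma={k: float(v) for k, v in d.get("gamma", {}).items()},
            gamma_int={tuple(k.split("*")): float(v)
                       for k, v in d.get("gamma_int", {}).items()},
            sigma2_psi=float(d.get("sigma2_psi", 0.0)),
            cov_psi_theta=float(d.get("cov_psi_theta", 0.0)),
            var_theta=float(d.get("var_theta", 1.0)),
            z_free=(None if d.get("z_free") is None else float(d["z_free"])),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ParameterSet":
        return cls.from_dict(json.loads(s))


class QuadratureGrid:
    """Gauss-Hermite nodes and weights against the standard-normal base.

    ``nodes`` has shape (Q, dim); ``weights`` are positive and sum to one,
    so that sums over the grid approximate expectations under N(0, I).
    """

    def __init__(self, nodes: np.ndarray, weights: np.ndarray):
        nodes = np.asarray(nodes, dtype=float)
        if nodes.ndim == 1:
            nodes = nodes[:, None]
        weights = np.asarray(weights, dtype=float)
        if nodes.shape[0] != weights.shape[0]:
            raise InvalidArgumentError("nodes/weights length mismatch")
        if np.any(weights <= 0):
            raise InvalidArgumentError("weights must be positive")
        if nodes.shape[0] < 5:
            raise InvalidArgumentError("need at least 5 nodes per dimension")
        self.nodes = nodes
        self.weights = weights / weights.sum()
        self.log_weights = np.log(self.weights)

    @property
    def dim(self) -> int:
        return self.nodes.shape[1]

    @classmethod
    def gauss_hermite(cls, n_nodes: int = 15, dim: int = 1) -> "QuadratureGrid":
        if n_nodes < 5:
            raise InvalidArgumentError("need at least 5 nodes per dimension")
        # probabilists' Hermite: weight function exp(-x^2/2)
        x, w = np.polynomial.hermite_e.hermegauss(n_nodes)
        w = w / w.sum()
        if dim == 1:
            return cls(x[:, None], w)
        if dim == 2:
            xx1, xx2 = np.meshgrid(x, x, indexing="ij")
            ww = np.outer(w, w).ravel()
            return cls(np.column_stack([xx1.ravel(), xx2.ravel()]), ww)
        raise InvalidArgumentError("only 1- or 2-dimensional grids supported")


# ---------------------------------------------------------------------------
# elementary probability operations
# ---------------------------------------------------------------------------


def _check_finite(name, *vals):
    for v in vals:
        if not np.all(np.isfinite(v)):
            raise InvalidArgumentError(f"{name}: non-finite input")


def rasch_prob(theta, beta):
    """Solution-behavior success probability: logistic in theta - beta."""
    _check_finite("rasch_prob", theta, beta)
    return expit(np.asarray(theta, dtype=float) - np.asarray(beta, dtype=float))


def guess_prob(n_options):
    """Disengaged-class success probability 1/M for an M-option item."""
    m = np.asarray(n_options)
    if not np.issubdtype(m.dtype, np.integer):
        if not np.all(np.equal(np.mod(m, 1), 0)):
            raise InvalidArgumentError("n_options must be an integer")
    if np.any(m < 1):
        raise InvalidArgumentError("n_options must be >= 1")
    out = 1.0 / m.astype(float)
    return float(out) if np.isscalar(n_options) else out


def engagement_prob(eta):
    """Probability of solution behavior from the class-regression predictor."""
    _check_finite("engagement_prob", eta)
    return expit(np.asarray(eta, dtype=float)) if not np.isscalar(eta) \
        else float(expit(eta))


def linear_predictor(spec: ModelSpec, params: ParameterSet,
                     enc: EncounterRecord, psi: float = 0.0) -> float:
    """Engagement-regression linear predictor for one encounter."""
    if not spec.has_engagement_regression:
        raise InvalidArgumentError("rasch family has no engagement regression")
    eta = params.alpha0
    if enc.item_id in spec.intercept_items:
        eta += params.alpha_item.get(enc.item_id, 0.0)
    vals = {}
    for c in spec.covariates:
        v = enc.covariate(c)
        if v is None:
            raise InvalidArgumentError(
                f"covariate {c!r} required by spec but missing")
        vals[c] = float(v)
        eta += params.gamma.get(c, 0.0) * vals[c]
    for a, b in spec.interactions:
        eta += params.gamma_int.get((a, b), 0.0) * vals[a] * vals[b]
    return float(eta + (psi if spec.has_random_effect else 0.0))


def mixture_response_prob(pi, p_sol, z, y):
    """Two-class mixture response probability for a scored response y."""
    for name, v in (("pi", pi), ("p_sol", p_sol), ("z", z)):
        if np.any(np.asarray(v) < 0) or np.any(np.asarray(v) > 1):
            raise InvalidArgumentError(f"{name} must lie in [0, 1]")
    y_arr = np.asarray(y)
    if not np.all(np.isin(y_arr, (0, 1))):
        raise InvalidArgumentError("y must be 0 or 1")
    p1 = np.asarray(pi) * np.asarray(p_sol) + (1.0 - np.asarray(pi)) * np.asarray(z)
    out = np.where(y_arr == 1, p1, 1.0 - p1)
    return float(out) if out.ndim == 0 else out


def _z_for_item(spec: ModelSpec, params: ParameterSet,
                bank: ItemBank, item_id) -> float:
    if spec.z_mode == "equal_free":
        if params.z_free is None:
            raise InvalidParameterError("z_mode=equal_free requires z_free")
        return params.z_free
    return bank.z[bank.index_of(item_id)]


def person_conditional_loglik(spec: ModelSpec, params: ParameterSet,
                              encounters: Iterable[EncounterRecord],
                              theta: float, psi: float = 0.0,
                              bank: ItemBank | None = None) -> float:
    """Conditional log-likelihood of one person's encounters given (theta, psi).

    Encounters invalid for the spec contribute zero.  Items are assumed
    conditionally independent given the latent variables.
    """
    encounters = list(encounters)
    persons = {e.person_id for e in encounters}
    if len(persons) > 1:
        raise InvalidArgumentError("encounters must belong to a single person")
    if bank is None:
        ids = tuple(sorted({e.item_id for e in encounters}))
        bank = ItemBank(ids, (4,) * len(ids))
    total = 0.0
    for enc in encounters:
        if not enc.is_valid(spec):
            continue
        beta_j = params.beta[enc.item_id]
        p_sol = rasch_prob(theta, beta_j)
        if spec.has_engagement_regression:
            pi = engagement_prob(linear_predictor(spec, params, enc, psi))
        else:
            pi = 1.0
        z = _z_for_item(spec, params, bank, enc.item_id)
        m = mixture_response_prob(pi, p_sol, z, enc.y)
        total += math.log(min(max(m, _PROB_FLOOR), 1.0 - _PROB_FLOOR))
    return total


# ---------------------------------------------------------------------------
# vectorized dataset and marginal likelihood
# ---------------------------------------------------------------------------


class EncounterData:
    """Valid encounters of a dataset packed into arrays for likelihood work.

    Rows are sorted by person so that per-person sums reduce to
    ``np.add.reduceat`` over contiguous blocks.
    """

    def __init__(self, spec: ModelSpec, bank: ItemBank,
                 person_ids: np.ndarray, item_index: np.ndarray,
                 y: np.ndarray, X: np.ndarray | None,
                 n_total_encounters: int):
        self.spec = spec
        self.bank = bank
        self.person_ids = person_ids          # per valid encounter
        self.item_index = item_index
        self.y = y
        self.X = X                            # engagement design or None
        self.n_total_encounters = n_total_encounters

        uniq, codes = np.unique(person_ids, return_inverse=True)
        order = np.argsort(codes, kind="stable")
        self._order = order
        self.person_ids = person_ids[order]
        self.item_index = item_index[order]
        self.y = y[order]
        if X is not None:
            self.X = X[order]
        codes = codes[order]
        self.person_codes = codes
        self.unique_persons = uniq
        self.n_persons = len(uniq)
        self.person_starts = np.searchsorted(codes, np.arange(len(uniq)))
        self.n_valid = len(self.y)
        self.sign = (2.0 * self.y - 1.0)[:, None]
        self.z_item = np.asarray(bank.z, dtype=float)[self.item_index]
        # center non-intercept design columns: pure reparameterization that
        # decorrelates the general intercept from the covariates (slopes are
        # unchanged; the intercept is shifted back on the way out)
        self.X_mean = None
        if self.X is not None and self.X.shape[0] > 0:
            self.X_mean = self.X.mean(axis=0)
            self.X_mean[0] = 0.0
            self.X = self.X - self.X_mean[None, :]

    def center_coefs(self, raw: np.ndarray) -> np.ndarray:
        """Raw engagement coefficients -> coefficients for the centered X."""
        if self.X_mean is None:
            return raw
        c = np.asarray(raw, dtype=float).copy()
        c[0] += float(raw[1:] @ self.X_mean[1:])
        return c

    def uncenter_intercept(self, c0: float, slopes: np.ndarray) -> float:
        """Centered intercept -> raw general intercept."""
        if self.X_mean is None:
            return c0
        return float(c0 - slopes @ self.X_mean[1:])

    @classmethod
    def from_table(cls, table: pd.DataFrame, spec: ModelSpec,
                   bank: ItemBank) -> "EncounterData":
        df = table.copy()
        n_total = len(df)
        if "rt_seconds" in df.columns:
            rt = pd.to_numeric(df["rt_seconds"], errors="coerce")
        else:
            rt = pd.Series(np.nan, index=df.index)
        bad_rt = rt.isna() | (rt <= 0)
        log_rt = np.where(bad_rt, np.nan, np.log(rt.where(~bad_rt, 1.0)))
        cov_cols = {}
        cov_cols["log_rt"] = log_rt
        for short, col in (("ac", "ac_count"), ("tr", "tr_count"),
                           ("iv", "iv_count")):
            if col in df.columns:
                cnt = pd.to_numeric(df[col], errors="coerce")
            elif short in df.columns:
                cnt = pd.to_numeric(df[short], errors="coerce")
            else:
                cnt = pd.Series(np.nan, index=df.index)
            flag = (cnt.to_numpy(dtype=float) >= 1).astype(float)
            flag[np.isnan(cnt.to_numpy(dtype=float))] = np.nan
            flag[bad_rt.to_numpy()] = np.nan
            cov_cols[short] = flag

        y = pd.to_numeric(df["y"], errors="coerce").to_numpy(dtype=float)
        valid = np.isin(y, (0.0, 1.0))
        for c in spec.covariates:
            valid &= ~np.isnan(cov_cols[c])

        df_v = df.loc[valid]
        item_pos = {iid: k for k, iid in enumerate(bank.item_ids)}
        try:
            item_index = np.array([item_pos[i] for i in df_v["item_id"]],
                                  dtype=np.int64)
        except KeyError as exc:
            raise InvalidArgumentError(
                f"item {exc.args[0]!r} not present in the item bank") from exc

        X = None
        if spec.has_engagement_regression:
            cols = [np.ones(valid.sum())]
            for j in spec.intercept_items:
                cols.append((df_v["item_id"].to_numpy() == j).astype(float))
            cvals = {c: cov_cols[c][valid] for c in spec.covariates}
            for c in spec.covariates:
                cols.append(cvals[c])
            for a, b in spec.interactions:
                cols.append(cvals[a] * cvals[b])
            X = np.column_stack(cols)

        return cls(spec, bank,
                   person_ids=df_v["person_id"].to_numpy(),
                   item_index=item_index,
                   y=y[valid].astype(np.int8),
                   X=X, n_total_encounters=n_total)

    # -- likelihood kernel ---------------------------------------------------

    def _mixture_matrices(self, theta_nodes, psi_nodes, beta_vec,
                          eta_coefs, z_free):
        """Per-encounter x per-node mixture probabilities and ingredients."""
        P = expit(theta_nodes[None, :] - beta_vec[self.item_index][:, None])
        Py = np.where(self.y[:, None] == 1, P, 1.0 - P)
        if self.spec.has_engagement_regression:
            eta0 = self.X @ eta_coefs
            PI = expit(eta0[:, None] + psi_nodes[None, :])
        else:
            PI = None
        z = np.full(self.n_valid, z_free) if z_free is not None else self.z_item
        zy = np.where(self.y == 1, z, 1.0 - z)[:, None]
        if PI is None:
            M = Py
        else:
            M = zy + PI * (Py - zy)
        M = np.clip(M, _PROB_FLOOR, 1.0 - _PROB_FLOOR)
        return P, Py, PI, zy, z, M

    def loglik(self, theta_nodes, psi_nodes, log_weights, beta_vec,
               eta_coefs=None, z_free=None, want_grad=False):
        """Marginal log-likelihood on transformed nodes; optional pieces of
        the gradient (see callers for the chain rule to actual parameters)."""
        P, Py, PI, zy, z, M = self._mixture_matrices(
            theta_nodes, psi_nodes, beta_vec, eta_coefs, z_free)
        logm = np.log(M)
        L = np.add.reduceat(logm, self.person_starts, axis=0)
        A = L + log_weights[None, :]
        ll_i = logsumexp(A, axis=1)
        ll = float(ll_i.sum())
        if not want_grad:
            return ll, None

        W = np.exp(A - ll_i[:, None])
        WE = W[self.person_codes]
        dPdt = P * (1.0 - P)
        pi_eff = PI if PI is not None else 1.0
        Dth = pi_eff * self.sign * dPdt / M          # d logm / d theta
        wth = Dth * WE
        g_beta = -np.bincount(self.item_index, weights=wth.sum(axis=1),
                              minlength=len(beta_vec))
        v_theta = wth.sum(axis=0)                    # per-node theta score
        out = {"g_beta": g_beta, "v_theta": v_theta}
        if PI is not None:
            Deta = PI * (1.0 - PI) * (Py - zy) / M   # d logm / d eta
            weta = Deta * WE
            out["g_eta"] = self.X.T @ weta.sum(axis=1)
            out["v_psi"] = weta.sum(axis=0)
            if z_free is not None:
                Dz = (1.0 - PI) * self.sign / M
                out["g_z"] = float((Dz * WE).sum())
        return ll, out

    def posterior_node_weights(self, theta_nodes, psi_nodes, log_weights,
                               beta_vec, eta_coefs=None, z_free=None):
        """Per-person posterior over quadrature nodes, plus mixture pieces."""
        _, Py, PI, zy, z, M = self._mixture_matrices(
            theta_nodes, psi_nodes, beta_vec, eta_coefs, z_free)
        logm = np.log(M)
        L = np.add.reduceat(logm, self.person_starts, axis=0)
        A = L + log_weights[None, :]
        W = np.exp(A - logsumexp(A, axis=1)[:, None])
        return W, Py, PI, zy, M


def transformed_nodes(grid: QuadratureGrid, params: ParameterSet,
                      two_level: bool):
    """Map standard-normal nodes through the latent covariance Cholesky."""
    u = grid.nodes
    sd_t = math.sqrt(params.var_theta)
    theta_nodes = sd_t * u[:, 0]
    if not two_level:
        return theta_nodes, np.zeros_like(theta_nodes)
    if grid.dim != 2:
        raise InvalidArgumentError("dlc_tl requires a 2-D quadrature grid")
    params.validate()
    c1 = params.cov_psi_theta / sd_t
    rem = params.sigma2_psi - c1 ** 2
    c2 = math.sqrt(max(rem, 0.0))
    psi_nodes = c1 * u[:, 0] + c2 * u[:, 1]
    return theta_nodes, psi_nodes


def eta_coefficients(spec: ModelSpec, params: ParameterSet) -> np.ndarray:
    """Engagement-regression coefficient vector in design-column order."""
    coefs = [params.alpha0]
    coefs += [params.alpha_item.get(j, 0.0) for j in spec.intercept_items]
    coefs += [params.gamma.get(c, 0.0) for c in spec.covariates]
    coefs += [params.gamma_int.get(p, 0.0) for p in spec.interactions]
    return np.asarray(coefs, dtype=float)


def marginal_loglik(spec: ModelSpec, params: ParameterSet, data,
                    grid: QuadratureGrid, bank: ItemBank | None = None) -> float:
    """Marginal log-likelihood, integrating (theta, psi) out by quadrature."""
    if isinstance(data, EncounterData):
        enc = data
    else:
        if bank is None:
            raise InvalidArgumentError(
                "an ItemBank is required when passing a raw table")
        enc = EncounterData.from_table(data, spec, bank)
    params.validate()
    if spec.has_random_effect and grid.dim != 2:
        raise InvalidArgumentError("dlc_tl requires a 2-D grid")
    if not spec.has_random_effect and grid.dim != 1:
        raise InvalidArgumentError("this family requires a 1-D grid")
    theta_nodes, psi_nodes = transformed_nodes(grid, params,
                                               spec.has_random_effect)
    beta_vec = np.asarray([params.beta[i] for i in enc.bank.item_ids])
    eta = enc.center_coefs(eta_coefficients(spec, params)) \
        if spec.has_engagement_regression else None
    z_free = params.z_free if spec.z_mode == "equal_free" else None
    ll, _ = enc.loglik(theta_nodes, psi_nodes, grid.log_weights, beta_vec,
                       eta_coefs=eta, z_free=z_free)
    return ll
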