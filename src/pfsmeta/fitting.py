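"""Marginal-likelihood estimation of the hierarchical survival-fraction model.

The data are observed Kaplan-Meier fractions Obs_{j,i} at times t_j in
study i.  The model is

    Obs = Pred * (1 + SE * eps1) + SE * eps2,
    Pred = S(t; P_i),   P_i = P_pop * exp(eta_i),   eta_i ~ N(0, omega^2),

with SE the binomial standard error sqrt(p(1-p)/N) of the fraction, eps1
(proportional) and eps2 (additive) zero-mean Gaussians, and study-level
random effects eta on the family's positive parameters (mu and sigma for
the log-normal family, lambda0 otherwise; diagonal Omega).

Estimation maximizes the Laplace-approximated marginal likelihood: each
study's eta is profiled at the mode of its penalized Gaussian log-density
(residual variance Var_j = Pred_j^2 SE_j^2 eps_prop^2 + SE_j^2 eps_add^2,
so the approximation retains the eta-dependence of the residual variance),
and -2 log L is minimized over the fixed effects, omegas and residual SDs
on a transformed (log / log1p) scale.  The objective function value (OFV)
is -2 log L; standard errors come from the central-difference Hessian of
the OFV at the optimum.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtr

from .covariates import CovariateEffect
from .dataset import Arm, Corpus

__all__ = [
    "ModelSpec",
    "RandomEffectsSpec",
    "ResidualSpec",
    "FitResult",
    "EstimationError",
    "residual_se",
    "arm_prediction",
    "marginal_ofv",
    "fit",
    "empirical_bayes",
]

_LOG_2PI = math.log(2.0 * math.pi)

FAMILY_PARAMS = {
    "exponential": ("lambda0",),
    "gompertz": ("lambda0", "beta"),
    "weibull_form": ("lambda0", "beta"),
    "lognormal": ("mu", "sigma"),
}
# parameters carrying a study-level random effect, per family
FAMILY_RE_TARGETS = {
    "exponential": ("lambda0",),
    "gompertz": ("lambda0",),
    "weibull_form": ("lambda0",),
    "lognormal": ("mu", "sigma"),
}


class EstimationError(RuntimeError):
    """The likelihood is not computable (e.g. zero residual variance)."""


def _json_scalar(obj):
    """Coerce numpy scalars/arrays for json.dumps."""
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def residual_se(obs_fraction: float, n: int) -> float:
    """Binomial standard error sqrt(p(1-p)/n) of an observed fraction."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= obs_fraction <= 1.0:
        raise ValueError(f"obs_fraction must be in [0,1], got {obs_fraction}")
    return math.sqrt(obs_fraction * (1.0 - obs_fraction) / n)


@dataclass
class ModelSpec:
    """A fit specification: hazard family plus covariate structure.

    ``se_weighting`` chooses the binomial SE entering the residual
    variance: ``"model"`` (default) evaluates sqrt(p(1-p)/n) at the current
    model prediction, matching the generating process and avoiding the
    noise-weight correlation that biases variance components when the
    observed fraction is plugged in; ``"observed"`` uses the data-side SE
    of each digitized fraction.
    """

    family: str = "lognormal"
    covariate_effects: list[CovariateEffect] = field(default_factory=list)
    se_weighting: str = "model"

    def __post_init__(self) -> None:
        if self.family not in FAMILY_PARAMS:
            raise ValueError(f"unknown family {self.family!r}")
        if self.se_weighting not in ("model", "observed"):
            raise ValueError(f"unknown se_weighting {self.se_weighting!r}")
        for eff in self.covariate_effects:
            if eff.target_parameter not in FAMILY_PARAMS[self.family]:
                raise ValueError(
                    f"covariate targets {eff.target_parameter!r}, not a "
                    f"{self.family} parameter"
                )

    @property
    def re_targets(self) -> tuple[str, ...]:
        return FAMILY_RE_TARGETS[self.family]


@dataclass
class RandomEffectsSpec:
    """Diagonal inter-study variability (standard deviations of eta)."""

    omega_mu: float = 0.0
    omega_sigma: float = 0.0
    correlation: float = 0.0  # fixed at 0; kept for report completeness

    def sds(self, model: ModelSpec) -> np.ndarray:
        vals = (self.omega_mu, self.omega_sigma)
        return np.array(vals[: len(model.re_targets)])


@dataclass
class ResidualSpec:
    """Standard deviations of the proportional and additive residuals."""

    eps_prop: float
    eps_add: float

    def __post_init__(self) -> None:
        if self.eps_prop < 0 or self.eps_add < 0:
            raise ValueError("residual SDs must be >= 0")


@dataclass
class FitResult:
    family: str
    theta: dict[str, float]
    random_effects: RandomEffectsSpec
    residual: ResidualSpec
    ofv: float
    se_pct: dict[str, float]
    ebe: dict[str, dict[str, float]]
    converged: bool
    model: ModelSpec = None
    ebe_var: dict[str, np.ndarray] = field(default_factory=dict)
    n_studies: int = 0
    n_obs: int = 0
    message: str = ""

    def params(self) -> dict[str, float]:
        """Flat parameter dict accepted by :func:`marginal_ofv`."""
        out = dict(self.theta)
        out["omega_mu"] = self.random_effects.omega_mu
        out["omega_sigma"] = self.random_effects.omega_sigma
        out["eps_prop"] = self.residual.eps_prop
        out["eps_add"] = self.residual.eps_add
        return out

    def to_json(self, path=None) -> str:
        doc = {
            "family": self.family,
            "theta": self.theta,
            "omega": {"mu": self.random_effects.omega_mu,
                      "sigma": self.random_effects.omega_sigma},
            "residual": {"eps_prop": self.residual.eps_prop,
                         "eps_add": self.residual.eps_add},
            "ofv": self.ofv,
            "se_pct": self.se_pct,
            "ebe": self.ebe,
            "ebe_var": {k: np.asarray(v).tolist() for k, v in self.ebe_var.items()},
            "converged": self.converged,
            "n_studies": self.n_studies,
            "n_obs": self.n_obs,
            "model": {
                "family": self.model.family,
                "se_weighting": self.model.se_weighting,
                "covariate_effects": [
                    {
                        "covariate": e.covariate,
                        "kind": e.kind,
                        "target_parameter": e.target_parameter,
                        "theta_cov": e.theta_cov,
                        "reference_level": e.reference_level,
                        "level": e.level,
                    }
                    for e in self.model.covariate_effects
                ],
            } if self.model is not None else None,
        }
        text = json.dumps(doc, indent=2, default=_json_scalar)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FitResult":
        """Rebuild a FitResult from :meth:`to_json` output (path or str)."""
        if isinstance(source, dict):
            doc = source
        else:
            text = source
            try:
                import os

                if os.path.exists(str(source)):
                    with open(source) as fh:
                        text = fh.read()
            except (OSError, ValueError):
                pass
            doc = json.loads(text)
        model = None
        if doc.get("model"):
            m = doc["model"]
            model = ModelSpec(
                family=m["family"],
                se_weighting=m.get("se_weighting", "model"),
                covariate_effects=[CovariateEffect(**e) for e in m["covariate_effects"]],
            )
        return cls(
            family=doc["family"],
            theta=doc["theta"],
            random_effects=RandomEffectsSpec(
                omega_mu=doc["omega"]["mu"], omega_sigma=doc["omega"]["sigma"]
            ),
            residual=ResidualSpec(**doc["residual"]),
            ofv=doc["ofv"],
            se_pct=doc["se_pct"],
            ebe=doc["ebe"],
            converged=doc["converged"],
            model=model,
            ebe_var={k: np.asarray(v) for k, v in doc.get("ebe_var", {}).items()},
            n_studies=doc.get("n_studies", 0),
            n_obs=doc.get("n_obs", 0),
        )

    def report(self) -> str:
        """Parameter table in the usual estimate (SE%) layout."""
        lines = [f"{'parameter':<28}{'estimate':>12}{'SE%':>10}",
                 "-" * 50]
        items = list(self.theta.items()) + [
            ("omega_mu", self.random_effects.omega_mu),
            ("omega_sigma", self.random_effects.omega_sigma),
            ("eps_prop", self.residual.eps_prop),
            ("eps_add", self.residual.eps_add),
        ]
        for name, value in items:
            se = self.se_pct.get(name)
            se_s = f"{se:>9.1f}" if se is not None and np.isfinite(se) else "      -- "
            lines.append(f"{name:<28}{value:>12.4g}{se_s}")
        lines.append(f"OFV: {self.ofv:.3f}   converged: {self.converged}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# corpus compilation


class _CompiledStudy:
    """Per-study numpy views used by the likelihood inner loop."""

    __slots__ = ("study_id", "t", "logt", "obs", "se_w", "n_arr", "X",
                 "arm_rows", "m", "at_lo", "at_hi", "interior", "any_boundary")

    def __init__(self, study_id, t, obs, se_w, n_arr, X, arm_rows):
        self.study_id = study_id
        self.t = t
        self.logt = np.log(t)
        self.obs = obs
        self.se_w = se_w
        self.n_arr = n_arr  # per-observation arm sample size
        self.X = X  # (m, k) regressors per covariate effect
        self.arm_rows = arm_rows  # list of (arm, slice)
        self.m = len(t)
        # fractions clipped to the boundaries are censored, not exact
        self.at_lo = obs <= 0.0
        self.at_hi = obs >= 1.0
        self.interior = ~(self.at_lo | self.at_hi)
        self.any_boundary = bool(self.at_lo.any() or self.at_hi.any())


def _weighting_se(obs: np.ndarray, n: int) -> np.ndarray:
    """Residual-weighting SE with a half-count floor at the boundaries.

    A digitized fraction that clips to exactly 0 or 1 has binomial SE 0,
    which would zero the residual variance; the weighting SE therefore
    evaluates sqrt(p(1-p)/n) at p clamped to [0.5/n, 1 - 0.5/n].  Interior
    fractions are unaffected.
    """
    p = np.clip(obs, 0.5 / n, 1.0 - 0.5 / n)
    return np.sqrt(p * (1.0 - p) / n)


def _compile(corpus: Corpus, model: ModelSpec) -> list[_CompiledStudy]:
    corpus.validate()
    compiled = []
    for study_id, arms in corpus.studies.items():
        ts, obss, ses, ns, rows = [], [], [], [], []
        Xs = []
        start = 0
        for arm in arms:
            t = arm.times
            obs = arm.fractions
            ts.append(t)
            obss.append(obs)
            ses.append(_weighting_se(obs, arm.n))
            ns.append(np.full(len(t), float(arm.n)))
            x_arm = np.array(
                [eff.design_value(arm.covariates) for eff in model.covariate_effects]
            )
            Xs.append(np.tile(x_arm, (len(t), 1)))
            rows.append((arm, slice(start, start + len(t))))
            start += len(t)
        k = len(model.covariate_effects)
        X = np.vstack(Xs) if k else np.zeros((start, 0))
        compiled.append(
            _CompiledStudy(study_id, np.concatenate(ts), np.concatenate(obss),
                           np.concatenate(ses), np.concatenate(ns), X, rows)
        )
    return compiled


# ---------------------------------------------------------------------------
# predictions


def _cov_log_adjust(study: _CompiledStudy, model: ModelSpec, params: dict) -> dict[str, np.ndarray]:
    """Per-observation log-scale covariate adjustment for each target param."""
    adj: dict[str, np.ndarray] = {}
    for j, eff in enumerate(model.covariate_effects):
        theta = params[eff.key]
        g = math.log1p(theta) if eff.kind == "categorical" else theta
        contrib = g * study.X[:, j]
        if eff.target_parameter in adj:
            adj[eff.target_parameter] = adj[eff.target_parameter] + contrib
        else:
            adj[eff.target_parameter] = contrib
    return adj


def _study_pred(study: _CompiledStudy, model: ModelSpec, params: dict,
                eta: np.ndarray, adj: dict[str, np.ndarray]) -> np.ndarray:
    """Model-predicted survival fractions for one study given its eta.

    ``eta`` may be a single vector (n_re,) giving an (m,) prediction, or a
    batch (k, n_re) giving (k, m); the batch form lets the inner Newton
    evaluate its whole finite-difference stencil in one numpy sweep.
    """
    fam = model.family
    re_targets = model.re_targets
    eta = np.asarray(eta, dtype=float)
    single = eta.ndim == 1
    eta2 = eta.reshape(1, -1) if single else eta

    def individual(name: str):
        base = math.log(params[name])
        log_pop = base + adj[name] if name in adj else base  # scalar or (m,)
        if name in re_targets:
            col = eta2[:, re_targets.index(name)][:, None]  # (k, 1)
            return np.exp(log_pop + col)  # (k, m) by broadcast
        return np.exp(log_pop) * np.ones((eta2.shape[0], 1))

    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        if fam == "lognormal":
            mu = individual("mu")
            sigma = individual("sigma")
            z = (study.logt - mu) / sigma
            out = ndtr(-z)
        elif fam == "exponential":
            out = np.exp(-individual("lambda0") * study.t)
        elif fam == "gompertz":
            lam = individual("lambda0")
            beta = params["beta"]
            if abs(beta) < 1e-8:
                bt = beta * study.t
                H = lam * study.t * (1.0 + bt / 2.0 + bt * bt / 6.0)
            else:
                H = lam * (np.exp(beta * study.t) - 1.0) / beta
            out = np.exp(-H)
        else:  # weibull_form
            lam = individual("lambda0")
            k = params["beta"] + 1.0
            out = np.exp(-lam * np.power(study.t, k) / k)
    return out[0] if single else out


def arm_prediction(theta: dict, eta: dict, profile, times,
                   model: ModelSpec | None = None) -> np.ndarray:
    """Predicted survival fractions for one arm.

    ``theta`` holds population fixed effects (family parameters plus any
    covariate thetas named as in :attr:`CovariateEffect.key`); ``eta`` maps
    random-effect target parameters to that study's eta values.  The
    individual parameter is P_pop * exp(eta), with P_pop from the covariate
    model applied to ``profile``.
    """
    from .hazards import HazardParams, survival

    model = model or ModelSpec()
    times = np.asarray(times, dtype=float)
    if np.any(times <= 0):
        raise ValueError("prediction times must be > 0")
    values = {}
    for name in FAMILY_PARAMS[model.family]:
        p = theta[name]
        effs = [e for e in model.covariate_effects if e.target_parameter == name]
        if effs:
            effs = [replace(e, theta_cov=theta[e.key]) for e in effs]
            from .covariates import apply_covariate

            p = apply_covariate(p, profile, effs)
        p *= math.exp(eta.get(name, 0.0))
        values[name] = p
    hp = HazardParams(family=model.family, **values)
    return np.asarray(survival(hp, times))


# ---------------------------------------------------------------------------
# Laplace marginal likelihood


def _neg_log_joint(study: _CompiledStudy, model: ModelSpec, params: dict,
                   adj: dict, omega: np.ndarray, active: np.ndarray,
                   eps_prop2: float, eps_add2: float):
    """Return g(eta) = -log [p(y|eta) p(eta)] restricted to active dims.

    Interior fractions contribute Gaussian densities; fractions clipped to
    0 or 1 are censored and contribute tail probabilities Phi((bound -
    pred)/sd) instead (the latent noisy fraction fell beyond the bound).
    The returned callable accepts a single eta vector (d,) -> float or a
    batch (k, d) -> (k,); rows with an invalid likelihood evaluate to +inf.
    """
    from scipy.special import log_ndtr

    n_re = len(model.re_targets)
    model_se = model.se_weighting == "model"
    n = study.n_arr
    active_idx = np.nonzero(active)[0]
    w2 = omega[active] ** 2
    prior_const = 0.5 * float(np.sum(np.log(w2) + _LOG_2PI)) if active_idx.size else 0.0

    def g(eta_active: np.ndarray):
        eta_active = np.asarray(eta_active, dtype=float)
        single = eta_active.ndim == 1
        ea = eta_active.reshape(1, -1) if single else eta_active
        k = ea.shape[0]
        eta = np.zeros((k, n_re))
        if active_idx.size:
            eta[:, active_idx] = ea
        with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
            pred = _study_pred(study, model, params, eta, adj)  # (k, m)
            if model_se:
                pc = np.clip(pred, 0.5 / n, 1.0 - 0.5 / n)
                se2 = pc * (1.0 - pc) / n
            else:
                se2 = study.se_w ** 2
            var = se2 * (pred ** 2 * eps_prop2 + eps_add2)
            bad = ~np.all(np.isfinite(var) & (var > 0), axis=1)
            var = np.where(var > 0, var, 1.0)  # placeholder on bad rows
            r = study.obs - pred
            if study.any_boundary:
                i = study.interior
                val = 0.5 * np.sum(r[:, i] ** 2 / var[:, i]
                                   + np.log(var[:, i]) + _LOG_2PI, axis=1)
                sd = np.sqrt(var)
                hi, lo = study.at_hi, study.at_lo
                if hi.any():
                    val -= np.sum(log_ndtr((pred[:, hi] - 1.0) / sd[:, hi]), axis=1)
                if lo.any():
                    val -= np.sum(log_ndtr(-pred[:, lo] / sd[:, lo]), axis=1)
            else:
                val = 0.5 * np.sum(r * r / var + np.log(var) + _LOG_2PI, axis=1)
            if ea.shape[1]:
                val = val + 0.5 * np.sum(ea ** 2 / w2, axis=1) + prior_const
            val = np.where(bad | ~np.isfinite(val), np.inf, val)
        if single:
            if not np.isfinite(val[0]):
                raise EstimationError(
                    "non-finite likelihood (zero or invalid residual variance)"
                )
            return float(val[0])
        return val

    return g


_LINE_ALPHAS = 0.5 ** np.arange(10)


def _stencil(g, x: np.ndarray, h: float):
    """One batched finite-difference stencil: value, gradient, Hessian."""
    d = x.size
    if d == 1:
        pts = np.array([x, x + h, x - h])
    else:  # d == 2
        e1 = np.array([h, 0.0])
        e2 = np.array([0.0, h])
        pts = np.array([x, x + e1, x - e1, x + e2, x - e2,
                        x + e1 + e2, x + e1 - e2, x - e1 + e2, x - e1 - e2])
    v = g(pts)
    f0 = v[0]
    grad = np.empty(d)
    hess = np.empty((d, d))
    grad[0] = (v[1] - v[2]) / (2 * h)
    hess[0, 0] = (v[1] - 2 * f0 + v[2]) / (h * h)
    if d == 2:
        grad[1] = (v[3] - v[4]) / (2 * h)
        hess[1, 1] = (v[3] - 2 * f0 + v[4]) / (h * h)
        hess[0, 1] = hess[1, 0] = (v[5] - v[6] - v[7] + v[8]) / (4 * h * h)
    return float(f0), grad, hess


def _newton_mode(g, x0: np.ndarray, tol: float = 1e-9, max_iter: int = 60):
    """Minimize g (dim <= 2) by damped Newton with batched finite differences.

    Returns (x_hat, g(x_hat), Hessian at x_hat).
    """
    x = x0.astype(float).copy()
    d = x.size
    h = 1e-4
    f0, grad, hess = _stencil(g, x, h)
    if not np.isfinite(f0):
        raise EstimationError("non-finite likelihood at the eta start point")
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            break
        # Levenberg damping to guarantee a descent direction
        ridge = 0.0
        for _try in range(40):
            H = hess + ridge * np.eye(d)
            try:
                np.linalg.cholesky(H)
                step = np.linalg.solve(H, grad)
                break
            except np.linalg.LinAlgError:
                ridge = max(2.0 * ridge, 1e-6)
        else:  # pragma: no cover
            step = grad
        # batched backtracking line search
        cand = x[None, :] - _LINE_ALPHAS[:, None] * step[None, :]
        vals = g(cand)
        better = np.nonzero(np.isfinite(vals) & (vals < f0))[0]
        if better.size == 0:
            break
        i = int(better[0])
        x_new, f_new = cand[i], float(vals[i])
        small = (abs(f0 - f_new) < tol * (1.0 + abs(f0))
                 and np.max(np.abs(x_new - x)) < 1e-7)
        x = x_new
        f0, grad, hess = _stencil(g, x, h)
        if small:
            break
    return x, f0, hess


def _ofv_compiled(compiled: list[_CompiledStudy], model: ModelSpec, params: dict,
                  warm: dict | None = None) -> float:
    """-2 log Laplace marginal likelihood over all studies."""
    # first RE target maps to omega_mu, second (lognormal sigma) to omega_sigma
    omega = np.array([
        params.get("omega_mu", 0.0) if i == 0 else params.get("omega_sigma", 0.0)
        for i in range(len(model.re_targets))
    ])
    if np.any(omega < 0):
        raise EstimationError("omega must be >= 0")
    eps_prop2 = params.get("eps_prop", 0.0) ** 2
    eps_add2 = params.get("eps_add", 0.0) ** 2
    active = omega > 0
    d = int(active.sum())
    total = 0.0
    for study in compiled:
        adj = _cov_log_adjust(study, model, params)
        g = _neg_log_joint(study, model, params, adj, omega, active,
                           eps_prop2, eps_add2)
        if d == 0:
            total += 2.0 * g(np.zeros(0))
            continue
        x0 = np.zeros(d)
        if warm is not None and study.study_id in warm:
            x0 = warm[study.study_id].copy()
        x_hat, g_hat, hess = _newton_mode(g, x0)
        sign, logdet = np.linalg.slogdet(hess)
        if sign <= 0:
            # fall back to a ridged determinant; the mode search already
            # damped its steps, so this only fires in pathological corners
            logdet = float(np.linalg.slogdet(hess + 1e-8 * np.eye(d))[1])
        total += 2.0 * g_hat - d * _LOG_2PI + logdet
        if warm is not None:
            warm[study.study_id] = x_hat
    return total


def marginal_ofv(corpus: Corpus, model: ModelSpec, params: dict) -> float:
    """-2 log of the Laplace-approximated marginal likelihood.

    ``params`` is a flat dict: family parameters (``mu``, ``sigma`` or
    ``lambda0``, ``beta``), one entry per covariate theta (keyed as
    ``theta_<covariate>[_<level>]``), ``omega_mu``, ``omega_sigma``,
    ``eps_prop`` and ``eps_add``.  With both omegas zero this reduces to
    the closed-form weighted Gaussian -2 log likelihood at eta = 0.
    """
    compiled = _compile(corpus, model)
    return _ofv_compiled(compiled, model, params)


# ---------------------------------------------------------------------------
# outer optimization


@dataclass
class _Par:
    name: str
    transform: str  # "log" | "identity" | "log1p"
    init: float
    lo: float
    hi: float

    def to_z(self, value: float) -> float:
        if self.transform == "log":
            return math.log(value)
        if self.transform == "log1p":
            return math.log1p(value)
        return value

    def to_nat(self, z: float) -> float:
        if self.transform == "log":
            return math.exp(z)
        if self.transform == "log1p":
            return math.expm1(z)
        return z


def _default_inits(corpus: Corpus, model: ModelSpec) -> dict[str, float]:
    """Crude moment-style starting values from the observed fractions."""
    # median survival per arm by linear interpolation across 0.5
    t50s = []
    for arm in corpus.arms:
        t, f = arm.times, arm.fractions
        below = np.nonzero(f <= 0.5)[0]
        if below.size and below[0] > 0:
            i = below[0]
            t0, t1, f0, f1 = t[i - 1], t[i], f[i - 1], f[i]
            t50s.append(t0 + (f0 - 0.5) * (t1 - t0) / max(f0 - f1, 1e-9))
        elif below.size:
            t50s.append(t[0])
        else:
            t50s.append(t[-1] * 1.5)  # curve never crossed 0.5
    t50 = float(np.median(t50s))
    fam = model.family
    if fam == "lognormal":
        init = {"mu": math.log(t50), "sigma": 1.0}
    elif fam == "exponential":
        init = {"lambda0": math.log(2.0) / t50}
    elif fam == "gompertz":
        init = {"lambda0": math.log(2.0) / t50, "beta": 0.01}
    else:
        init = {"lambda0": math.log(2.0) / t50, "beta": 0.2}
    for eff in model.covariate_effects:
        init[eff.key] = eff.theta_cov
    init.update({"omega_mu": 0.1, "eps_prop": 0.3, "eps_add": 1.0})
    init["omega_sigma"] = 0.1 if len(model.re_targets) > 1 else 0.0
    return init


def _build_pars(model: ModelSpec, init: dict[str, float]) -> list[_Par]:
    pars: list[_Par] = []
    fam = model.family
    for name in FAMILY_PARAMS[fam]:
        if name == "beta" and fam == "gompertz":
            pars.append(_Par(name, "identity", init[name], -1.0, 1.0))
        elif name == "beta":  # weibull_form: beta > -1
            pars.append(_Par(name, "log1p", init[name], -4.0, 3.0))
        else:
            pars.append(_Par(name, "log", init[name], -12.0, 6.0))
    for eff in model.covariate_effects:
        if eff.kind == "categorical":
            pars.append(_Par(eff.key, "log1p", init.get(eff.key, 0.0), -3.0, 3.0))
        else:
            pars.append(_Par(eff.key, "identity", init.get(eff.key, 0.0), -5.0, 5.0))
    pars.append(_Par("omega_mu", "log", max(init.get("omega_mu", 0.1), 1e-4), -9.0, 2.0))
    if len(model.re_targets) > 1:
        pars.append(_Par("omega_sigma", "log", max(init.get("omega_sigma", 0.1), 1e-4), -9.0, 2.0))
    pars.append(_Par("eps_prop", "log", max(init.get("eps_prop", 0.3), 1e-4), -9.0, 4.0))
    pars.append(_Par("eps_add", "log", max(init.get("eps_add", 1.0), 1e-4), -9.0, 4.0))
    return pars


def _params_from_z(pars: list[_Par], z: np.ndarray) -> dict[str, float]:
    out = {p.name: p.to_nat(zi) for p, zi in zip(pars, z)}
    out.setdefault("omega_sigma", 0.0)
    return out


def fit(corpus: Corpus, model: ModelSpec | None = None,
        init: dict[str, float] | None = None, seed: int = 0,
        n_starts: int = 3, compute_se: bool = True) -> FitResult:
    """Fit the mixed-effects model by minimizing the Laplace OFV.

    Starting values default to moment-style heuristics from the observed
    fractions; up to ``n_starts`` seeded jittered restarts are attempted
    if the first optimization does not converge.  Standard errors are
    delta-method transforms of the inverse central-difference Hessian of
    the OFV, reported as percent of the estimate.
    """
    model = model or ModelSpec()
    if len(corpus.studies) < 2:
        raise ValueError("random-effect estimation requires at least 2 studies")
    compiled = _compile(corpus, model)
    inits = _default_inits(corpus, model)
    if init:
        inits.update(init)
    pars = _build_pars(model, inits)
    z0 = np.array([p.to_z(p.init) for p in pars])
    bounds = [(p.lo, p.hi) for p in pars]
    z0 = np.clip(z0, [b[0] for b in bounds], [b[1] for b in bounds])

    warm: dict[str, np.ndarray] = {}

    def objective(z: np.ndarray) -> float:
        try:
            return _ofv_compiled(compiled, model, _params_from_z(pars, z), warm)
        except (EstimationError, FloatingPointError, OverflowError):
            return 1e12

    rng = np.random.default_rng(seed)
    best = None
    message = ""
    for attempt in range(n_starts):
        z_start = z0 if attempt == 0 else np.clip(
            z0 + 0.15 * rng.standard_normal(len(z0)),
            [b[0] for b in bounds], [b[1] for b in bounds])
        warm.clear()
        # the FD step must sit well above the inner-Laplace noise floor or
        # flat directions (weak variance components) stall at their starts
        res = minimize(objective, z_start, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 1000, "ftol": 1e-13, "gtol": 1e-8,
                                "eps": 1e-5})
        if best is None or res.fun < best.fun:
            best = res
        message = str(res.message)
        if res.success and res.fun < 1e11:
            best = res
            break
    converged = bool(best.success and best.fun < 1e11)
    z_hat = best.x
    params = _params_from_z(pars, z_hat)

    # standard errors: central-difference Hessian of the OFV, cov = 2 H^-1
    se_pct: dict[str, float] = {}
    if converged and compute_se:
        npar = len(pars)
        H = np.zeros((npar, npar))
        hstep = 1e-3
        f0 = objective(z_hat)
        fp = np.empty(npar); fm = np.empty(npar)
        for i in range(npar):
            e = np.zeros(npar); e[i] = hstep
            fp[i] = objective(z_hat + e)
            fm[i] = objective(z_hat - e)
            H[i, i] = (fp[i] - 2 * f0 + fm[i]) / hstep ** 2
        for i in range(npar):
            for j in range(i + 1, npar):
                ei = np.zeros(npar); ei[i] = hstep
                ej = np.zeros(npar); ej[j] = hstep
                H[i, j] = H[j, i] = (
                    objective(z_hat + ei + ej) - objective(z_hat + ei - ej)
                    - objective(z_hat - ei + ej) + objective(z_hat - ei - ej)
                ) / (4 * hstep ** 2)
        try:
            cov_z = 2.0 * np.linalg.inv(H)
            var_z = np.diag(cov_z)
            for p, zi, vz in zip(pars, z_hat, var_z):
                if vz <= 0 or not np.isfinite(vz):
                    se_pct[p.name] = float("nan")
                    continue
                sd_z = math.sqrt(vz)
                est = p.to_nat(zi)
                if p.transform == "log":
                    sd_nat = abs(est) * sd_z
                elif p.transform == "log1p":
                    sd_nat = abs(1.0 + est) * sd_z
                else:
                    sd_nat = sd_z
                se_pct[p.name] = 100.0 * sd_nat / abs(est) if est != 0 else float("inf")
        except np.linalg.LinAlgError:
            se_pct = {p.name: float("nan") for p in pars}

    # empirical Bayes modes and conditional variances at the optimum
    ebe, ebe_var = _ebe_compiled(compiled, model, params)

    theta = {name: params[name] for name in FAMILY_PARAMS[model.family]}
    for eff in model.covariate_effects:
        theta[eff.key] = params[eff.key]
    result = FitResult(
        family=model.family,
        theta=theta,
        random_effects=RandomEffectsSpec(
            omega_mu=params.get("omega_mu", 0.0),
            omega_sigma=params.get("omega_sigma", 0.0),
        ),
        residual=ResidualSpec(eps_prop=params["eps_prop"], eps_add=params["eps_add"]),
        ofv=float(best.fun),
        se_pct=se_pct,
        ebe=ebe,
        converged=converged,
        model=model,
        ebe_var=ebe_var,
        n_studies=len(compiled),
        n_obs=sum(s.m for s in compiled),
        message=message,
    )
    return result


def _ebe_compiled(compiled, model, params):
    omega = np.array([
        params.get("omega_mu", 0.0) if i == 0 else params.get("omega_sigma", 0.0)
        for i in range(len(model.re_targets))
    ])
    eps_prop2 = params.get("eps_prop", 0.0) ** 2
    eps_add2 = params.get("eps_add", 0.0) ** 2
    active = omega > 0
    d = int(active.sum())
    ebe: dict[str, dict[str, float]] = {}
    ebe_var: dict[str, np.ndarray] = {}
    for study in compiled:
        eta_full = np.zeros(len(model.re_targets))
        var_full = np.zeros((len(model.re_targets), len(model.re_targets)))
        if d:
            adj = _cov_log_adjust(study, model, params)
            g = _neg_log_joint(study, model, params, adj, omega, active,
                               eps_prop2, eps_add2)
            x_hat, _, hess = _newton_mode(g, np.zeros(d))
            eta_full[active] = x_hat
            try:
                cond = np.linalg.inv(hess)
            except np.linalg.LinAlgError:  # pragma: no cover
                cond = np.full((d, d), np.nan)
            ix = np.nonzero(active)[0]
            for a, ia in enumerate(ix):
                for b, ib in enumerate(ix):
                    var_full[ia, ib] = cond[a, b]
        ebe[study.study_id] = {
            name: float(eta_full[i]) for i, name in enumerate(model.re_targets)
        }
        ebe_var[study.study_id] = var_full
    return ebe, ebe_var


def empirical_bayes(fit_result: FitResult, corpus: Corpus) -> dict[str, dict[str, float]]:
    """Per-study eta modes under a converged fit's parameters."""
    if not fit_result.converged:
        raise ValueError("empirical Bayes estimates require a converged fit")
    compiled = _compile(corpus, fit_result.model)
    ebe, _ = _ebe_compiled(compiled, fit_result.model, fit_result.params())
    return ebe
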