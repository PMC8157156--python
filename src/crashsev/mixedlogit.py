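"""Multinomial and random-parameters (mixed) logit for 3-level crash severity.

The severity of crash *i* is modelled through level propensities
``V_ik = X_ik @ beta_k + eps_ik`` with iid Gumbel errors, giving multinomial
logit choice probabilities.  Unobserved heterogeneity enters by letting a
coefficient vary across crashes::

    beta = beta_bar + delta @ Z_i + sigma * exp(omega @ W_i) * v_ir

with ``v ~ N(0, 1)``: ``delta`` shifts the coefficient *mean* with observed
covariates Z, and ``omega`` scales its *standard deviation* with covariates
W.  The resulting probability is an integral over the mixing density,
approximated by averaging the logit probability over quasi-random
(Halton) standard-normal draws; estimation maximizes this simulated
log-likelihood.  The score of the simulated log-likelihood is computed
analytically, which keeps fitting fast and the Hessian-based standard
errors accurate.

The base severity level (default PDO) has all parameters fixed at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import ndtr

from .halton import HaltonConfig, halton_draws
from .severity import SEVERITY_LEVELS, validate_severity_labels

CONST = "const"

#: Floor applied to a simulated probability before taking logs.
PROBABILITY_FLOOR = 1e-300


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class SpecEntry:
    """One term of the propensity of one (non-base) severity level.

    ``term`` is a covariate column name, or :data:`CONST` for the level
    constant.  A ``random`` entry mixes normally across crashes; its
    ``mean_shifters`` (Z) and ``variance_shifters`` (W) name the covariates
    that move the mixing mean and log standard deviation.
    """

    level: str
    term: str
    role: str = "fixed"
    mean_shifters: tuple[str, ...] = ()
    variance_shifters: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ("fixed", "random"):
            raise ValueError(f"role must be 'fixed' or 'random', got {self.role!r}")
        if self.role == "fixed" and (self.mean_shifters or self.variance_shifters):
            raise ValueError("shifters are only meaningful on random entries")
        object.__setattr__(self, "mean_shifters", tuple(self.mean_shifters))
        object.__setattr__(self, "variance_shifters", tuple(self.variance_shifters))


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter which severity level, and which of them are random."""

    entries: tuple[SpecEntry, ...]
    levels: tuple[str, ...] = SEVERITY_LEVELS
    base: str = "PDO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", tuple(self.entries))
        validate_severity_labels(self.levels)
        if self.base not in self.levels:
            raise ValueError(f"base level {self.base!r} not among {self.levels}")
        seen = set()
        for e in self.entries:
            if e.level not in self.levels:
                raise ValueError(f"entry level {e.level!r} not among {self.levels}")
            if e.level == self.base:
                raise ValueError(
                    f"base level {self.base!r} must carry no parameters"
                )
            key = (e.level, e.term)
            if key in seen:
                raise ValueError(f"duplicate entry for {key}")
            seen.add(key)

    @property
    def fixed_entries(self) -> tuple[SpecEntry, ...]:
        return tuple(e for e in self.entries if e.role == "fixed")

    @property
    def random_entries(self) -> tuple[SpecEntry, ...]:
        return tuple(e for e in self.entries if e.role == "random")

    @property
    def n_random_dims(self) -> int:
        return len(self.random_entries)

    def parameter_names(self) -> list[str]:
        """Flat parameter order used by every array interface of this module."""
        names = [f"b:{e.level}:{e.term}" for e in self.fixed_entries]
        for e in self.random_entries:
            names.append(f"mean:{e.level}:{e.term}")
            names += [f"delta:{e.level}:{e.term}|{z}" for z in e.mean_shifters]
            names.append(f"sd:{e.level}:{e.term}")
            names += [f"omega:{e.level}:{e.term}|{w}" for w in e.variance_shifters]
        return names

    @property
    def n_parameters(self) -> int:
        return len(self.parameter_names())

    def demoted(self) -> "ModelSpec":
        """The same specification with every random entry made fixed."""
        return replace(
            self,
            entries=tuple(
                replace(e, role="fixed", mean_shifters=(), variance_shifters=())
                for e in self.entries
            ),
        )

    # -- plain-dict form, for YAML configs --------------------------------
    def to_dict(self) -> dict:
        return {
            "levels": list(self.levels),
            "base": self.base,
            "entries": [
                {
                    "level": e.level,
                    "term": e.term,
                    "role": e.role,
                    **(
                        {"mean_shifters": list(e.mean_shifters)}
                        if e.mean_shifters
                        else {}
                    ),
                    **(
                        {"variance_shifters": list(e.variance_shifters)}
                        if e.variance_shifters
                        else {}
                    ),
                }
                for e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        return cls(
            entries=tuple(
                SpecEntry(
                    level=e["level"],
                    term=e["term"],
                    role=e.get("role", "fixed"),
                    mean_shifters=tuple(e.get("mean_shifters", ())),
                    variance_shifters=tuple(e.get("variance_shifters", ())),
                )
                for e in d["entries"]
            ),
            levels=tuple(d.get("levels", SEVERITY_LEVELS)),
            base=d.get("base", "PDO"),
        )

    @classmethod
    def from_truth(cls, truth) -> "ModelSpec":
        """Specification matching a synthetic ground-truth parameter set."""
        entries = [
            SpecEntry(level=lvl, term=CONST) for lvl in truth.constants
        ]
        entries += [
            SpecEntry(level=lvl, term=cov)
            for lvl, cov in truth.fixed_coefficients
        ]
        entries += [
            SpecEntry(
                level=rc.level,
                term=rc.covariate,
                role="random",
                mean_shifters=tuple(rc.mean_shifters),
                variance_shifters=tuple(rc.variance_shifters),
            )
            for rc in truth.random_coefficients
        ]
        return cls(entries=tuple(entries), base=truth.base)


# ---------------------------------------------------------------------------
# likelihood machinery


class _Workspace:
    """Design arrays extracted once from a dataset for repeated evaluation."""

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        self.spec = spec
        self.n = len(data)
        self.K = len(spec.levels)
        level_index = {lvl: k for k, lvl in enumerate(spec.levels)}
        validate_severity_labels(data["severity"])
        self.y = data["severity"].map(level_index).to_numpy(dtype=np.int64)

        def column(term: str) -> np.ndarray:
            if term == CONST:
                return np.ones(self.n)
            if term not in data.columns:
                raise ValueError(f"covariate {term!r} missing from data")
            return data[term].to_numpy(dtype=np.float64)

        self.fixed = [
            (level_index[e.level], column(e.term)) for e in spec.fixed_entries
        ]
        self.random = []
        for e in spec.random_entries:
            self.random.append(
                {
                    "k": level_index[e.level],
                    "x": column(e.term),
                    "Z": np.column_stack(
                        [column(z) for z in e.mean_shifters]
                    )
                    if e.mean_shifters
                    else np.zeros((self.n, 0)),
                    "W": np.column_stack(
                        [column(w) for w in e.variance_shifters]
                    )
                    if e.variance_shifters
                    else np.zeros((self.n, 0)),
                }
            )

    def unpack(self, theta: np.ndarray):
        """Split the flat parameter vector by entry, mirroring parameter_names."""
        theta = np.asarray(theta, dtype=np.float64)
        if theta.shape != (self.spec.n_parameters,):
            raise ValueError(
                f"expected {self.spec.n_parameters} parameters, got {theta.shape}"
            )
        pos = len(self.fixed)
        fixed_betas = theta[:pos]
        rand_params = []
        for e in self.spec.random_entries:
            mean = theta[pos]
            pos += 1
            nz = len(e.mean_shifters)
            delta = theta[pos : pos + nz]
            pos += nz
            sd = theta[pos]
            pos += 1
            nw = len(e.variance_shifters)
            omega = theta[pos : pos + nw]
            pos += nw
            rand_params.append((mean, delta, sd, omega))
        return fixed_betas, rand_params


def _loglik_and_grad(
    theta: np.ndarray, ws: _Workspace, draws: np.ndarray | None
):
    """Simulated log-likelihood and its analytic gradient.

    ``draws`` has shape ``(n, R, J)`` with J the number of random entries;
    ``None`` is accepted for a purely fixed specification (R = 1,
    closed-form MNL likelihood).
    """
    n, K = ws.n, ws.K
    fixed_betas, rand_params = ws.unpack(theta)

    U_fixed = np.zeros((n, K))
    for (k, x), b in zip(ws.fixed, fixed_betas):
        U_fixed[:, k] += b * x

    if ws.random:
        if draws is None:
            raise ValueError("random entries present but no draws supplied")
        R = draws.shape[1]
        U = np.repeat(U_fixed[:, None, :], R, axis=1)
        scales = []  # per random entry: sigma * exp(omega @ W), shape (n,)
        for j, (entry, (mean, delta, sd, omega)) in enumerate(
            zip(ws.random, rand_params)
        ):
            mu = mean + entry["Z"] @ delta
            scale = sd * np.exp(entry["W"] @ omega)
            scales.append(scale)
            beta = mu[:, None] + scale[:, None] * draws[:, :, j]
            U[:, :, entry["k"]] += entry["x"][:, None] * beta
    else:
        R = 1
        U = U_fixed[:, None, :]
        scales = []

    if not np.all(np.isfinite(U)):
        raise FloatingPointError("non-finite propensity during evaluation")

    # stable softmax pieces, computed once and reused for the score
    Umax = U.max(axis=2)
    E = np.exp(U - Umax[:, :, None])  # (n, R, K)
    denom = E.sum(axis=2)  # (n, R)
    logdenom = Umax + np.log(denom)
    logp = (
        np.take_along_axis(U, ws.y[:, None, None], axis=2)[:, :, 0] - logdenom
    )  # (n, R)
    P = np.exp(logp)
    L = P.mean(axis=1)
    if np.any(L < PROBABILITY_FLOOR):
        warnings.warn(
            "simulated probability underflow; flooring at "
            f"{PROBABILITY_FLOOR:g}",
            RuntimeWarning,
            stacklevel=3,
        )
        L = np.maximum(L, PROBABILITY_FLOOR)
    ll = float(np.sum(np.log(L)))

    # score: sum_i sum_r w_ir * dlogP_ir, with w_ir = P_ir / (R * L_i)
    w = P / (R * L[:, None])  # (n, R)
    s = E / denom[:, :, None]  # softmax, (n, R, K)
    resid = -s
    np.add.at(resid, (np.arange(n), slice(None), ws.y), 1.0)
    # resid[i, r, y_i] += 1  — one-hot of the observed level minus softmax
    Wres = np.einsum("nr,nrk->nk", w, resid)  # (n, K)

    grad = np.empty_like(theta, dtype=np.float64)
    pos = 0
    for (k, x), _ in zip(ws.fixed, fixed_betas):
        grad[pos] = x @ Wres[:, k]
        pos += 1
    for j, (entry, (mean, delta, sd, omega)) in enumerate(
        zip(ws.random, rand_params)
    ):
        k, x = entry["k"], entry["x"]
        grad[pos] = x @ Wres[:, k]  # beta_bar
        pos += 1
        for z_col in entry["Z"].T:  # delta
            grad[pos] = (x * z_col) @ Wres[:, k]
            pos += 1
        # E_i = sum_r w_ir v_irj resid_ir,k
        E = np.einsum("nr,nr->n", w * resid[:, :, k], draws[:, :, j])
        grad[pos] = (x * scales[j] / sd if sd != 0 else x * np.exp(entry["W"] @ omega)) @ E  # sigma
        pos += 1
        for w_col in entry["W"].T:  # omega
            grad[pos] = (x * w_col * scales[j]) @ E
            pos += 1
    return ll, grad


def _draws_for(spec: ModelSpec, halton: HaltonConfig | None, n_obs: int):
    if spec.n_random_dims == 0:
        return None
    if halton is None:
        raise ValueError("a HaltonConfig is required for random entries")
    return halton_draws(halton, n_obs, spec.n_random_dims)


def simulated_loglik(
    spec: ModelSpec,
    params: Mapping[str, float] | Sequence[float] | np.ndarray,
    data: pd.DataFrame,
    draws: np.ndarray | None = None,
    halton: HaltonConfig | None = None,
) -> float:
    """Simulated log-likelihood of ``data`` at fixed ``params``.

    ``params`` is either a flat vector in :meth:`ModelSpec.parameter_names`
    order or a mapping keyed by those names.  Supply either precomputed
    ``draws`` of shape (n, R, J) or a ``halton`` config to build them.
    """
    ws = _Workspace(spec, data)
    theta = _pack(spec, params)
    if draws is None:
        draws = _draws_for(spec, halton, ws.n)
    ll, _ = _loglik_and_grad(theta, ws, draws)
    return ll


def _pack(spec: ModelSpec, params) -> np.ndarray:
    if isinstance(params, Mapping):
        names = spec.parameter_names()
        missing = [p for p in names if p not in params]
        if missing:
            raise ValueError(f"missing parameter(s) {missing}")
        return np.array([params[p] for p in names], dtype=np.float64)
    return np.asarray(params, dtype=np.float64)


# ---------------------------------------------------------------------------
# probabilities and prediction


def mnl_probabilities(
    beta: Mapping[tuple[str, str], float],
    x: Mapping[str, float],
    levels: tuple[str, ...] = SEVERITY_LEVELS,
) -> np.ndarray:
    """Closed-form logit probabilities for one covariate row.

    ``beta`` maps ``(level, term)`` to a coefficient; absent pairs
    (including everything on the base level) are zero.  ``term`` may be
    :data:`CONST`.  Numerically stable for arbitrarily large predictors.
    """
    V = np.zeros(len(levels))
    for (lvl, term), b in beta.items():
        if lvl not in levels:
            raise ValueError(f"unknown level {lvl!r}")
        xv = 1.0 if term == CONST else float(x[term])
        V[levels.index(lvl)] += b * xv
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite linear predictor")
    V -= V.max()
    p = np.exp(V)
    return p / p.sum()


def severity_probabilities(
    spec: ModelSpec,
    params,
    data: pd.DataFrame,
    draws: np.ndarray | None = None,
    halton: HaltonConfig | None = None,
) -> pd.DataFrame:
    """Per-crash severity probabilities, averaged over the mixing draws.

    Returns a DataFrame with one column per level; rows sum to 1.
    """
    ws = _Workspace(spec, data)
    theta = _pack(spec, params)
    if draws is None:
        draws = _draws_for(spec, halton, ws.n)

    n, K = ws.n, ws.K
    fixed_betas, rand_params = ws.unpack(theta)
    U_fixed = np.zeros((n, K))
    for (k, x), b in zip(ws.fixed, fixed_betas):
        U_fixed[:, k] += b * x
    if ws.random:
        R = draws.shape[1]
        U = np.repeat(U_fixed[:, None, :], R, axis=1)
        for j, (entry, (mean, delta, sd, omega)) in enumerate(
            zip(ws.random, rand_params)
        ):
            mu = mean + entry["Z"] @ delta
            scale = sd * np.exp(entry["W"] @ omega)
            beta = mu[:, None] + scale[:, None] * draws[:, :, j]
            U[:, :, entry["k"]] += entry["x"][:, None] * beta
    else:
        U = U_fixed[:, None, :]
    U = U - U.max(axis=2, keepdims=True)
    s = np.exp(U)
    s /= s.sum(axis=2, keepdims=True)
    probs = s.mean(axis=1)
    return pd.DataFrame(probs, columns=list(spec.levels), index=data.index)


def predict_severity(
    estimate: "RPLEstimate", data: pd.DataFrame
) -> tuple[np.ndarray, pd.DataFrame]:
    """Predicted labels (argmax probability) plus the probability table.

    Ties break toward the less severe level, which is first in the level
    ordering.
    """
    probs = severity_probabilities(
        estimate.spec, estimate.params, data, halton=estimate.halton
    )
    order = list(estimate.spec.levels)
    labels = np.array(order, dtype=object)[
        np.argmax(probs.to_numpy(), axis=1)
    ]
    return labels, probs


def share_negative(mean: float, sd: float) -> float:
    """Fraction of a normal coefficient distribution that is below zero.

    For a coefficient ~ N(mean, sd²) this is Φ(−mean/sd); the complement is
    the share of observations for which the effect is positive.
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    return float(ndtr(-mean / sd))


# ---------------------------------------------------------------------------
# fitting


@dataclass(frozen=True)
class RPLEstimate:
    """A fitted (possibly mixed) logit model.

    ``params`` and ``se`` are keyed by :meth:`ModelSpec.parameter_names`;
    sigma components are sign-normalized to be nonnegative (the sign of
    sigma is not identified).
    """

    spec: ModelSpec
    params: dict[str, float]
    se: dict[str, float]
    loglik: float
    n_obs: int
    converged: bool
    n_iter: int
    halton: HaltonConfig | None = None
    message: str = ""

    @property
    def theta(self) -> np.ndarray:
        return np.array(
            [self.params[p] for p in self.spec.parameter_names()]
        )

    def summary(self) -> pd.DataFrame:
        """Coefficient table: estimate, standard error, z, |share below 0|."""
        rows = []
        for name in self.spec.parameter_names():
            est, se = self.params[name], self.se[name]
            z = est / se if se > 0 else np.nan
            rows.append({"parameter": name, "estimate": est, "se": se, "z": z})
        out = pd.DataFrame(rows).set_index("parameter")
        # distributional share for each random coefficient
        for e in self.spec.random_entries:
            m = self.params[f"mean:{e.level}:{e.term}"]
            s = self.params[f"sd:{e.level}:{e.term}"]
            if s > 0:
                out.loc[f"mean:{e.level}:{e.term}", "share_below_zero"] = (
                    share_negative(m, s)
                )
        return out

    def to_text(self) -> str:
        lines = [
            f"log-likelihood at convergence: {self.loglik:.4f}",
            f"observations: {self.n_obs}   converged: {self.converged} "
            f"({self.n_iter} iterations)",
        ]
        if self.halton is not None:
            lines.append(
                f"simulation: {self.halton.n_draws} Halton draws, "
                f"burn {self.halton.burn}"
            )
        lines.append(self.summary().to_string(float_format="%.4f"))
        return "\n".join(lines)


def _hessian(fun_grad, theta: np.ndarray, step: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian from an analytic gradient."""
    p = len(theta)
    H = np.zeros((p, p))
    for i in range(p):
        h = step * max(1.0, abs(theta[i]))
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        _, gp = fun_grad(tp)
        _, gm = fun_grad(tm)
        H[i] = (gp - gm) / (2 * h)
    return (H + H.T) / 2


def _standard_errors(fun_grad, theta: np.ndarray) -> np.ndarray:
    """SEs from the inverse observed information (negative Hessian of LL)."""
    H = _hessian(fun_grad, theta)
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    d = np.diag(cov).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)


def _fit(
    spec: ModelSpec,
    data: pd.DataFrame,
    halton: HaltonConfig | None,
    start: np.ndarray | None,
    gtol: float,
    maxiter: int,
    compute_se: bool = True,
) -> RPLEstimate:
    ws = _Workspace(spec, data)
    draws = _draws_for(spec, halton, ws.n)

    def fun_grad(theta):
        return _loglik_and_grad(theta, ws, draws)

    def neg(theta):
        ll, g = fun_grad(theta)
        return -ll, -g

    theta0 = (
        np.zeros(spec.n_parameters) if start is None else np.asarray(start, float)
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = optimize.minimize(
            neg,
            theta0,
            jac=True,
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
    theta = res.x
    ll, grad = fun_grad(theta)
    converged = bool(res.success) or float(np.max(np.abs(grad))) < gtol

    # sign-normalize sigma: |sigma| is what the mixing distribution uses
    names = spec.parameter_names()
    for i, name in enumerate(names):
        if name.startswith("sd:") and theta[i] < 0:
            theta[i] = -theta[i]
    ll, grad = fun_grad(theta)

    if compute_se:
        se = _standard_errors(fun_grad, theta)
    else:
        se = np.full(len(theta), np.nan)
    for e in spec.random_entries:
        sd_val = theta[names.index(f"sd:{e.level}:{e.term}")]
        if abs(sd_val) < 1e-4:
            warnings.warn(
                f"sigma for {e.level}:{e.term} collapsed to ~0; the "
                "coefficient is effectively fixed",
                RuntimeWarning,
                stacklevel=3,
            )
    if not converged:
        warnings.warn(
            f"optimizer did not converge: {res.message}",
            RuntimeWarning,
            stacklevel=3,
        )
    return RPLEstimate(
        spec=spec,
        params=dict(zip(names, theta)),
        se=dict(zip(names, se)),
        loglik=float(ll),
        n_obs=ws.n,
        converged=converged,
        n_iter=int(res.nit),
        halton=halton,
        message=str(res.message),
    )


def fit_mnl(
    spec: ModelSpec,
    data: pd.DataFrame,
    start: np.ndarray | None = None,
    gtol: float = 1e-5,
    maxiter: int = 500,
    compute_se: bool = True,
) -> RPLEstimate:
    """Maximum-likelihood multinomial logit (no random entries allowed)."""
    if spec.random_entries:
        raise ValueError("fit_mnl requires a specification without random entries")
    return _fit(spec, data, None, start, gtol, maxiter, compute_se)


def fit_rpl(
    spec: ModelSpec,
    data: pd.DataFrame,
    halton: HaltonConfig | None = None,
    start: np.ndarray | None = None,
    gtol: float = 1e-5,
    maxiter: int = 500,
    sigma_start: float = 0.1,
    compute_se: bool = True,
) -> RPLEstimate:
    """Mixed logit by simulated maximum likelihood over Halton draws.

    Starting values: the coefficients of the corresponding all-fixed MNL fit
    for the means, ``sigma_start`` for each standard deviation, zero for the
    heterogeneity shifters.
    """
    if not spec.random_entries:
        raise ValueError("fit_rpl requires at least one random entry")
    if halton is None:
        halton = HaltonConfig()
    if start is None:
        mnl = fit_mnl(spec.demoted(), data, gtol=gtol, maxiter=maxiter)
        start_map = {name: 0.0 for name in spec.parameter_names()}
        for e in spec.fixed_entries:
            start_map[f"b:{e.level}:{e.term}"] = mnl.params[f"b:{e.level}:{e.term}"]
        for e in spec.random_entries:
            start_map[f"mean:{e.level}:{e.term}"] = mnl.params[
                f"b:{e.level}:{e.term}"
            ]
            start_map[f"sd:{e.level}:{e.term}"] = sigma_start
        start = np.array(
            [start_map[p] for p in spec.parameter_names()]
        )
    return _fit(spec, data, halton, start, gtol, maxiter, compute_se)
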