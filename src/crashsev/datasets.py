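"""Synthetic multi-vehicle crash generator with a known ground truth.

Crash severities are drawn from the same data-generating process the
estimation code assumes: each severity level k gets a linear propensity
``V_k = X @ beta_k + eps_k`` with iid standard Gumbel errors, so the implied
choice probabilities are multinomial logit.  Coefficients may be random
across crashes, with heterogeneity in both the mean and the variance::

    beta_k = mean + delta @ Z + sd * exp(omega @ W) * v,   v ~ N(0, 1)

Covariates are independent Bernoulli indicators (one column per covariate),
mirroring the structure of police-reported crash extracts: four variable
groups (driver, roadway, crash, occupant) of 0/1 indicators, a year label,
and a heavily imbalanced 3-level outcome.

A dataset is a plain :class:`pandas.DataFrame` with columns
``crash_id, year, severity`` followed by one 0/1 column per covariate.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .severity import SEVERITY_LEVELS, validate_severity_labels

ID_COLUMNS = ("crash_id", "year", "severity")

COVARIATE_GROUPS = ("driver", "roadway", "crash", "occupant")


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class CovariateSpec:
    """A Bernoulli indicator covariate.

    Parameters
    ----------
    name
        Column name, unique within a config.
    group
        One of ``driver, roadway, crash, occupant``.
    prevalence
        P(indicator = 1), in [0, 1].
    """

    name: str
    group: str
    prevalence: float = 0.5

    def __post_init__(self) -> None:
        if self.group not in COVARIATE_GROUPS:
            raise ValueError(
                f"group {self.group!r} not in {COVARIATE_GROUPS}"
            )
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence {self.prevalence} outside [0, 1]")


@dataclass(frozen=True)
class RandomCoefficient:
    """A normally mixed coefficient on one covariate at one severity level.

    ``mean_shifters`` maps covariate names to the shift they apply to the
    coefficient mean; ``variance_shifters`` maps covariate names to the
    log-scale shift they apply to the coefficient standard deviation.
    """

    level: str
    covariate: str
    mean: float
    sd: float
    mean_shifters: dict[str, float] = field(default_factory=dict)
    variance_shifters: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("random-coefficient sd must be >= 0")


@dataclass(frozen=True)
class TrueParameterSet:
    """Ground-truth parameters of the generating process.

    The ``base`` level carries no parameters (its propensity is pure noise);
    all other levels may have a constant, fixed coefficients, and random
    coefficients.
    """

    constants: dict[str, float] = field(default_factory=dict)
    fixed_coefficients: dict[tuple[str, str], float] = field(default_factory=dict)
    random_coefficients: tuple[RandomCoefficient, ...] = ()
    base: str = "PDO"

    def __post_init__(self) -> None:
        validate_severity_labels([self.base])
        validate_severity_labels(self.constants)
        validate_severity_labels(lvl for lvl, _ in self.fixed_coefficients)
        validate_severity_labels(rc.level for rc in self.random_coefficients)
        if self.base in self.constants or any(
            lvl == self.base for lvl, _ in self.fixed_coefficients
        ) or any(rc.level == self.base for rc in self.random_coefficients):
            raise ValueError(f"base level {self.base!r} must have no parameters")
        object.__setattr__(
            self, "random_coefficients", tuple(self.random_coefficients)
        )

    # -- parameter addressing (used by year perturbations) ----------------
    def parameter_keys(self) -> list[str]:
        keys = [f"const:{lvl}" for lvl in self.constants]
        keys += [f"beta:{lvl}:{cov}" for lvl, cov in self.fixed_coefficients]
        for rc in self.random_coefficients:
            keys.append(f"mean:{rc.level}:{rc.covariate}")
            keys.append(f"sd:{rc.level}:{rc.covariate}")
        return keys

    def perturbed(self, shifts: dict[str, float]) -> "TrueParameterSet":
        """Return a copy with additive shifts applied to named parameters."""
        known = set(self.parameter_keys())
        unknown = sorted(set(shifts) - known)
        if unknown:
            raise ValueError(
                f"perturbation references unknown parameter(s) {unknown}; "
                f"known keys: {sorted(known)}"
            )
        constants = dict(self.constants)
        fixed = dict(self.fixed_coefficients)
        randoms = list(self.random_coefficients)
        for key, shift in shifts.items():
            kind, rest = key.split(":", 1)
            if kind == "const":
                constants[rest] += shift
            elif kind == "beta":
                lvl, cov = rest.split(":", 1)
                fixed[(lvl, cov)] += shift
            else:  # mean / sd of a random coefficient
                lvl, cov = rest.split(":", 1)
                for i, rc in enumerate(randoms):
                    if rc.level == lvl and rc.covariate == cov:
                        if kind == "mean":
                            randoms[i] = replace(rc, mean=rc.mean + shift)
                        else:
                            randoms[i] = replace(rc, sd=rc.sd + shift)
        return replace(
            self,
            constants=constants,
            fixed_coefficients=fixed,
            random_coefficients=tuple(randoms),
        )


@dataclass(frozen=True)
class YearConfig:
    """One simulated year: a label plus optional additive parameter shifts."""

    label: int
    perturbation: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for a synthetic crash dataset."""

    n_crashes: int
    covariates: tuple[CovariateSpec, ...]
    truth: TrueParameterSet
    years: tuple[YearConfig, ...] = (YearConfig(2017),)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_crashes < 1:
            raise ValueError("n_crashes must be >= 1")
        object.__setattr__(self, "covariates", tuple(self.covariates))
        object.__setattr__(self, "years", tuple(self.years))
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ValueError("covariate names must be unique")
        # every covariate referenced by the truth must be declared
        declared = set(names)
        used = {cov for _, cov in self.truth.fixed_coefficients}
        for rc in self.truth.random_coefficients:
            used.add(rc.covariate)
            used |= set(rc.mean_shifters) | set(rc.variance_shifters)
        missing = sorted(used - declared)
        if missing:
            raise ValueError(f"truth references undeclared covariate(s) {missing}")
        known = set(self.truth.parameter_keys())
        for yc in self.years:
            bad = sorted(set(yc.perturbation) - known)
            if bad:
                raise ValueError(
                    f"year {yc.label}: perturbation references unknown "
                    f"parameter(s) {bad}"
                )


# ---------------------------------------------------------------------------
# generation


def _propensities(
    truth: TrueParameterSet, X: pd.DataFrame, rng: np.random.Generator
) -> np.ndarray:
    """Per-crash propensity V (n, K), Gumbel noise included."""
    n = len(X)
    K = len(SEVERITY_LEVELS)
    V = np.zeros((n, K))
    for k, lvl in enumerate(SEVERITY_LEVELS):
        V[:, k] += truth.constants.get(lvl, 0.0)
    for (lvl, cov), beta in truth.fixed_coefficients.items():
        V[:, SEVERITY_LEVELS.index(lvl)] += beta * X[cov].to_numpy()
    for rc in truth.random_coefficients:
        mean = np.full(n, rc.mean)
        for cov, delta in rc.mean_shifters.items():
            mean += delta * X[cov].to_numpy()
        log_scale = np.zeros(n)
        for cov, omega in rc.variance_shifters.items():
            log_scale += omega * X[cov].to_numpy()
        v = rng.standard_normal(n)
        beta = mean + rc.sd * np.exp(log_scale) * v
        V[:, SEVERITY_LEVELS.index(rc.level)] += beta * X[rc.covariate].to_numpy()
    if not np.all(np.isfinite(V)):
        raise ValueError(
            "non-finite severity propensity; the configured parameters are "
            "too extreme (overflow)"
        )
    # Gumbel errors via inverse transform of uniforms
    u = rng.random((n, K))
    V += -np.log(-np.log(u))
    return V


def _generate_one_year(
    config: SyntheticConfig,
    truth: TrueParameterSet,
    year: int,
    seed_seq: np.random.SeedSequence,
    id_offset: int,
) -> pd.DataFrame:
    rng = np.random.default_rng(seed_seq)
    n = config.n_crashes
    X = pd.DataFrame(
        {
            c.name: (rng.random(n) < c.prevalence).astype(np.int64)
            for c in config.covariates
        }
    )
    V = _propensities(truth, X, rng)
    chosen = np.argmax(V, axis=1)
    out = pd.DataFrame(
        {
            "crash_id": np.arange(id_offset, id_offset + n, dtype=np.int64),
            "year": np.full(n, year, dtype=np.int64),
            "severity": np.array(SEVERITY_LEVELS, dtype=object)[chosen],
        }
    )
    return pd.concat([out, X], axis=1)


def generate_dataset(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate one year of crashes (the first entry of ``config.years``).

    Covariates are Bernoulli draws, coefficients are realized per crash from
    the configured mixing distribution, severities are the argmax of the
    Gumbel-perturbed propensities.  Deterministic given ``config.seed``.
    """
    yc = config.years[0]
    truth = config.truth.perturbed(yc.perturbation)
    seed_seq = np.random.SeedSequence(config.seed).spawn(1)[0]
    return _generate_one_year(config, truth, yc.label, seed_seq, 0)


def generate_multi_year(config: SyntheticConfig) -> pd.DataFrame:
    """Simulate every configured year and concatenate.

    Each year uses an independent random substream and its (possibly
    perturbed) parameter set; ``n_crashes`` rows are generated per year.
    """
    if len(config.years) < 2:
        raise ValueError("generate_multi_year requires at least 2 year entries")
    labels = [yc.label for yc in config.years]
    if len(set(labels)) != len(labels):
        raise ValueError(f"duplicate year labels in {labels}")
    streams = np.random.SeedSequence(config.seed).spawn(len(config.years))
    frames = []
    for i, (yc, ss) in enumerate(zip(config.years, streams)):
        truth = config.truth.perturbed(yc.perturbation)
        frames.append(
            _generate_one_year(config, truth, yc.label, ss, i * config.n_crashes)
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# CSV round trip


def covariate_columns(data: pd.DataFrame) -> list[str]:
    """Covariate column names: everything after the id/year/severity triple."""
    return [c for c in data.columns if c not in ID_COLUMNS]


def write_crash_csv(data: pd.DataFrame, path) -> None:
    """Write a crash dataset as headered CSV (lossless round trip)."""
    data.to_csv(path, index=False)


def read_crash_csv(path) -> pd.DataFrame:
    """Read a crash dataset written by :func:`write_crash_csv`.

    Raises ``ValueError`` for missing required columns or severity codes
    outside the 3-level scheme.
    """
    data = pd.read_csv(path)
    missing = [c for c in ID_COLUMNS if c not in data.columns]
    if missing:
        raise ValueError(f"crash CSV is missing required column(s) {missing}")
    validate_severity_labels(data["severity"])
    for col in covariate_columns(data):
        data[col] = data[col].astype(np.int64)
    data["crash_id"] = data["crash_id"].astype(np.int64)
    data["year"] = data["year"].astype(np.int64)
    data["severity"] = data["severity"].astype(object)
    return data


# ---------------------------------------------------------------------------
# exact choice shares and constant calibration


def expected_shares(
    truth: TrueParameterSet,
    covariates: tuple[CovariateSpec, ...],
    gh_nodes: int = 32,
) -> np.ndarray:
    """Exact population severity shares under the generating process.

    Enumerates all covariate patterns that matter (weighted by their
    Bernoulli probabilities) and integrates the normal mixing with
    Gauss–Hermite quadrature; no simulation involved.  Only feasible for
    modest numbers of relevant covariates (<= 20).
    """
    relevant = {cov for _, cov in truth.fixed_coefficients}
    for rc in truth.random_coefficients:
        relevant.add(rc.covariate)
        relevant |= set(rc.mean_shifters) | set(rc.variance_shifters)
    rel_specs = [c for c in covariates if c.name in relevant]
    if len(rel_specs) > 20:
        raise ValueError("too many relevant covariates to enumerate exactly")

    K = len(SEVERITY_LEVELS)
    n_rand = len(truth.random_coefficients)
    if n_rand:
        nodes, weights = np.polynomial.hermite_e.hermegauss(gh_nodes)
        weights = weights / weights.sum()
        grids = np.array(
            list(itertools.product(*[nodes] * n_rand))
        )  # (Q, n_rand)
        wgrid = np.prod(
            np.array(list(itertools.product(*[weights] * n_rand))), axis=1
        )
    else:
        grids = np.zeros((1, 0))
        wgrid = np.ones(1)

    shares = np.zeros(K)
    for pattern in itertools.product((0, 1), repeat=len(rel_specs)):
        p_pattern = 1.0
        x = {}
        for spec, bit in zip(rel_specs, pattern):
            p_pattern *= spec.prevalence if bit else 1.0 - spec.prevalence
            x[spec.name] = bit
        if p_pattern == 0.0:
            continue
        U = np.zeros((len(grids), K))
        for k, lvl in enumerate(SEVERITY_LEVELS):
            U[:, k] += truth.constants.get(lvl, 0.0)
        for (lvl, cov), beta in truth.fixed_coefficients.items():
            U[:, SEVERITY_LEVELS.index(lvl)] += beta * x[cov]
        for j, rc in enumerate(truth.random_coefficients):
            mean = rc.mean + sum(
                d * x[cov] for cov, d in rc.mean_shifters.items()
            )
            scale = rc.sd * np.exp(
                sum(w * x[cov] for cov, w in rc.variance_shifters.items())
            )
            beta = mean + scale * grids[:, j]
            U[:, SEVERITY_LEVELS.index(rc.level)] += beta * x[rc.covariate]
        U -= U.max(axis=1, keepdims=True)
        P = np.exp(U)
        P /= P.sum(axis=1, keepdims=True)
        shares += p_pattern * (wgrid @ P)
    return shares


def calibrate_constants(
    truth: TrueParameterSet,
    covariates: tuple[CovariateSpec, ...],
    target_shares: dict[str, float],
    tol: float = 1e-10,
    max_iter: int = 200,
) -> TrueParameterSet:
    """Adjust the non-base constants so the exact shares hit the targets.

    Fixed-point iteration on the log-share mismatch, which converges fast for
    logit-type share functions.
    """
    targets = np.array([target_shares[lvl] for lvl in SEVERITY_LEVELS])
    if not np.isclose(targets.sum(), 1.0, atol=1e-8):
        raise ValueError("target shares must sum to 1")
    current = truth
    for _ in range(max_iter):
        shares = expected_shares(current, covariates)
        if np.max(np.abs(shares - targets)) < tol:
            break
        consts = dict(current.constants)
        for k, lvl in enumerate(SEVERITY_LEVELS):
            if lvl == current.base:
                continue
            consts[lvl] = consts.get(lvl, 0.0) + np.log(targets[k] / shares[k]) \
                - np.log(targets[SEVERITY_LEVELS.index(current.base)]
                         / shares[SEVERITY_LEVELS.index(current.base)])
        current = replace(current, constants=consts)
    return current


# ---------------------------------------------------------------------------
# plain-dict (YAML) form


def config_to_dict(config: SyntheticConfig) -> dict:
    """Plain-dict form of a config, suitable for YAML round trips."""
    t = config.truth
    return {
        "n_crashes": config.n_crashes,
        "seed": config.seed,
        "covariates": [
            {"name": c.name, "group": c.group, "prevalence": c.prevalence}
            for c in config.covariates
        ],
        "truth": {
            "base": t.base,
            "constants": dict(t.constants),
            "fixed": [
                {"level": lvl, "covariate": cov, "value": v}
                for (lvl, cov), v in t.fixed_coefficients.items()
            ],
            "random": [
                {
                    "level": rc.level,
                    "covariate": rc.covariate,
                    "mean": rc.mean,
                    "sd": rc.sd,
                    "mean_shifters": dict(rc.mean_shifters),
                    "variance_shifters": dict(rc.variance_shifters),
                }
                for rc in t.random_coefficients
            ],
        },
        "years": [
            {"label": yc.label, "perturbation": dict(yc.perturbation)}
            for yc in config.years
        ],
    }


def config_from_dict(d: dict) -> SyntheticConfig:
    """Inverse of :func:`config_to_dict`."""
    t = d["truth"]
    truth = TrueParameterSet(
        constants={k: float(v) for k, v in t.get("constants", {}).items()},
        fixed_coefficients={
            (e["level"], e["covariate"]): float(e["value"])
            for e in t.get("fixed", ())
        },
        random_coefficients=tuple(
            RandomCoefficient(
                level=e["level"],
                covariate=e["covariate"],
                mean=float(e["mean"]),
                sd=float(e["sd"]),
                mean_shifters={
                    k: float(v) for k, v in e.get("mean_shifters", {}).items()
                },
                variance_shifters={
                    k: float(v)
                    for k, v in e.get("variance_shifters", {}).items()
                },
            )
            for e in t.get("random", ())
        ),
        base=t.get("base", "PDO"),
    )
    return SyntheticConfig(
        n_crashes=int(d["n_crashes"]),
        covariates=tuple(
            CovariateSpec(
                name=c["name"],
                group=c["group"],
                prevalence=float(c.get("prevalence", 0.5)),
            )
            for c in d["covariates"]
        ),
        truth=truth,
        years=tuple(
            YearConfig(
                label=int(y["label"]),
                perturbation={
                    k: float(v) for k, v in y.get("perturbation", {}).items()
                },
            )
            for y in d.get("years", ({"label": 2017},))
        ),
        seed=int(d.get("seed", 0)),
    )


# ---------------------------------------------------------------------------
# presets


#: Severity shares of the Washington multi-vehicle evaluation sample the
#: default preset emulates (PDO / injury / fatal).
WASHINGTON_SHARES = {"PDO": 0.6832, "I": 0.3153, "FI": 0.0015}


def washington_preset(
    n_crashes: int = 6700,
    years: tuple[int, ...] = (2017, 2018),
    seed: int = 0,
    perturbations: dict[int, dict[str, float]] | None = None,
) -> SyntheticConfig:
    """A config emulating a two-year Washington State multi-vehicle extract.

    ~13,000 crashes over two years, four indicator groups, one random
    coefficient (occupant restraints) with heterogeneity in its mean and
    variance, and constants calibrated exactly to the heavily imbalanced
    severity shares observed in such extracts (68.3% PDO, 31.5% injury,
    0.15% fatal).

    ``n_crashes`` is per year.  ``perturbations`` optionally maps a year
    label to additive parameter shifts, for temporal-stability experiments.
    """
    covariates = (
        CovariateSpec("male_driver", "driver", 0.62),
        CovariateSpec("middle_aged_driver", "driver", 0.45),
        CovariateSpec("old_aged_driver", "driver", 0.15),
        CovariateSpec("sudden_slowing", "driver", 0.20),
        CovariateSpec("wet_road_surface", "roadway", 0.30),
        CovariateSpec("rural_freeway", "roadway", 0.18),
        CovariateSpec("straight_alignment", "roadway", 0.75),
        CovariateSpec("not_at_intersection", "crash", 0.55),
        CovariateSpec("weekend", "crash", 0.25),
        CovariateSpec("daylight", "crash", 0.70),
        CovariateSpec("occupant_restraints", "occupant", 0.90),
        CovariateSpec("male_occupant", "occupant", 0.55),
        CovariateSpec("old_aged_occupant", "occupant", 0.12),
        CovariateSpec("second_row", "occupant", 0.10),
    )
    truth = TrueParameterSet(
        constants={"I": 0.0, "FI": 0.0},
        fixed_coefficients={
            ("I", "male_driver"): -0.25,
            ("I", "wet_road_surface"): -0.30,
            ("I", "not_at_intersection"): -0.20,
            ("I", "weekend"): -0.15,
            ("I", "male_occupant"): 0.20,
            ("I", "old_aged_occupant"): 0.35,
            ("I", "second_row"): -0.25,
            ("FI", "rural_freeway"): 0.60,
            ("FI", "sudden_slowing"): -0.50,
            ("FI", "old_aged_occupant"): 0.70,
        },
        random_coefficients=(
            RandomCoefficient(
                level="I",
                covariate="occupant_restraints",
                mean=-1.0,
                sd=1.0,
                mean_shifters={"sudden_slowing": -0.55},
                variance_shifters={"middle_aged_driver": -0.50},
            ),
        ),
        base="PDO",
    )
    truth = calibrate_constants(truth, covariates, WASHINGTON_SHARES)
    perturbations = perturbations or {}
    year_cfgs = tuple(
        YearConfig(y, perturbations.get(y, {})) for y in years
    )
    return SyntheticConfig(
        n_crashes=n_crashes,
        covariates=covariates,
        truth=truth,
        years=year_cfgs,
        seed=seed,
    )
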