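"""Multinomial / mixed logit: probabilities, likelihood, fitting, shares."""

import math

import numpy as np
import pandas as pd
import pytest

from crashsev.datasets import (
    CovariateSpec,
    SyntheticConfig,
    TrueParameterSet,
    generate_dataset,
)
from crashsev.halton import HaltonConfig
from crashsev.mixedlogit import (
    CONST,
    ModelSpec,
    SpecEntry,
    _loglik_and_grad,
    _Workspace,
    fit_mnl,
    fit_rpl,
    mnl_probabilities,
    predict_severity,
    severity_probabilities,
    share_negative,
    simulated_loglik,
)


# ---------------------------------------------------------------------------
# probabilities


def test_mnl_probabilities_symmetry():
    assert np.allclose(mnl_probabilities({}, {}), [1 / 3, 1 / 3, 1 / 3])


def test_mnl_probabilities_closed_form():
    p = mnl_probabilities({("PDO", CONST): math.log(2)}, {})
    assert np.allclose(p, [0.5, 0.25, 0.25])


def test_mnl_probabilities_overflow_safe():
    p = mnl_probabilities({("FI", CONST): 1000.0}, {})
    assert np.isfinite(p).all()
    assert p[2] == pytest.approx(1.0)


def test_probability_invariant_constant_shift():
    """Adding the same constant to every level leaves probabilities unchanged."""
    beta = {("I", CONST): 0.4, ("I", "x"): -0.9, ("FI", "x"): 1.2}
    x = {"x": 1.0}
    base = mnl_probabilities(beta, x)
    shifted = dict(beta)
    for lvl in ("PDO", "I", "FI"):
        shifted[(lvl, CONST)] = shifted.get((lvl, CONST), 0.0) + 7.3
    assert np.allclose(mnl_probabilities(shifted, x), base)


def test_severity_probabilities_rows_normalize(mnl_spec, mnl_data):
    probs = severity_probabilities(
        mnl_spec.demoted(), np.zeros(mnl_spec.n_parameters), mnl_data
    )
    assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-10)
    assert ((probs >= 0) & (probs <= 1)).all().all()


# ---------------------------------------------------------------------------
# simulated log-likelihood


def _toy_spec():
    return ModelSpec(
        entries=(
            SpecEntry("I", CONST),
            SpecEntry("I", "x", role="random"),
        )
    )


def test_simulated_loglik_single_crash_uniform():
    data = pd.DataFrame(
        {"crash_id": [0], "year": [2017], "severity": ["FI"], "x": [1]}
    )
    draws = np.zeros((1, 4, 1))
    ll = simulated_loglik(_toy_spec(), [0.0, 0.0, 0.0], data, draws=draws)
    assert ll == pytest.approx(math.log(1 / 3), abs=1e-12)


def test_simulated_loglik_matches_brute_force_over_draws():
    """Average of per-draw softmax probabilities, computed by hand."""
    data = pd.DataFrame(
        {
            "crash_id": [0, 1],
            "year": [2017, 2017],
            "severity": ["I", "PDO"],
            "x": [1, 1],
        }
    )
    const, mean, sd = 0.3, -0.5, 0.8
    vs = [-1.0, -0.2, 0.4, 1.3]
    draws = np.array(vs).reshape(1, 4, 1).repeat(2, axis=0)

    expected = 0.0
    for sev in ("I", "PDO"):
        probs = []
        for v in vs:
            u_i = const + (mean + sd * v) * 1.0
            denom = 1.0 + math.exp(u_i) + 1.0  # PDO, I, FI propensities
            probs.append(
                (math.exp(u_i) if sev == "I" else 1.0) / denom
            )
        expected += math.log(sum(probs) / 4)

    ll = simulated_loglik(_toy_spec(), [const, mean, sd], data, draws=draws)
    assert ll == pytest.approx(expected, abs=1e-12)


def test_degenerate_mixture_equals_closed_form_mnl(mnl_data):
    """With sigma = 0 the simulated likelihood is exactly MNL."""
    spec = _toy_spec()
    params = [0.25, -0.6, 0.0]
    data2 = mnl_data.rename(columns={"restraint": "x"})
    draws = np.linspace(-2, 2, 8).reshape(1, 8, 1).repeat(len(data2), axis=0)

    # independent closed form: log softmax over the three levels
    x = data2["x"].to_numpy(dtype=float)
    u_i = 0.25 + (-0.6) * x
    denom = 1.0 + np.exp(u_i) + 1.0
    ll_exact = 0.0
    for sev, ui, d in zip(data2["severity"], u_i, denom):
        num = math.exp(ui) if sev == "I" else 1.0
        ll_exact += math.log(num / d)

    ll_sim = simulated_loglik(spec, params, data2, draws=draws)
    # relative 1e-12: the absolute sums differ only by accumulation order
    assert ll_sim == pytest.approx(ll_exact, rel=1e-12)


def test_analytic_gradient_matches_finite_differences(mnl_data):
    spec = ModelSpec(
        entries=(
            SpecEntry("I", CONST),
            SpecEntry("FI", CONST),
            SpecEntry(
                "I",
                "restraint",
                role="random",
                mean_shifters=("male",),
                variance_shifters=("wet",),
            ),
        )
    )
    ws = _Workspace(spec, mnl_data)
    draws = np.linspace(-1.5, 1.5, 6).reshape(1, 6, 1).repeat(ws.n, axis=0)
    theta = np.array([0.2, -1.1, -0.4, 0.3, 0.6, -0.2])
    _, g = _loglik_and_grad(theta, ws, draws)
    h = 1e-6
    for i in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h
        tm[i] -= h
        fd = (
            _loglik_and_grad(tp, ws, draws)[0]
            - _loglik_and_grad(tm, ws, draws)[0]
        ) / (2 * h)
        assert g[i] == pytest.approx(fd, rel=1e-5, abs=1e-7)


# ---------------------------------------------------------------------------
# fitting


def test_fit_mnl_recovers_truth(simple_covariates, mnl_truth):
    cfg = SyntheticConfig(
        n_crashes=20_000, covariates=simple_covariates, truth=mnl_truth, seed=9
    )
    data = generate_dataset(cfg)
    spec = ModelSpec.from_truth(mnl_truth)
    est = fit_mnl(spec, data)
    assert est.converged
    true = {
        "b:I:const": -0.7,
        "b:FI:const": -4.0,
        "b:I:restraint": -0.8,
        "b:FI:male": 0.6,
    }
    for name, value in true.items():
        assert abs(est.params[name] - value) < 3 * est.se[name]


def test_intercept_only_constants_are_log_share_ratios(mnl_data):
    spec = ModelSpec(
        entries=(SpecEntry("I", CONST), SpecEntry("FI", CONST))
    )
    est = fit_mnl(spec, mnl_data)
    counts = mnl_data["severity"].value_counts()
    assert est.params["b:I:const"] == pytest.approx(
        math.log(counts["I"] / counts["PDO"]), abs=1e-5
    )
    assert est.params["b:FI:const"] == pytest.approx(
        math.log(counts["FI"] / counts["PDO"]), abs=1e-4
    )


def test_perfect_separation_flagged_or_unbounded():
    """A covariate that fully determines the outcome cannot stabilize."""
    n = 200
    data = pd.DataFrame(
        {
            "crash_id": range(n),
            "year": 2017,
            "severity": ["I" if i % 2 else "PDO" for i in range(n)],
            "x": [1 if i % 2 else 0 for i in range(n)],
        }
    )
    spec = ModelSpec(entries=(SpecEntry("I", CONST), SpecEntry("I", "x")))
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est = fit_mnl(spec, data, maxiter=50)
    # the MLE diverges: either flagged as non-converged or runaway estimate
    assert (not est.converged) or abs(est.params["b:I:x"]) > 5


def test_fit_rpl_deterministic_given_halton(mnl_data):
    spec = _toy_spec()
    data = mnl_data.rename(columns={"restraint": "x"}).head(500)
    hc = HaltonConfig(n_draws=30)
    a = fit_rpl(spec, data, halton=hc, compute_se=False)
    b = fit_rpl(spec, data, halton=hc, compute_se=False)
    assert a.params == b.params
    assert a.loglik == b.loglik


def test_sigma_zero_process_reduces_to_mnl(simple_covariates, mnl_truth):
    """On data without mixing, RPL and MNL converge to the same fit."""
    cfg = SyntheticConfig(
        n_crashes=2000, covariates=simple_covariates, truth=mnl_truth, seed=13
    )
    data = generate_dataset(cfg)
    spec = ModelSpec(
        entries=(
            SpecEntry("I", CONST),
            SpecEntry("FI", CONST),
            SpecEntry("I", "restraint", role="random"),
            SpecEntry("FI", "male"),
        )
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        rpl = fit_rpl(
            spec, data, halton=HaltonConfig(n_draws=100), compute_se=False
        )
    mnl = fit_mnl(spec.demoted(), data)
    # nested model: equal up to optimizer termination tolerance
    assert rpl.loglik == pytest.approx(mnl.loglik, abs=0.05)
    assert rpl.loglik >= mnl.loglik - 0.01


# ---------------------------------------------------------------------------
# distributional shares and prediction


@pytest.mark.parametrize(
    "mean,sd,expected,tol",
    [
        (-1.5017, 4.5840, 0.6284, 5e-5),  # reported split for a fitted mix
        (0.0, 2.7, 0.5, 1e-12),
        (-1.0, 1.0, 0.8413, 5e-5),
    ],
)
def test_share_negative(mean, sd, expected, tol):
    assert share_negative(mean, sd) == pytest.approx(expected, abs=tol)


def test_share_negative_rejects_bad_sd():
    with pytest.raises(ValueError):
        share_negative(0.0, 0.0)


def test_predict_ties_break_to_less_severe(mnl_data):
    """All-zero parameters give equal probabilities; PDO wins the tie."""
    from crashsev.mixedlogit import RPLEstimate

    spec = ModelSpec(entries=(SpecEntry("I", CONST), SpecEntry("FI", CONST)))
    est = RPLEstimate(
        spec=spec,
        params={p: 0.0 for p in spec.parameter_names()},
        se={p: float("nan") for p in spec.parameter_names()},
        loglik=0.0,
        n_obs=3,
        converged=True,
        n_iter=0,
    )
    labels, probs = predict_severity(est, mnl_data.head(3))
    assert np.allclose(probs, 1 / 3)
    assert list(labels) == ["PDO", "PDO", "PDO"]


def test_predict_matches_hand_computed_argmax():
    data = pd.DataFrame(
        {"crash_id": [0], "year": [2017], "severity": ["PDO"], "x": [1]}
    )
    spec = ModelSpec(
        entries=(SpecEntry("I", "x"), SpecEntry("FI", "x"))
    )
    est_params = {"b:I:x": 0.7, "b:FI:x": 1.9}
    probs = severity_probabilities(spec, est_params, data)
    expect = np.exp([0.0, 0.7, 1.9])
    expect /= expect.sum()
    assert np.allclose(probs.iloc[0], expect)
    assert probs.iloc[0].idxmax() == "FI"


def test_predict_rejects_missing_covariate(mnl_data):
    spec = ModelSpec(entries=(SpecEntry("I", "ghost"),))
    with pytest.raises(ValueError, match="ghost"):
        severity_probabilities(spec, [0.5], mnl_data)
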