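"""Likelihood-ratio tests for temporal stability of severity models.

Two families of tests ask whether the determinants of crash severity are
stable across calendar years.  The pairwise (transferability) test fixes the
parameters estimated on year *y2* and evaluates them on year *y1*'s data::

    chi2 = -2 [ LL(beta_y2 ; data_y1) - LL(beta_y1 ; data_y1) ]

which is nonnegative by construction because the free fit maximizes the
likelihood on y1.  The joint test compares a pooled fit with per-year fits::

    chi2 = -2 [ LL(pooled) - sum_y LL(year y) ]

Results are reported as the chi-square CDF at the statistic ("confidence
level"), so large statistics read as ~100%.

A calibration caveat, verified by simulation in the test-suite: when the
transferred parameters are themselves estimated on a finite sample of size
comparable to the evaluation year, the pairwise statistic's null
distribution is inflated — approximately (1 + n1/n2) times a chi-square —
because the estimation noise of *both* years enters the quadratic form.
The classic chi-square reference is exact only when the source-year sample
is much larger than the evaluation year's.  ``null_scale`` on the pairwise
test exposes the correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .halton import HaltonConfig
from .mixedlogit import ModelSpec, RPLEstimate, fit_mnl, fit_rpl, simulated_loglik


@dataclass(frozen=True)
class LRTestResult:
    """One likelihood-ratio comparison.

    ``confidence`` is the chi-square CDF at the statistic; ``direction`` is
    ``(y1, y2)`` for a pairwise test (parameters from y2, data from y1) or
    ``"joint"``.
    """

    chi2: float
    df: int
    confidence: float
    direction: tuple | str
    converged: bool = True

    def formatted(self) -> str:
        """Render as ``chi2 (df)[confidence%]``."""
        return f"{self.chi2:.2f} ({self.df})[{100 * self.confidence:.2f}%]"


def chi2_confidence(chi2: float, df: int) -> float:
    """P(X <= chi2) for X chi-square with ``df`` degrees of freedom."""
    if df < 1:
        raise ValueError("df must be >= 1")
    if chi2 < 0:
        chi2 = 0.0
    return float(stats.chi2.cdf(chi2, df))


def evaluate_fixed_params(
    estimate: RPLEstimate, data: pd.DataFrame
) -> float:
    """Log-likelihood of ``data`` under an already-fitted model's parameters.

    No re-estimation: the transferred coefficients are held fixed.  The same
    draw construction as fitting is used (same Halton settings, draws sized
    to this dataset).
    """
    return simulated_loglik(
        estimate.spec, estimate.params, data, halton=estimate.halton
    )


def _fit(spec: ModelSpec, data: pd.DataFrame, halton: HaltonConfig | None):
    if spec.random_entries:
        return fit_rpl(spec, data, halton=halton)
    return fit_mnl(spec, data)


def lr_test_pairwise(
    data_y1: pd.DataFrame,
    data_y2: pd.DataFrame,
    spec: ModelSpec,
    halton: HaltonConfig | None = None,
    labels: tuple = ("y1", "y2"),
    null_scale: float = 1.0,
) -> dict[tuple, LRTestResult]:
    """Both directions of the pairwise transferability test.

    The key ``(a, b)`` holds the test that evaluates *b*'s fitted parameters
    on *a*'s data against *a*'s own fit.  ``df`` is the number of estimated
    parameters of the transferred model.  ``null_scale`` divides the
    statistic before the CDF lookup (see the module note on the
    equal-sample-size null inflation); the reported ``chi2`` is always the
    raw statistic.
    """
    if len(data_y1) == 0 or len(data_y2) == 0:
        raise ValueError("both year datasets must be nonempty")
    fits = {labels[0]: _fit(spec, data_y1, halton), labels[1]: _fit(spec, data_y2, halton)}
    data = {labels[0]: data_y1, labels[1]: data_y2}
    out: dict[tuple, LRTestResult] = {}
    for a, b in ((labels[0], labels[1]), (labels[1], labels[0])):
        ll_transfer = evaluate_fixed_params(fits[b], data[a])
        chi2 = -2.0 * (ll_transfer - fits[a].loglik)
        df = fits[b].spec.n_parameters
        out[(a, b)] = LRTestResult(
            chi2=float(chi2),
            df=df,
            confidence=chi2_confidence(max(chi2, 0.0) / null_scale, df),
            direction=(a, b),
            converged=fits[a].converged and fits[b].converged,
        )
    return out


def lr_test_joint(
    data_all: pd.DataFrame,
    per_year: dict,
    spec: ModelSpec,
    halton: HaltonConfig | None = None,
) -> LRTestResult:
    """Joint-versus-separate test across all years.

    ``per_year`` maps year labels to datasets that partition ``data_all``.
    df = (sum of per-year parameter counts) − (joint parameter count); with
    a single year the statistic and df are both zero (degenerate edge case,
    reported as confidence 0).
    """
    total = sum(len(d) for d in per_year.values())
    if total != len(data_all):
        raise ValueError(
            "per-year datasets must partition the joint dataset "
            f"({total} rows vs {len(data_all)})"
        )
    joint = _fit(spec, data_all, halton)
    separate = {y: _fit(spec, d, halton) for y, d in per_year.items()}
    ll_sep = sum(f.loglik for f in separate.values())
    chi2 = -2.0 * (joint.loglik - ll_sep)
    df = sum(f.spec.n_parameters for f in separate.values()) - joint.spec.n_parameters
    confidence = chi2_confidence(max(chi2, 0.0), df) if df >= 1 else 0.0
    return LRTestResult(
        chi2=float(chi2),
        df=df,
        confidence=confidence,
        direction="joint",
        converged=joint.converged and all(f.converged for f in separate.values()),
    )


def stability_matrix(
    datasets: dict,
    spec: ModelSpec,
    halton: HaltonConfig | None = None,
    threshold: float = 0.95,
) -> pd.DataFrame:
    """Asymmetric year-by-year matrix of pairwise tests.

    Cell (row y1, column y2) evaluates y2's parameters on y1's data.  Cells
    hold :class:`LRTestResult`; the diagonal holds ``None``.  With a single
    year the matrix is empty.  Use :func:`format_stability_matrix` for the
    ``chi2 (df)[confidence%]`` rendering, with sub-threshold cells marked
    as not rejecting stability.
    """
    years = list(datasets)
    if len(years) < 2:
        return pd.DataFrame(index=years, columns=years, dtype=object)
    fits = {y: _fit(spec, datasets[y], halton) for y in years}
    mat = pd.DataFrame(index=years, columns=years, dtype=object)
    for y1 in years:
        for y2 in years:
            if y1 == y2:
                continue
            ll_transfer = evaluate_fixed_params(fits[y2], datasets[y1])
            chi2 = -2.0 * (ll_transfer - fits[y1].loglik)
            df = fits[y2].spec.n_parameters
            mat.loc[y1, y2] = LRTestResult(
                chi2=float(chi2),
                df=df,
                confidence=chi2_confidence(max(chi2, 0.0), df),
                direction=(y1, y2),
                converged=fits[y1].converged and fits[y2].converged,
            )
    mat.attrs["threshold"] = threshold
    return mat


def format_stability_matrix(mat: pd.DataFrame, threshold: float = 0.95) -> str:
    """Human-readable matrix: ``chi2 (df)[conf%]``, flagging stable cells."""
    rendered = pd.DataFrame(index=mat.index, columns=mat.columns, dtype=object)
    for y1 in mat.index:
        for y2 in mat.columns:
            cell = mat.loc[y1, y2]
            if not isinstance(cell, LRTestResult):
                rendered.loc[y1, y2] = "-"
                continue
            text = cell.formatted()
            if cell.confidence < threshold:
                text += " *"
            if not cell.converged:
                text += " (fit did not converge)"
            rendered.loc[y1, y2] = text
    return (
        rendered.to_string()
        + "\n* stability not rejected at the "
        + f"{100 * threshold:.0f}% confidence threshold"
    )
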