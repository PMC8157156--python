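"""Confusion-matrix and crash-cost evaluation of severity predictors.

Raw accuracy is a poor yardstick for heavily imbalanced crash data: a model
that calls everything "property damage only" scores well while missing every
fatal crash.  The cost-weighted view prices each severity level with its
comprehensive crash cost — economic cost plus the monetized quality-adjusted
life-year (QALY) loss — and compares the total cost implied by the
predictions with the total cost of the actual outcomes:

* ``AOCC`` — actual overall crash cost, row totals x unit costs;
* ``POCC`` — predicted overall crash cost, column totals x unit costs;
* ``OPMAE  = |AOCC - POCC| / N``        (USD per crash)
* ``OPAPE  = |AOCC - POCC| / AOCC``     (fraction)
* ``OPRMSE = |AOCC - POCC| / sqrt(N)``  (USD per sqrt-crash)

The default unit costs are the 2017 US comprehensive crash costs by
severity level (economic / QALY, USD): PDO 12,456 / 0; injury
46,132 / 97,535; fatal 588,738 / 3,173,900.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .severity import SEVERITY_LEVELS, SEVERITY_NAMES, validate_severity_labels


@dataclass(frozen=True)
class CostTable:
    """Per-severity unit costs (USD): economic, QALY, and their sum."""

    economic: dict[str, float]
    qaly: dict[str, float]

    def __post_init__(self) -> None:
        for table in (self.economic, self.qaly):
            validate_severity_labels(table)
            if any(v < 0 for v in table.values()):
                raise ValueError("unit costs must be nonnegative")
        missing = [
            lvl
            for lvl in SEVERITY_LEVELS
            if lvl not in self.economic or lvl not in self.qaly
        ]
        if missing:
            raise ValueError(f"cost table missing level(s) {missing}")

    @property
    def comprehensive(self) -> dict[str, float]:
        """Comprehensive crash cost: economic + QALY, per level."""
        return {
            lvl: self.economic[lvl] + self.qaly[lvl] for lvl in SEVERITY_LEVELS
        }

    def scaled(self, factor: float) -> "CostTable":
        """All unit costs multiplied by ``factor`` (e.g. a CPI re-index)."""
        if factor <= 0:
            raise ValueError("scale factor must be positive")
        return CostTable(
            economic={k: v * factor for k, v in self.economic.items()},
            qaly={k: v * factor for k, v in self.qaly.items()},
        )

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {
                "level": lvl,
                "economic": self.economic[lvl],
                "qaly": self.qaly[lvl],
                "comprehensive": self.comprehensive[lvl],
            }
            for lvl in SEVERITY_LEVELS
        ]
        return pd.DataFrame(rows).set_index("level")


def comprehensive_cost(ecc: float, qalycc: float) -> float:
    """Comprehensive unit cost of one severity level: economic + QALY."""
    if ecc < 0 or qalycc < 0:
        raise ValueError("unit costs must be nonnegative")
    return ecc + qalycc


def default_cost_table() -> CostTable:
    """The 2017 US comprehensive crash unit costs by severity level."""
    return CostTable(
        economic={"PDO": 12_456.0, "I": 46_132.0, "FI": 588_738.0},
        qaly={"PDO": 0.0, "I": 97_535.0, "FI": 3_173_900.0},
    )


@dataclass(frozen=True)
class ConfusionMatrix:
    """3x3 counts, actual level on rows, predicted level on columns."""

    counts: np.ndarray
    levels: tuple[str, ...] = SEVERITY_LEVELS

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.shape != (len(self.levels), len(self.levels)):
            raise ValueError(
                f"counts must be {len(self.levels)}x{len(self.levels)}"
            )
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @classmethod
    def from_labels(cls, actual, predicted) -> "ConfusionMatrix":
        actual = np.asarray(actual, dtype=object)
        predicted = np.asarray(predicted, dtype=object)
        if actual.shape != predicted.shape:
            raise ValueError("actual and predicted must have equal length")
        validate_severity_labels(actual)
        validate_severity_labels(predicted)
        K = len(SEVERITY_LEVELS)
        lut = {lvl: k for k, lvl in enumerate(SEVERITY_LEVELS)}
        counts = np.zeros((K, K), dtype=np.int64)
        for a, p in zip(actual, predicted):
            counts[lut[a], lut[p]] += 1
        return cls(counts=counts)

    @property
    def row_totals(self) -> np.ndarray:
        """Actual crash counts per severity level (N_i)."""
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        """Predicted crash counts per severity level."""
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def ratios(self) -> np.ndarray:
        """Row-normalized prediction shares R_ij = P_ij / N_i (NaN if N_i=0)."""
        totals = self.row_totals.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.counts / totals[:, None]

    def overall_accuracy(self) -> float:
        """Share of crashes predicted at their actual level (trace / N)."""
        if self.n == 0:
            raise ValueError("empty confusion matrix")
        return float(np.trace(self.counts) / self.n)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.levels), columns=list(self.levels)
        )

    # CSV round trip (level-labelled 3x3 table)
    def to_csv(self, path) -> None:
        self.as_frame().to_csv(path, index_label="actual")

    @classmethod
    def read_csv(cls, path) -> "ConfusionMatrix":
        frame = pd.read_csv(path, index_col="actual")
        missing = [l for l in SEVERITY_LEVELS if l not in frame.index]
        if missing or list(frame.columns) != list(SEVERITY_LEVELS):
            raise ValueError(
                f"confusion CSV must be a {SEVERITY_LEVELS}-labelled table"
            )
        return cls(counts=frame.loc[list(SEVERITY_LEVELS)].to_numpy())


def build_confusion(actual, predicted) -> ConfusionMatrix:
    """Tabulate actual-versus-predicted labels over the 3 levels."""
    return ConfusionMatrix.from_labels(actual, predicted)


def overall_accuracy(cm: ConfusionMatrix) -> float:
    return cm.overall_accuracy()


def _cost_vector(costs: CostTable, levels) -> np.ndarray:
    ccc = costs.comprehensive
    return np.array([ccc[lvl] for lvl in levels])


def aocc(cm: ConfusionMatrix, costs: CostTable) -> float:
    """Actual overall crash cost: sum_i N_i * CCC_i (USD)."""
    return float(cm.row_totals @ _cost_vector(costs, cm.levels))


def pocc(cm: ConfusionMatrix, costs: CostTable) -> float:
    """Predicted overall crash cost: sum_j (column total)_j * CCC_j (USD)."""
    return float(cm.column_totals @ _cost_vector(costs, cm.levels))


def cost_errors(cm: ConfusionMatrix, costs: CostTable) -> tuple[float, float, float]:
    """(OPMAE, OPAPE, OPRMSE): cost-gap per crash, relative, per sqrt-crash."""
    if cm.n == 0:
        raise ValueError("empty confusion matrix")
    a, p = aocc(cm, costs), pocc(cm, costs)
    gap = abs(a - p)
    if a == 0:
        raise ValueError("AOCC is zero; OPAPE undefined")
    return gap / cm.n, gap / a, gap / math.sqrt(cm.n)


@dataclass(frozen=True)
class EvaluationReport:
    """All prediction-quality indicators for one model on one evaluation set."""

    name: str
    r_overall: float
    r_diagonal: dict[str, float]
    aocc: float
    pocc: float
    opmae: float
    opape: float
    oprmse: float
    n: int
    confusion: ConfusionMatrix = field(repr=False, compare=False, default=None)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "r_overall": self.r_overall,
            "r_diagonal": self.r_diagonal,
            "aocc": self.aocc,
            "pocc": self.pocc,
            "opmae": self.opmae,
            "opape": self.opape,
            "oprmse": self.oprmse,
            "n": self.n,
            "confusion": self.confusion.counts.tolist()
            if self.confusion is not None
            else None,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "EvaluationReport":
        d = json.loads(text)
        cm = (
            ConfusionMatrix(counts=np.array(d["confusion"]))
            if d.get("confusion") is not None
            else None
        )
        return cls(
            name=d["name"],
            r_overall=d["r_overall"],
            r_diagonal=d["r_diagonal"],
            aocc=d["aocc"],
            pocc=d["pocc"],
            opmae=d["opmae"],
            opape=d["opape"],
            oprmse=d["oprmse"],
            n=d["n"],
            confusion=cm,
        )


def evaluation_report(
    cm: ConfusionMatrix, costs: CostTable | None = None, name: str = "model"
) -> EvaluationReport:
    """Compute every indicator from a confusion matrix and cost table."""
    costs = costs or default_cost_table()
    opmae, opape, oprmse = cost_errors(cm, costs)
    ratios = cm.ratios()
    r_diag = {
        lvl: float(ratios[k, k]) if cm.row_totals[k] > 0 else float("nan")
        for k, lvl in enumerate(cm.levels)
    }
    return EvaluationReport(
        name=name,
        r_overall=cm.overall_accuracy(),
        r_diagonal=r_diag,
        aocc=aocc(cm, costs),
        pocc=pocc(cm, costs),
        opmae=opmae,
        opape=opape,
        oprmse=oprmse,
        n=cm.n,
        confusion=cm,
    )


def compare_models(
    reports: list[EvaluationReport], paper_style: bool = False
) -> pd.DataFrame:
    """Side-by-side indicator table, one column per model.

    ``paper_style=True`` renders the conventional display scale: accuracies
    as percentages, OPMAE in whole USD, OPRMSE and the overall costs in
    thousands/millions of USD, all truncated to integers (truncation
    happens here, never in the stored values).
    """
    if not reports:
        raise ValueError("need at least one report")
    cols = {}
    for rep in reports:
        if paper_style:
            cols[rep.name] = {
                "R_overall (%)": round(100 * rep.r_overall, 2),
                "OPMAE (USD)": int(rep.opmae),
                "OPAPE (%)": round(100 * rep.opape, 2),
                "OPRMSE (thousand USD)": int(rep.oprmse / 1e3),
                "POCC (USD millions)": int(rep.pocc / 1e6),
                "AOCC (USD millions)": int(rep.aocc / 1e6),
            }
        else:
            cols[rep.name] = {
                "R_overall": rep.r_overall,
                "OPMAE": rep.opmae,
                "OPAPE": rep.opape,
                "OPRMSE": rep.oprmse,
                "POCC": rep.pocc,
                "AOCC": rep.aocc,
            }
    if paper_style:
        # object series keep truncated integers rendered as integers
        return pd.DataFrame(
            {name: pd.Series(col, dtype=object) for name, col in cols.items()}
        )
    return pd.DataFrame(cols)


def format_report(rep: EvaluationReport) -> str:
    """Full-precision text rendering of one report."""
    lines = [
        f"model: {rep.name}   (N = {rep.n})",
        f"overall accuracy: {100 * rep.r_overall:.2f}%",
    ]
    for lvl, r in rep.r_diagonal.items():
        lines.append(f"  {SEVERITY_NAMES[lvl]} correct: {100 * r:.2f}%")
    lines += [
        f"AOCC:  {rep.aocc:,.0f} USD",
        f"POCC:  {rep.pocc:,.0f} USD",
        f"OPMAE: {rep.opmae:,.2f} USD/crash",
        f"OPAPE: {100 * rep.opape:.2f}%",
        f"OPRMSE: {rep.oprmse:,.2f} USD",
    ]
    return "\n".join(lines)
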