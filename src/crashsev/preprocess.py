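"""From raw occupant/vehicle-level crash extracts to one analysis row per crash.

Police-reported extracts arrive with one row per vehicle (or occupant) and
carry a vehicle count (``numvehs``), a within-crash vehicle index
(``vehno``), and a raw injury code on the KABCO scale.  The analysis wants
crash-level rows: multi-vehicle crashes only, complete records, the first
vehicle's row as the crash representative (the other vehicles duplicate the
crash-level information), and the severity collapsed to three levels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .severity import SEVERITY_LEVELS

logger = logging.getLogger(__name__)

#: Default collapse of 5-level KABCO-style codes onto the 3-level scheme.
#: O (no injury) -> PDO; C/B/A (possible .. incapacitating) -> I; K -> FI.
#: The 3-level codes map to themselves so already-collapsed data passes
#: through unchanged.
DEFAULT_SEVERITY_MAP: dict[str, str] = {
    "O": "PDO",
    "C": "I",
    "B": "I",
    "A": "I",
    "K": "FI",
    "PDO": "PDO",
    "I": "I",
    "FI": "FI",
}

#: Values treated as missing by :func:`drop_incomplete`.
DEFAULT_MISSING_TOKENS: tuple[str, ...] = ("", "NA")


def filter_multivehicle(
    raw: pd.DataFrame, min_vehicles: int = 2
) -> pd.DataFrame:
    """Keep crashes involving at least ``min_vehicles`` vehicles.

    The default of 2 follows the usual multi-vehicle definition (two or
    more vehicles involved); pass 3 for the stricter more-than-two reading.
    Row order is preserved.
    """
    if "numvehs" not in raw.columns:
        raise ValueError("raw table is missing the 'numvehs' column")
    return raw[raw["numvehs"] >= min_vehicles].copy()


@dataclass
class DropResult:
    """Outcome of :func:`drop_incomplete`."""

    data: pd.DataFrame
    n_removed: int
    #: rows failing each required column; a row missing several columns is
    #: counted once per column here but removed once
    removed_by_column: dict[str, int] = field(default_factory=dict)


def drop_incomplete(
    raw: pd.DataFrame,
    required_columns: list[str],
    missing_tokens: tuple[str, ...] = DEFAULT_MISSING_TOKENS,
) -> DropResult:
    """Remove rows with a missing value in any required column.

    NaN and any value whose string form is in ``missing_tokens`` count as
    missing.  Per-column removal counts are logged and returned.
    """
    missing = pd.DataFrame(False, index=raw.index, columns=required_columns)
    for col in required_columns:
        if col not in raw.columns:
            raise ValueError(f"required column {col!r} absent from raw table")
        vals = raw[col]
        missing[col] = vals.isna() | vals.astype(str).str.strip().isin(
            missing_tokens
        )
    bad = missing.any(axis=1)
    by_column = {c: int(missing[c].sum()) for c in required_columns}
    n_removed = int(bad.sum())
    if n_removed:
        logger.info(
            "drop_incomplete: removed %d row(s); per-column missing counts %s",
            n_removed,
            by_column,
        )
    return DropResult(
        data=raw[~bad].copy(), n_removed=n_removed, removed_by_column=by_column
    )


def select_first_vehicle(raw: pd.DataFrame) -> pd.DataFrame:
    """Keep exactly one row per crash: the one with the smallest ``vehno``.

    The non-representative rows duplicate crash-level information and would
    otherwise induce severe collinearity.  If the minimal ``vehno`` is
    duplicated within a crash, the first occurrence wins and a warning is
    logged.
    """
    if "vehno" not in raw.columns:
        raise ValueError("raw table is missing the 'vehno' column")
    if "crash_id" not in raw.columns:
        raise ValueError("raw table is missing the 'crash_id' column")
    idx = raw.groupby("crash_id", sort=False)["vehno"].idxmin()
    kept = raw.loc[idx]
    dup = raw.merge(
        kept[["crash_id", "vehno"]], on=["crash_id", "vehno"], how="inner"
    )
    if len(dup) > len(kept):
        logger.warning(
            "select_first_vehicle: %d crash(es) have a duplicated minimal "
            "vehno; keeping the first occurrence",
            len(dup) - len(kept),
        )
    return kept.sort_index().copy()


def encode_severity(
    raw: pd.DataFrame,
    mapping: dict[str, str] | None = None,
    covariate_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Collapse raw severity codes to the 3-level scheme and emit the
    analysis table (``crash_id, year, severity`` + 0/1 covariates).

    ``mapping`` defaults to the KABCO collapse in
    :data:`DEFAULT_SEVERITY_MAP`; every code present in the data must be
    covered.  ``covariate_columns`` defaults to every column other than the
    bookkeeping ones.
    """
    mapping = DEFAULT_SEVERITY_MAP if mapping is None else mapping
    bad_targets = sorted(set(mapping.values()) - set(SEVERITY_LEVELS))
    if bad_targets:
        raise ValueError(
            f"mapping targets {bad_targets} are not severity levels "
            f"{list(SEVERITY_LEVELS)}"
        )
    codes = raw["severity"].astype(str)
    unmapped = sorted(set(codes) - set(mapping))
    if unmapped:
        raise ValueError(
            f"severity code(s) {unmapped} not covered by the mapping; "
            f"accepted codes are {sorted(mapping)}"
        )
    if covariate_columns is None:
        bookkeeping = {"crash_id", "year", "severity", "numvehs", "vehno"}
        covariate_columns = [c for c in raw.columns if c not in bookkeeping]
    out = pd.DataFrame(
        {
            "crash_id": raw["crash_id"].to_numpy(),
            "year": raw["year"].to_numpy(),
            "severity": codes.map(mapping).to_numpy(),
        }
    )
    for col in covariate_columns:
        out[col] = raw[col].astype("int64").to_numpy()
    return out


def prepare(
    raw: pd.DataFrame,
    required_columns: list[str] | None = None,
    min_vehicles: int = 2,
    mapping: dict[str, str] | None = None,
    covariate_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Full pipeline: multi-vehicle filter → completeness → first vehicle →
    severity encoding.  Idempotent on its own output (when the output's
    columns are fed back with ``numvehs``/``vehno`` absent the first two
    stages are skipped)."""
    data = raw
    if "numvehs" in data.columns:
        data = filter_multivehicle(data, min_vehicles)
    if required_columns is None:
        required_columns = ["severity", "year"]
    data = drop_incomplete(data, required_columns).data
    if "vehno" in data.columns:
        data = select_first_vehicle(data)
    return encode_severity(data, mapping, covariate_columns)
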