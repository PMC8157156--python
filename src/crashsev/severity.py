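"""Severity-level conventions shared across the package.

Crash outcomes are coded on three ordered levels: property damage only
(``PDO``), injury (``I``), and fatal injury (``FI``).  Everything downstream
-- data generation, model fitting, evaluation -- orders levels from least to
most severe, and all tie-breaking rules resolve toward the less severe level.
"""

from __future__ import annotations

from collections.abc import Iterable

#: Ordered severity labels, least severe first.
SEVERITY_LEVELS: tuple[str, str, str] = ("PDO", "I", "FI")

#: Long names, for report formatting.
SEVERITY_NAMES: dict[str, str] = {
    "PDO": "Property Damage Only",
    "I": "Injury",
    "FI": "Fatal Injury",
}


def severity_index(label: str) -> int:
    """Position of ``label`` in the least-to-most-severe ordering."""
    try:
        return SEVERITY_LEVELS.index(label)
    except ValueError:
        raise ValueError(
            f"unknown severity code {label!r}; accepted codes are "
            f"{list(SEVERITY_LEVELS)}"
        ) from None


def validate_severity_labels(labels: Iterable[str]) -> None:
    """Raise ``ValueError`` naming every label not in the 3-level scheme."""
    bad = sorted({str(v) for v in labels} - set(SEVERITY_LEVELS))
    if bad:
        raise ValueError(
            f"unknown severity code(s) {bad}; accepted codes are "
            f"{list(SEVERITY_LEVELS)}"
        )
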