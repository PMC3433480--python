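"""Oral-bioavailability threshold screen with exception rules.

The primary ADME filter keeps compounds whose predicted oral bioavailability
is at or above a threshold (default 50%).  Three exception rules re-admit
pharmacologically motivated compounds that fail the threshold: highly
abundant constituents, designated parent compounds (e.g. intact saponins
whose metabolites act in vivo), and designated metabolites of library
compounds.  Every selected compound carries exactly one provenance tag with
precedence ob_pass > abundant_exception > designated_parent >
designated_metabolite.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .library import FormulaLibrary, LibraryError

__all__ = [
    "CandidateSet",
    "ObDistribution",
    "round_half_up",
    "ob_distribution",
    "select_candidates",
]

PROVENANCE_TAGS = (
    "ob_pass",
    "abundant_exception",
    "designated_parent",
    "designated_metabolite",
)


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (90/320 -> 28.13, not banker's 28.12)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ObDistribution:
    """Cumulative OB distribution: rows of (threshold, count, percent)."""

    rows: list[tuple[float, int, float]]
    total: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.rows, columns=["ob_threshold", "n_compounds", "percent"]
        )


@dataclass
class CandidateSet:
    members: frozenset[str]
    provenance: dict[str, str]

    def __post_init__(self) -> None:
        if set(self.provenance) != set(self.members):
            raise ValueError("provenance keys must equal members")

    def __len__(self) -> int:
        return len(self.members)

    def counts_by_provenance(self) -> dict[str, int]:
        out = {tag: 0 for tag in PROVENANCE_TAGS}
        for tag in self.provenance.values():
            out[tag] += 1
        return out


def ob_distribution(
    library: FormulaLibrary, thresholds: list[float]
) -> ObDistribution:
    """Count compounds with OB >= t for each threshold, with percentages.

    Thresholds must be sorted descending (cumulative table convention).
    An empty library yields explicit zero rows.
    """
    if list(thresholds) != sorted(thresholds, reverse=True):
        raise ValueError("thresholds must be sorted descending")
    total = len(library)
    obs = [rec.ob_percent for rec in library.compounds.values()]
    rows = []
    for t in thresholds:
        count = sum(1 for ob in obs if ob >= t)
        pct = round_half_up(100.0 * count / total, 2) if total else 0.0
        rows.append((float(t), count, pct))
    return ObDistribution(rows=rows, total=total)


def select_candidates(
    library: FormulaLibrary, ob_threshold: float = 50.0
) -> CandidateSet:
    """Apply the OB screen and the exception rules.

    Membership is the union of the inclusive threshold filter and the three
    exception sets; the provenance tag records which rule (highest
    precedence first) admitted each compound.
    """
    provenance: dict[str, str] = {}
    for rec in library.compounds.values():
        if rec.ob_percent >= ob_threshold:
            provenance[rec.compound_id] = "ob_pass"
        elif rec.abundant:
            provenance[rec.compound_id] = "abundant_exception"
        elif rec.designated and rec.parent_id is None:
            provenance[rec.compound_id] = "designated_parent"
        elif rec.designated and rec.parent_id is not None:
            if rec.parent_id not in library:
                raise LibraryError(
                    f"designated metabolite {rec.compound_id!r}: parent "
                    f"{rec.parent_id!r} absent from library"
                )
            provenance[rec.compound_id] = "designated_metabolite"
    return CandidateSet(members=frozenset(provenance), provenance=provenance)
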