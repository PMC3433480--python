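"""MM-PBSA binding free-energy bookkeeping.

Binding free energies from the molecular mechanics / Poisson-Boltzmann
surface area decomposition are combined from their components:

    dE_gas  = dE_int + dE_vdw + dE_ele
    dG_sol  = dG_pb + dG_np          with dG_np = gamma * SASA + offset
    dG_bind = dE_gas + dG_sol        (no entropy)
    dG_bind(entropy) = dG_bind + (-T dS)

The -T dS term is stored with the sign convention of published component
tables: positive when entropy opposes binding, and it is *added* to the
enthalpic estimate.  For single-trajectory protocols dE_int cancels and
defaults to 0.

This module never computes PB energies, SASA or normal modes; it combines,
aggregates over frames, and audits published component tables against the
identities above.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "EnergyComponents",
    "BindingSummary",
    "AuditViolation",
    "nonpolar_energy",
    "combine",
    "aggregate_frames",
    "audit_table",
]

DEFAULT_GAMMA = 0.0072  # surface tension, kcal mol^-1 A^-2

COMPONENT_FIELDS = ("e_int", "e_vdw", "e_ele", "g_pb", "g_np", "minus_t_ds")


@dataclass
class EnergyComponents:
    """Per-complex MM-PBSA components in kcal/mol (means, optional stds)."""

    e_vdw: float
    e_ele: float
    g_pb: float
    g_np: float
    minus_t_ds: float = 0.0
    e_int: float = 0.0  # cancels in single-trajectory protocols
    std: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for name in COMPONENT_FIELDS:
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise ValueError(f"component {name} missing or non-finite: {v!r}")

    def __add__(self, other: "EnergyComponents") -> "EnergyComponents":
        return EnergyComponents(
            **{f: getattr(self, f) + getattr(other, f) for f in COMPONENT_FIELDS}
        )


@dataclass
class BindingSummary:
    """Derived MM-PBSA sums; always recomputed, never stored."""

    e_gas: float
    g_sol: float
    g_bind_no_entropy: float
    g_bind_with_entropy: float

    def __add__(self, other: "BindingSummary") -> "BindingSummary":
        return BindingSummary(
            self.e_gas + other.e_gas,
            self.g_sol + other.g_sol,
            self.g_bind_no_entropy + other.g_bind_no_entropy,
            self.g_bind_with_entropy + other.g_bind_with_entropy,
        )


def nonpolar_energy(
    sasa: float, gamma: float = DEFAULT_GAMMA, offset: float = 0.0
) -> float:
    """Nonpolar solvation term gamma * SASA + offset (SASA in A^2)."""
    if sasa < 0:
        raise ValueError(f"SASA must be non-negative, got {sasa}")
    return gamma * sasa + offset


def combine(components: EnergyComponents) -> BindingSummary:
    e_gas = components.e_int + components.e_vdw + components.e_ele
    g_sol = components.g_pb + components.g_np
    g_bind = e_gas + g_sol
    return BindingSummary(
        e_gas=e_gas,
        g_sol=g_sol,
        g_bind_no_entropy=g_bind,
        g_bind_with_entropy=g_bind + components.minus_t_ds,
    )


def aggregate_frames(frames: list[EnergyComponents]) -> EnergyComponents:
    """Per-field mean and sample (n-1) standard deviation over MD frames.

    A single frame reports std 0 by convention rather than undefined.
    """
    if not frames:
        raise ValueError("aggregate_frames requires at least one frame")
    n = len(frames)
    means = {}
    stds = {}
    for f in COMPONENT_FIELDS:
        vals = [getattr(fr, f) for fr in frames]
        m = sum(vals) / n
        means[f] = m
        if n == 1:
            stds[f] = 0.0
        else:
            stds[f] = math.sqrt(sum((v - m) ** 2 for v in vals) / (n - 1))
    return EnergyComponents(**means, std=stds)


@dataclass
class AuditViolation:
    complex_id: str
    quantity: str
    printed: float
    recomputed: float

    @property
    def deviation(self) -> float:
        return self.recomputed - self.printed


# printed-total column -> attribute of the recomputed BindingSummary
_PRINTED_KEYS = {
    "e_gas": "e_gas",
    "g_sol": "g_sol",
    "g_bind_no_entropy": "g_bind_no_entropy",
    "g_bind_with_entropy": "g_bind_with_entropy",
}


def audit_table(
    rows: dict[str, tuple[EnergyComponents, dict[str, float]]],
    tolerance: float = 0.05,
) -> list[AuditViolation]:
    """Check printed MM-PBSA totals against recomputation from components.

    ``rows`` maps complex_id -> (components, printed totals), where the
    printed dict may hold any of e_gas / g_sol / g_bind_no_entropy /
    g_bind_with_entropy.  Every derived quantity deviating from its printed
    counterpart by more than ``tolerance`` kcal/mol is reported with the
    recomputed value.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    violations: list[AuditViolation] = []
    for cid, (components, printed) in rows.items():
        summary = combine(components)
        for key, attr in _PRINTED_KEYS.items():
            if key in printed and printed[key] is not None:
                recomputed = getattr(summary, attr)
                if abs(recomputed - printed[key]) > tolerance:
                    violations.append(
                        AuditViolation(cid, key, printed[key], recomputed)
                    )
    return violations
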