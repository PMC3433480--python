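"""Target-screening cascade: pharmacophore hits -> candidate targets ->
disease-relevant targets -> docking-validated potential targets.

Three filters are applied in order, each inclusive at its boundary:

1. fit-score / rank filter (fit >= 3.00 within the per-compound top 300,
   restricted to an allowed human-target set),
2. disease-relevance partition from an annotation table,
3. docking acceptance (binding free energy <= -5.0 kcal/mol).

Every stage reports the compounds and targets it eliminated, and a
:class:`ScreenReport` collects the full bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "InteractionRecord",
    "FilterResult",
    "RelevancePartition",
    "DockingResult",
    "ScreenReport",
    "ScreenError",
    "load_hits",
    "load_energies",
    "filter_hits",
    "annotate_disease_relevance",
    "docking_validate",
    "run_cascade",
]


class ScreenError(ValueError):
    pass


@dataclass(frozen=True)
class InteractionRecord:
    """One compound-target pair carried through the cascade."""

    compound_id: str
    target_id: str
    fit_score: float
    rank: int
    binding_energy: float | None = None

    def __post_init__(self) -> None:
        if self.fit_score < 0:
            raise ScreenError(
                f"({self.compound_id}, {self.target_id}): negative fit score"
            )
        if self.rank < 1:
            raise ScreenError(
                f"({self.compound_id}, {self.target_id}): rank must be >= 1"
            )


@dataclass
class FilterResult:
    interactions: list[InteractionRecord]
    candidate_targets: frozenset[str]
    compounds_without_hits: frozenset[str]


@dataclass
class RelevancePartition:
    relevant: frozenset[str]
    not_relevant: frozenset[str]
    compounds_without_relevant_target: frozenset[str]


@dataclass
class DockingResult:
    interactions: list[InteractionRecord]
    potential_targets: frozenset[str]
    eliminated_compounds: frozenset[str]
    eliminated_targets: frozenset[str]


@dataclass
class ScreenReport:
    """Stage-by-stage counts; recomputable from the output sets."""

    n_raw_hits: int
    n_candidate_interactions: int
    n_candidate_targets: int
    n_relevant_targets: int
    n_relevant_interactions: int
    n_potential_interactions: int
    n_potential_targets: int
    n_potential_compounds: int
    eliminated_no_hit: frozenset[str] = frozenset()
    eliminated_no_relevant_target: frozenset[str] = frozenset()
    eliminated_by_docking: frozenset[str] = frozenset()
    targets_eliminated_by_docking: frozenset[str] = frozenset()

    def to_dict(self) -> dict:
        d = {
            k: (sorted(v) if isinstance(v, frozenset) else v)
            for k, v in self.__dict__.items()
        }
        return d


def load_hits(path) -> list[InteractionRecord]:
    df = pd.read_csv(path, sep="\t")
    need = {"compound_id", "target_id", "fit_score", "rank"}
    if not need.issubset(df.columns):
        raise ScreenError(f"hits table missing columns: {sorted(need - set(df.columns))}")
    return [
        InteractionRecord(
            compound_id=str(r.compound_id),
            target_id=str(r.target_id),
            fit_score=float(r.fit_score),
            rank=int(r.rank),
        )
        for r in df.itertuples()
    ]


def load_energies(path) -> dict[tuple[str, str], float]:
    df = pd.read_csv(path, sep="\t")
    need = {"compound_id", "target_id", "binding_energy_kcal_mol"}
    if not need.issubset(df.columns):
        raise ScreenError(
            f"energies table missing columns: {sorted(need - set(df.columns))}"
        )
    return {
        (str(r.compound_id), str(r.target_id)): float(r.binding_energy_kcal_mol)
        for r in df.itertuples()
    }


def filter_hits(
    hits: list[InteractionRecord],
    min_fit: float = 3.00,
    max_rank: int = 300,
    allowed_targets: frozenset[str] | set[str] | None = None,
) -> FilterResult:
    """Keep hits with fit_score >= min_fit, rank <= max_rank and (when an
    allowed set is given) target inside the allowed human-target set.

    Compounds whose entire hit list is removed are reported separately.
    """
    kept = [
        h
        for h in hits
        if h.fit_score >= min_fit
        and h.rank <= max_rank
        and (allowed_targets is None or h.target_id in allowed_targets)
    ]
    all_compounds = {h.compound_id for h in hits}
    kept_compounds = {h.compound_id for h in kept}
    return FilterResult(
        interactions=kept,
        candidate_targets=frozenset(h.target_id for h in kept),
        compounds_without_hits=frozenset(all_compounds - kept_compounds),
    )


def annotate_disease_relevance(
    candidate_targets: frozenset[str] | set[str],
    annotations,
    interactions: list[InteractionRecord] | None = None,
) -> RelevancePartition:
    """Partition candidate targets by their disease-relevance flag.

    ``annotations`` maps target_id -> TargetRecord (or any object with a
    ``cvd_related`` attribute).  If interactions are supplied, compounds all
    of whose candidate targets fall in the non-relevant part are flagged.
    """
    missing = sorted(t for t in candidate_targets if t not in annotations)
    if missing:
        raise ScreenError(f"unannotated targets: {missing}")
    relevant = frozenset(
        t for t in candidate_targets if annotations[t].cvd_related
    )
    not_relevant = frozenset(candidate_targets) - relevant
    orphans: set[str] = set()
    if interactions is not None:
        by_compound: dict[str, set[str]] = {}
        for rec in interactions:
            by_compound.setdefault(rec.compound_id, set()).add(rec.target_id)
        orphans = {
            c for c, ts in by_compound.items() if not (ts & relevant)
        }
    return RelevancePartition(
        relevant=relevant,
        not_relevant=not_relevant,
        compounds_without_relevant_target=frozenset(orphans),
    )


def docking_validate(
    interactions: list[InteractionRecord],
    energies: dict[tuple[str, str], float] | None = None,
    max_energy: float = -5.0,
) -> DockingResult:
    """Keep interactions whose docking binding energy is <= max_energy.

    Energies may already live on the records or be supplied as a lookup
    keyed by (compound_id, target_id); a pair missing an energy is an error.
    Compounds and targets with no surviving interaction are reported.
    """
    resolved: list[InteractionRecord] = []
    for rec in interactions:
        e = rec.binding_energy
        if e is None and energies is not None:
            e = energies.get((rec.compound_id, rec.target_id))
        if e is None:
            raise ScreenError(
                f"missing binding energy for ({rec.compound_id}, {rec.target_id})"
            )
        resolved.append(
            InteractionRecord(rec.compound_id, rec.target_id, rec.fit_score,
                              rec.rank, float(e))
        )
    kept = [r for r in resolved if r.binding_energy <= max_energy]
    in_compounds = {r.compound_id for r in resolved}
    in_targets = {r.target_id for r in resolved}
    out_compounds = {r.compound_id for r in kept}
    out_targets = {r.target_id for r in kept}
    return DockingResult(
        interactions=kept,
        potential_targets=frozenset(out_targets),
        eliminated_compounds=frozenset(in_compounds - out_compounds),
        eliminated_targets=frozenset(in_targets - out_targets),
    )


def run_cascade(
    hits: list[InteractionRecord],
    annotations,
    energies: dict[tuple[str, str], float] | None = None,
    min_fit: float = 3.00,
    max_rank: int = 300,
    max_energy: float = -5.0,
    allowed_targets=None,
) -> tuple[DockingResult, ScreenReport]:
    """Run all three screening stages and assemble the bookkeeping report."""
    stage1 = filter_hits(hits, min_fit=min_fit, max_rank=max_rank,
                         allowed_targets=allowed_targets)
    stage2 = annotate_disease_relevance(
        stage1.candidate_targets, annotations, interactions=stage1.interactions
    )
    relevant_interactions = [
        r for r in stage1.interactions if r.target_id in stage2.relevant
    ]
    stage3 = docking_validate(relevant_interactions, energies, max_energy)
    report = ScreenReport(
        n_raw_hits=len(hits),
        n_candidate_interactions=len(stage1.interactions),
        n_candidate_targets=len(stage1.candidate_targets),
        n_relevant_targets=len(stage2.relevant),
        n_relevant_interactions=len(relevant_interactions),
        n_potential_interactions=len(stage3.interactions),
        n_potential_targets=len(stage3.potential_targets),
        n_potential_compounds=len({r.compound_id for r in stage3.interactions}),
        eliminated_no_hit=stage1.compounds_without_hits,
        eliminated_no_relevant_target=stage2.compounds_without_relevant_target,
        eliminated_by_docking=stage3.eliminated_compounds,
        targets_eliminated_by_docking=stage3.eliminated_targets,
    )
    return stage3, report
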