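"""Key-player identification on the compound rows of a centrality table.

Hubs are high-degree nodes, bottlenecks high-betweenness nodes; key players
satisfy both thresholds.  The module also computes the squared Pearson
correlation between degree and betweenness, per-herb attribution of a
selected compound set, and parent-versus-metabolite rank comparisons.

Rankings are deterministic: primary metric descending, then the other
metric descending, then compound_id ascending.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .library import FormulaLibrary

__all__ = [
    "dual_threshold_select",
    "rank_by",
    "topk_intersection",
    "degree_betweenness_r2",
    "herb_attribution",
    "rank_compare",
]

REQUIRED_COLUMNS = {"compound_id", "degree", "betweenness"}


def _check_table(table: pd.DataFrame) -> None:
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"ranked table missing columns: {sorted(missing)}")
    if table["compound_id"].duplicated().any():
        raise ValueError("ranked table has duplicate compound ids")


def dual_threshold_select(
    table: pd.DataFrame,
    min_degree: float = 8,
    min_betweenness: float = 48.05,
) -> pd.DataFrame:
    """Rows satisfying both inclusive thresholds (hubs AND bottlenecks)."""
    _check_table(table)
    mask = (table["degree"] >= min_degree) & (table["betweenness"] >= min_betweenness)
    return table[mask].reset_index(drop=True)


def rank_by(table: pd.DataFrame, primary: str) -> pd.DataFrame:
    """Sort by ``primary`` metric desc, the other metric desc, id asc."""
    _check_table(table)
    secondary = "betweenness" if primary == "degree" else "degree"
    return table.sort_values(
        by=[primary, secondary, "compound_id"],
        ascending=[False, False, True],
    ).reset_index(drop=True)


@dataclass
class TopKIntersection:
    members: frozenset[str]
    size: int
    tie_at_degree_boundary: bool
    tie_at_betweenness_boundary: bool


def topk_intersection(table: pd.DataFrame, k: int = 20) -> TopKIntersection:
    """Intersection of the top-k-by-degree and top-k-by-betweenness sets.

    A metric tie straddling the k-th position is resolved by the stated
    tie-break and flagged in the result metadata.
    """
    _check_table(table)
    if k > len(table):
        raise ValueError(f"k={k} exceeds table size {len(table)}")
    by_deg = rank_by(table, "degree")
    by_btw = rank_by(table, "betweenness")

    def boundary_tie(ranked: pd.DataFrame, col: str) -> bool:
        if k == len(ranked):
            return False
        return bool(ranked[col].iloc[k - 1] == ranked[col].iloc[k])

    top_deg = set(by_deg["compound_id"].iloc[:k])
    top_btw = set(by_btw["compound_id"].iloc[:k])
    members = frozenset(top_deg & top_btw)
    return TopKIntersection(
        members=members,
        size=len(members),
        tie_at_degree_boundary=boundary_tie(by_deg, "degree"),
        tie_at_betweenness_boundary=boundary_tie(by_btw, "betweenness"),
    )


def degree_betweenness_r2(table: pd.DataFrame) -> float:
    """Squared Pearson correlation between degree and betweenness."""
    _check_table(table)
    if len(table) < 3:
        raise ValueError("need at least 3 rows for a correlation")
    deg = table["degree"].to_numpy(dtype=float)
    btw = table["betweenness"].to_numpy(dtype=float)
    if np.ptp(deg) == 0:
        raise ValueError("degree is constant; correlation undefined")
    r = np.corrcoef(deg, btw)[0, 1]
    return float(r * r)


def herb_attribution(
    selected, library: FormulaLibrary
) -> dict[str, int]:
    """Per-herb counts over a selected compound set; a compound belonging
    to several herbs counts once for each."""
    counts: dict[str, int] = {h: 0 for h in library.per_herb_counts}
    for cid in selected:
        if cid not in library:
            raise KeyError(f"unknown compound {cid!r}")
        for h in library[cid].herbs:
            counts[h] = counts.get(h, 0) + 1
    return counts


def rank_compare(
    table: pd.DataFrame, pairs: list[tuple[str, list[str]]]
) -> dict[tuple[str, str], bool]:
    """Does each metabolite outrank its parent compound?

    Comparison is by betweenness first, degree second (strictly greater on
    the deciding metric).  Returns {(parent, metabolite): verdict}.
    """
    _check_table(table)
    idx = table.set_index("compound_id")
    out: dict[tuple[str, str], bool] = {}
    for parent, metabolites in pairs:
        for m in [parent] + list(metabolites):
            if m not in idx.index:
                raise KeyError(f"compound {m!r} not in table")
        pb, pd_ = idx.loc[parent, "betweenness"], idx.loc[parent, "degree"]
        for met in metabolites:
            mb, md = idx.loc[met, "betweenness"], idx.loc[met, "degree"]
            if mb != pb:
                verdict = bool(mb > pb)
            else:
                verdict = bool(md > pd_)
            out[(parent, met)] = verdict
    return out
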