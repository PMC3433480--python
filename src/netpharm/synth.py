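"""Seeded synthetic input bundles and packaged reference tables.

The generator emits a complete, schema-valid input set for the whole
cascade — compound library, target annotations, pharmacophore hits and
docking energies — with the statistical structure the screening pipeline
assumes for a three-herb formula:

* 320 unique compounds distributed 201/112/31 over the three herbs, with
  24 compounds shared between two herbs (the membership excess that makes
  those counts sum);
* an oral-bioavailability distribution whose cumulative fractions at the
  90/80/70/60/50% thresholds match the published screen (28.13% at the
  50% cut), realized by stratified bin counts with piecewise-uniform draws
  inside each bin;
* heavy-tailed per-compound target-hit counts (truncated discrete power
  law, exponent 1.65, capped at the rank window of 300), giving a maximum
  hit count around 180 across ~100 candidate compounds;
* docking energies calibrated so the expected fraction of disease-relevant
  interactions at or below -5.0 kcal/mol is 46.5%.

One integer seed drives every draw, so bundles are byte-identical across
runs and platforms.  Identities are synthetic tokens (C###, T###); no
chemical or biological meaning is attached.

``load_fixtures`` returns the transcribed published tables shipped with the
package (OB distribution, MM-PBSA components, the 85-row compound
centrality table, the potential-target/disease table, per-pathway compound
counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .library import (
    CompoundRecord,
    FormulaLibrary,
    HerbRecord,
    TargetRecord,
    library_to_frame,
    write_library,
    write_targets,
)
from .mmpbsa import EnergyComponents
from .screen_ob import select_candidates
from .screen_targets import InteractionRecord, filter_hits

__all__ = [
    "SynthConfig",
    "SynthBundle",
    "generate_bundle",
    "write_bundle",
    "load_fixtures",
    "table3_components",
    "synthetic_cp_interactions",
]

HERBS = {
    "RSM": "Radix Salviae Miltiorrhizae",
    "PN": "Panax Notoginseng",
    "BORNEOL": "Borneolum",
}

HERB_ROLES = {"RSM": "emperor", "PN": "minister", "BORNEOL": "courier"}

PATHWAY_NAMES = [
    "PPAR Signaling Pathway",
    "Glucocorticoid and Inflammatory Pathway",
    "L-arginine/NO Signaling Pathway",
    "Renin-Angiotensin-Aldosterone System",
    "Platelet Aggregation Pathway",
    "TGF-beta Signaling Pathway",
]

DISEASE_VOCABULARY = [
    "Hypertension", "Coronary artery disease", "Arteriosclerosis",
    "Atherosclerosis", "Heart failure", "Stroke", "Thromboembolism",
    "Myocardial infarction", "Hyperlipidemia", "Venous thrombosis",
    "Angina pectoris", "Thrombosis", "Acute coronary syndrome",
    "Cardiovascular diseases", "Arrhythmia", "Diabetes", "Hypokinesia",
    "Heart diseases", "Kidney disease", "Asthma",
]


@dataclass
class SynthConfig:
    """Study conditions for a synthetic bundle (defaults = published setup)."""

    seed: int = 0
    n_compounds: int = 320
    per_herb_counts: dict = field(
        default_factory=lambda: {"RSM": 201, "PN": 112, "BORNEOL": 31}
    )
    # compounds shared between exactly two herbs: (herb_a, herb_b, count)
    shared_counts: tuple = (("RSM", "PN", 14), ("RSM", "BORNEOL", 10))
    # cumulative fraction of compounds with OB >= threshold
    ob_anchors: tuple = (
        (90.0, 0.0188), (80.0, 0.0469), (70.0, 0.0969),
        (60.0, 0.1656), (50.0, 0.2813),
    )
    ob_threshold: float = 50.0
    n_abundant_exceptions: int = 3
    n_designated_parents: int = 17
    n_designated_metabolites: int = 4
    n_targets: int = 385
    n_cvd_targets: int = 42
    n_pathways: int = 6
    hit_alpha: float = 1.65
    hit_cap: int = 300
    extra_hit_fraction: float = 0.3  # sub-threshold hits, exercise the filter
    n_no_hit_compounds: int = 8
    survival_prob: float = 735.0 / 1580.0  # docking acceptance fraction

    def validate(self) -> None:
        fracs = [f for _, f in self.ob_anchors]
        if any(not 0 <= f <= 1 for f in fracs):
            raise ValueError("anchor fractions must lie in [0, 1]")
        if fracs != sorted(fracs):
            raise ValueError("anchor fractions must be monotone "
                             "(thresholds descending)")
        shared_total = sum(c for _, _, c in self.shared_counts)
        if sum(self.per_herb_counts.values()) - shared_total != self.n_compounds:
            raise ValueError("per-herb counts, shared counts and n_compounds "
                             "are inconsistent")
        if not 0 <= self.survival_prob <= 1:
            raise ValueError("survival_prob must lie in [0, 1]")


@dataclass
class SynthBundle:
    library: FormulaLibrary
    targets: dict[str, TargetRecord]
    hits: list[InteractionRecord]
    energies: dict[tuple[str, str], float]
    config: SynthConfig


def _herb_memberships(config: SynthConfig) -> list[frozenset]:
    """Deterministic membership list honoring per-herb and shared counts."""
    singles = dict(config.per_herb_counts)
    shared: list[frozenset] = []
    for a, b, count in config.shared_counts:
        singles[a] -= count
        singles[b] -= count
        shared += [frozenset({a, b})] * count
    members: list[frozenset] = []
    for herb in sorted(singles):
        if singles[herb] < 0:
            raise ValueError(f"herb {herb}: shared counts exceed total")
        members += [frozenset({herb})] * singles[herb]
    return members + shared


def _ob_values(config: SynthConfig, n: int, rng) -> np.ndarray:
    """Stratified piecewise-uniform OB draws matching the anchor quantiles."""
    anchors = sorted(config.ob_anchors, reverse=True)  # high threshold first
    cum = [int(round(frac * n)) for _, frac in anchors]
    edges = [t for t, _ in anchors]
    values = np.empty(n)
    prev_cum = 0
    upper = 100.0
    for (lo, _), c in zip(anchors, cum):
        k = c - prev_cum
        values[prev_cum:c] = rng.uniform(lo, upper, size=k)
        prev_cum, upper = c, lo
    values[prev_cum:] = rng.uniform(0.0, edges[-1], size=n - prev_cum)
    rng.shuffle(values)
    return values


def _truncated_power_law(rng, alpha: float, cap: int, size: int) -> np.ndarray:
    ks = np.arange(1, cap + 1)
    p = ks.astype(float) ** (-alpha)
    p /= p.sum()
    return rng.choice(ks, size=size, p=p)


def generate_bundle(config: SynthConfig | None = None) -> SynthBundle:
    """Generate a full synthetic input bundle (deterministic per seed)."""
    config = config or SynthConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    n = config.n_compounds
    memberships = _herb_memberships(config)
    ob = _ob_values(config, n, rng)
    width = max(3, len(str(n)))
    ids = [f"C{i + 1:0{width}d}" for i in range(n)]

    compounds: dict[str, CompoundRecord] = {}
    for cid, herbs, o in zip(ids, memberships, ob):
        compounds[cid] = CompoundRecord(
            compound_id=cid, name=f"compound {cid[1:]}",
            herbs=herbs, ob_percent=float(o),
        )

    low_ob = [c for c in compounds.values() if c.ob_percent < config.ob_threshold]

    def pick(pool, k, used):
        avail = [c.compound_id for c in pool if c.compound_id not in used]
        chosen = rng.choice(avail, size=min(k, len(avail)), replace=False)
        used.update(chosen)
        return list(chosen)

    used: set[str] = set()
    abundant = pick([c for c in low_ob if "RSM" in c.herbs],
                    config.n_abundant_exceptions, used)
    parents = pick([c for c in low_ob if c.herbs == frozenset({"PN"})],
                   config.n_designated_parents, used)
    for cid in abundant:
        compounds[cid] = CompoundRecord(
            **{**compounds[cid].__dict__, "abundant": True})
    for cid in parents:
        compounds[cid] = CompoundRecord(
            **{**compounds[cid].__dict__, "designated": True})

    # metabolites of designated parents, appended to the library
    for j in range(config.n_designated_metabolites):
        parent = parents[j % len(parents)] if parents else None
        mid = f"C{n + j + 1:0{width}d}"
        compounds[mid] = CompoundRecord(
            compound_id=mid, name=f"metabolite of {parent}",
            herbs=compounds[parent].herbs if parent else frozenset({"PN"}),
            ob_percent=float(rng.uniform(0, 30)),
            parent_id=parent, designated=True,
        )

    herbs = {
        hid: HerbRecord(hid, name, HERB_ROLES.get(hid, "unassigned"))
        for hid, name in HERBS.items()
    }
    library = FormulaLibrary(compounds=compounds, herbs=herbs)

    # -- targets ------------------------------------------------------------
    twidth = max(3, len(str(config.n_targets)))
    tids = [f"T{i + 1:0{twidth}d}" for i in range(config.n_targets)]
    cvd_ids = (
        set(rng.choice(tids, size=config.n_cvd_targets, replace=False))
        if config.n_cvd_targets else set()
    )
    pathways = PATHWAY_NAMES[: config.n_pathways]
    targets: dict[str, TargetRecord] = {}
    for tid in tids:
        cvd = tid in cvd_ids
        diseases: frozenset[str] = frozenset()
        pws: frozenset[str] = frozenset()
        if cvd:
            k = 1 + rng.poisson(1.5)
            diseases = frozenset(
                rng.choice(DISEASE_VOCABULARY,
                           size=min(k, len(DISEASE_VOCABULARY)),
                           replace=False)
            )
            npw = int(rng.integers(0, 3))
            if npw and pathways:
                pws = frozenset(rng.choice(pathways, size=npw, replace=False))
        targets[tid] = TargetRecord(
            target_id=tid, short_name=tid, gene_name=tid,
            cvd_related=cvd, diseases=diseases, pathways=pws,
        )

    # -- pharmacophore hits for the OB-screen candidates --------------------
    candidates = sorted(select_candidates(library, config.ob_threshold).members)
    no_hit = set(rng.choice(candidates,
                            size=min(config.n_no_hit_compounds, len(candidates)),
                            replace=False))
    cap = min(config.hit_cap, config.n_targets)
    hits: list[InteractionRecord] = []
    if cap == 0 or not candidates:
        candidates = []
    counts = _truncated_power_law(rng, config.hit_alpha, max(cap, 1),
                                  len(candidates))
    for cid, k in zip(candidates, counts):
        if cid in no_hit:
            scored = [(float(rng.uniform(0.5, 2.99)), t)
                      for t in rng.choice(tids, size=5, replace=False)]
        else:
            chosen = rng.choice(tids, size=int(k), replace=False)
            scored = [(3.0 + float(rng.exponential(1.0)), t) for t in chosen]
            n_extra = rng.binomial(int(k), config.extra_hit_fraction)
            remaining = sorted(set(tids) - set(chosen))
            extra = rng.choice(remaining, size=min(n_extra, len(remaining)),
                               replace=False)
            scored += [(float(rng.uniform(0.5, 2.99)), t) for t in extra]
        scored.sort(key=lambda st: (-st[0], st[1]))
        for rank, (fit, tid) in enumerate(scored, start=1):
            hits.append(InteractionRecord(cid, tid, fit, rank))

    # -- docking energies for disease-relevant candidate interactions -------
    stage1 = filter_hits(hits, min_fit=3.00, max_rank=config.hit_cap,
                         allowed_targets=set(tids))
    energies: dict[tuple[str, str], float] = {}
    for rec in stage1.interactions:
        if not targets[rec.target_id].cvd_related:
            continue
        if rng.random() < config.survival_prob:
            e = -5.0 - float(rng.exponential(2.0))
        else:
            e = -5.0 + 0.01 + float(rng.exponential(3.0))
        energies[(rec.compound_id, rec.target_id)] = e

    return SynthBundle(library=library, targets=targets, hits=hits,
                       energies=energies, config=config)


def write_bundle(bundle: SynthBundle, out_dir) -> dict[str, Path]:
    """Write a bundle as the pipeline's TSV input files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "compounds": out / "compounds.tsv",
        "targets": out / "targets.tsv",
        "hits": out / "hits.tsv",
        "energies": out / "energies.tsv",
    }
    write_library(bundle.library, paths["compounds"])
    write_targets(bundle.targets, paths["targets"])
    pd.DataFrame(
        [(h.compound_id, h.target_id, repr(h.fit_score), h.rank)
         for h in bundle.hits],
        columns=["compound_id", "target_id", "fit_score", "rank"],
    ).to_csv(paths["hits"], sep="\t", index=False)
    pd.DataFrame(
        [(c, t, repr(e)) for (c, t), e in bundle.energies.items()],
        columns=["compound_id", "target_id", "binding_energy_kcal_mol"],
    ).to_csv(paths["energies"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# packaged reference tables
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "table1": "table1_ob_distribution.tsv",
    "table3": "table3_mmpbsa.tsv",
    "table5": "table5_compound_centrality.tsv",
    "table2": "table2_potential_targets.tsv",
    "networks_cp": "cp_pathway_counts.tsv",
}


def load_fixtures(name: str) -> pd.DataFrame:
    """Load a transcribed published table as a DataFrame.

    Names: ``table1`` (OB distribution), ``table3`` (MM-PBSA components),
    ``table5`` (85-row compound degree/betweenness), ``table2``
    (potential targets and diseases), ``networks_cp`` (per-pathway
    compound counts).
    """
    if name not in _FIXTURE_FILES:
        raise KeyError(f"unknown fixture {name!r}; "
                       f"known: {sorted(_FIXTURE_FILES)}")
    ref = resources.files("netpharm.data") / _FIXTURE_FILES[name]
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def table3_components() -> dict[str, tuple[EnergyComponents, dict[str, float]]]:
    """MM-PBSA fixture reshaped for the audit: per-complex components plus
    the printed derived totals."""
    df = load_fixtures("table3")
    out = {}
    component_terms = {"e_ele", "e_vdw", "g_np", "g_pb", "minus_t_ds"}
    printed_terms = {"e_gas", "g_sol", "g_bind_no_entropy",
                     "g_bind_with_entropy"}
    for cid, grp in df.groupby("complex_id", sort=False):
        terms = dict(zip(grp["term"], grp["mean"]))
        stds = {
            t: s for t, s in zip(grp["term"], grp["std"]) if pd.notna(s)
        }
        components = EnergyComponents(
            std={k: v for k, v in stds.items() if k in component_terms},
            **{t: float(terms[t]) for t in component_terms},
        )
        printed = {t: float(terms[t]) for t in printed_terms if t in terms}
        out[cid] = (components, printed)
    return out


def synthetic_cp_interactions() -> tuple[list[InteractionRecord], dict[str, frozenset]]:
    """A synthetic compound-pathway realization of the published per-pathway
    compound counts.

    The true compound-to-pathway incidence is not printed; this deterministic
    stand-in assigns the published number of compounds to each pathway by
    cycling through 78 synthetic compounds, so every compound joins at least
    one pathway and per-pathway degrees match exactly.  Each pathway is
    realized through one synthetic proxy target.
    """
    counts = load_fixtures("networks_cp")
    n_compounds = 78
    compounds = [f"C{i + 1:03d}" for i in range(n_compounds)]
    interactions: list[InteractionRecord] = []
    target_pathways: dict[str, frozenset] = {}
    offset = 0
    for j, row in counts.iterrows():
        tid = f"TP{j + 1}"
        target_pathways[tid] = frozenset({row["pathway"]})
        for i in range(int(row["n_compounds"])):
            cid = compounds[(offset + i) % n_compounds]
            interactions.append(InteractionRecord(cid, tid, 3.0, 1))
        offset += int(row["n_compounds"])
    return interactions, target_pathways
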