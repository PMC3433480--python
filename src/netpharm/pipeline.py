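"""End-to-end orchestration of the screening-and-networks cascade.

Stage order: OB screen -> target cascade (fit/rank filter, disease
relevance, docking validation) -> network construction (C-cT, C-T, C-P,
T-D) -> topology metrics -> key-player selection.  Every artifact is
written to the output directory together with a manifest of counts and
parameters; identical configs produce identical manifests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import keyplayers as kp
from . import metrics as mt
from . import networks as nw
from .library import load_library, load_targets
from .screen_ob import ob_distribution, select_candidates
from .screen_targets import load_energies, load_hits, run_cascade
from .synth import SynthConfig, generate_bundle, write_bundle

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_config"]

DEFAULT_THRESHOLDS = {
    "ob": 50.0,
    "fit": 3.00,
    "rank": 300,
    "energy": -5.0,
    "degree": 8,
    "betweenness": 48.05,
    "topk": 20,
}


@dataclass
class PipelineConfig:
    """Input paths (or a synth seed) plus every cascade threshold."""

    compounds: str | None = None
    targets: str | None = None
    hits: str | None = None
    energies: str | None = None
    out_dir: str = "netpharm_out"
    seed: int | None = None  # synth mode: generate inputs from this seed
    thresholds: dict = field(default_factory=lambda: dict(DEFAULT_THRESHOLDS))

    def __post_init__(self) -> None:
        merged = dict(DEFAULT_THRESHOLDS)
        merged.update(self.thresholds)
        self.thresholds = merged
        bad = set(self.thresholds) - set(DEFAULT_THRESHOLDS)
        if bad:
            raise ValueError(f"unknown threshold keys: {sorted(bad)}")
        if self.seed is None:
            missing = [k for k in ("compounds", "targets", "hits", "energies")
                       if getattr(self, k) is None]
            if missing:
                raise ValueError(
                    f"no seed given and input paths missing: {missing}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


@dataclass
class PipelineResult:
    manifest: dict
    candidates: object
    report: object
    graphs: dict
    node_metrics: object
    summaries: dict
    keyplayers: dict


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    th = config.thresholds

    if config.seed is not None:
        bundle = generate_bundle(SynthConfig(seed=config.seed))
        write_bundle(bundle, out / "inputs")
        library, targets = bundle.library, bundle.targets
        hits, energies = bundle.hits, bundle.energies
    else:
        library = load_library(config.compounds)
        targets = load_targets(config.targets)
        hits = load_hits(config.hits)
        energies = load_energies(config.energies)

    # stage 1: OB screen
    candidates = select_candidates(library, th["ob"])
    dist = ob_distribution(library, [90.0, 80.0, 70.0, 60.0, 50.0])
    dist.to_frame().to_csv(out / "ob_table.tsv", sep="\t", index=False)

    # stage 2: target cascade (hits restricted to OB candidates)
    cand_hits = [h for h in hits if h.compound_id in candidates.members]
    docking, report = run_cascade(
        cand_hits, targets, energies,
        min_fit=th["fit"], max_rank=th["rank"], max_energy=th["energy"],
        allowed_targets=set(targets),
    )
    (out / "screen_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, sort_keys=True))

    # stage 3: networks
    candidate_interactions = [
        h for h in cand_hits
        if h.fit_score >= th["fit"] and h.rank <= th["rank"]
    ]
    compound_herbs = {c.compound_id: c.herbs
                      for c in library.compounds.values()}
    graphs = {
        "cct": nw.build_compound_target(candidate_interactions,
                                        compound_herbs=compound_herbs),
        "ct": nw.build_compound_target(docking.interactions,
                                       compound_herbs=compound_herbs),
        "cp": nw.build_compound_pathway(
            docking.interactions,
            {t: targets[t].pathways for t in
             {r.target_id for r in docking.interactions}},
            compound_herbs=compound_herbs),
        "td": nw.build_target_disease(
            {t: targets[t] for t in docking.potential_targets}),
    }
    for name, g in graphs.items():
        nw.export_graph(g, out / f"{name}.graphml", "graphml")

    # stage 4: metrics on the validated compound-target network
    summaries = {}
    for name in ("cct", "ct"):
        if graphs[name].number_of_nodes():
            summaries[name] = mt.summarize(graphs[name]).to_dict()
    nm = mt.node_metrics(graphs["ct"]) if graphs["ct"].number_of_nodes() \
        else None
    if nm is not None:
        nm.to_csv(out / "node_metrics.tsv", sep="\t", index=False)
    (out / "summary.json").write_text(
        json.dumps(summaries, indent=2, sort_keys=True))

    # stage 5: key players among compound nodes
    key = {}
    if nm is not None:
        table = (
            nm[nm["partition"] == "compound"]
            .rename(columns={"node_id": "compound_id"})
            [["compound_id", "degree", "betweenness"]]
            .reset_index(drop=True)
        )
        if len(table) >= 3 and table["degree"].nunique() > 1:
            selected = kp.dual_threshold_select(
                table, th["degree"], th["betweenness"])
            k = min(th["topk"], len(table))
            inter = kp.topk_intersection(table, k)
            key = {
                "n_dual_threshold": int(len(selected)),
                "dual_threshold_members": sorted(selected["compound_id"]),
                "topk": k,
                "topk_intersection_size": inter.size,
                "topk_intersection": sorted(inter.members),
                "degree_betweenness_r2": kp.degree_betweenness_r2(table),
                "herb_attribution": kp.herb_attribution(
                    selected["compound_id"], library),
            }
    (out / "keyplayers.json").write_text(
        json.dumps(key, indent=2, sort_keys=True))

    manifest = {
        "thresholds": th,
        "seed": config.seed,
        "counts": {
            "library_compounds": len(library),
            "candidate_compounds": len(candidates),
            "candidate_provenance": candidates.counts_by_provenance(),
            **report.to_dict(),
            "graphs": {
                name: {"nodes": g.number_of_nodes(),
                       "edges": g.number_of_edges()}
                for name, g in graphs.items()
            },
        },
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True))
    return PipelineResult(
        manifest=manifest, candidates=candidates, report=report,
        graphs=graphs, node_metrics=nm, summaries=summaries, keyplayers=key,
    )
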