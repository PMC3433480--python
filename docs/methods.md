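# Methods

## Scope and model

netpharm implements the analysis layer of a systems-pharmacology screen
for a multi-herb formula. The upstream predictors are *inputs*, never
recomputed here: oral bioavailability values come from a QSAR model,
pharmacophore hits from reverse pharmacophore mapping, binding energies
from docking, and MM-PBSA components from MD post-processing. What this
package owns is everything downstream: the filtering cascade with its
bookkeeping, the energy-identity algebra, the network constructions, the
topology metrics, and the key-player statistics.

## Screening cascade

**OB screen.** A compound is a *candidate* if OB ≥ threshold (default
50%), or if an exception rule admits it: `abundant` (mass fraction ≥ 0.2%
of an herb), `designated` parent, or `designated` metabolite
(`parent_id` set, parent must exist). Threshold comparisons are inclusive.
Each candidate carries exactly one provenance tag, with precedence
ob_pass > abundant_exception > designated_parent > designated_metabolite,
so provenance counts partition the candidate set. The candidate count is
always derived from the rule, never asserted; published candidate totals
do not reconcile arithmetically with their own OB-passing counts, and this
package reports what the rule produces.

**Target cascade.** Three inclusive filters in order: fit ≥ 3.00 within
the per-compound top 300 ranks restricted to an allowed human-target set;
disease relevance from an annotation table (a deliberate design: live
database queries drift, an explicit table does not); docking energy ≤
−5.0 kcal/mol. Ranks are per-compound hit-list positions; equal fit scores
are broken by target id so rankings are deterministic. Each stage reports
the compounds/targets it removed, the lists are disjoint across stages,
and the `ScreenReport` counts are recomputable from the output sets
(tested).

## MM-PBSA bookkeeping

Components are stored per complex in kcal/mol; derived sums are always
recomputed:

    dE_gas  = dE_int + dE_vdw + dE_ele
    dG_np   = gamma * SASA + offset        (gamma default 0.0072)
    dG_sol  = dG_pb + dG_np
    dG_bind = dE_gas + dG_sol              [+ (-T dS) with entropy]

`e_int` defaults to 0: single-trajectory protocols cancel internal energy,
and published component tables omit it. The −TΔS term keeps the sign
convention of those tables (positive when entropy opposes binding) and is
added, which reproduces the two self-consistent published complexes to
within ±0.02 kcal/mol (printed rounding). Frame aggregation uses the
sample (n−1) standard deviation; a single frame reports 0 rather than
NaN. `audit_table` recomputes every derived quantity and flags deviations
beyond a caller-chosen tolerance; on the packaged three-complex fixture at
0.05 kcal/mol it flags exactly one entropy-corrected total, which cannot
be reproduced from its own column (the recomputation gives −13.93 against
a printed −27.14). The package flags; it does not guess which number was
intended.

## Networks

All four graphs are undirected, unweighted, bipartite `networkx.Graph`s
with a `partition` node attribute; self-loops, parallel edges and
within-partition edges are invalid and checked. Zero-degree nodes are
excluded (compounds with no surviving target or pathway simply do not
appear). Scores and energies never enter topology — the metric set assumes
unweighted graphs — though they can ride along as edge attributes.
Disease names are normalized by whitespace/case only; synonym merging is
deliberately out of scope because the disease vocabulary is uncontrolled.

## Metrics

* Betweenness: Brandes on unweighted shortest paths, unordered pairs,
  endpoints excluded, fractional credit over equal-length paths, reported
  unnormalized (matches the magnitudes of published per-node tables; a
  normalized option exists). Verified against an independent brute-force
  all-shortest-paths enumeration on hundreds of random ≤ 12-node graphs.
* Eccentricity: plain max hop distance over reachable nodes. The
  reciprocal variant used by some tools is exposed separately
  (`reciprocal_eccentricity`).
* Centroid: `min over w != v of (#{u: d(u,v) < d(u,w)} − #{u closer to w})`.
  The u = v and u = w terms contribute +1 and −1 and cancel, so the
  vectorized implementation counts over all u; equality with the explicit
  exclusion definition is property-tested.
* Global summary: avg degree 2E/n; density 2E/n(n−1) and centralization
  (n/(n−2))·(k_max/(n−1) − density) with *unipartite* denominators even on
  bipartite graphs — this is the convention under which the published
  values reproduce exactly; a bipartite-density variant is provided under
  its own name. Centralization is undefined below 3 nodes and reported as
  missing. Characteristic path length and the shortest-path count are over
  reachable ordered pairs only; unreachable pairs contribute to neither
  numerator nor denominator. Heterogeneity is the coefficient of variation
  of the degree sequence (population std).

## Key players

Key compounds satisfy both inclusive thresholds, degree ≥ 8 and
betweenness ≥ 48.05 by default. "Top-k" rankings sort by the primary
metric descending, the other metric descending, then compound id — a
deterministic tie-break; a tie crossing the k boundary is flagged in the
result metadata. The top-k claim is realized as the intersection of the
top-k-by-degree and top-k-by-betweenness sets, the reading consistent
with the published per-node table (intersection 18 at k = 20). R² is the
squared Pearson correlation over compound rows only, undefined (explicit
error) for constant degree. Herb attribution counts a multi-herb compound
once per herb.

## Synthetic data

The generator emulates the statistical structure of the study inputs, not
their chemistry:

* **Library**: 320 unique compounds with 201/112/31 herb memberships and
  24 compounds shared between two herbs (14 + 10). The membership excess
  (344 − 320 = 24) admits no assignment with 24 *three-way* shared
  compounds, so sharing is pairwise. Three abundant low-OB compounds, 17
  designated parents and 4 metabolites (appended, parented to the
  designated saponin-like compounds) exercise every exception rule.
* **OB values**: piecewise-uniform between the cumulative anchor
  thresholds (90 → 1.88%, 80 → 4.69%, 70 → 9.69%, 60 → 16.56%,
  50 → 28.13%), with stratified bin counts (rounded expected counts), so
  the ≥ 50% fraction matches the anchor up to integer rounding for every
  seed. Below 50% the density is uniform — only the cumulative fractions
  are constrained by the source table.
* **Hit counts**: truncated discrete power law on [1, 300] with exponent
  1.65, chosen so the expected maximum over ~100 candidates is ≈ 180, the
  published maximum. A configurable fraction of sub-threshold (fit < 3)
  hits and 8 all-sub-threshold compounds exercise the filters. Note the
  resulting *mean* hit count (~9) is far below the study's (~99): a power
  law cannot match both the maximum and the mean, and the maximum is the
  calibrated feature. Synthetic validated networks are therefore much
  sparser than the study's, and passing end-to-end tests demonstrates
  correct bookkeeping and calibration, not realistic network density.
* **Energies**: each disease-relevant candidate interaction survives with
  probability 735/1580 ≈ 0.465; survivors draw −5 − Exp(2) kcal/mol,
  non-survivors −4.99 + Exp(3). The survival indicator is explicit, so
  the calibration is exact in expectation and the mean over 20 seeds sits
  well within 5 percentage points of 46.5%.
* One `numpy` Generator seeded by the single config seed drives every
  draw; bundles are byte-identical across runs (tested).

The generator does not model: compound structures, target identity or
homology, correlated hit profiles between similar compounds, or any
relationship between fit score and binding energy.

## Numerical choices

* Percentages print with decimal half-up rounding to 2 places (90/320 →
  28.13); ratios to 1 place where the convention is 1-dp.
* Energy identities are exact in float; audits compare at user tolerance,
  with ±0.02 kcal/mol the natural tolerance for 2-dp printed tables.
* Degenerate inputs: empty library → explicit zero-percent rows; empty
  frame list, missing energies, unannotated targets, dangling graph
  endpoints → errors naming the offending row/pair/ids.

## Problem sizes in tests

The betweenness oracle runs on 200 random graphs of ≤ 12 nodes (exhaustive
path enumeration is exponential, and 12 nodes already exercises every
branch); calibration checks average 20 seeded bundles; pipeline tests run
one 320-compound bundle end to end. The full suite completes in a few
seconds.

## Known limitations

* The compound→herb map behind published per-herb key-player counts is
  not in the main text; herb attribution is therefore tested on synthetic
  data only.
* The compound–pathway incidence is realized by a deterministic synthetic
  assignment that matches the published per-pathway degrees exactly but
  not (unknowably) the true incidence.
* Disease nodes are string-normalized, not ontology-mapped; "heart
  diseases" and "cardiovascular diseases" stay distinct.
* Betweenness is computed over the full bipartite graph; restricting
  sources/sinks to one partition is not offered.
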