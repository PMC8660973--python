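# Methods

This note documents the measurement model, the synthetic-data model, the
numerical conventions, and the open design choices made in `synmorph`.

## Annotation model and units

A dataset is a list of *sections*: one ~70 nm EM section per synapse,
annotated with vesicle centers/diameters (nm), an open active-zone (AZ)
polyline, an open axolemma (membrane) polyline, and closed cisterna
outlines. All geometry is planar and rigid-motion invariant: no image
orientation is assumed, the coordinate origin is arbitrary per section.
Lengths are nm throughout, except the distance from the injection site
(μm, matching how dose zones are defined) and membrane areas (μm²).
Hand-traced AZ endpoints rarely lie exactly on the membrane trace; they
are snapped within a 5 nm tolerance.

The file container is a single self-describing JSON document
(`synmorph-annotation` v1) with fixed field order and `repr`-faithful
floats, so `read(write(X)) == X` exactly and identical inputs produce
identical bytes. A flat CSV export of the vesicle table is provided for
spreadsheets. Raw image formats are out of scope: the package consumes
annotations, not pixels.

## Classification and membrane budget

- **SV vs cisterna.** Uncoated vesicles with diameter < 100 nm are SVs;
  ≥ 100 nm are cisterna-like. The literature convention ("<100 nm" SVs,
  ">100 nm" cisternae) leaves exactly 100 nm unassigned; a total rule is
  required, and assigning the boundary to the cisterna side preserves the
  strict SV definition. Coated structures (CCP/CCV) are excluded from
  both pools and carried separately; their developmental stage labels are
  accepted as input, never computed.
- **Docked SVs.** Center distance to the AZ strictly < 50 nm. The center
  (not the vesicle edge) is used because the distance definition
  throughout is center-based; with ~50 nm vesicles the two conventions
  differ by one radius, so the threshold is configurable for
  sensitivity analyses.
- **Evagination.** For each AZ edge, walk outward along the membrane
  trace and find the first point whose chord distance from the edge
  equals the 1 μm probe; the squared chord distance is quadratic within a
  segment, so the crossing is solved in closed form rather than sampled.
  The side value is the arc length walked; the two sides are averaged. A
  flat membrane yields exactly 1 μm; curvature yields more (a
  semicircular detour of radius r adds (π − 2)·r, which the tests verify
  analytically). If the trace ends before the probe distance on one side,
  that side is reported missing and the other side is used with a
  warning; both sides missing is an error. Traces that re-approach the
  edge (non-monotone chord) are handled by taking the first crossing.
- **Budget.** sv_area = Σ 4πr² over SVs with each vesicle's own radius;
  ccpv_area likewise (coated structures are treated as spheres of their
  annotated diameter regardless of stage); pm_area = mean evagination
  length × section thickness; cisternae_area = summed perimeters ×
  thickness; total = sum, enforced to 1e-9 μm². Per-vesicle summation is
  exact and reduces to "mean sphere area × count" for equal diameters;
  the coarser mean-radius bookkeeping is available as
  `budget_radius_mode="mean"` for comparison with legacy spreadsheets.

## Spatial statistics

- **Profiles.** SVs are binned by AZ distance into half-open 50 nm bins
  up to 800 nm (the bin width is not canonical in the literature; 50 nm
  matches the docked cutoff and is configurable, and must divide the
  maximum). Counts are reported as mean per synapse; vesicles at or
  beyond the maximum are tallied separately so that
  Σ bins × n_synapses + excluded = total (mass conservation, tested).
  Normalization to a control is a per-bin ratio of means; bins with an
  empty control are NaN — neither 0 nor ∞ — and are skipped downstream.
- **Nearest neighbors.** Per section, center-to-center distances within
  the SV pool only (cisterna-like and coated structures are not
  "neighbors"). Sections with fewer than two SVs contribute no records
  (a lone vesicle has no neighbor) and warn. The de-clustering statistic
  is the pooled OLS of NN distance on AZ distance across all SVs of a
  condition — pooling at the vesicle level, because the natural n of this
  regression is vesicles, not synapses; a per-synapse aggregation can be
  built from the records table if a conservative unit of analysis is
  preferred. Raw two-sided slope p-values are reported together with
  Holm-adjusted values across conditions (the adjustment procedure for
  such slope families is not standardized; Holm is uniformly valid).
- **Subclusters.** Single-linkage connected components of the graph
  joining SV pairs within 60 nm (≈ one vesicle diameter, the spacing of
  tightly packed vesicles). Labels are deterministic (descending size,
  then smallest member id); singletons are legitimate size-1 clusters.
  This operation is exploratory — the de-clustering phenotype it
  quantifies is usually assessed qualitatively — and its threshold is a
  free parameter.
- **Theory anchor.** For a homogeneous Poisson process of intensity λ the
  mean NN distance is 1/(2√λ) with variance (4 − π)/(4πλ). The test
  suite checks the generator + estimator chain against this closed form
  on a ~2,500-point field, using interior points only (a 300 nm guard
  margin) to avoid edge inflation — a standard minus-sampling correction.

## Dose–response

Zones are closed ranges of distance from the injection site: high
30–140 μm, low 150–390 μm, untreated > 400 μm. Distances in the unnamed
gaps are excluded from grouped analyses rather than snapped — the ranges
are definitions, not estimates. (Some figure legends in the source
literature give 20 μm as the lower high-zone bound; the Methods value of
30 μm is the default and the bounds are configurable.) Group comparisons
are fixed-effects one-way ANOVA on per-synapse values with Tukey HSD
pairwise p-values from the studentized-range distribution; no
axon/animal nesting is modeled (the unit of analysis is the synapse).
Identical groups return F = 0, p = 1 rather than the 0/0 indeterminate
form. A two-way fixed-effects ANOVA (zone × distance-bin, no interaction
reporting) is provided for binned profiles. Percent change is
100·(ref − treated)/ref, scale-invariant, with a strictly positive
reference required.

## Synthetic generator

The generator emulates the *statistical structure* of annotated resting
synapses, not their biophysics:

- AZ of 1 μm on a flat membrane trace long enough for the evagination
  probe on both sides (so untreated pm evaginations measure exactly
  1 μm; membrane curvature is not emulated).
- SV count ~ Poisson(130) per control section (matching control-scale
  counts of ~121–130 per section); positions uniform along the AZ with
  AZ-distance density exponential with a 250 nm scale (no functional form
  is canonical; uniform is available), truncated at 800 nm; a docked
  fraction (default 0.10) is placed within 10–49 nm.
- A hard-core minimum spacing of 40 nm (vesicles are ~50 nm objects whose
  centers cannot coincide) imposed by dart-throwing with a crowding
  fallback; the CSR field generator applies **no** hard core, so it
  matches the Poisson closed form.
- Diameters ~ Normal(51.5, 4) nm truncated positive. The 4 nm spread is
  a deliberate emulator parameter; measured populations can be wider
  (an SEM of 0.6 nm over ~200 SVs implies an SD near 8.6 nm). No
  computed quantity in this package depends on the diameter spread.
- De-clustering: each zone maps to a programmed fraction (default
  untreated 0, low 0.4, high 0.75 — a per-zone step, mirroring the zoned
  experimental design; within-zone dose heterogeneity is not modeled).
  Two modes, both exercised in tests: **remove** (vesicles leave the
  section — reproduces vesicle loss and the loss of total membrane) and
  **disperse** (vesicle number conserved; the selected fraction is
  reassigned to satellite subclusters displaced ~400 nm from the cluster
  centroid plus a singleton fraction — reproduces dispersal; mean NN
  distance increases monotonically with the displacement, tested by
  Spearman correlation over a sweep).
- Nuisance structures: Poisson numbers of cisternae (circle outlines,
  75–200 nm radius) and staged CCP/Vs near the membrane.
- Experiments: per-zone synapse counts (default 30) with distances
  uniform in each zone's range; untreated internal controls are labeled
  `untreated`, injected zones `synuclein_ab`. All randomness flows from
  one root seed via `SeedSequence` spawning: identical (params, seed)
  give byte-identical datasets.

What passing tests on this emulator do **not** show: robustness to
annotation noise (mis-traced membranes, missed vesicles), non-flat
membrane geometry, within-zone dose gradients, serial-section
correlations, or cluster cohesion as strong as real synapses (the
emulated untreated cluster fragments into more 60 nm-linkage components
than a real tight cluster would). Those require real annotations.

## Sequence conservation

Pairwise global alignment stands in for a multiple alignment when only
pairwise identities are needed. Scoring: BLOSUM62, gap open 10, extend
0.5, with a length-L gap penalized open + (L − 1)·extend; identity is
identical columns over the alignment length (the denominator is
configurable to the shorter sequence, the other common convention);
similarity additionally counts aligned pairs with a positive substitution
score. Published identity percentages from other tools depend on their
unstated parameterizations, so agreement is expected within a couple of
percentage points, not bit-exactly. Domain windows: N-terminal 1–95,
NAC 60–95, antibody epitope 11–26 (windows are clipped to shorter
sequences). Charge profiles use centered odd windows with truncated ends
and K/R = +1, D/E = −1, H = +0.5 (configurable to 0; +0.5 is the common
physiological-pH convention).

The human α/β/γ proteins bundled in `data/` are the canonical CDS
products of the named transcripts. The lamprey γ-synuclein protein
(JN544525.1) is not redistributed: it is loaded from a user-provided
cache or fetched from NCBI at call time. The bundled
`lamprey_gamma_synuclein_synthetic.fasta` is a clearly labelled synthetic
stand-in (seeded random perturbation of human γ-synuclein) for offline
pipeline demonstrations only; functions that answer biological questions
refuse to substitute it.

## Numerical conventions and degenerate inputs

- Point-to-polyline distance is exact per-segment projection (shapely);
  it is translation/rotation invariant to < 1e-6 nm (tested with random
  rigid transforms).
- OLS with a zero-variance predictor is an error; a zero-variance
  response is a flat fit (slope 0, R² 0, p 1).
- Connected-component labels, JSON key order, and report serialization
  are all deterministic; reports embed a config hash, seed and version
  but no timestamps, so reruns are byte-identical.
- Problem sizes in the test suite (20 recovery replicates of 90 sections;
  one ~2,500-point CSR field; 500-case geometry fuzzing) keep the full
  run around half a minute while leaving Monte-Carlo margins of ≥3
  standard errors on every stochastic assertion.
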