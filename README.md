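# synmorph

Quantitative morphometry of synaptic-vesicle (SV) clusters in annotated
electron-microscopy sections of presynaptic terminals.

Giant reticulospinal synapses (e.g. in lamprey spinal cord) hold a large,
tight cluster of ~50 nm vesicles at the active zone (AZ). Acute
perturbations delivered by axonal microinjection — which creates a
concentration gradient along the axon, so distance from the injection site
is an inverse dose proxy — can deplete or disperse that cluster.
`synmorph` is the analysis side of such experiments: it consumes
per-section annotations (vesicle centers and diameters, AZ and axolemma
polylines, cisterna outlines) and produces the standard ultrastructural
statistics used to quantify vesicle loss, membrane redistribution and
de-clustering. It is intended for synapse ultrastructure labs and for
anyone who needs reproducible point-pattern statistics on hand-annotated
EM sections.

## What it computes

**Organelle classification and membrane budget** (per section, stereology
with section thickness *t* = 70 nm):

- SVs: small clear vesicles with diameter < 100 nm; larger uncoated
  structures are cisterna-like; clathrin-coated pits/vesicles (CCP/V) are
  counted separately.
- Docked SVs: center distance to the AZ polyline < 50 nm.
- Plasma-membrane evagination: from each AZ edge, the curved (arc) length
  along the axolemma to the first point whose straight-line distance from
  that edge equals a 1 μm probe; the two sides are averaged.
- Membrane areas: SV and CCP/V membrane as summed sphere surfaces
  Σ 4πr², plasma membrane as evagination length × *t*, cisternae as
  summed outline perimeters × *t*; total = sum of the four compartments
  (exact to 1e-9 μm²).

**Spatial statistics of de-clustering:**

- Distance-to-AZ profiles: mean SV count per synapse in 50 nm bins to
  800 nm, optionally normalized bin-by-bin to a control condition.
- Nearest-neighbor (NN) analysis: for every SV, the center-to-center
  distance to its nearest SV and its distance to the AZ; the pooled OLS
  regression of NN distance on AZ distance is the de-clustering statistic
  (tight clusters sit near one vesicle diameter, ~50–60 nm, with a flat
  slope; dispersal raises distal NN distances and the slope).
- Subcluster detection: single-linkage connected components at a 60 nm
  threshold (≈ one vesicle diameter); singletons are fully de-clustered
  vesicles.
- Theory anchor: for complete spatial randomness with intensity λ, mean
  NN distance = 1/(2√λ); the simulator's Poisson fields reproduce it.

**Dose–response:** zoning by distance from the injection site (high
30–140 μm, low 150–390 μm, untreated internal control > 400 μm), OLS of
per-synapse SV count on distance, one-way ANOVA with Tukey HSD across
groups, and percent change 100·(ref − treated)/ref.

**Synthetic data:** a seedable generator of annotated sections and whole
injection-gradient experiments (clustered vesicle fields with hard-core
spacing, docked subpopulation, programmable removal/dispersal
de-clustering, cisterna and CCP/V nuisance structures), so the entire
pipeline is testable without microscope data.

**Sequence conservation:** pairwise global alignment (BLOSUM62, affine
gaps 10/0.5) with percent identity/similarity over full-length and domain
windows (N-terminal 1–95, NAC 60–95, epitope 11–26), and sliding-window
charge profiles (K/R = +1, D/E = −1, H = +0.5). The canonical human α-,
β- and γ-synuclein proteins ship with the package; the lamprey
γ-synuclein ortholog (GenBank JN544525.1) is fetched from NCBI when
network access is available.

## Worked example

Simulate an injection-gradient experiment (30 synapses per zone, ~130 SVs
per untreated section, a programmed 75% high-zone depletion), then run
the pipeline:

```sh
$ synmorph simulate --seed 42 --out experiment.json
wrote 90 sections to experiment.json
$ synmorph measure experiment.json --out metrics.csv
90 sections; mean SV diameter 51.5 +/- 0.0 nm
$ synmorph nn experiment.json --out nn.csv
n=7149 SVs: slope=0.0473, R^2=0.1310, p=3.74e-220
$ synmorph report experiment.json --outdir report
```

`report/report.json` then contains (excerpted):

- per-group SV counts: untreated 128.8 ± 2.1 (n = 30), low-dose
  76.8 ± 1.1, high-dose 32.7 ± 0.6 — a one-way ANOVA p ≈ 1e-63 and a
  74.6% high-zone reduction, recovering the programmed 75% depletion;
- dose–response regression of SV count on injection distance over the
  treated synapses: slope 0.174 SVs/μm, R² 0.69, p < 1e-15 — clusters
  shrink toward the injection site;
- NN-vs-AZ-distance slopes ordered untreated (0.037) < low (0.055) <
  high (0.071) with Holm-adjusted p-values — dispersal grows with dose.

Every table cross-references the thresholds used (`config` and
`provenance` blocks), and rerunning with the same dataset and
configuration reproduces the report byte-for-byte.

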