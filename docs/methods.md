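# Methods

## Statistical model

Scaling relations are fit as power laws on log-log axes,
log10(y) = b·log10(x) + c, by generalized least squares. Species are not
independent observations: under Brownian-motion (BM) trait evolution the
residual covariance of species i and j is proportional to Cᵢⱼ, the branch
length they share between the root and their most recent common ancestor.
The model used is

    ε ~ N(0, σ² V(λ)),   V(λ) = λ·C_offdiag + diag(C)

with Pagel's λ ∈ [0, 1] interpolating between phylogenetically independent
residuals (λ = 0, plain OLS on an ultrametric tree) and full BM covariance
(λ = 1). λ is estimated by profile maximum likelihood with a bounded scalar
search on [0, 1] (tolerance 1e-6), with both interval endpoints evaluated
explicitly since the optimum is often at a boundary. This matches common
comparative-methods practice (e.g. the default behavior of caper-style
PGLS). REML is not offered.

Inference choices that the PGLS literature leaves open and we fixed:

- CI and p-value for the slope from a t distribution with n − 2 degrees of
  freedom on the GLS standard errors (σ̂² = RSS_gls/(n − 2)).
- Adjusted R² from sums of squares in the whitened space: R² = 1 −
  RSS_gls/TSS_gls with TSS from the GLS intercept-only model, then the
  usual (n − 1)/(n − 2) adjustment.
- Exactly collinear data (zero residual variance) return the exact slope
  with a `degenerate_variance` flag, zero SEs and NaN p rather than an
  error; several analytic baselines are exact lines.
- Volumetric/area fits use log10 (the exponent is base-invariant;
  intercepts are base-10). Network-metric fits z-transform both sides
  ((value − mean)/SD across species, ddof = 1), so slopes are standardized
  β.
- Polytomies need no special handling: the covariance definition is
  topology-agnostic.

Reduced major axis (slope = sign(r)·SD(y)/SD(x)) is provided as the
symmetric-fit alternative; it refuses zero variance or zero correlation,
where its slope sign is undefined.

## Parcellation

"Evenly dispersed random regions" is operationalized as farthest-point
sampling: the first center is a seeded uniform draw over vertices, each
further center the vertex maximizing the minimum geodesic distance to the
centers chosen so far; vertices then join the nearest center, ties to the
lowest center index. Geodesic distance means shortest paths on the mesh
edge graph weighted by Euclidean edge length — exact on the graph and
adequate at parcel scale; Euclidean distance is available behind the
`metric` switch. The default resolution is 50 regions per hemisphere (25
and 100 supported). The right hemisphere receives the left labels through
the meshes' vertex bijection, making region r on the right the spatial
homolog of region r on the left.

## Connectomes and normalization

Density is observed connections over possible region pairs, computed per
hemisphere on intrahemispheric pairs. Before path length, clustering and
asymmetry are compared across species, every hemisphere is thresholded to
the minimum per-hemisphere density in the set by keeping its strongest-NOS
edges (ties at the cutoff: higher weight, then lexicographic node-pair
order). Thresholding by NOS rank is our choice of mechanism for the stated
goal of equal density; the density analysis itself uses unthresholded
networks.

Connection lengths are compared on a brain-size-normalized scale: 10 bins
spanning 0 to the anterior-posterior (AP) extent (the y-axis range of the
mesh bounding box; the AP axis is a configuration convention), each bin
10% of AP length, with connections longer than the AP extent placed in bin
10. Binning counts unique connections, not streamlines. The "short vs
long" contrast is bins 1–2 against bins 3–10.

Path length and clustering are binary metrics; each is normalized by the
mean of the same metric over degree-preserved Maslov-Sneppen rewired
reference networks (default 1000 per connectome; swap budget 10 attempts
per edge, counting attempts, rejecting swaps that would create self-loops
or multi-edges). Normalization is the ratio raw/null-mean, the
conventional small-world normalization; a z-score against the null is
recoverable from the recorded null mean and SD. Rewiring can disconnect a
graph, so path length averages over reachable pairs and reports the
unreachable fraction.

## Connectivity asymmetry

Within each hemisphere the m edge weights are mapped, rank-preservingly,
onto normal quantiles: the k-th smallest weight becomes
M + SD·Φ⁻¹((k − 0.5)/m), with M = 1, SD = 0.2. Resampling is applied per
hemisphere (not pooled per species), so both hemispheres end with
identical weight distributions and only rank/topology differences can
register; any common monotone rescaling of raw weights is therefore
irrelevant. A homolog pair's score is the mean |w_A(t) − w_A′(t′)| over
intrahemispheric targets connected in both profiles; pairs sharing no
connection are excluded from the species mean (rather than scored 0),
since the score is only defined on shared connections. A binary variant
scores 1 − |shared|/|union|. The permutation null shuffles weights among
existing edges within each hemisphere (topology fixed), recomputes every
species' total asymmetry and refits the standardized PGLS slope against
the trait; p = (1 + #{null β ≥ observed})/(1 + n_perm). PGLS (not OLS) is
used in the permutation refit for consistency with the main analysis.

## Synthetic data generator

The generator emulates the study conditions: 14 species, cerebral volume
log-spanning 2.5–900 cm³ (~350-fold), generating exponents 0.85
(surface~volume), 1.10 (WM~GM), 0.88 (CC~surface), with BM residuals whose
SD defaults to 5% of the predictor's SD. Log cerebral volume is a BM
realization on a Yule tree rescaled to the requested range; anchoring
intercepts place a galago-sized brain at ~11 cm² of surface, ~1 cm² of CC
per 90 cm² of surface, half the cerebrum as cortical gray matter and ~37%
as white matter. An `iid` noise model replaces the BM residual for
phylogenetic-signal calibration.

Surfaces are subdivided icospheres stretched into AP-elongated ellipsoids
(elongation 1.6, subdivision 3 → 642 vertices by default) scaled to the
species' surface area; the right hemisphere is the exact x-mirror with an
identity vertex correspondence.

Connectomes use an exponential distance rule: left-hemisphere edges are
selected with probability p(d) = min(1, c·e^(−d/d0)), d the centroid
distance and d0 the decay length, with c calibrated by bisection so the
expected density hits the target. The realized edge set is then fixed to
exactly round(target × pairs) edges by ranking pairs on u/p for seeded
uniform u, so the achieved density is always within one edge of the target
rather than only in expectation. NOS weights are a discretized lognormal
(log-mean 2, log-SD 1, floored at 1); the right hemisphere mirrors the
left topology and multiplies each weight by exp(a·N(0,1)) at asymmetry
level a (a = 0 is an exact mirror and scores exactly zero asymmetry).
Connection lengths are centroid distances, as no streamlines exist.

Size-dependence rules are (value at smallest, value at largest) pairs
interpolated linearly in normalized log volume. The "bottleneck"
configuration uses decay fraction 0.40 → 0.15 of AP extent, density
0.52 → 0.33 and asymmetry 0.02 → 0.35; the matched null
(`SpeciesSpec.bottleneck_off`) holds them at 0.25/0.40/0.15. Density
endpoints follow the observed galago-to-great-ape density range; the decay
and asymmetry endpoints are generator conventions chosen to produce a
clear, not extreme, size effect. One known saturation: at fixed density,
once the decay is strong enough the selected edges are simply the
shortest pairs, so further shrinking d0 changes nothing — the length-
distribution contrast between decay settings is weakly monotone at the
strong-decay end.

What the generator does not emulate: cortical folding, tractography error
(false positives/negatives), subject-level variation within species,
interhemispheric (callosal) edges, and any biological mechanism behind the
distance rule. Passing recovery tests on this generator demonstrates that
the pipeline estimates what it claims under its own model assumptions, not
that those assumptions hold in real diffusion MRI data.

## Pipeline

Stages run in methodological order: generate/load → density and length
bins (unthresholded) → density equalization → normalized metrics →
asymmetry (+ permutation null) → PGLS fits. Left and right hemispheres are
reported separately where applicable. Every sub-seed derives from the
master seed through named `SeedSequence` keys, so a config hash plus
master seed determines every output byte; the manifest records both, plus
all warnings (discarded streamlines, excluded homolog pairs). A metric
that is exactly constant across species (possible in the size-independent
null configuration, where density is fixed by construction) is reported
with β = 0 and NaN p rather than fit.

## Problem sizes in the test and acceptance suites

Simulation-based checks run at sizes chosen to make their statistical
criteria sharp while keeping the default suite quick: λ-endpoint recovery
uses 100 replicates × 100 taxa (median λ̂ separates the endpoints cleanly
at that size); exponent recovery uses 200 replicates × 14 taxa; CI
coverage uses 200 replicates × 50 taxa (λ-ML PGLS is known to undercover
at very small n, and 50 is a realistic comparative sample); end-to-end
sign recovery and the matched-null calibration use 10 master seeds × 14
species with 30 rewired nulls per hemisphere; the permutation-uniformity
check uses 30 repeats × 49 permutations on 8-species toy sets. The
pipeline defaults remain 1000 nulls and 1000 permutations.

The matched-null calibration is asserted per metric (each metric
non-significant at α = 0.05 in ≥ 8 of 10 seeds): with four metrics tested
jointly, even a perfectly calibrated procedure would fail an all-metrics-
at-once criterion in a substantial fraction of seeds by the 5% false-
positive arithmetic alone.

## Known limitations

- Streamline input is plain text (endpoint labels + arclength); TRK/TCK
  binary formats are out of scope.
- Weighted path-length/clustering variants, Ornstein-Uhlenbeck and
  early-burst covariance models, and FA-weighted networks are not
  implemented.
- `fit_pgls` takes one value per species; averaging multiple subjects per
  species is the caller's responsibility.
- Random parcels are not anatomically homologous across species; homology
  is only defined within species, between hemispheres.
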