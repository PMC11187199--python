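# Methods

## The spatial system

All analysis operates on bipolar channels: each channel has a coordinate
(the midpoint of its two contacts, mm, in a normalized template space) and
a per-segment interictal event rate in events/min. Excluded channels
(white matter, extra-cerebral, artifact) are carried in the data model but
never enter any computation.

Given a spatial reference channel, the *spatial system* is the set of
(log distance, log rate) pairs over all other included channels. Under
the working hypothesis that a well-sampled unifocal generator produces
rates decaying as `f = α·d^κ` (κ < 0), the system is linear in log-log
space and its Pearson correlation ρ is the goodness of fit of the
power-law hypothesis. Implementation details:

* Natural logarithms throughout. ρ and κ are base-invariant; the
  intercept α̃ = log α is base-dependent. Anyone comparing ρ̂ thresholds
  across implementations must fix the base first.
* The reference channel is removed from the point set (its distance is
  zero, so its logarithm is undefined).
* Channels with a rate of exactly 0 receive a floor of 0.1 events/min
  (configurable) so the logarithm is defined. The floor is added only to
  exact zeros — clamping would destroy the ordering of very small
  nonzero rates.
* ρ is undefined — represented as an explicit flag (`None`), never NaN —
  for fewer than 3 points or when either axis has zero variance.
  Downstream consumers decide how to handle it (the removal framework
  zero-substitutes; the ranked framework treats an undefined permuted
  correlation as 0 before differencing).
* Distances are Euclidean in template mm space; no geodesic or
  anatomical distance.
* Argmax reference selection breaks ties lexicographically on channel id
  so every run is deterministic.

## Virtual-removal framework

Per 10-minute segment: ρ_BR anchors the system at the maximum-rate
channel *inside* the marked SOZ; ρ_AR deletes every SOZ channel,
re-anchors at the remaining maximum, and re-measures; ρ_RR instead
deletes `round(0.2 · N_SOZ)` (at least 1) uniformly chosen non-SOZ
channels, 100 iterations, and takes the median — the control for pure
sample-size effects. Segments qualify only if their busiest channel
exceeds 1 event/min (strictly, "more than one per minute"); after SOZ
removal, if every surviving channel is below that rate the correlation is
set to exactly 0, since fits on near-silent recordings produce spurious
correlations. Per-patient values are medians over valid segments, and

```
ρ̂ = log(ν + |ρ̄_BR / ρ̄_AR|),   ν = 1 by default
```

is the perturbation strength. ν > 0 keeps the logarithm defined at ratio
0; being monotone it never changes patient ranking (asserted in tests as
Spearman 1.0 between ν = 0.5 and ν = 2). When ρ̄_AR = 0 with ρ̄_BR ≠ 0 the
ratio is capped at |ρ̄_BR|·10⁶ — an implementation constant that keeps ρ̂
finite while preserving "effectively infinite perturbation". Classification
uses the ROC operating point maximizing Youden's J (ties resolved toward
higher sensitivity); patients with ρ̂ at or above the threshold are called
well sampled. The AUC confidence interval is a 1000-resample patient
bootstrap.

## Ranked framework and the SP map

Without any SOZ information, the system is anchored at the unconstrained
maximum-rate channel (ρ_ref) and then re-anchored at every channel c_i in
turn; `P̂_i = 1 − (ρ_i − ρ_ref)`. Each permuted system excludes the global
reference channel from its point set so that the permutation measures the
spatial role of c_i rather than the leverage of the dominant channel; when
c_i *is* the global reference the two systems coincide and P̂ = 1 by
construction. Channel-wise medians over valid segments give P̄.

The perturbation centroid is the unweighted mean coordinate of channels
with P̄ at or above the 70th percentile (linear interpolation; the
inclusive comparison keeps the set non-empty under ties). The SP map
ranks channels by P̄ (descending — the convention that puts the strongest
channels at the top row, matching how the maps are read) against the
distance to the centroid, binned into 200 equal-width bins on
[0, max distance] per patient; bins are half-open with the last bin
closed. Each channel lights one pixel of intensity P̄; a single-pass
grayscale morphological closing with a 3×3 square element connects nearby
activations (the operator and element size are a design choice —
parameterized — since only "morphological transformations" is prescribed
by the approach this implements). A map whose channels are all coincident
with the centroid is flagged degenerate rather than binned.

Quadrants are numbered Q1 top-left, Q2 top-right, Q3 bottom-right, Q4
bottom-left, fixed by the requirement that a "good" (diagonal,
top-left → bottom-right) map have small Q2 and Q4. `quadrant_features`
returns the mean of strictly positive pixels per quadrant (0 when none).

## Cluster and probability model

The quadrant subset maximizing Dunn's index (standard definition:
single-linkage separation over maximum cluster diameter; a zero-diameter
clustering maps to +inf) under 2-means is selected from all subsets of
size ≥ 2, ties toward the smaller then lexicographically earlier subset.
On feature cohorts with an uninformative Q3 this selects (Q1, Q2, Q4).

The cluster model bootstraps k-means (k = 2, k-means++): each of 1000
iterations fits on 75% of patients (stratified by outcome when labels
exist), aligns the pair of centroids to the first iteration's by
minimal-displacement matching, and averages. The averaged centroid nearer
the feature-space origin is ĉ1 — the adequate-sampling cluster. Location-
scale Student-t distributions are fit by maximum likelihood (df ≥ 1;
normal fallback below 4 members) to the within-cluster distances to each
centroid. A patient's probability of adequate implantation combines the
upper tails: `p = (p1 + (1 − p2))/2` with `p1 = P(T1 > d(f, ĉ1))`,
`p2 = P(T2 > d(f, ĉ2))` — one admissible reading of "in cluster 1 but
not in cluster 2"; the combination rule is isolated in one function and
easily swapped. Nearest-centroid classification breaks exact ties
optimistically to well_sampled.

## Volumetrics

Channel sets are inflated to 5 mm radius spheres and the union volume is
counted on a 0.5 mm axis-aligned grid (voxel centers; the grid covers the
bounding box of the centers padded by the radius), reported in cm³ —
overlaps counted once. A single sphere reproduces the analytic volume
within 1% at the default resolution. Percent-SOZ-resected is
|SOZ ∩ Resected| / |SOZ| over per-contact atlas region labels (the
projection is an input); an empty SOZ set returns an undefined flag. The
incomplete-resection threshold is the 75th percentile (linear
interpolation) of resected-SOZ volumes among patients marked as
incompletely resected.

## Synthetic cohort generator

The generator is the package's study bench: protected clinical recordings
cannot ship, so every claim the tests make is about this generative
model, and its realism bounds what passing tests show about real data.

Geometry: 12 straight depth electrodes, 12 contacts at 3.5 mm spacing,
from random scalp-sphere entries (70 mm) toward targets in a central
25 mm ball → 132 bipolar channels, emulating a typical exploration.

Rates: expected rate `λ = α·max(d, 1 mm)^κ` from the strongest applicable
generator, with α = 30 events/min at 1 mm and κ = −1.5 by default (SOZ-core
channels then sit at realistic ~5–15/min); a per-channel log-normal factor
(σ = 0.3) shared across segments (so segment medians estimate a stable
spatial field); a spatially unstructured log-normal background (median
0.1 events/min — the typical non-SOZ channel rate — σ = 1.0) so recordings
are never silent; Poisson counts per 10-minute segment (5 segments per
patient). The 1 mm distance floor keeps the law finite at the source.

Scenarios: *well_sampled* places the source centrally among the electrode
targets (an implantation designed around the correct hypothesis), jittered
off a channel, with ≥ 3 channels inside the 12 mm SOZ radius; the marked
SOZ is the true one. Both poorly sampled scenarios keep every channel at
least 20 mm from the true source, so the implantation records *propagated*
activity: spatially extended secondary generators (sub-sources along one
electrode at 40–70% of α — *missed*, one region; or two well-separated
islands — *propagation*). The marked SOZ is then the 12 mm neighborhood of
the strongest recorded channel, as clinical marking would produce. The
extended propagated regions are essential: deleting the marked
neighborhood leaves structured activity behind, which is exactly the
phenotype that distinguishes a poorly sampled implantation (coupling
survives removal) from a well-sampled focus (coupling collapses). Under
these defaults the class medians of (ρ̄_BR, ρ̄_AR, ρ̄_RR) fall near
(−0.6, −0.2, −0.6) for well-sampled and (−0.4, −0.4, −0.4) for poorly
sampled patients, and ρ̂ separates the classes with AUC ≳ 0.9.

What the generator does **not** emulate: cortical anatomy and anisotropic
propagation, gray/white-matter channel exclusion, rate nonstationarity
across the night, and the patchy multi-region irritative zones of real
poorly-implanted patients. Two consequences worth knowing: a *single*
compact propagated island is indistinguishable from a genuine focus by
construction (the method's real blind spot — the generator deliberately
uses extended or multiple islands); and the missed-focus scenario yields
focal-*looking* SP maps, so map-based clustering separates well-sampled
from propagation patients but not from missed-focus patients — the
virtual-removal statistic is the discriminator for those, mirroring the
complementarity of the two frameworks.

## Numerical and testing choices

Problem sizes in the test suite and acceptance script — 20 + 20 patient
cohorts, 200-seed recovery experiments, 100-instance oracles — are chosen
to estimate each property stably while keeping a full run in a few
minutes on one CPU. All randomness flows from explicit seeds through
per-patient streams derived from the seed and a stable hash of the
patient id, so results are independent of cohort order and reruns are
byte-identical. The decay-exponent recovery experiment places 100
channels in a 2–10 mm shell so that Poisson counts stay well above the
zero-rate floor across the whole κ grid; at larger distances the floor
censors low rates and would bias κ̂ toward zero — a property of the
measurement, not of the estimator.
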