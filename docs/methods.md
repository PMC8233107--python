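# Methods

This note documents the models, numerical choices and limitations behind
`brainstates`. It describes what the code computes; every empirical claim
here is one the test suite or acceptance script computes itself.

## Synthetic study generator

`synthetic.generate_study` emulates a continuous block-design scanning
session: a fixed sequence of 3-minute condition blocks (rest, math, memory,
video — tasks presented twice), each preceded by a 12-second instruction
block, sampled at TR = 1.5 s. The default sequence places rest first and
video last so that cone-of-influence trimming (120 samples per temporal
edge) removes one whole rest and one whole video presentation while leaving
both math and both memory presentations intact for condition balancing.

Per condition, a fixed random partition assigns the regions to
`n_communities` (default 4) communities. Within a block, each community
shares a latent signal built as random-phase Fourier noise band-limited to
0.009–0.08 Hz — spectrally faithful to band-passed hemodynamic fluctuations
without modelling an HRF. The latent is scaled by

    gain = coupling_strength * (1 + performance_effect * (performance - 0.5))

so block-wise percent-correct performance modulates coupling around the 0.5
midpoint. Each volunteer applies an idiosyncratic mixing matrix
`I + idiosyncrasy_strength * G/sqrt(R)` (G standard normal) to the coupled
component, and AR1(φ = 0.4 by default) observation noise with unit marginal
SD is added region-wise. Instruction blocks carry no coupling (rest-like
filler).

Defaults are desk-scale: 6 volunteers × 60 regions × ~1024 samples
(≈ 25.6 min), coupling_strength 3, idiosyncrasy 0.5, performance_effect 1.
Task performances (0.90/0.55 math, 0.80/0.60 memory, 0.85/0.65 video)
straddle the mean split so each task has one high- and one low-performance
presentation. The magnitude of volunteer idiosyncrasy relative to condition
effects is not empirically constrained; both are exposed as free parameters
rather than asserting a ratio.

What the generator does *not* emulate: volumetric/NIfTI structure,
physiological noise, HRF variability, scanner drift, or realistic
inter-regional distance profiles. A green statistical test therefore
establishes that the machinery detects community-coupling contrasts of the
stated strength under AR1 noise — not that it would reach the same power on
real scans.

`ar1_surrogate` refits each region by method of moments (lag-1
autocorrelation, mean, variance) and emits an independent AR1 realisation;
it is the null model behind `coherence_significance_threshold`.

## Wavelet coherence TVFC

The CWT uses the complex Morlet kernel ψ(t) = e^{iω₀t/s} e^{−t²/2s²} with
ω₀ = 6 (spectral selectivity at maximal temporal resolution; a lower ω₀
would leave the kernel's nonzero mean above machine precision). Scales map
to frequencies via f = ω₀/(2πs), the Morlet approximate-center convention,
and the filterbank is log-spaced in frequency, endpoints included
(0.007–0.15 Hz, 15 scales). The kernel is discretised on ±4s support with
δt = TR and applied by zero-padded FFT convolution; the trimmed 120-sample
margins absorb the resulting edge artifacts.

The smoothing operator ⟨·⟩ in the coherence is a per-scale Gaussian in time
with standard deviation equal to the scale (in samples), followed by a
3-scale boxcar across scales — the conventional Torrence–Webster shape; the
window family and widths are configurable since only "smoothing in time and
scale" is canonical. Zero-power cells yield coherence 0 (logged). Coherence
exceeding 1 by more than 1e-6 raises; smaller excursions are clipped.

The broadband average weights R²ₜ(s) by the smoothed cross-wavelet power
|⟨s⁻¹Wₜˣʸ⟩| and normalises by the *sum* of weights. A max-normalisation of
the weights cannot keep an 11-term weighted sum of values ≤ 1 bounded by 1,
so the sum-normalised weighted mean is the only reading under which the
broadband coherence stays in [0, 1]; this is a deliberate design choice.
Edges are 1 − coherence; graphs are symmetric with zero diagonal by
construction.

The AR1 significance threshold is the lower quantile (default 0.05) of the
edge-distance distribution over independent AR1 surrogate pairs. Note the
direction: narrower smoothing *inflates* null coherence (with no smoothing
R² ≡ 1 identically), so the required coherence 1 − threshold falls as the
smoothing widens.

## Simplicial metric spaces

A state point carries three vectors: node topography (|CWT| over the 11
retained scales, region-major — the trimmed support, not all 15 scales),
edge weights (upper triangle) and per-region strength (weighted degree).
Node distance is Euclidean; edge and strength distances are weighted Jaccard
1 − Σmin/Σmax, with two all-zero vectors defined as distance 0 (identical
emptiness).

Edge/strength Jaccard operates on **coherence weights** (1 − distance) by
default, with a `weight_mode="distance"` toggle. Jaccard overlap semantics
("shared connectivity") and the known correlation between strength and
homological-cycle participation both read naturally on connectivity
intensity; the alternative is one flag away.

## Topological metric spaces

The Vietoris–Rips filtration K_r is the clique complex of the graph with
edges strictly shorter than r; equal filtration values are ordered
lexicographically so results are deterministic. H0 is computed as
single-linkage clustering (merge heights = death times, all births at 0,
exactly n − 1 finite classes plus one essential component) via scipy;
H1/H2 run an in-package Z2 boundary-matrix reduction with the clearing
optimisation, processing dimensions top-down with columns stored as
Python-int bitsets. A brute-force global-reduction oracle in the test suite
verifies exact agreement on hundreds of random metric spaces.

Essential (never-dying) classes are excluded from diagram comparisons: the
single essential H0 class is common to every diagram and carries no
contrast, and capping it at an arbitrary max radius would inject that
arbitrary choice into every distance. The essential count is retained on the
diagram object.

The sliced-Wasserstein distance augments each diagram with the diagonal
projections of the other's points, projects both multisets onto 20 *fixed*
evenly spaced directions in [−π/2, π/2), and averages the sorted-order l1
matching costs. Fixed rather than random slices keep the distance
deterministic. The all-pairs matrix pads diagrams to a common size with
diagonal points — adding the same diagonal point to both sides of a 1-D
transport problem leaves the cost unchanged — which lets the computation
batch into chunked vectorised sorts.

Computing H2 above a few hundred nodes is combinatorially explosive
(C(n,4) reduction columns); `vr_persistence` refuses n > 400 with
max_dim ≥ 2 unless forced. The end-to-end pipeline defaults to
node/edge/strength/H0 for the same reason; H1/H2 are first-class but opt-in
at scale.

## State space

UMAP runs in precomputed-distance mode (n_neighbors 15, min_dist 0.1,
seeded) on the embedding-training group only. umap-learn does not support
out-of-sample transform for precomputed metrics, so projection places each
new point at the inverse-distance-weighted mean of its n_neighbors nearest
training points' coordinates; a point identical to a training point lands on
its twin, and re-projecting the training set reproduces it to numerical
precision.

The density grid gives the axis with the larger coordinate range 256 pixels
and trims the other to keep pixels square. The Gaussian bandwidth per axis
is 0.08 × that axis' coordinate range (the bandwidth of a KDE on the
extent-normalised embedding). An SD-multiple reading of the same factor was
rejected empirically: at 0.08 × SD even a single n = 500 Gaussian cloud
fragments into > 100 watershed clusters, while the extent reading yields one
cluster per density mode and merges monotonically as the factor grows.
Watershed markers are the local density maxima (minimum separation of one
kernel SD in pixels), regions grow by steepest ascent on 8-connectivity, and
pixels below 1e-6 of the peak density stay unassigned (label 0). Points are
assigned the label of their containing pixel.

## Statistics

Volunteers split into three equal groups (embed / cluster / test); per draw,
one randomly chosen presentation each of math and memory is removed from
every volunteer to balance conditions, and 100 training points per
embedding-group volunteer are taken on an even temporal lattice with random
phase — a deterministic, seed-controlled reading of "maximal temporal
separation". The clustering/testing groups can be subsampled the same way
(`n_eval`) purely as a desk-scale cost control.

Permutation nulls shuffle point labels 300 times and summarise per-cluster
counts by mean and SD; p-values come from the normal summary by default,
with an empirical-rank mode available (which of the two the original
procedure used is not determinable, so both exist). Points outside every
watershed cluster are excluded from the tests. Corrections: volunteer
underrepresentation (left tail) at α/(V × clusters); stimulus enrichment
(right tail) at α/(conditions × clusters), with five conditions (rest,
math, memory, video, instruction); performance (two-tailed, within
task-significant clusters only) with mean-split valence where observed ≥
null mean counts as high. Cohen's d uses the pooled-SD formula; zero pooled
variance reports a signed infinity sentinel with a warning. All reported
percentages are computed on the test group only.

The bootstrap driver re-seeds and repeats the split/embed/segment/test cycle
(production convention: 256 reinitialisations; tests and the acceptance
script use 4–10 and say so), aggregating means and 95% normal CIs.

## Mean performance graphs

For each task and valence, every test point falling (in any draw) into a
cluster significantly valenced for that task contributes its TVFC graph —
once per draw in which it qualifies, so duplicates are allowed — and the
element-wise mean forms the mean performance graph. Cross-valence distances
reuse the weighted-Jaccard and sliced-Wasserstein operations verbatim (a
mock-based test enforces the call path). RMS/SD distances from each mean
graph back to its components quantify the centrality phenomenon: under edge
Jaccard the mean sits centrally among its components, under H0 it can sit
far from all of them.

## Known limitations

- Per-scale (multilayer) graphs are out of scope; coherence is collapsed to
  a broadband average before any distance is taken.
- The exact scale-grid convention and smoothing windows of the original
  procedure are not recoverable; retained-band endpoints therefore differ
  slightly from any particular published grid.
- H2 at 60 regions is minutes per graph stack in pure Python; a compiled
  persistence backend would be needed for full-scale H2 bootstraps.
- Statistical power at desk scale (6 volunteers, ≤ 60 regions, ≤ 10 draws)
  is far below a real 18-volunteer study; the acceptance checks are
  qualitative (ordering of metric spaces, type-I control), not quantitative
  reproductions of published percentages.
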