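# Methods

This note documents the models, estimators and numerical choices behind
`memdomain`, and what the synthetic-data generators do and do not emulate.

## Synthetic data: the study conditions

The generators are first-class, tested code; their defaults define the
conditions under which every recovery test runs.

**SMLM fields.** Cluster centers follow a homogeneous Poisson process
(default 5 clusters/μm²); member counts are Poisson (mean 10); member
positions are isotropic Gaussian around the center (σ = 30 nm); background
molecules are CSR (20/μm²). Each molecule produces k localization
appearances with k geometric on {1, 2, …} and mean α = 3.3 — equivalently
1 + a geometric number of re-appearances — because only the mean number of
appearances of this probe class is established; a geometric count is the
standard single-dark-state blinking kinetics. Appearance times start
uniformly in the acquisition (60,000 frames × 10 ms) and successive
appearances are separated by exponential dark gaps. The gap scale defaults
to 2 s: burst trains then span ≈ 5 s of the 600 s acquisition, so
end-of-acquisition truncation biases the realized α by well under 1%, which
the law-of-large-numbers test (1% at 10⁵ molecules) confirms. Every
localization adds isotropic Gaussian error (15 nm) and the cumulative stage
drift of its frame (linear by default, 0.001/0.0005 nm per frame ≈ 60/30 nm
total — under the ≤ 100 nm convention; a random-walk component is available
behind a flag). Three fiducial beads are emitted in every frame, flagged in
the output and independently discoverable by persistence.

Not emulated: camera frames and PSF fitting (localizations are synthesized
directly), multiple dark states, photoconversion, localization-precision
heterogeneity, sample-dependent background structure. Passing tests
therefore validate the estimators against the assumed point-process and
blinking model, not against raw-camera artifacts.

**FCS traces.** Brownian particles step with per-axis SD √(2DΔt) in a
periodic box (≥ 10 ω_xy); membrane (2D) particles stay in the focal plane;
detection weight is the Gaussian profile exp(−2r²xy/ω²xy)·exp(−2z²/ω²z);
an optional two-state triplet telegraph process gates emission (simulated
as a per-bin Markov chain, valid for bin_time ≲ τ_T/2); photon counts per
bin are Poisson. Steps equal the bin time (no sub-stepping); at the default
bin (0.2 ms) the step SD is 14 nm against ω_xy = 200 nm, inflating the
apparent beam waist by < 1%. Defaults are the membrane measurement
conditions: D_2d = 0.5 μm²/s, ω_xy = 0.2 μm, S = 5, 50 particles in a 2 μm
box, 30 kHz molecular brightness, 200 s.

**Calcium transients.** The true ratio is baseline_ratio before the
stimulus frame (default 4) and 1 + (amplitude/baseline)·s(t) after, with
s(t) rising linearly over 3 frames and decaying exponentially (20 frames).
The transient is split symmetrically between the channels (bound up,
unbound down, √g each) so that the channel product carries no transient —
mimicking interconversion of the two indicator forms — and both channels
bleach exponentially and carry additive Gaussian noise.

**GP ring images.** A Gaussian-profile ring (cell radius 5 μm, half-width
0.4 μm) with summed membrane intensity 1 split as (1±GP)/2 between the two
spectral channels, a dim interior, dimmer background, and additive noise.

## qSMLM estimators

**Drift.** Per-frame drift is the mean fiducial displacement from a
reference position, averaged over beads, interpolated over gaps and
smoothed with a centered 100-frame moving average. Two numerical details
matter: the reference is the bead's mean position over its first ~100
appearances (a single-frame reference imprints that frame's localization
noise as a constant offset on every frame), and the smoothing window
truncates at the series ends instead of padding (padding replicates one
noisy endpoint sample ~50 times). With three beads at 15 nm precision the
recovered trajectory is within ~2 nm RMS of truth; a noiseless fiducial
leaves < 0.001 nm.

**Photophysics.** On sparse fields, localizations are grouped by 100 nm
spatial linkage (exact KD-tree connected components); α is the mean group
size and the maximum dark time is the chosen quantile (default: maximum) of
within-group frame gaps. The quantile is exposed because the authors'
grouping threshold is not established. For drift/persistence detection on
dense tables the linkage uses grid-cell components instead — fiducial
tracks hold ~60k points and exact pairwise linkage is quadratic.

**Counting.** Molecules = localizations/α; fractional counts are kept.

**Pair correlation.** g(r) per 10 nm bin up to 500 nm is the observed pair
count over its CSR expectation, with the exact isotropized set covariance
of the square ROI (γ̄(r) = L² − 4Lr/π + r²/π) as edge correction — no Monte
Carlo. The model g(r) = 1 + A_psf·exp(−r²/4σ²) + A_c·exp(−r/ξ) combines
the correlated-blinking (PSF-scale) term with an exponential cluster term;
ξ is the reported cluster radius. Two numerical choices stabilize the fit
on per-cell data: bins are weighted by the Poisson standard error of their
pair count, and σ is fixed to the table's median localization precision —
repeat localizations of one molecule are spread by exactly that scale, and
leaving σ free lets the Gaussian term absorb the cluster peak when cluster
σ and precision are within a factor of ~2 (observed as occasional runaway
ξ on small fields). The "truth" against which ξ recovery is judged is the
same weighted fit applied to the analytic pair correlation of the
generating process (Gaussian cluster kernel of scale √(σ²c + σ²prec) plus
the blinking kernel), i.e. the estimator's infinite-data target; for the
default truth it is ≈ 31 nm.

**Molecule merging and clustering.** Localizations are merged into
molecules by spatiotemporal linkage (join the nearest open track within
100 nm whose last appearance is at most the maximum dark time ago).
Cluster assignment is k-means-like with a data-driven cluster count: seeds
are local maxima of a 2D histogram with bin = ξ (seeds closer than ξ are
coalesced — tied maxima otherwise split one physical cluster into two
sub-threshold halves), molecules attach to the nearest center within 2ξ or
stay unassigned, centers move to member centroids until stable. Only
clusters with more than four molecules are counted. Member counts use
α-division on the localizations inside the cluster rather than the number
of merged tracks: in a dense nanodomain the appearance bursts of different
molecules interleave inside the linkage window, so track counts
systematically under-count members (with 10 true molecules per cluster,
enough clusters fell below the >4 rule to bias clusters/μm² ~60% low);
localizations/α per cluster is unbiased against this failure mode and is
the same correction the density estimate uses. Merged-track positions are
still what gets clustered.

## FCS

The autocorrelation uses the definition G(τ) = ⟨I(t)I(t+τ)⟩/⟨I⟩² evaluated
exactly (per-lag dot products) on a multi-tau-style quasi-logarithmic grid
(16 linear channels, then half as many per octave at doubling spacing), per
20 s segment, averaged with the per-lag SD kept; this grid-with-exact-
evaluation matches the brute-force oracle to 10⁻¹⁰ by construction while
keeping the cost at O(n · n_lags). Segments with a monotone intensity drop
> 20% (10-block means, decreasing within 2% tolerance) are excluded as
bleaching; zero-mean segments likewise.

Fits are weighted least squares (weights 1/SD across segments, uniform
fallback for noiseless curves) through lmfit. Initial values: N from
1/(G(τ_min)−1), τ_D from the half-decay lag, F_T = 0.1, τ_T = 5 μs; bounds
F_T ∈ [0, 1), times > 0, S ∈ [1, 20]; parameters landing on a bound flag
the result, as does a violated τ_T < τ_D1 < τ_D2 ordering. The
two-component fit holds τ_D1 (default 213 μs, the free-probe value in
medium) and S (from calibration) fixed. Both models carry a free baseline
G_inf (default on): estimating ⟨I⟩ from a finite 20 s segment biases the
ACC tail low by ≈ 2∫(G−1)dτ/T — about 1% of baseline under the 2D membrane
conditions, enough to pull τ_D2 ~20% low if the baseline is pinned at 1.
On noiseless curves the offset fits exactly 1 and every round trip is
recovered to ≤ 10⁻³ relative.

Calibration follows ω_xy = √(4 D_ref τ_D,ref) with D_ref = 330 μm²/s for
the reference dye and ω_z = S·ω_xy. Derived quantities: ρ = (1−F₁)N/ω²xy,
CPM = I/N, D_membrane = ω²xy/(4τ_D2). Note ρ follows that conventional
definition verbatim; it differs from the geometric area density of the
simulation box by the beam-profile factor, which cancels in any
between-condition comparison.

## Ratiometrics

FRr is computed per frame with frames of non-positive unbound intensity
excluded; the baseline averages exactly the pre-stimulus frames (default
first 4). The "first maximum" is operationalized as the first frame at or
after the stimulus whose 3-frame-median-smoothed ratio exceeds its left
neighbor and is at least its right neighbor — the median filter flattens a
sharp peak into a two-frame plateau, and the filter pads with edge values
(zero padding fabricates spurious end plateaus). The amplitude is read from
the raw (unsmoothed) ratio at the detected frame. If no local maximum
exists the global post-stimulus maximum is used and flagged.

GP profiles locate the membrane jointly as the maximum of the summed
channels, so both intensities come from the same point; per-cell GP is the
arithmetic mean over (conventionally 4–10) positions. Line profiles are
bilinear at unit-pixel spacing, both channels at identical coordinates.
Ratio images are never formed; all ratios are computed on extracted
scalars.

## Statistics

The split-sampling sufficiency test permutes the values, splits them in
half (first half takes the extra element — fixed for determinism),
applies a two-tailed Welch t-test, repeats 15 times and reports the mean
p-value; sampling is "sufficient" at p_split ≥ 0.1. Degenerate splits
(zero variance in both halves) score p = 1 for equal means, 0 otherwise.
A structural caveat: because the halves are exchangeable draws from the
pooled sample, the between-half test is null-true by construction — the
per-split p-value is approximately uniform whatever the heterogeneity of
the input, so p_split concentrates near 0.5 and the test can confirm
sufficiency but has essentially no power to flag even a grossly bimodal
sample. The test suite documents this limit explicitly.

Group comparisons wrap scipy: Welch t (the qSMLM reporting test),
Mann–Whitney (exact where ties permit; fully tied identical samples return
p = 1 directly), one-way ANOVA with Tukey HSD pairwise adjustment.

## Pipeline

A run config (YAML/JSON) names conditions (label × ground-truth parameters
× cells), a control label and the analysis parameters. Per-cell seeds are
seed + 1000·condition + cell, so cohorts are reproducible and
parallel-safe; simulate mode writes byte-identical data directories for a
given seed (fixed CSV float formats), and re-analyzing unchanged inputs
reproduces identical tables. Metric tables are long-format per-ROI rows of
the four standard outputs; the report carries per-metric split tests,
comparisons against the control, and provenance (config hash, seed,
version). Stage failures raise errors tagged simulate/analyze/report, and
the CLI exits non-zero.

## Problem sizes in the test suite

Recovery tests run at the full study conditions for the SMLM field
(60,000 frames, 5-seed means) and the 200 s FCS membrane traces; the
cohort-level pipeline checks use smaller per-cell fields (4 μm, 5,000
frames) and 10-cell cohorts, and the pure-3D diffusion check uses a 5 s
trace at 5 μs bins — sizes chosen so the statistical assertions (3 SE
windows, fraction-of-seeds criteria) remain meaningful on a single CPU.

## Known limitations

* Cluster metrics near ROI edges are clipped, biasing clusters/μm² and
  molecules/cluster slightly low against the open-field truth (~10% at the
  default geometry); comparisons between conditions share the bias.
* The exponential cluster term is a phenomenological summary of the
  Gaussian-cluster truth; ξ is comparable across conditions but is not the
  cluster σ itself.
* The FCS simulator's telegraph triplet needs bins ≲ τ_T/2 and is
  impractical for long traces with microsecond triplets; triplet-model
  correctness is therefore established by round trips on analytic curves.
* No cross-correlation, anomalous diffusion, 3D localization, or absolute
  calcium calibration; vendor raw formats are out of scope (documented
  CSV/TIFF layouts only).
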