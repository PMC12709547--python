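# Methods

This note documents the models implemented in `tfcausal`, the parameter
choices that matter, what the synthetic generator does and does not
emulate, and the numerical decisions taken where the design was open.

## Time–frequency substrate

All connectivity is computed from complex Morlet coefficients of
multi-trial parcel data (`mne.time_frequency.tfr_array_morlet`, L2-
normalized wavelets, zero-mean). Defaults: 4–40 Hz in 1-Hz steps, analysis
grid decimated to 10-ms steps over a −200…1100 ms epoch, number of cycles
= f/2. The f/2 rule makes the wavelet duration n_cycles/f equal to 0.5 s
at *every* frequency — constant temporal smoothing (Gaussian SD
1/(4π) ≈ 80 ms) and proportionally finer spectral resolution at higher
frequencies. Each `TimeFreqRep` carries a `valid_mask` flagging time
points within half a wavelet support (250 ms) of an epoch edge; downstream
statistics include edge points by default (the full epoch is analyzed) but
the mask supports sensitivity checks.

Cross-spectra are ensemble averages across trials only, S_xy(τ, f) =
⟨W_x W_y*⟩, preserving full time resolution; block matrices are
symmetrized to exact Hermitian form and checked positive semidefinite
(eigenvalue tolerance 1e-10 relative).

Frequencies below 4 Hz are excluded by design: at a 1.3 s epoch there is
no room for slower wavelets.

## Phase slope index

PSI uses the *vertex-averaged* parcel time course per trial (one channel
per parcel); coherency is the normalized cross-spectrum, and PSI(τ) sums
Im{C*(f) C(f+Δf)} over band bins, excluding the top bin (the f+Δf partner
of the penultimate bin is the top bin itself). Sign convention: with
S_xy = ⟨W_x W_y*⟩ and y lagging x, the coherency phase is +2πfd, so
positive PSI means the first argument (seed) leads. PSI is left
unnormalized by its standard deviation — the band sum itself, as defined —
so magnitudes are comparable only within one analysis.

Band edges are inclusive on both sides (theta 4–7, alpha 7–13, low beta
13–20, high beta 20–30, low gamma 30–40, broadband 4–40 Hz); a bin sitting
on a printed boundary belongs to both adjacent bands. Consequently the
broadband bin-pair set equals the union of the narrow-band pair sets.

PSI time courses are baselined by subtracting the −200…0 ms mean, per
subject and band, before group statistics; window means are reported for
the early (100–400), middle (400–700) and late (700–1100 ms) windows.

## Spectral Granger causality

GC uses vertex-level channels. Both parcels of a pair are PCA-reduced to a
*common* rank (unequal ranks bias the measure asymmetrically): `"auto"`
picks the smallest rank in 5…7 explaining ≥95% variance in both parcels,
clipped to the available vertex count (desk-scale data with 3 vertices per
parcel run at rank 3). Projections are fitted on trial-concatenated data
pooled across conditions, so condition contrasts are not confounded by
condition-specific projections (a per-condition refit is available via the
`fit_x`/`fit_y` arguments).

Per analysis time point τ:

1. **Spectrum → autocovariance.** The 4–40 Hz spectral matrix is embedded
   in a full DFT grid (N = sfreq/Δf bins): missing bins below/above the
   band (including DC and Nyquist) are filled with the nearest in-band
   value — the band-pass regime of the data makes out-of-band power
   approximately flat at the band-edge level — negative frequencies mirror
   by conjugation, and the inverse DFT gives G(k) for k = 0…2p (max lag
   twice the VAR order, a standard safety factor). Imaginary residuals
   above 1e-8 relative are treated as a Hermitian-symmetry violation and
   rejected.
2. **Autocovariance → VAR.** Whittle's multichannel Levinson recursion
   solves the block Yule–Walker equations at order p = 20. Singular or
   unstable intermediate solutions trigger escalating diagonal loading
   (ε·trace/dim, ε from 1e-12 up); persistent failure raises rather than
   returning a silent result. Order 20 at 200 Hz spans 100 ms of history,
   comfortably covering the injected 25-ms interaction lags.
3. **VAR → spectral GC.** H(f) = (I − Σ A_k e^{−i2πfk/fs})⁻¹,
   S = HΣH^H, and Geweke's measure with the partial residual covariance
   Σ_yy|x = Σ_yy − Σ_yx Σ_xx⁻¹ Σ_xy. Determinants are evaluated on
   symmetrized Hermitian matrices via `slogdet`.
4. **Time reversal.** G(k) → G(k)ᵀ at every lag (the autocovariance of
   the time-reversed process), refit, re-evaluate. Corrected GC is the
   difference (original − reversed); net GC is the difference of the two
   corrected directions. Corrected values are legitimately negative when
   the causal asymmetry favors the opposite direction — in a strictly
   unidirectional x→y system the reversed measure concentrates in ỹ→x̃,
   driving corrected y→x strongly negative.

The per-time-point estimation from trial-averaged wavelet spectra (rather
than sliding-window time-domain VAR fits) is the key reconstruction
choice: it matches the τ-indexed spectral matrices the rest of the
analysis uses and inherits the wavelets' uniform temporal resolution. Raw
GC values at τ therefore integrate information from roughly ±160 ms of
data, and effect onsets/offsets in GC maps are smoothed accordingly.

GC maps (net and both corrected directions) are baselined like PSI before
group statistics.

## Cluster-based permutation statistics

Group inference is a one-sample t test per point (paired contrasts enter
as difference maps), clusters formed from sign-consistent suprathreshold
points — runs on 1-D time axes, 4-connected components on time–frequency
grids, graph components on parcel domains with a supplied edge list — and
scored by mass (summed t). The null flips each subject's map by a random
sign; when 2^n ≤ n_perm all assignments are enumerated (exact,
deterministic, invariant to subject ordering), otherwise 5000 draws with
replacement. Cluster-forming thresholds follow the analysis conventions:
t > 1 for whole-cortex maps (moderate, spatially distributed effects),
t > 2 for pairwise tests and condition contrasts.

Two-tailed convention: the default null statistic is the maximum |mass|
over both signs, which controls family-wise error without doubling.
A structural caveat at small n: every sign assignment is paired with its
complement, which mirrors the t map exactly, so the smallest attainable
two-sided p is 2/2^n (0.0625 at n = 5). Directional hypotheses — is there
a *positive* cluster in the feedforward window? — are therefore evaluated
with the one-tailed variants (`tail="pos"`/`"neg"`, per-sign max-mass
null, minimum p = 1/2^n). The pipeline stores both.

Cluster-guided summaries project each significant time–frequency cluster
onto its time window and frequency band; overlapping same-sign extents
are replaced by their intersection. Post-hoc one-sample and paired t
tests on windowed averages are Benjamini–Hochberg corrected.

## Synthetic ground truth

The generator emulates the structure of an event-related reading
experiment: four conditions of 150 trials (desk-scale pipeline default:
30), epochs −200…1100 ms at 200 Hz, two latent sources (seed "vOT",
target "ST") with directed lagged coupling switched on inside specified
windows with 20-ms cosine ramps, vertex-level mixing (3 vertices per
parcel, tapered gains, distance-decaying cross-parcel leakage), and white
vertex noise at SNR 1 — the same signal-to-noise regime assumed for
single-trial source estimates.

Default condition schedules mirror the qualitative study findings:
feedforward coupling vOT→ST at 100–400 ms in every condition, with
strength decreasing in word-likeness (0.8 / 0.7 / 0.6 / 0.5 for RW / RL1 /
RL2 / RL3-like — the real-word-like condition has the strongest
feedforward sweep); feedback ST→vOT at 400–700 ms (strength 0.8) for the
least word-like condition, late feedback at 700–1050 ms for the most
word-like one, and a weak (0.3) mid-to-late trend in between. Sources are
AR(2) damped oscillators at a requested carrier band, or white
("broadband", the default — matching the band-pass-then-analyze regime).
Stability of the implied time-varying VAR is asserted at generation
(companion spectral radius < 1 at full coupling), and unstable requests
are rejected naming the offending coupling.

"Subjects" are independent replicates with a truncated Gaussian random
effect on coupling strength (SD 0.15, floor 0.2), giving
group t statistics genuine between-subject variance. All randomness flows
from one master seed through hierarchically spawned generators (per
subject / condition / parcel), so any subset is reproducible bit for bit.

A trial-latency jitter parameter exists (`jitter_ms`) but defaults to 0;
real evoked responses jitter, and turning this on is the first sensitivity
check a user should run.

**What passing tests do not show:** the generator's leakage is linear
static mixing with white noise — it does not emulate correlated noise,
inverse-operator spatial structure, nonstationary background rhythms, or
inter-subject anatomical variability. Recovery results here demonstrate
the estimator chain is correct, not that real-data effect timings are
recoverable at these sample sizes.

## Validation studies (what `scripts/acceptance.py` measures)

- **Stimulus distances** of the four published condition examples (0–3).
- **PSI analytics**: exact antisymmetry under pair swap; zero PSI for
  identical signals and zero-lag common-source pairs; positive PSI for a
  pure-delay leader matching a brute-force band-sum evaluation.
- **GC oracle agreement**: 20 random stable bivariate VAR(2) models
  against an independent impulse-response/partial-covariance oracle
  (agreement ~1e-14, asserted < 1e-6) and Geweke's spectral–temporal
  integral identity (< 1%).
- **Time-reversal control**: with two uncoupled channels observing a
  common 10-Hz source at unequal noise (SNR ≈ 1 vs ≈ 0.4), raw GC exceeds
  the matched symmetric-noise null threshold in ~100% of simulations;
  |corrected GC| in < 10% (it is unbiased under this confound; the null
  threshold is the 95th percentile under symmetric noise at the
  geometric-mean level).
- **Recovery**: the 5-subject × 30-trial pipeline finds a significant
  positive net-GC cluster overlapping the injected feedforward window
  (temporal Jaccard ≈ 0.6–0.9 across seeds) with no spurious negative
  cluster, and a significant negative cluster overlapping the injected
  feedback window.
- **Calibration**: family-wise type-I rate of the sign-flip cluster test
  on pure-noise maps (200 repetitions × 500 permutations) within the
  binomial 95% interval around 0.05.

## Stimulus module decisions

Distance variant: *restricted* Damerau–Levenshtein (optimal string
alignment) — the common convention. It is deliberately not a metric: the
triangle inequality fails (e.g. CA→ABC costs 3 though CA→AC→ABC costs 2);
tests pin this rather than asserting a false property. Pseudoword
generation replaces letters at exactly k positions (length-preserving),
verifies the resulting distance is exactly k (adjacent substitutions can
collapse into a cheaper transposition), and requires every *other* lexicon
word to be farther than k; the search order over (positions, letters) is
seed-randomized, the alphabet defaults to the letters present in the
lexicon (diacritics included, case-sensitive), and an unsatisfiable
constraint raises naming the blocking words — dense neighborhoods
genuinely admit no solution at times. The uniqueness *checker* uses the
full distance (transpositions included) while the *generator* proposes
substitutions only; both are exposed since the stricter check is the
conservative choice.

## Known limitations

- Pairwise block GC only; no conditional (multi-region-partialized) GC.
- The spectrum→autocovariance step assumes negligible out-of-band power;
  strongly colored out-of-band spectra would bias the VAR fit (use an
  appropriate band-pass upstream).
- Per-time-point VAR fits are independent across τ; no state-space
  smoothing across time points.
- Desk-scale group tests at n = 5 rely on exact enumeration of 32 sign
  assignments; p-values are correspondingly coarse (multiples of 1/32).
- The PSI and GC branches share the wavelet substrate, so their temporal
  resolutions are identical, but PSI uses vertex-averaged signals and GC
  vertex-level ones — their magnitudes are not directly comparable.
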