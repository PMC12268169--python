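# Methods

`ricstf` implements bulk-level raster image correlation spectroscopy
(RICS) and cross-correlation RICS (ccRICS) for quantifying the nuclear
concentration, mobility, and chromatin-binding fractions of fluorescently
tagged transcription factors, together with the thermodynamic equilibrium
dose/response model that links total nuclear concentration to DNA-bound
concentration.  Because real two-channel embryo movies are large and not
generally available, the package ships a raster-scan image simulator with
full ground truth; every stage of the analysis is validated against it.

## The RICS model

A raster-scanned confocal image hides two time axes: adjacent pixels along
a line are separated by the pixel dwell time τ_p (≈2 µs) and adjacent
lines by the line time τ_ℓ (≈5 ms).  The spatial autocorrelation of the
intensity fluctuations δI = I − ⟨I⟩ over pixel lags (Δx, Δy),

    G(Δx, Δy) = ⟨δI(x, y) δI(x+Δx, y+Δy)⟩ / ⟨I⟩²,

therefore mixes spatial structure (the PSF) with temporal decorrelation
(diffusion).  For free diffusion with diffusivity D through a 3D Gaussian
PSF with lateral/axial 1/e² radii w0, wz, the normalized correlation is

    G_n(Δx, Δy) = (1 + 4Dτ/w0²)⁻¹ (1 + 4Dτ/wz²)^(−1/2)
                  · exp[ −Δr²(Δx² + Δy²)/w0² / (1 + 4Dτ/w0²) ],

with τ = |τ_p Δx + τ_ℓ Δy| the time separation of the pixel pair and Δr
the pixel size.  The absolute value makes the kernel symmetric under
(Δx, Δy) → (−Δx, −Δy), as an autocorrelation must be.  The amplitude A
multiplying G_n is inversely proportional to the mean number of
independent fluorescent particles in the observation volume.

### Two-step fitting

1. **Fast axis.** Along Δy = 0 the time separation is microseconds, so
   diffusive decay is negligible and the cut is fitted with
   `A·exp(−Δr²Δx²/w0²) + B`.  The zero-lag bin is excluded (it carries
   uncorrelated detector shot noise), |B| is constrained below 10⁻³, and
   w0 may move ±30% from its configured value.  This yields an accurate
   amplitude A.
2. **Full surface.** Holding A fixed, the 2D surface is fitted with
   `A·[φ·G_imm + (1−φ)·G_n(D)] + B`, where G_imm is the D = 0 kernel
   (pure Gaussian).  The weight φ ∈ [0, 1] is the immobile fraction; the
   slow-axis decay determines D ∈ [0.01, 100] µm²/s.  The fit uses
   bounded least squares from 8 random starts (D log-uniform, φ uniform);
   the best residual wins and residual ties break toward the smaller D.

### Concentration conversion

With the illumination shape factor γ = 2^(−3/2) of a 3D Gaussian beam,
N = γ/A counts molecules in the observation volume
V_obs = γ·π^(3/2)·w0²·wz (= (π/2)^(3/2) w0² wz at the default γ), and
C = N/(N_A·V_obs).  This pairing is exact for the simulator's detection
profile exp(−2r²/w0² − 2z²/wz²): the zero-lag fluctuation amplitude of a
uniform solution of concentration c is analytically 1/(c·π^(3/2)w0²wz),
so the conversion recovers c with no residual γ factor.  Setting γ = 1
reproduces the alternative convention V_PSF = π^(3/2)w0²wz.  γ and the
PSF radii are configuration, not constants; the package default
w0 = 0.25 µm, wz = 1.5 µm is typical of a high-NA water objective and
must be replaced by a bead calibration for real data.

### Cross-correlation and the active fraction

The two-channel cross-correlation surface of a green-tagged factor
against a red chromatin label (His2Av-RFP) is fitted with a displaced
Gaussian `A_cc·exp(−((ΔrΔx−Δx₀)² + (ΔrΔy−Δy₀)²)/w0_avg²) + B`, with
w0_avg² = (w0_g² + w0_r²)/2 and the lateral channel displacements Δx₀,
Δy₀ free (the co-bound pool is chromatin-associated, hence the immobile
kernel; a diffusive cross kernel is available behind a flag).  The axial
displacement Δz₀ cannot be seen in a 2D fit; it attenuates the cross
amplitude by exp(−2Δz₀²/(wz_g²+wz_r²)), which follows from the overlap
integral of two axially displaced Gaussians.  Δz₀ is calibrated from
two-channel bead z-stacks (per-bead 3D Gaussian fits, aggregate over
beads after dropping >3 MAD outliers) and the reciprocal factor
multiplies A_cc.  For a typical 0.1–0.2 µm displacement the factor is
≈1.01–1.02.

The active fraction is ψ = A_cc/A_red, the fraction of green molecules
co-moving with the red label, with A_red the red-channel fast-axis
amplitude.  With matched observation volumes this ratio equals
⟨N_cc⟩/⟨N_green,tot⟩ and is invariant to the detector gain of either
channel.  Pools then follow by construction: C_immobile = φ·C_tot,
C_active = ψ·C_tot, C_free = (1−φ)·C_tot, C_inactive = (φ−ψ)·C_tot.
When fit noise produces ψ > φ the record is flagged and C_inactive set
to 0 rather than negative.

## Preprocessing

Movies are split into groups of 7–12 frames (default 10; a trailing
remainder below 7 is redistributed so all groups stay within range — the
only impossible total, 13, rides in the final group).  Background is
estimated per group-average frame by locating the low-intensity mode of
the pixel histogram (smoothed, prominence-filtered peak search, then a
Gaussian fit to the mode core); a bright unimodal image falls back to
the 1st percentile.  Nuclei are segmented on the average frame with a
standard watershed recipe — Gaussian smoothing (σ = 2 px), Otsu
threshold with a contrast guard against pure-noise splits, distance
transform, h-maxima seeds (h = 10% of the distance maximum), watershed,
minimum area 500 px — and the mask is reused for every member frame.
Static structure is removed per group ("detrending"): each member frame
has the group-average frame subtracted pixelwise and the scalar nuclear
mean added back.  The correlation mask is eroded by 2 px to avoid edge
gradients.

Subtracting an n-frame mean from temporally uncorrelated frames scales
the fluctuation ACF by (n−1)/n; group-averaged surfaces are rescaled by
n/(n−1) to undo this.  The correction is exact for the free pool and
approximate for the quasi-immobile pool.

Masked correlation is computed with zero-padded FFTs of the masked
fluctuation image, normalized per lag by the autocorrelation of the mask
(the count of valid pixel pairs), which makes the estimator exactly
equal to the direct double-sum definition for arbitrary mask shapes; a
literal direct-sum oracle is part of the package and the test suite
checks equality to 10⁻¹⁰.  Lag bins supported by fewer than 100 pairs
are set to missing.

## Brightness analysis

For an analog detector the shot-noise variance grows linearly with the
mean signal; the slope is the S-factor.  Per group the package records
the mean nuclear intensity I, the nuclear pixel variance σ², and the
zero-intensity variance σ₀² (lowest-intensity pixels).  Apparent
brightness is B = (σ² − σ₀²)/I; shot noise is σ² − A·I² (the molecular
term removed using the group's fitted amplitude); S is the OLS slope of
shot noise against intensity (intercept free, for robustness).
Molecular brightness Q = (B − S)/S is concentration-independent.  If Q
rises above its reference level — e.g. bright multi-molecule assemblies
("hubs") — amplitudes and immobile fractions are inflated; the
correction divides both by q(t) = Q(t)/Q_min (floored at 1), where
Q_min is the maximum Q inside a user-designated reference window, so
points within the window are never corrected.  The exact algebraic form
of the Q(B, S) and correction relations follows the convention that
q = 1 is the identity and corrections can only reduce A and φ; both are
isolated in single functions so an alternative convention is a one-line
change.

## Equilibrium binding model

Bound pools follow Hill isotherms
C_bound = C_B·C_free^n/(K_D^n + C_free^n) with capacity C_B and
dissociation constant K_D; an "active" pool (co-localized with the
transcriptionally competent chromatin marked by His2Av) and an
"inactive" pool are tracked.  Conservation
C_tot = C_free + C_active + C_inactive is strictly increasing in
C_free, so C_free is found by bracketed bisection on [0, C_tot] to
10⁻¹⁰ nM (vectorized; conservation then holds to machine precision).
Hill coefficients default to 1, with n = 2 available for sigmoidal
inactive pools.  For a factor whose accessible active sites shrink as
chromatin compacts (Zelda-like), the active capacity can follow a power
law C_B,a = a·C_free^k (defaults a = 420, k = 0.7) instead of a
constant.

Fitting minimizes observation-normalized squared residuals of
(C_active, C_inactive) across dose/response records; normalization by
the observed values is used because the measurement noise is
multiplicative, so relative errors are homoscedastic.  Parameters are
fitted in log₁₀ space from 20 log-uniform multistarts.  Records from
excluded cycles (default: nuclear cycle 10, too short to equilibrate)
and the first m = 2 points of each cycle (equilibrium not yet
established after mitosis) are dropped before fitting; both are
configuration since cycle labels are user-supplied metadata.

Auxiliary calculators: accessible-site concentration
L = ploidy·n_sites/(N_A·V); K_D back-out from a single measured
occupancy, K_D = C_free(L − C_bound)/C_bound; the accessible-site time
course by inverting the n = 1 isotherm,
C_B(t) = C_active(t)(K_D + C_free(t))/C_free(t), converted to site
counts with a per-cycle nuclear-volume table (only the cycle-11 volume,
435 µm³, is well established; other cycles are user-supplied and the
counts marked approximate); and diffusion-limited kinetics
k_on = 4πDba (converted to nM⁻¹s⁻¹) with residence time τ = 1/(k_on·K_D).

## The simulator

The generator produces what the analysis assumes: disk-shaped nuclei
(default four disks of radius 60 px) whose particles are confined to
cylinders (radial reflection at the rim, specular reflection at
±z_half = 2.5 µm); a 3D Gaussian detection profile; raster timing with
the reference acquisition's values (pixel 31.95 nm, dwell 2.06 µs, line
4.94 ms); and an analog detector adding Gaussian noise of variance
`read_noise + S_true·signal` on top of a constant offset, rounded to
non-negative integers.  Defaults: S_true = 400, read noise variance
100, offset 50 counts, particle brightness 1500 counts/dwell.  The
brightness default keeps the signal well clear of the detector's
zero-clipping floor (mean ≫ 2.5 noise SD); at much lower signal levels
clipping of the analog noise distorts second moments, which is a
detector-saturation regime, not a failure of the estimators.

Positions advance once per scan line: at D ≈ 2 µm²/s a particle moves
well under a pixel within one line's pixel dwells, so the fast axis is
PSF-dominated, exactly as the fast-axis fit assumes.  Three species
exist per channel: free diffusers; quasi-immobile binders — a two-state
Markov process, strictly immobile while bound (mean dwell 1/k_off),
diffusing while unbound (mean dwell 1/k_on, default k_on = 19·k_off,
i.e. 95% duty) — and cobound binders rendered in both channels with the
red image displaced by the configured channel-registration offset.

The binder dwell default is k_off = 1/frame_time.  This sits in the only
window where the analysis can see the bound pool at full weight: the
dwell must exceed the slow-axis correlation window (max_lag·τ_ℓ ≈
0.16 s) so the bound contribution has the immobile kernel's shape, yet
successive frames (≈1.3 s apart at 256 rows) must sample nearly
independent binding configurations so the group-average detrend removes
the bound pool no more than the 1/n it removes from the free pool.
Slower exchange (several frames per dwell) leaves bound structure in
the group average, and subtracting it destroys 30–50% of the bound-pool
amplitude — the measured immobile fraction then understates the truth
substantially.  Real embryo data with residence times of tens of
seconds live in that lossy regime; simulator runs with slow `k_off_s`
reproduce it, and measured φ should then be read as "post-detrend
quasi-immobile fraction", not total bound fraction.

What the simulator does not emulate: photobleaching, triplet blinking,
mitotic chromosome dynamics, nuclear import/export (concentrations are
stationary within a movie), embryo-scale geometry, or nuclear-cycle
structure (cycle labels are metadata).  Passing recovery tests therefore
demonstrate correctness of the estimators under the model's own
assumptions, not robustness to these real-data effects.

## Numerical choices and problem sizes

- Default analysis surfaces use lags Δx ∈ [−32, 32], Δy ∈ [0, 32]
  (auto; negative Δy is redundant) or Δy ∈ [−32, 32] (cross; a channel
  displacement breaks the symmetry).
- Auto fits exclude (0, 0); cross fits include it (detector noise is
  independent between channels).
- Amplitudes below 3× the fit residual are flagged (auto) or set to
  zero (cross, "no detectable co-binding").
- The validation suite runs desk-scale problems: 256×256 movies of 30
  frames in 3 groups for end-to-end recovery (median over 5 seeds),
  96–128 px single-nucleus movies for unit-level checks, and 30-record
  synthetic dose/response sets for the binding fit.  These sizes were
  chosen so the full suite completes on one CPU in minutes while every
  stated tolerance retains a clear margin.

## Known limitations

- Concentration and φ estimates carry a small residual bias (few
  percent) from PSF truncation at the nuclear rim and from the
  approximate moving-average correction for the quasi-immobile pool.
- The power-law active-capacity fit has a strong K_D–a trade-off;
  single-fit K_D estimates scatter widely and should be reported as
  medians over replicates.
- The watershed recipe is tuned for blastoderm-like fields of similar
  disk-shaped nuclei; densely packed or highly aspherical nuclei will
  need parameter changes.
- Site-count time courses depend linearly on the per-cycle nuclear
  volume table, which is approximate outside cycle 11.
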