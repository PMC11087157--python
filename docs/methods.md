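# Methods

## Scope and pipeline

`icmreduce` implements a CNR-preserving contrast-dose planning chain for
CT: **simulate** (synthetic phantom volumes) → **measure** (insert and
background ROIs, CNR) → **fit** (zero-intercept CNR-vs-concentration slope
per stratum) → **plan** (slope-ratio equivalence and percent ICM
reduction), plus a **patient** module for worked-example arithmetic on
printed ROI statistics. A *stratum* is one (scanner, mode, energy, phantom
size, reconstruction) combination; all comparisons are made within a
phantom size, at matched dose.

## Iodine contrast coefficient

κ(E), the HU added per mg/mL of dissolved iodine at photon energy E, is
computed from iodine and water mass-attenuation coefficients under the
dilute-solution approximation:

κ(E) = 1000 · [(μ/ρ)_I − (μ/ρ)_w] / [(μ/ρ)_w · ρ_w] · 10⁻³, with ρ_w = 1 g/mL.

A small reference table (40–150 keV, standard published values, entirely
above the iodine K-edge so log–log interpolation is valid) ships with the
package; users may substitute their own. The planner's domain is
40–140 keV. Typical values: κ(40) ≈ 81, κ(50) ≈ 53, κ(70) ≈ 25,
κ(140) ≈ 4.4 HU/(mg/mL).

Polychromatic SECT beams are mapped to one configured *effective*
monochromatic energy per kV station (defaults: 70→48, 80→52, 100→58,
120→65, 135→69, 140→70 keV) and reuse the same κ curve. No spectral model
is attempted: the framework only needs a monotone contrast–energy
response, and the mapping is configuration, not measured truth. A
consequence worth knowing: against the 120 kV baseline (effective 65 keV),
VMIs above ~65 keV correctly show *negative* reductions (they would need
more iodine) because the simulator holds noise constant across energies.

## Synthetic phantom simulator

Two phantom families mirror the emulated two-part study design:

* SECT family — elliptical abdomen bodies (aspect 1.25) with effective
  diameters 9.7, 15.9, 21.1, 28.5 cm; five 13.1 mm iodine rods
  (2, 5, 10, 15, 20 mg/mL; four peripheral, one central); soft-tissue
  background (35 HU default); z = 150 mm.
* DECT family — a 20 cm solid-water circle and elliptical bodies (aspect
  1.35) of effective diameters 29.5, 34.6, 39.7 cm; four 28.5 mm inserts
  (2, 5, 10, 15 mg/mL) on a 60 mm ring; water background (0 HU);
  z = 165 mm.

Voxel values: air (−1000 HU) outside the body, background HU inside,
background + κ(E)·c inside each insert, plus i.i.d. Gaussian noise on body
voxels. Voxels are classified by their centre (no partial-volume
weighting) because measurement ROIs erode insert edges anyway. Volumes
are deterministic given (spec, acquisition, models, grid, seed); child
seeds are sha256 hashes of the stratum labels with the top-level seed, so
adding a volume to a suite never perturbs the others.

**Noise model.** σ(d, CTDIvol, recon) = σ_ref · exp(k·(d − d_ref)) ·
sqrt(CTDIref/CTDIvol) · f_recon, defaults σ_ref = 10 HU at d_ref = 20 cm
and 10 mGy, k = 0.09 /cm (noise doubles roughly every 8 cm of water at
abdominal effective energies), f_recon ∈ {sbir: 1.0, dlr: 0.6, ir: 0.9}.
The per-size default doses (1.5–10 mGy paediatric→adult SECT; 10–35 mGy
adult DECT) are plausible clinical values. All of these constants are
stand-ins chosen once on physical grounds — the emulated study published
no phantom noise or HU figures — and are configuration, never presented as
measurements. The default study plan omits 70 kV for the two largest SECT
bodies, mirroring the tube-output limit of the emulated protocol.

**What the simulator does not emulate:** beam hardening and other
artifacts, projection/reconstruction physics and noise texture/correlation
(noise is white here; real IR/DLR changes texture, not just magnitude),
automatic exposure control, partial volume, DECT material decomposition.
Passing tests therefore demonstrate the *statistical* correctness of the
measurement–calibration–planning chain under the assumed model, not
scanner-specific reduction percentages, which depend on hardware.

## CNR measurement

CNR = (mean_insert − mean_background)/SD_background, signed, with the
sample (n−1) SD from four pooled background ROIs — never the insert ROI,
whose texture would conflate contrast with noise. Insert ROIs are
concentric disks at 0.7 of the insert diameter (eroding edge pixels);
background ROIs have the same area and are auto-placed on the insert ring
at the evenly spaced angular offset maximising clearance from the inserts
(explicit offsets may be supplied; collisions are errors). Statistics pool
voxels across the central 60% of slices — end slices of physical rods risk
cone/edge effects — and ROIs smaller than 25 voxels are rejected.

ROI placement offers a `geometry` mode (from the phantom spec) and an
`auto` mode (Gaussian smoothing, HU threshold, connected components,
nearest-centre matching to the spec, erroring on any undetected insert).
The original automated method this emulates is unspecified, so both modes
are provided without any claim of fidelity; they agree to within one pixel
on noise-free images. Whether voxels should be pooled across slices or
averaged per slice is likewise unspecified; pooling was chosen as the
lower-variance default.

## Calibration fit

Per stratum, α = Σcᵢ·CNRᵢ / Σcᵢ² (unweighted least squares through the
origin — the calibration model has no intercept term and no weighting is
assumed), SE(α)² = [RSS/(n−1)]/Σcᵢ², and R² = 1 − RSS/ΣCNRᵢ² *about the
origin* (uncentred; output headers say so because it is not comparable to
the centred R²). Replicates enter individually; at least two distinct
positive concentrations are required, and strata failing that are reported
as failures, never dropped silently. A diagnostic intercept-allowed OLS
fit is reported alongside and flagged when its intercept exceeds 2 SE; the
planner never consumes it.

**Validity regime of SE(α).** The homoscedastic-independent SE is
calibrated when each CNR point comes from its own image (independent
background estimates) and when CNR magnitudes are modest relative to the
background sample size: the measured background SD contributes
multiplicative noise of variance ≈ CNR²/(2·n_bg) per point, which is
heteroscedastic in c and, if several inserts share one background estimate,
correlated within an image. The simulation studies below are designed
inside this regime (single-insert images); with the default 4-ROI pooled
background the SD-driven term stays below the additive ROI-mean term for
CNR ≲ 10.

## Reduction planner

conc_ratio = α_b/α_t, reduction% = 100·(1 − α_b/α_t), with first-order
uncertainty Var(ratio) = ratio²·[(SE_b/α_b)² + (SE_t/α_t)²] (slopes
independent). Orientation note: pairing the equivalence relation
c_t = (α_b/α_t)·c_b with "reduction = 1 − c_t/c_b" fixes the ratio as
α_b/α_t; writing it with both subscripts in the same order would flip the
sign of every reported value, so the implementation pins the orientation
that makes lower-energy targets positive and 135/140 kV targets negative
(a required increase). Cross-size comparisons are refused by default
(override flag warns) since noise conditions differ across sizes. Report
percentages are rounded to one decimal; averages across sizes are computed
on unrounded values.

## Patient worked example

From printed aorta means ± SDs: percent difference uses the reduced-dose,
CNR-matched low-keV scan as denominator (the convention under which both
printed differences, 0.5% and 1.1%, are reproduced; both orderings are
exposed in the report); percent drop at matched 70 keV uses the full-dose
baseline as denominator (reproducing 26% and 54%); differences are
reported to 1 d.p. and drops to integers; the 150→100 mL volume cut is
33% (integer) or 33.3% (1 d.p.). The published psoas-based CNR values are
echoed for context only — their background statistics were not published,
so they cannot be recomputed; the packaged `case_cnr` consistency fixture
uses an explicitly synthetic background pair.

## Simulation studies (tests and `scripts/acceptance.py`)

All studies are deterministic given one seed; problem sizes are chosen for
a laptop-scale run (grid 2.5 mm pixels, 3 slices).

* **Oracle equivalence** — 100 random slope pairs: closed-form equivalent
  concentration vs a 0.001 mg/mL grid search over (0, 30]; inversion
  identity (1 − r_ab/100)(1 − r_ba/100) = 1 to 1e-12.
* **Slope recovery** — 200 independent suites of 5 concentrations ×
  10 replicate single-insert images on the largest (39.7 cm) phantom at a
  standard 10 mGy dose and 140 keV VMI (the small-κ/σ regime where SE(α)
  is calibrated; see above). Checks mean(α̂/α_true) ∈ [0.99, 1.01] and
  ≥99% coverage of α_true by α̂ ± 3·SE. Truth is κ(E)/σ by construction.
* **Closure** — fit baseline (120 kV) and target (50 keV) slopes from
  single-insert suites (4 concentrations × 12 replicates each) on the
  29.5 cm phantom, convert c_b = 10 mg/mL with the planner, re-simulate
  the target at the equivalent concentration (20 replicates per arm), and
  compare mean CNRs within 3·sqrt(SE_b² + SE_t² + (CNR_b·relSE(c_eq))²) —
  the Monte-Carlo errors of both arms plus the slope uncertainty
  propagated through the equivalent concentration. Being a 3·SE bound it
  admits rare (order 1%) seed-level exceedances by construction.
* **Trend** — full 4-size DECT-like suite (SECT 100/120 kV + VMIs
  40–80 keV, 5 replicates): reduction% must strictly increase as keV
  decreases for every size, and every reduction against the 100 kV
  baseline must be smaller than against 120 kV (100 kV images start with
  more iodine CNR).
* **Invariances** — CNR is exactly invariant under a constant HU offset;
  doubling the nominal noise SD halves expected CNR (Monte-Carlo, 3 SE);
  realised background SD matches nominal within 5% on ≥10⁴ voxels;
  doubling dose scales SD by √2 within 3%.

## Numerical and degenerate-input choices

Zero background SD, non-positive slopes, zero reference means, empty
masks/tables, single-concentration designs, out-of-range energies,
inserts outside the body or overlapping, and ROI/background collisions are
all hard errors with named causes — never silently patched. R² is NaN when
ΣCNR² = 0 (all-zero response; the slope is still 0). DICOM output rounds
HU to int16 (round-trip within 0.5 HU; the npz container is exact), with
UIDs derived deterministically from the volume's entropy string. CSV
artifacts carry a schema-versioned header with seed and config hash and no
timestamps, so identical runs are byte-identical; readers reject unknown
major schema versions.

## Known limitations

Scanner-specific reduction percentages cannot be validated at a desk; the
package validates the method, not the hardware numbers. White Gaussian
noise understates what iterative/deep-learning reconstruction does to
texture; CNR is the only image-quality metric (no NPS, resolution, or
artifact metrics); injection dynamics (flow rate, timing, physiology) are
out of scope; and the equivalence assumes dose-matched acquisitions within
one phantom size.
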