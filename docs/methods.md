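# Methods

`cobaltmc` simulates dose deposition from a cobalt-60 teletherapy unit
configured for total-body irradiation (TBI): a 2-cm-radius source 195.4 cm
above the treatment-room floor, a stacked-lead flattening filter, and a
50 cm x 200 cm field at floor level, with the patient or phantom resting on
a couch 6.0 cm above the floor.  The engine trades generality for speed: it
exploits the near-monoenergetic Co-60 spectrum and the modest accuracy
requirements of TBI dose reporting to strip the physics to the processes
that matter at 1.25 MeV in tissue.

## Source and beam model

Co-60 emits 1.17 and 1.33 MeV gammas in equal number; the engine uses the
single effective line at their mean, 1.25 MeV.  Emission points are uniform
on the source disk.  Directions are uniform in solid angle within the
collimation limits, realized by sampling the floor-field rectangle
uniformly and accepting each target with its cos^3(theta) solid-angle
weight.  An aperture-uniform variant (no weighting) was considered and
rejected: it makes the open-field entry fluence flat by construction, which
both misrepresents an isotropic emitter and leaves the flattening filter
nothing to flatten.

## Flattening filter

Six concentric lead plates, 0.3175 cm each, diameters 7.62-33.0 cm, bottom
25.4 cm below the source, clipped to the 33 x 14 cm filter footprint.  The
lead thickness seen by a ray is the per-plate thickness times the number of
plates covering its lateral position at the stack mid-plane (thin-stack
approximation; plate separation is negligible against the 195 cm SSD).
Transport keeps zero- and single-scatter photons only:

* survival with probability `exp(-mu t)` (`mu` = lead attenuation at the
  photon energy);
* otherwise one interaction at an exponentially distributed depth within
  `t`: photoelectric (photon absorbed), Compton (new direction and energy,
  recoil electron dismissed), or Rayleigh (new direction), with
  probabilities proportional to their shares of `mu`;
* a scattered photon must then traverse the remaining thickness without
  further interaction or it is dismissed.

No electrons exit the filter (the physical unit carries an acrylic sheet
that suppresses electron contamination).  Photons are then projected in
vacuum onto the top plane of the voxel grid and dismissed if they miss its
lateral extent; air interactions over the ~1.6 m drop are ignored.

Measured behavior of this geometry worth knowing: the six-plate stack
attenuates the central ray to ~0.28 while the solid-angle rolloff over the
central 80 % of the 200 cm field is only ~1.3x, so the filter flattens the
fluence within its shadow (roughly the central 80 cm of field length) and
overcompensates toward the extreme field ends.  The flattening test asserts
improvement within the shadow, which is what this filter can deliver.

## CT calibration and materials

Voxel densities come from the bilinear CT calibration
`rho = 0.001 HU + 1.034` (HU <= 0) and `rho = 0.0006 HU + 1.034` (HU > 0),
clamped to a 0.001 g/cm^3 floor.  Densities are binned into material
classes at 0.05 / 0.6 / 1.1 / 2.0 g/cm^3 (air, lung, soft tissue = water,
bone, metal = aluminum); the bin edges are conventional CT segmentation
bands and are configurable.  Lead exists only in the filter.

Material tables (CSV files under `cobaltmc/data/`, log-log interpolated)
hold photoelectric/Compton/Rayleigh mass attenuation components on
10 keV-1.33 MeV grids and mass collision stopping powers.  The Compton
component is the exact free-electron Klein-Nishina cross section per gram;
totals are anchored to standard reference tabulations; the photoelectric
component is the anchored total minus Compton and Rayleigh.  Above
~100 keV, where nearly all dose is deposited, this split is accurate; below
that the free-electron assumption shifts a little photoelectric weight into
Compton, which only perturbs how the last ~20 keV of a cascade is labelled,
not where it is deposited.  Coherent-scattering anchors and the lead form
factor are approximate at the few-percent level; coherent scattering is
excluded in tissue transport altogether (negligible at these energies) and
contributes only a small share of filter interactions.  Pair production is
ignored everywhere (threshold 1.022 MeV, negligible cross section at
1.25 MeV).

## Angle sampling

Scattering angles are drawn from pre-inverted tables rather than by
run-time rejection: for each process the polar-angle density (Klein-Nishina
times the sin(theta) Jacobian for Compton; Thomson times squared form
factor for Rayleigh in lead) is evaluated at 1 degree resolution, summed
into a CDF, and quantized into 1000 slots, for every 10 keV energy row up
to 1.25 MeV.  A uniform deviate times 1000, rounded, indexes the angle
directly -- no per-event comparisons.  Event energies snap to the nearest
10 keV row.  The quantization bounds any slot probability error by 1/1000,
which is the resolution against which the sampling tests are written.

Two printed-formula ambiguities are resolved on physical grounds, each with
a "literal" switch for sensitivity studies: the Rayleigh angular factor is
`(1 + cos^2 theta)` (standard coherent scattering), and the Compton recoil
electron angle follows `cot(phi) = (1 + hv/m0c^2) tan(theta/2)` (the
momentum-conserving form; the sign variant would emit recoil electrons
backward).  The classical electron radius is 2.8179e-13 cm.

## In-patient transport

Photon flights use survival-probability stepping: one uniform draw fixes
the surviving probability; the photon then advances in fixed 1 mm steps,
accumulating `exp(-sum h/lambda_j)` with the mean free path of the voxel at
each step midpoint (photoelectric + Compton only), and interacts at the
first step where the accumulated transmission drops below the draw.  The
step size is the spatial resolution of interaction placement; a new
surviving probability is drawn after every scatter.

Photoelectric events deposit the full photon energy locally -- at the
energies where photoelectric absorption is probable the photoelectron range
is below the voxel size.  Compton events sample the tabled angle, compute
the scattered energy from the Compton relation (photon + electron energy is
conserved exactly), and hand the recoil electron to the electron
transport.  Electrons travel in straight lines (CSDA, no angular scatter,
no energy straggling), depositing `(dT/rho dx)_c * rho * h` per 1 mm step
into the midpoint voxel until exhausted.  Photons and electrons below
10 keV deposit their remaining energy locally.  Space outside the grid is
vacuum; energy leaving the grid is tallied so that every run satisfies
entered = deposited + exited to float precision.

Dose to medium is deposited energy per voxel mass; dose to water
multiplies each voxel by the water-to-medium mass collision stopping-power
ratio at 0.3 MeV (Bragg-Gray), applied once at the end of a run.  Note the
ratio exceeds 1 for bone and aluminum: their mass stopping powers are lower
than water's (smaller Z/A), so dose-to-water is larger than dose-to-medium
in those voxels.

Known transport limitations (deliberate, for speed): no electron lateral
scatter, path-length corrections, straggling, or interface effects;
straight-line CSDA pushes electron energy slightly deeper than real
transport would, which softens the buildup edge (see below).

## Randomness and reproducibility

All sampling uses Mersenne-twister uniform deviates.  The operation-level
API takes an explicit seeded `RandomStream`; the fused simulation kernel
seeds its own twister once per run.  Identical seeds give bit-identical
dose arrays; every stochastic test in the suite is seeded.

## Implementation shape

The per-event math lives in numba-compiled kernels used both by the
operation-level API (one event at a time, for tests and exploration) and
by a fused single-pass driver that runs emit -> filter -> entry window ->
cascade for millions of histories per minute of CPU.  With the default
water phantom at (0.254, 0.254, 0.1) cm voxels, 1e8 histories take on the
order of 1.5 minutes on one core.

## Validation phantoms

`make_water_phantom` rebuilds the 31.8 x 48.4 x 30 cm water tank (HU = 0
everywhere, density 1.034).  `add_aluminum_insert` places two 9.5-mm
aluminum bars directly above and below a water gap at 3.0 cm depth
(bar footprint and gap are configurable; the original insert's exact
lateral placement is not published).  Aluminum is assigned by material
override at 2.70 g/cm^3 rather than through the HU calibration.
`make_layered_body` builds a slab phantom with configurable HU layers
(defaults: soft tissue / lung / bone / soft tissue) -- a heterogeneity
test object standing in for an anthropomorphic phantom, not an anatomical
replica; conclusions drawn from it transfer to real anatomy only at the
level of material-class behavior.  `read_ct_series` ingests an axial DICOM
CT series for patient-geometry runs.

## Evaluation surface

PDD and profile extraction average over a lateral/depth window to tame
Monte Carlo noise and normalize to the curve maximum.  The depth of
maximum is refined with a 3-point parabola around the raw argmax; optional
Savitzky-Golay pre-smoothing exists for noisy curves but biases a narrow
buildup peak toward an adjacent scatter plateau, so wide lateral averaging
is preferred over smoothing.  The gamma index is the standard global
formulation (dose difference as percent of the reference maximum, default
10 % low-dose cutoff, evaluated plane bilinearly upsampled when its
spacing is coarser than the DTA) and is verified point-for-point against
an exhaustive brute-force oracle.  The efficiency estimator times repeated
runs of a scoring-box recipe and reports 1/(variance x time).

## Behavior of the physics model at the depth-dose maximum

In this beam geometry (huge field, ~160 cm SSD) the central-axis depth
dose rises steeply over the first ~5 mm as secondary electrons build up,
then rides a long phantom-scatter plateau that stays within ~2 % of the
maximum out to ~2.5 cm before the exponential attenuation takes over.  A
semi-analytic check (numeric convolution of the exponential interaction
density with the stepped CSDA electron kernel) places the primary-beam
maximum at 0.55 cm on a 1 mm grid; in the full simulation the
phantom-scatter plateau shifts the global maximum to ~0.6-0.65 cm, with
the straight-line CSDA approximation accounting for the slight deepening
relative to the textbook 0.5 cm of Co-60.  On a 5 mm grid -- the slice
resolution of the CT export this engine mirrors -- the maximum falls in
the bin beginning at 0.5 cm.  Because the peak rises only ~1-2 % above
the plateau, locating it on the 1 mm grid requires of order 1e8-1e9
histories together with ~15 cm central lateral averaging (the beam is
flat over that span); `scripts/acceptance.py` uses 6e8 histories, for
which the read-out is reproducible to roughly +-0.05 cm.
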