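# Methods

`protonct` studies how X-ray beam-hardening artifacts (BHA) propagate through
CT-number–to–proton-stopping-power calibration into range-relevant quantities.
Because the physical experiment requires a clinical CT scanner, the package
couples a synthetic polychromatic CT simulator to the analysis chain: every
quantity reported by the experiment runners is computed end-to-end from
simulated scans of digital phantoms.

## Stopping power and material parameters

A material is characterized by its relative electron density ρe, effective
atomic number Zeff, and mean excitation energy I. For materials given by an
elemental composition (mass fractions w_i):

- ρe = ρ · Σ w_i Z_i/A_i, normalized to water at 1 g/cm³;
- Zeff = (Σ λ_i Z_i^m)^{1/m} over electron fractions λ_i, with the power-law
  exponent m = 3.31 by default (configurable). Tissue-substitute calibration
  plugs instead carry vendor/literature ρe and Zeff, used verbatim and never
  recomputed; their packaged mixture compositions feed only I;
- I from Bragg additivity, ln I = Σ λ_i ln I_i, with elemental I values from
  the ICRU 37 recommendations; I_water defaults to 75 eV.

Proton relative stopping power at kinetic energy T (default 200 MeV,
β = 0.5662) is the Bethe–Bloch ratio

    RSP = ρe · L(I) / L(I_water),
    L(I) = ln( 2 m_e c² β² / (I (1 − β²)) ) − β²,

without shell or Barkas corrections. The water prefactor
k0 = 4π r_e² m_e c² n_e,water = 0.17045 MeV/cm is packaged and is reproduced
from the physical constants to < 0.01 %; the proton rest energy is fixed at
938.272 MeV.

Where only Zeff is known (dual-energy parameter maps), I comes from a
log-linear Zeff→I interpolation anchored on the packaged reference-tissue
compositions, so the mapping is consistent with Bragg additivity over the
tissue range.

### Reference tissues

The HU→RSP curve is built over 33 adult reference tissues (23 soft tissues
and 10 skeletal sites) with White/Woodard-style elemental compositions.  The
exact membership of the original tissue set is not fixed by any table we
reproduce; the packaged set is an explicit assumption and can be replaced by
any CSV with the same schema.

## Stoichiometric calibration

The CT-number model is U = (HU + 1000)/1000 = ρe · f(Zeff) with f a power
series Σ_{m=1..M} b_m Zeff^{m−1}; the coefficients are fitted by unweighted
linear least squares to plug readings (degree M−1 = 5 by default; a
1/sd² weighting is available behind a flag). The fitted model evaluated at
each reference tissue, paired with its Bethe–Bloch RSP, yields the
(model HU, RSP) knot sequence. Conversion of measured HU is piecewise-linear
through the knots, runs to the air point (−1000 HU, RSP 0) below the first
knot, extrapolates the final bone segment above the last knot, and clamps
negative interpolants to zero with a logged count.

Knot ties: exact HU duplicates raise an error naming the tissues; an optional
`merge_tol_hu` merges near-coincident knots by averaging RSP.  The default is
0 (no merging) so that every tissue's model HU round-trips to its exact RSP —
with realistic tissue sets a positive tolerance would silently merge distinct
soft tissues and break that exactness.

## The CT simulator

Parallel-beam geometry with Ram-Lak filtered back projection
(scikit-image `radon`/`iradon`); the artifacts under study arise already in
parallel beam, so the clinical helical fan-beam geometry is not modelled.
Defaults: 180 projections over 180°, in-plane grids sized to the phantom
(128² in the packaged experiments), 1-mm slices. A 50-cm field of view is a
hard bound and phantoms must fit the reconstruction circle.

Attenuation follows a two-process model per electron,

    μ(E) = ρe n_e,water ( a_pe Zeff^{n−1} / E³ + σ_KN(E) ),

with σ_KN the Klein–Nishina cross-section, photoelectric exponent n = 4.0,
and a_pe anchored once so water's μ at 60 keV equals 0.2059 cm⁻¹. Coherent
scatter, scatter-to-detector, and detector effects are not modelled. Spectra
are Kramers bremsstrahlung at the tube potential filtered by 2.5 mm Al,
binned at 1 keV — generic tungsten-anode stand-ins, since real scanner
spectra are proprietary.

Forward projection computes per-material path lengths per ray once and sums
μ(E) over energy bins; the detected signal is Σ w(E) e^{−∫μ dE} and the
post-log projection p = −ln(signal). Optional noise is Gaussian on post-log
projections with standard deviation `noise_level`·e^{p/2}, a Poisson-like
growth with attenuation, seeded and bit-reproducible.

### Effective energy

Each spectrum carries a *beam-hardened effective energy*: the energy whose
water attenuation matches the polychromatic water response over a 20-cm
path. This is the energy scale clinical HU are calibrated on (scanners
normalize in a water phantom of roughly that size) and it anchors three
things: the linearized projection domain, the reference bone contrast of the
iterative correction, and the per-voxel energies of the dual-energy basis
solve. The unattenuated fluence-weighted mean would sit far too low
(~40 keV for 80 kVp) and systematically overstate photoelectric contrast in
reconstructed values.

### Corrections

*Water linearization* remaps each projection through the inverse of the
simulated polychromatic water response so water paths become linear in
length. It is ON by default — clinical reconstructions always include it —
so "uncorrected" throughout the package means water-linearized but without
bone correction. It removes cupping in water-like media and leaves
bone-induced streaking, as expected.

*Iterative two-material correction* (the generic stand-in for vendor
iterative beam-hardening corrections): per pass, voxels above the bone
threshold (default +300 HU) define a fractional bone-equivalent density map
(HU excess relative to the reference bone HU at the effective energy) which
is forward projected; per ray, the water/bone split (L_w, L_b) is found by a
fixed-point step so the known spectrum's polychromatic response reproduces
the measured linearized projection; the projection is then replaced by the
ideal monochromatic one, μ_w(E_eff)·L_w + μ_bone(E_eff)·L_b, and the slice
is reconstructed. Two passes by default, re-segmenting between passes. The
bone reference material is the densest material of the scanned phantom
(self-calibration), falling back to the cortical-bone plug. A fractional
(rather than binary) bone map matters: intermediate-density bone
surrogates would otherwise be treated as full cortical bone and
overcorrected in a geometry-dependent way.

*Dual-energy synthesis and decomposition*: per voxel the two reconstructed
μ values (at the two spectra's effective energies) are solved against the
photoelectric (1/E³) and Compton (Klein–Nishina) basis; pseudo-monochromatic
images evaluate the basis at the target energy and convert to HU at that
energy, and the ρe/Zeff decomposition inverts the same two-parameter μ model.
Voxels with non-physical solutions (ρe ≤ 0, dominated by air) are masked and
counted. Spectra with indistinguishable effective energies raise a
conditioning error.

## Phantoms

- *Cupping series*: wax cylinders (CH₂ hydrocarbon, ρe 0.96) of 13.5, 17.8
  and 26.9 cm diameter with a central 28-mm cortical-bone plug, plus a
  laterally extended variant whose effective diameter √(AP·LAT) is 30.2 cm.
- *Streak phantom*: a 330×120 mm wax slab cross-section with three collinear
  28-mm holes spaced 15 mm edge-to-edge (43 mm center-to-center). Region 1
  (artifact-free) has wax plugs around a central solid-water plug; region 2
  has two cortical-bone plugs around the identical solid-water plug. The two
  regions occupy separate axial segments of one phantom.
- *Digital head*: a soft-tissue ellipse (default 15×19 cm) with a cranium
  shell, brain interior, and two dense petrous bone blocks flanking the
  brain on the lateral axis — the geometry that produces the classic streak
  between the petrous pyramids.
- *Calibration phantom*: a water cylinder (33 cm, and a 20-cm variant
  standing in for a water-filled acrylic phantom) holding the 13
  tissue-substitute plugs as a center-plus-ring arrangement.

ROIs are cylinders contracted diametrally (default 2 mm: a 28-mm plug reads
as a 26-mm ROI, i.e. a 1-mm radial margin, with the length shortened by the
same amount split over both ends); statistics use the population standard
deviation, and repeat-scan confidence intervals use the t distribution on
the seeded repeats (3 by default).

## What the experiments show — and what they cannot

The experiment runners reproduce the *directions and orderings* of the
physical findings: bone HU falls strongly and near-linearly with phantom
effective diameter for single-energy techniques and the fall is strongly
damped by the iterative correction; streak ΔHU between the bone-flanked and
artifact-free solid-water plugs decreases with tube potential, decreases
across 60/80/100 keV pseudo-monochromatic syntheses, and shrinks under the
iterative correction at every technique; the head water-equivalent-thickness
difference between 33-cm and 20-cm calibrations is positive in the petrous
band and shrinks when both calibrations use the correction.

Magnitudes are *not* comparable to a clinical scanner: the generic Kramers
spectra are softer than filtered clinical beams, the two-process attenuation
model omits coherent scatter, the geometry is parallel-beam, and the vendor
correction algorithms are proprietary. Passing tests therefore validate the
propagation physics and the analysis chain, not scanner-specific numbers.

## Numerical choices and problem sizes

Packaged experiments and tests run at 128² in-plane grids with 180
projections; the monochromatic-limit validation uses 256²/360, where
reconstructed plug HU agree with analytic μ-based HU to < 10 HU. The
water-linearization table spans 0–64 cm of water (513 nodes) with linear
extrapolation beyond (logged). Fits use `numpy.linalg.lstsq`; rank
deficiency (too few distinct Zeff) raises rather than silently truncating.
Degenerate trend fits (zero variance) return slope 0 with a degeneracy flag.
FBP noise is spatially anti-correlated, so ROI-mean noise shrinks faster
than 1/√N for large ROIs — relevant when interpreting repeat-scan CIs.

## Known limitations

- No scatter, detector afterglow, helical interpolation, tube-current
  modulation, or dose metrics.
- Pseudo-monochromatic synthesis is physics-based; vendor algorithms apply
  undisclosed spatial weighting and are not numerically reproduced.
- Arbitrary-angle WET projection is deferred; 0°/90° axis-aligned rays only.
- DICOM I/O is not implemented; volumes move through NIfTI and CSV/JSON.
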