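# Methods

`thzpol` models a reflection-mode polarimetric terahertz time-domain
scanner and the analysis chain that turns its raw per-pixel pulses into
power-spectrum images, 16-element Mueller-matrix images and fibre
orientation estimates. Because raw clinical scan data of this kind are not
publicly deposited, every stage is exercised against a physics-based
synthetic phantom whose ground truth is known exactly. This note records
the model, its assumptions, the defaults and the deliberate design
choices.

## Measurement model

Each pixel is probed by a broadband picosecond pulse at 30° incidence in
four linear polarisation channels (HH, VH, VV, HV; first letter detector,
second emitter). The horizontal channel is s-polarised (field
perpendicular to the plane of incidence), the vertical channel
p-polarised. In the frequency domain the sample response at a pixel is a
2×2 complex scattering matrix in the (V, H) basis,

    S(f) = [[Svv, Svh], [Shv, Shh]],

and the recorded channel spectrum is the emitter pulse spectrum times the
corresponding entry. Synthesis is therefore exact inverse FFT filtering;
analysis is the same chain run backwards (FFT, reference deconvolution).

**Isotropic pixels** reflect with the Fresnel amplitudes of a planar
interface: `Svv = rp`, `Shh = rs`, no channel mixing. The Fresnel sign
convention is Hecht's (`rs = rp` in magnitude and opposite in sign at
normal incidence); only magnitudes and relative phases reach the images,
so the convention is a bookkeeping choice, documented in `optics.py`.

**Fibrous (collagen) pixels** additionally act as a linear retarder whose
fast axis lies along the in-plane fibre orientation θ. The beam crosses
the birefringent layer, reflects, and crosses it again, so the model
composes the interface response D = diag(rp, rs) symmetrically between two
single-pass retarder Jones matrices P (retardance δ/2 each pass):

    S = P(θ, δ/2) · D · P(θ, δ/2),      δ = 2π f Δn (2d) / c.

The symmetric composition keeps S exactly reciprocal (Svh = Shv), which a
one-sided product `retarder · D` would not when rs ≠ rp. This is a
normal-incidence Jones approximation multiplied onto the oblique Fresnel
amplitudes; exact oblique anisotropic reflection is out of scope. It
reproduces the qualitative orientation physics: cross-pol vanishes when
the axis lies along either polariser axis, peaks at 45°, and is 90°
periodic — exactly so for a lossless layer. With an absorbing layer the
90° degeneracy is broken at third order in sin(δ/4) (about 1% with the
defaults), which is why pipeline-level periodicity checks carry a 5%
tolerance while the lossless retarder is tested for exact symmetry.

**Polariser leakage.** Imperfect wire-grid polarisers transmit a fraction
ε of the orthogonal field on both the emitter and the detector side,
modelled as L(ε)·S·L(ε) with L = [[1, ε], [ε, 1]] and default ε = 0.02
(the 2% figure quoted for broadband wire grids). The gold calibration
mirror is modelled as the identity channel response, for which the
sandwich gives a cross/co amplitude ratio of exactly 2ε/(1+ε²) ≈ 0.04 —
the small-but-nonzero mirror cross-pol seen in practice. (The signed
Fresnel mirror limit diag(+1, −1) would make the emitter- and
detector-side leakage cancel exactly; treating the mirror as the
instrument's identity reference is the modelling choice that matches the
observation.)

## Synthetic phantom

The phantom is a raster label map painted from shape primitives
(rectangles, disks, half-planes; painter's order), standing in for the
whole-slide pathology ground truth: adjacent cancer, fat and collagen
regions embedded in paraffin (block specimens, scanned from air) or on a
polymer slide (fresh specimens). Default grid step 150 µm, the common
scanning resolution for such specimens.

Published work constrains only the *ordering* of reflectivities (cancer
strongest, collagen intermediate, fat weakest, paraffin nearly
transparent) and the higher absorption of hydrated fresh tissue. The
numeric defaults are frequency-flat, literature-magnitude choices:

| class          | block n + iκ   | fresh n + iκ  | Δn   | layer d |
|----------------|----------------|---------------|------|---------|
| paraffin       | 1.50 + 0.005i  | 1.50 + 0.01i  | 0    | —       |
| fat            | 1.55 + 0.01i   | 1.60 + 0.15i  | 0    | —       |
| collagen       | 1.75 + 0.02i   | 1.90 + 0.30i  | 0.05 | 100 µm  |
| cancer         | 1.95 + 0.03i   | 2.10 + 0.40i  | 0    | —       |
| mineralization | 2.20 + 0.03i   | 2.30 + 0.40i  | 0    | —       |
| air bubble     | 1.00           | 1.00          | 0    | —       |
| slide          | 1.52           | 1.52          | 0    | —       |

Mineralization above cancer reflects the "stronger foci" reading of such
deposits but is otherwise unvalidated. Collagen Δn = 0.05 with a 100 µm
effective layer gives a double-pass retardance of ≈0.21 rad at 1 THz —
weak mixing, consistent with cross-pol signals an order of magnitude or
more below co-pol. What the phantom does **not** emulate: speckle,
surface-height variation and leveling error, depth-resolved structure,
moisture drift during a scan, partial-volume mixtures at boundaries, and
etalon echoes. Passing tests therefore demonstrate the correctness of the
image-formation chain, not the realism of any particular tissue contrast.

## Acquisition and frequency grids

Pulses are 1024 samples; the emitter pulse is a Gaussian first derivative
(width 0.1 ps, peak 1) whose magnitude spectrum stays above 1% of its peak
over 0.1–4 THz — checked at construction, with the usable band reported if
violated. Noise is additive white Gaussian in the time domain, independent
per pulse; block-style scans literally average `n_average = 5` repeats, so
the √5 noise reduction is an emergent Monte-Carlo property, not baked in.

The time window fixes the grid spacing Δf = 1/T. Two presets pin the
published band bookkeeping exactly: T = 20 ps (Δf = 0.05 THz) puts 41 bins
inclusive in 0.5–2.5 THz, and T = 33.33 ps (Δf = 0.03 THz) puts 68 bins in
0.505–2.525 THz. (A spacing of 0.0301 THz, the naive (2.525−0.505)/67,
yields only 67 inclusive bins; 0.03 is the spacing that realises the
printed count.)

## Image formation

**Power-spectrum image**: per pixel, the mean over band bins of
|E_samp|²/|E_ref|² (co-pol channels, each against its own single-point
reference trace) or of |E_samp|² (cross-pol channels, the display
convention). The band "integral" is implemented as a bin mean so the
reference pixel scores exactly 1; a Δf-weighted sum is available in
config. No apodization by default. Reference magnitudes below 10⁻⁶ of
their in-band maximum make the pixel NaN, counted in the log. Reference
traces are synthesised through the identical code path as sample pixels,
so reference-class pixels normalise to exactly 1.0, not 1 ± 1 ulp.

**Mueller images**: channel spectra are deconvolved into S entries —
default scheme divides each channel by the reference of its *emitter's*
co-polarised channel (VV, HV by ref VV; HH, VH by ref HH), since the
emitter spectrum is the common factor of both detector arms; a
detector-matched scheme and a raw (no deconvolution) scheme are
selectable, because the published processing does not state which was
used. The 4×4 matrix is evaluated element-wise in the radar-style linear
form whose first row is (|Svv|², |Svh|², Re(Svh*Svv), −Im(Svh*Svv)).
Five rank-one identities (M13²+M14² = M11·M12 and four more) hold exactly
per frequency and serve as the pipeline's algebraic oracle; band averaging
relaxes them to Cauchy–Schwarz inequalities, tested as such. M11, M22,
M12, M21 are computed with the same floating-point expression as the
per-frequency power images, so the two routes agree bit-for-bit. A
standard linear-basis Stokes vector is provided with s3 = −2 Im(Ev Eh*)
(right-circular s3 = +1); no depolarization decompositions are attempted.

## Rotation analysis

Rotating the sample by φ on the scanning window is modelled as
nearest-neighbour resampling of the label map about its centre plus adding
φ to every fibre axis. Cross-pol band power then follows
a + b·sin²(2(θ0 + φ)); the estimator fits this by exact linear least
squares in the basis (1, cos 4φ, sin 4φ) and reports θ0 mod 90°, declaring
the series isotropic when the modulation b falls below 5% of the mean
level. Noise-free recovery on a 10° grid is exact to machine precision;
with the per-angle power fluctuation set to ≈10% of the modulation
amplitude (noise σ = 0.008, 5-pulse averaging — the calibrated study
condition), recovery stays within ±2° over 20 seeds.

In the six-angle protocol {0, 30, 60, 90, 130, 160}°, a fibre axis of
exactly 85° makes the 60° and 130° rotations *exactly* degenerate: the
retarder power depends only on sin²2θ_eff and cos²2θ_eff, both invariant
under θ_eff → 180°−θ_eff, and those two rotations produce exactly that
pair (145° vs 35°). Any axis strictly between 85° and 90° breaks the
degeneracy in favour of 130°; the demonstrations use 87°.

## Numerical and interface choices

- Coordinates: row 0 top, column 0 left, pixel centres at
  (row+0.5, col+0.5)·step; angles CCW from the +x (column) axis, degrees,
  axes mod 180; one convention shared by phantom, optics and rotation.
- Scans round-trip losslessly through an HDF5 container
  (/channels, /references, /time_axis, /meta); derived images are 32-bit
  float TIFF with 8-bit PNG previews; statistics are CSV.
- Determinism: every stochastic step draws from `numpy` Generators seeded
  from one config seed; rotation sweeps derive per-angle seeds from a
  SeedSequence so angles are independent but reproducible.
- Problem sizes in the test-suite demonstrations (8–32 px grids, 18-angle
  sweeps, 20 seeds) are chosen so each property is measured well away from
  its tolerance while the whole suite stays interactive.

## Known limitations

The birefringence model is a thin uniaxial retarder at normal incidence;
it cannot produce depolarization, diattenuation along the fibre axis, or
depth-dependent orientation. Frequency-flat optical constants ignore real
tissue dispersion (a Debye-style option would slot into
`OpticalProperties` but is not implemented). Rotation by non-multiples of
90° is nearest-neighbour and loses edge pixels to the background fill.
The Mueller deconvolution gap (referenced vs raw fields) is surfaced in
config rather than resolved — the published processing is ambiguous on it.
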