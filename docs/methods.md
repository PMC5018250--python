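# Methods

`helifil` is a desk-scale implementation of the computational route by
which conjugative-pilus structures are determined: helical
reconstruction of filament segments from noisy, CTF-modulated
projections, determination and imposition of the helical symmetry,
resolution validation by Fourier shell correlation, construction of
complete filament atomic models from a single subunit by screw
transforms, and quantitative analysis of the resulting architecture
(buried surfaces, contact networks, diameters, lumen electrostatics).
Everything runs on simulated data generated by the package itself, with
full ground truth retained, so every stage can be scored exactly.

## Helical lattice model

A filament is described by a `HelicalSymmetry` triple: twist per layer
(degrees, signed; positive = right-handed), rise per layer (Å), and the
cyclic order n of each layer's Cn point group. The conjugative-pilus
lattices used as defaults throughout are C5 with twist ≈ 28° and rise
12.1 Å (pED208) or 12.5/13.2 Å (the two F-pilus forms), i.e. about
360/28.2 ≈ 12.8 subunits per turn of each of the five strands. The
layer-stack description (Cn layers related by one screw generator) and
the n-start strand description (n interleaved 1-start helices offset by
360/n) generate identical subunit sets; `strand_lattice_equivalence`
verifies this numerically and is property-tested over a parameter grid.
The absolute handedness of the pilus is not imposed by the data we
emulate; the generator default is right-handed with a config switch
(`simulation.right_handed`).

Conventions: helix axis = +z, layer 0 at z = 0, layer index increasing
along +z; all angles degrees, lengths Å. Screw decompositions of
general rigid transforms flag degenerate cases (identity, pure
translation) explicitly rather than returning silent defaults.

## Synthetic data generator

The generator stands in for micrographs of vitrified pili. Its
components and defaults:

- **Subunit template** — ~60 Gaussian pseudo-atoms in three rod-like
  clusters (a three-helix-bundle proxy) within a ~25×15×15 Å envelope,
  centred 25 Å from the helix axis; distinct rod curvatures plus seeded
  jitter leave no internal rotational symmetry (best nontrivial
  self-superposition RMSD > 2 Å, enforced by a rotation-grid oracle).
  Gaussian widths ≈ 2.5–2.9 Å, appropriate for the 3 Å voxels used at
  desk scale.
- **Volume rendering** — the template is propagated over the lattice
  and splatted as isotropic Gaussians onto a cubic grid with the
  filament axis through the box centre. Axial clipping (`clip_z`)
  models the filament continuing beyond the box; lateral overflow is
  an error.
- **Projection geometry** — line-integral projections at a random
  azimuth with out-of-plane tilt restricted to 90° ± 5° (filaments lie
  in the ice plane; a full out-of-plane search is out of scope), a
  random axial offset uniform over one rise, and optional lateral
  jitter.
- **CTF** — standard weak-phase model at 300 kV, Cs 2.0 mm, amplitude
  contrast 0.10: CTF(s) = −[√(1−A²)·sin γ + A·cos γ], γ = πλΔz s² −
  (π/2)Cs λ³s⁴, with underfocus stored positive and drawn uniformly
  from 0.5–3.5 μm per segment (the display convention "−0.5 to −3.5 μm"
  maps to positive underfocus). No astigmatism: one defocus per image.
- **Noise** — additive white Gaussian after the CTF; `target_snr` sets
  the noise SD from the empirical variance of the clean images so that
  var(signal)/var(noise) matches the request (SNR 0.1 is the standard
  study condition here). No structural noise, ice gradients or motion
  blur are simulated. Dose fractionation is emulated as two noise
  levels on identical geometry (≈20 and ≈10 e⁻/Å² stand-ins) for
  alignment-transfer experiments.
- **Geometry defaults** — 96 px boxes at 3.0 Å/px for routine runs;
  384 px at 1.1 Å/px is supported but not default. 43,952-segment
  datasets are far outside desk scale; the default stacks hold 200–300
  segments.

All outputs are bit-reproducible given (seed, config); every stochastic
stage receives a seed derived from one global seed by hashing.

What the generator does *not* emulate — structured background,
radiation-damage spectra, flexible filaments, defocus estimation error
— bounds what passing tests show: they certify the algorithms under a
clean, known forward model, not performance on real micrographs.

## Reconstruction engine

One iteration of the refinement cycle: make reference projections from
the current volume over the symmetry-reduced azimuth range (0–72° for
C5, 4° steps by default) → align every segment to the best reference by
FFT normalized cross-correlation over a bounded shift window (axial
window ± one rise; larger offsets are equivalent to an azimuth change
by the helical degeneracy) → back-project → search the helical symmetry
→ impose it. Convergence is declared when twist and rise move less than
(0.05°, 0.02 Å) between iterations.

**Back-projection.** With tilt fixed near 90°, every z-slice of the
volume is an independent 2D parallel-beam problem, so the engine uses
slice-wise filtered back-projection: segments are un-shifted, averaged
per matched azimuth, ramp-filtered along the in-plane axis, smeared
along their view directions and accumulated. Phase correction follows
the poor-SNR Wiener limit: image transforms are multiplied by their CTF
(`phase_flip`), and since the signal has then been CTF-multiplied twice
(microscope + correction), the reconstruction's transform is divided
per frequency shell by (ΣCTF² + w), with the Wiener constant w
defaulting to 0.1 × mean(ΣCTF²). The absolute scale and DC term of the
reconstruction are arbitrary (the ramp filter removes DC); all
downstream statistics are scale-invariant.

**Symmetry search.** Two estimators are provided. For clean volumes,
`symmetry_search` minimizes the variance-normalized mean-squared
difference between the volume screwed forward by half the candidate
operation and backward by the other half (comparing two
equally-interpolated copies cancels sub-voxel interpolation bias),
within a cylindrical mask of radii 5–45 Å, coarse grid then bounded
Nelder–Mead; it recovers construction parameters to (0.02°, 0.03 Å).
This self-consistency residual fails inside the refinement loop at low
SNR, for two reasons we measured: the noise term of the residual has a
trivial global minimum at the null screw (zero twist and rise), and
linear interpolation of fractional-voxel z-shifts attenuates noise and
signal unevenly, pulling the rise toward integer-pixel values. The
loop therefore uses `symmetry_search_split`: segments are split into
even/odd half-sets, each back-projected independently, and a candidate
(twist, rise) is scored by the covariance — inside the radial mask —
between the two half-maps after each is averaged over screw powers
−4..+4 of the candidate. Signal averages coherently only at the true
parameters; the independent noise of the halves cancels from the cross
term; z-shifts are applied exactly in Fourier space so no
integer-voxel bias remains (rotations, which are rise-independent, use
linear interpolation). The search window stays anchored at the initial
symmetry — a window that re-centres each iteration can walk to a
self-consistent wrong symmetry before azimuthal lock-in — and an
estimate pinned to the window edge is treated as a stall, never as
convergence.

Two scheduling details matter when starting from a featureless
cylinder. First, no axial shift search is allowed on the first pass:
against a z-featureless reference the axial shift is unconstrained, and
random shifts would wash out the layer periodicity that carries the
rise information. Second, the first pass searches the rise only: with
azimuths still effectively random, the twist is unidentifiable, while
the layer stacking (which survives azimuthal averaging as rings)
already determines the rise. The starting cylinder is seeded with a
small noise texture to speed up the spontaneous breaking of its
azimuthal symmetry. Under the standard conditions (240 segments, 96 px,
SNR 0.1, start (27.0°, 11.5 Å)) the cycle converges in 3–4 iterations
to within 0.21° and 0.10 Å of the true (28.2°, 12.1 Å).

**Symmetrization** averages the volume over the Cn rotations and all
screw powers whose z-shift keeps part of the box in view, weighting
each z-plane by its actual coverage. It uses cubic spline interpolation
(the rest of the loop is linear): the symmetrized map is the product
the invariance contract applies to — correlation > 0.999 with its own
screw- and Cn-transformed copies inside the valid region — and linear
interpolation loses ~10⁻³ of that per pass.

**Two-class sorting** (the F-pilus case) builds one unsorted
reconstruction (a short fixed-symmetry refinement at the mean of the
two candidate parameter sets), symmetrizes it once with each candidate
symmetry to create two references, then iterates: assign each segment
to the reference volume giving the higher best correlation (ties to
class a, deterministically), rebuild both class reconstructions,
repeat — 5 cycles by default ("several" is not quantified anywhere; 5
suffices here). On a 50/50 mixture of rise 12.5 vs 13.2 Å segments at
SNR 0.1 the sorting reaches ≥ 95% accuracy; with identical candidate
symmetries it stays at chance. An emptied class raises an error naming
the cycle.

**Alignment transfer** re-uses the (azimuth, shift) parameters found on
one stack to back-project a segment-for-segment paired stack, the
mechanism for reconstructing from low-dose frames with high-dose
alignments. In our noise-only forward model the measurable content of
the claim is parameter accuracy: at SNR 0.10 vs 0.01 the high-dose
alignments are correct for 97–100% of segments against 79–80% for the
low-dose self-alignment (scored modulo the helical degeneracy). A
naive "FSC to ground truth" comparison of the two reconstructions
inverts this ordering, because aligning a very noisy stack against
references derived from the truth overfits noise toward the reference
structure and inflates the correlation — the Einstein-from-noise
effect. Gold-standard (independent half-set) refinement, which removes
that bias, is deliberately out of scope.

## Resolution validation

`fsc` computes the per-shell normalized complex correlation between
two maps on matching grids (shell width one Fourier voxel, no masking
or phase-randomization correction); `resolution_at_threshold` reads
the first downward crossing with linear interpolation, returning the
Nyquist value with an explicit flag if the curve never crosses. The
named thresholds are 0.143 (independent half-maps) and 0.4 (map vs
refined model). `smooth_fsc_curve` (3-shell moving average) stabilizes
crossing detection in the noisy tail. `model_to_density` renders an
atomic model as one isotropic Gaussian per atom, amplitude
proportional to atomic number and variance B/(8π²) — a single-Gaussian
stand-in for tabulated scattering factors, adequate for FSC
consistency at ~4 Å and coarser.

In the synthetic workflow the role of the refined atomic model is
played by the noise-free ground-truth structure. On a reconstruction
with known alignment the half-map and map:truth FSC curves obey the
consistency relation C_ref = √(2C_half/(1+C_half)) to a mean deviation
of ~0.01–0.02, and the resolutions read at 0.143 and 0.4 agree closely.
Two caveats we quantified, worth knowing when interpreting such
numbers anywhere: (i) the 0.143/0.4 threshold pair is exactly
equivalent only where C_ref = 0.5, so the two readings separate by a
shell or more wherever the curve falls gently — they coincide tightly
only when the crossing sits in a steeply falling region, as it does for
large experimental datasets; (ii) after reference-based refinement the
half-map estimate inherits common-reference alignment bias that a
comparison against independent truth does not share.

## Assembly modelling

Filament atomic models are built the classical way: least-squares rigid
superposition (SVD-based, proper rotations only) of matched atom
selections — default Cα, matched by (residue number, atom name), with
unmatched atoms reported rather than dropped — yields the transform
between two adjacent chains; its screw decomposition gives the
per-subunit twist and rise; successive powers of the screw generate a
strand (16 units by default); the exact Cn rotation (or a fitted
inter-strand screw) replicates the strand into the full five-stranded
pilus, 80 pilin+lipid units. Chain naming is strand letter + unit index
("A1".."E16"; lipids lowercase), carried faithfully by mmCIF; the PDB
writer refuses assemblies that exceed the PDB chain-id width instead of
aliasing. Built models report the minimum inter-strand atom distance
and warn below 1.5 Å. The round trip — build from (symmetry, unit),
re-extract from any adjacent pair — reproduces the construction
parameters to 1e−6.

## Synthetic pilin+lipid unit

Because this package ships no experimental coordinates, the
interface/geometry analyses run on a fully synthetic pilin+lipid unit
(`synthetic_unit.make_pilin_unit`, labelled synthetic in code and
docstrings): a 63-residue (numbered 2–64, the TraA modelled range)
idealized three-helix bundle with approximate backbone and reduced
side chains, oriented radially with an axial lean so successive layers
interdigitate, plus a phosphatidylglycerol-like lipid whose phosphate
sits at the lumen surface and whose two ~C14 acyl chains run outward
between subunits. Its one-time calibration targets the gross pilus
architecture: outer diameter ≈ 86–89 Å, lumen ≈ 28 Å (van der
Waals-padded), N- and C-termini outside, a lysine loop facing the
lumen, no inter-strand clashes. It is not a refined structure: its
packing is looser than a real pilus (an interior subunit buries ~30%
of its surface against the ~72% of the experimental filament, and has
4 protein neighbours rather than 8), so the buried-area and
neighbour-count statistics computed on it demonstrate and test the
measurement machinery rather than reproduce the experimental values.

## Interface and lumen analysis

- **SASA** — Shrake–Rupley quadrature on a 960-point Fibonacci sphere,
  probe 1.4 Å, element radii C 1.70 / N 1.55 / O 1.52 / S 1.80 /
  P 1.80 Å (H 1.20 if present). Doubling the quadrature changes totals
  by < 0.5%; per-atom areas agree with an independent implementation
  (biotite) to ~3% on matched radii. Components are chains.
- **Buried areas** — buried(component) = SASA(isolated) − SASA(within
  assembly); pairwise buried areas use the reference's loss to one
  neighbour at a time. The two sides of an interface genuinely lose
  slightly different areas (~9% here); the invariant asserted is
  near-symmetry, not equality. Interior subunits of an ideal filament
  are helically equivalent (buried fractions agree to < 1%).
- **Contacts** — neighbour = pairwise buried area > 1 Å² (default; the
  criterion that matches "makes contact" language) or any heavy-atom
  pair < 4.0 Å (alternative, for residue-level cross-checks).
- **Radial geometry** — per-z-slice radial extrema of atom centres;
  lumen diameter = 2× the largest empty coaxial cylinder radius over
  the central half of the filament; outer diameter = 2× the 99th
  percentile of radial extents. Atom-centre and van der Waals-padded
  variants are both reported, since the measurement convention behind
  published diameters is typically unstated.
- **Lumen electrostatics** — a deliberately qualitative screened-
  Coulomb (Debye–Hückel) model: point charges at Arg/Lys (+1), Asp/Glu
  (−1), chain termini (±1) and lipid phosphates (−1), uniform
  dielectric 80, 150 mM ionic strength, 298 K (Bjerrum length 7.0 Å,
  Debye length ≈ 7.9 Å); the summary is the mean potential over a
  cylindrical shell just inside the lumen surface. The one claim this
  model supports is the sign flip: the synthetic assembly's lumen is
  positive without the lipids (+0.3 kT/e) and negative with their
  phosphates in place (−0.9 kT/e). It is not a Poisson–Boltzmann
  solver and its magnitudes should not be over-read.

## Problem sizes and defaults

| stage | default | note |
|---|---|---|
| segment stacks | 240 segments, 96 px, 3.0 Å/px | study-scale emulation |
| SNR | 0.1 | var(signal)/var(noise), whole box |
| defocus | 0.5–3.5 μm underfocus | uniform per segment |
| angular step | 4° | azimuth references, 0–72° for C5 |
| shift search | ± one rise axial, ±4 px lateral | first pass: no axial |
| symmetry search window | ±2°, ±1 Å around the start | anchored |
| IHRSR iterations | ≤ 10, tol (0.05°, 0.02 Å) | typically 3–4 |
| sorting | 200 segments, 5 cycles | ties → class a |
| filament model | 5 strands × 16 units | 80 subunit copies |
| SASA | 960 sphere points, probe 1.4 Å | doubling-stable < 0.5% |

## Known limitations

- The forward model omits structural noise, astigmatism, motion and
  dose-dependent damage; alignment transfer can therefore only be
  validated at the parameter level (see above).
- Full 5-parameter orientation search, gold-standard half-set
  refinement, per-particle defocus refinement and real-space model
  refinement are out of scope.
- The synthetic pilin packs more loosely than the real filament;
  absolute buried-area values are not comparable to experimental ones.
- Non-integer-start and seam-containing lattices, and dihedral point
  groups, are not supported.
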