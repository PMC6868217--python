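# Methods

## The synthetic lattice and what it stands in for

The generator (`lattice_synth`) produces pseudo-helical microtubule walls as
the stand-in for atomic models fitted into cryo-EM reconstructions. Its
parameters, with defaults and units:

| parameter | default | meaning |
|---|---|---|
| `n_pf` (N) | 13 | protofilament count, validated to 8–17 |
| `start` (S) | 3 | monomer helix start number; must be odd (see seam note) |
| `monomer_repeat` (a) | 41.0 Å | axial monomer spacing; dimer repeat 2a = 82 Å |
| `radius` (r) | 105.0 Å | radius of monomer centres |
| `skew_mode` / `skew_value` | `by_theta` / 0 | which of θ (deg), h (Å), ΔPHI/dimer (deg) is imposed |
| `mechanism` | `none` | how skew is realised: `tilt` or `stagger` |
| `seam_index`, `register` | 0, 0 | A-lattice junction position; global α/β register |
| `n_dimers` | 12 | dimers per protofilament (~1000 Å of wall) |
| `pf_radial_offsets` | 0 | per-pf radial displacement, Å |
| `lateral_compression` | 0 Å | reduction of adjacent-dimer COM separation |
| `coord_noise_sd` | 0 Å | isotropic pseudo-atom jitter |
| `seed` | 0 | single generator owning all randomness |

Lattice closure couples the skew parameters through
`tan θ = (S·a − N·h)/(2π r)` and `ΔPHI/dimer = (2a tan θ / r)·180/π`;
`accommodation_solve` completes the triple from whichever one is supplied and
rejects non-physical solutions (|θ| ≥ 90°, h ≤ 0). Positive θ/ΔPHI is
right-handed skew with PHI increasing toward the plus end (+z).

The dimer repeat is the only length printed in the source experiments; the
radius (and hence absolute diameters and chord lengths) is a package choice —
105 Å puts the ~4 Å diameter effects well above coordinate noise — and is
configurable. Absolute diameters are therefore not meaningful, only
differences between lattices measured the same way.

Monomers are 5-point chiral rigid bodies (~20 Å across) rather than points
because the two skew-accommodation mechanisms differ *only* in body
orientation at small skews: `tilt` rotates each body by θ about the local
radial axis so the protofilament behaves as a rigidly tilted rod, while
`stagger` keeps bodies axis-aligned and quantises the tangential offset per
dimer. Centres follow the continuous skewed helix in either case.

**Seam construction.** Junction k lies between pf k and pf k+1 (mod N).
Parity bookkeeping shifts every protofilament past the seam by one monomer,
which makes exactly one junction α-against-β; for the wrap-around junction the
S·a climb of the helix closes the parity loop, which is only consistent with a
single seam when S is odd — even S is rejected at spec validation. `register=1`
translates the whole decoration by a = 41 Å.

**What the generator does not emulate:** atomistic tubulin, nucleotide-state
lattice compaction, density maps, or curvature/breathing of real walls.
Passing tests therefore demonstrate that the *measurements* are correct and
well-conditioned under coordinate noise, not that real reconstructions are
noise-free.

## Geometry measurements

- **Diameter** = 2 × mean radial distance of dimer centres of mass from the
  helical axis, with per-pf radii for asymmetry. Generated lattices carry
  their ground-truth axis (updated under rigid motion) and measurements use
  it; a least-squares cylinder fit (`fit_helical_axis`) serves externally
  loaded coordinates. The distinction matters: asymmetric radial offsets bias
  a fitted axis centre by ~0.1 Å, which would contaminate per-pf offset
  readback that is otherwise exact.
- **Adjacent-dimer separations**: within one lateral turn, each junction's
  dimer is paired with the axially nearest dimer on the next protofilament;
  the seam junction is excluded by default (the comparison concerns B-lattice
  dimers). The measurement ring defaults to the lattice middle, clamped so
  the wrap-around junction's partner (which climbs ~S monomers) exists.
  For the ideal 13-pf lattice the separation is √(chord² + h²) = 51.14 Å with
  chord = 2r·sin(π/13).
- **Lateral angle**: mean azimuth gap between adjacent protofilament centre
  lines about the axis; 360/N for ideal walls, so 13- vs 14-pf differ by
  1.98°. Angles are intrinsic to each lattice's own axis, so comparison needs
  no prior superposition.
- **Skew from segments** (`fit_phi_slope`): per MT, segment rotation angles φ
  are unwrapped into the nearest branch of the protofilament spacing
  (period 360/N, i.e. successive differences mapped into (−180/N, +180/N] —
  per-dimer skew is far below one protofilament spacing) and regressed
  against dimer index; slopes aggregate as mean ± SD across MTs. Monte-Carlo
  tests (16 MTs × 11 segments, φ noise 0.5°, ≥200 replicates) bound the bias
  at 2 SE.

## Tilt / stagger decomposition

`rmsd_profile` reports pseudo-atom RMSD per axial dimer level in two modes.

*global_anchor*: lattice B is aligned to A and the per-level RMSD reported.
Default alignment is a robust whole-lattice fit followed by an anchor-ring
refinement restricted to rotation-about-axis + translation. The restriction
is deliberate: an unconstrained fit to one dimer's 10 atoms (~60 Å extent)
has a rotational uncertainty of several milliradians at 0.3 Å coordinate
noise, which extrapolates to several Å of spurious "growth" across a
~1000 Å lattice; axis-rotation and translation errors, by contrast, displace
all levels equally and leave the profile shape untouched. The literal
single-dimer anchoring is available as `anchor_scope="dimer"`. Because the
anchor ring itself climbs one helix turn, its RMSD is not exactly zero for a
skewed pair — it is the profile minimum.

*per_pf*: each protofilament pair is superposed on that protofilament's
anchor-level dimer and the per-level residual pooled. A tilted protofilament
is an internally rigid transform of its reference, so the residual stays
< 1 Å everywhere; a staggered one shears internally and the residual grows
linearly with axial distance.

`classify_mechanism` labels a pair `none` when the global profile is flat
within 0.25 Å of its anchor value. Tilt vs stagger is decided by the
body/protofilament rotation ratio computed alongside the per-pf profile: each
protofilament's net rigid rotation ψ (whole-pf least-squares fit, precise to
~10 µrad even at 0.3 Å noise) is compared with the mean rotation ω of its
monomer bodies; bodies co-rotating with the protofilament (ω/ψ ≈ 1) mean
tilt, axis-aligned bodies under a rotated path (ω/ψ ≈ 0) mean stagger, with
0.5 as the decision point. This is used instead of thresholding the per-pf
RMSD maximum (kept as the documented fallback at 1.0 Å when orientation
metadata is absent) because a whole-profile threshold is noise-fragile: a
linear stagger shear is absorbable into a rotation, so position-only
statistics carry second-order signal only. The per-pf rotations are measured
after a whole-lattice pre-alignment; around the full cylinder the coupling
between a skew field and an axis tilt cancels by symmetry, leaving only an
axial rotation with no radial component, so the ratio is invariant to rigid
motion of either lattice.

Classification suites: the noise-free confusion matrix covers
N ∈ {13, 14} × |ΔPHI| ∈ [0.05, 0.5]°/dimer and must be diagonal. The noisy
suite (coordinate noise sd 0.3 Å) runs at |ΔPHI| ≥ 0.2°/dimer — the magnitude
scale of CKK-induced skew; at 0.05°/dimer the orientation signal
(~0.01 Å per atom) is physically undetectable under 0.3 Å noise on a
12-dimer lattice, so no estimator could label it reliably.

## Seam/register hypotheses and binding sites

Hypothesis (k, ρ) composes the pseudo-helical symmetry operator k times
(rotation k·360/N, rise k·h) with an optional one-monomer shift ρ·a —
exactly the reference set of a pseudo-helical alignment (26 references for
N = 13). Transforms are deduplicated on (rotation mod 360°, rise mod 2a) at
1e-6 tolerance, since references differing by a whole dimer repeat act
identically on the periodic wall; degenerate parameter coincidences warn
rather than fail. `apply_hypothesis` keeps protofilament labels
azimuth-ordered so the truth seam index stays consistent with junction
labels.

Binding sites are one per non-seam junction per dimer ring at the midpoint of
the two adjacent dimer COMs; axial spacing equals the dimer repeat (8 nm to
the nearest nm). In a finite lattice the wrap-around junction's partner runs
out near the top, producing a few shortened edge gaps; counts per ring (N−1)
follow the junction/ring definition.

## Segment-restraint simulation

Observation noise is modelled as independent channels per 82 Å segment:
Gaussian φ noise with a uniform-outlier fraction, and categorical class /
seam-hypothesis calls that are correct with probability 1−ε, otherwise
uniform over alternatives (hypothesis index = 2·seam + register, so
register-only confusions are separable in the recovery report). Restraints:
per-MT modal class (ties to the earliest-observed class), per-MT circular
median φ after de-trending by the expected skew slope (median via
minimal-arc unwrap around the vector-mean estimate), and per-MT modal
hypothesis. The three stated noise levels for the error-reduction suite are
(φ sd, outliers, class ε, hyp ε) = (1°, 0.1, 0.1, 0.1), (2°, 0.2, 0.2, 0.25)
and (4°, 0.2, 0.3, 0.4), with ≥1000 MTs × 11 segments. Simulating
classification as a noise channel — rather than projecting densities — is
what makes the restraint logic testable at desk scale.

## NMR metrics

- CSP = √((0.15·ΔN)² + ΔH²) ppm, on the amide ¹H/¹⁵N differences.
- CPMG flatness = sample SD / mean of intensities across the refocusing
  grid (50–1500 Hz, constant 40 ms relaxation period); ~0 for a rigid
  backbone. A Luz–Meiboom fast-exchange forward simulator provides positive
  controls.
- CEST dips: baseline = median intensity; contiguous runs more than
  3·noise_sd below it are dips, the deepest (main resonance) excluded. The
  default grid is 8200→6325 Hz at 25 Hz spacing.
- Assignment transfer: greedy mutual-nearest matching in (HN, N, Cα) scaled
  by per-dimension tolerances — the measured ¹H/¹⁵N linewidths 0.1 and
  0.6 ppm; Cα has no printed linewidth, so its tolerance defaults to 0.5 ppm
  and is configurable. Greedy was chosen over global optimisation for
  transparency; on ≤10-peak instances it matches Hungarian-algorithm optimal
  assignment exactly (tested), and at half-tolerance perturbations ~13% of
  peaks fall outside tolerance in at least one dimension, bounding attainable
  recovery.
- Assignment completeness reports the exact percentage to one decimal
  (e.g. 124 assigned of residues 1474–1613 → 88.6%); any coarser rounding is
  left to the caller.

## Structure I/O

PDB/mmCIF parsing via gemmi; synthetic lattices are written one chain per
protofilament (residues ALP/BET, the five body pseudo-atoms as carbon
records), round-tripping to format precision (10⁻³ Å). Chain roles (CKK,
tubulin subunits α1/β1/α2/β2) come from a JSON sidecar because deposited
chain IDs are not portable across entries. The binding footprint is an
inclusive any-atom 5.0 Å distance criterion reported as per-subunit residue
lists and counts — a contact-count proxy, deliberately not a buried-surface
area. `region_rmsd` superposes on a core selection's backbone (N, CA, C, O;
falling back to all shared atom names for pseudo-atom models) and reports
per-region RMSD; divergent-region selections must be user-supplied since
loop boundaries are model-specific.

## Problem sizes and determinism

Default suites use 12-dimer lattices (4 dimers for the Monte-Carlo
architecture-recovery replicates), ≥200 replicates for recovery estimates and
1000–10000 simulated MTs for restraint statistics; these sizes put standard
errors well below the effects measured. All stochastic stages draw from
`numpy.random.default_rng` seeded explicitly; the CLI writes its resolved
config (including seeds) next to every output, and the acceptance script
derives all sub-seeds from its single `--seed`.

## Known limitations

- The tilt/stagger discriminator needs the rigid-body orientation signal; on
  point-only data (no bodies) only the RMSD-threshold fallback applies, with
  its stated noise fragility.
- `lateral_angle` averages azimuth gaps, which is exactly 360/N for any
  closed wall; per-junction values, not the mean, carry asymmetry
  information.
- The wrap-around junction has edge effects near the lattice top (separation
  pairing and site spacing); measurements default to interior rings.
- Real peak lists contain overlapped and missing peaks beyond the Gaussian
  perturbation model used in the transfer tests.
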