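# mtlattice

Quantitative analysis of microtubule (MT) pseudo-helical lattice geometry and
how lattice-binding proteins — in particular CAMSAP/Patronin CKK domains —
remodel it, together with the NMR metrics used to characterise the rigidity of
such domains.

## Who this is for

Structural biologists comparing decorated-MT architectures (e.g. models built
from cryo-EM reconstructions of a minus-end-recognising CKK domain vs. one
without end preference) who need the measurements behind those comparisons in
a desk-reproducible, testable form: protofilament skew per dimer, MT diameter,
adjacent-dimer separations, the interprotofilament lateral angle, tilt-versus-
stagger decomposition of skew, seam/register reference bookkeeping, per-MT
restraint logic, and chemical-shift / relaxation-dispersion summaries.

## The model

A microtubule wall is N protofilaments (pfs) of alternating α/β-tubulin
monomers on a cylinder of radius *r*. Lateral monomer contacts trace an
S-start helix (S = 3 canonically) whose closure around the wall links the
protofilament skew angle θ, lateral monomer rise *h*, axial monomer repeat
*a* (≈ 41 Å, dimer repeat ≈ 82 Å) and radius:

```
tan θ      = (S·a − N·h) / (2π r)
ΔPHI/dimer = (2a · tan θ / r) · 180/π
```

Positive θ is right-handed skew (the rotation angle PHI increases toward the
plus end). For N = 13 the closure is satisfied with θ = 0; a 14-pf wall at the
same rise is left-handed (θ < 0). Skew can be *accommodated* two ways: whole
protofilaments tilt as rigid rods, or successive dimers stagger tangentially
while staying axis-aligned. The two are indistinguishable for point lattices,
so every monomer in the synthetic generator carries a 5-point rigid pseudo-atom
body (~20 Å): in tilt the bodies co-rotate with the protofilament, in stagger
they do not, and the package's mechanism classifier exploits exactly that.

The wall is a B-lattice (α beside α) with a single A-lattice seam, which
breaks helical symmetry: alignment of a pseudo-helical MT must consider 2N
references (N seam positions × two α/β registers, the register mate translated
one monomer along the axis). CKK binding sites sit at the intradimer,
interprotofilament junctions — one per non-seam junction per dimer ring,
spaced one dimer repeat (~8 nm) axially.

NMR metrics implemented: the combined amide chemical-shift perturbation
`CSP = √((0.15·ΔN)² + ΔH²)` (ppm), the CPMG relaxation-dispersion flatness
ratio SD/mean across refocusing frequencies (low = no millisecond exchange),
CEST minor-dip scanning, and assignment transfer by spectral proximity in the
(HN, N, Cα) dimensions.

## Worked example

Generate an unskewed 13-pf reference and a 13-pf lattice with
+0.25°/dimer skew realised by whole-protofilament tilt, then measure and
classify:

```
$ mtlattice generate --n-pf 13 --out ref
$ mtlattice generate --n-pf 13 --skew-mode by_dphi --skew-value 0.25 \
    --mechanism tilt --out hs
$ mtlattice measure --config hs/config.json --out m
{
  "diameter": 209.99987505927385,
  "mean_separation": 51.2037352830988,
  "lateral_angle_deg": 27.692307692307693,
  "truth_dphi_per_dimer": 0.25
}
$ mtlattice decompose --config-a ref/config.json --config-b hs/config.json --out d
{
  "label": "tilt",
  "confidence": 1.0,
  "pf_rotation_deg": 0.32011610803019785,
  "body_rotation_deg": 0.32013137151776305,
  "orientation_ratio": 1.0000472663141042
}
```

Reading the numbers: the diameter is 2r = 210 Å (the generator default), the
mean adjacent B-lattice dimer separation is √(chord² + h²) ≈ 51.2 Å, and the
lateral angle is 360/13 = 27.69°. The decomposition finds that each
protofilament is rotated ~0.32° about its radial axis relative to the
reference and that the monomer bodies carry the same rotation
(orientation ratio ≈ 1), i.e. the skew arises from whole-protofilament
tilting, not interdimer stagger. A stagger-generated lattice gives the same
`pf_rotation_deg` but `body_rotation_deg ≈ 0`.

Other entry points: `mtlattice seamgrid --n-pf 13` (the 26-row seam/register
reference table), `mtlattice sites`, `mtlattice simulate-pipeline`,
`mtlattice nmr csp|cpmg|cest|transfer`, `mtlattice footprint`,
`mtlattice region-rmsd`. Every command writes a JSON config sidecar from
which its outputs can be regenerated bit-identically.

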