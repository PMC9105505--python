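# Methods

`shp2md` quantifies the conformational state of the SHP2 N-SH2 domain —
and its coupling to intramolecular interfaces — from conformer streams
stored as multi-model PDB files. This note records the models, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## The scientific setting

SHP2 is a tandem-SH2 tyrosine phosphatase (domains in author numbering:
N-SH2 1–103, C-SH2 111–213, catalytic PTP 253–529, exon-6-encoded region
E6 215–252). The enzyme self-inhibits by docking the N-SH2 D'E loop
(58–62) into the catalytic pocket. Independently of docking, N-SH2 has a
closed and an open conformation, distinguished by the separation of its
EF (66–68) and BG (89–92) loops, which gate the phosphotyrosine-peptide
cleft: the Gly67 Cα–Asn92 Cα distance is about 8.2 Å in the closed
crystal arrangement and about 14.8 Å in the open one. The analyses here
measure which state an ensemble occupies, how interfaces with E6 and the
other domains behave, and whether a suite of simulations supports a
statistically coherent closed-versus-open outcome across wild-type-like
and mutant-like constructs.

## Interface mapping

A residue of region A is *interfacial* with region B in a frame when its
closest heavy atom lies within a threshold (default 5.0 Å) of any heavy
atom of B. Hydrogens never participate. Covalent-junction residues are
excluded by default (the N-SH2/C-SH2 linker 104–110 and the E6 junction
residues Gln214 and Thr253) so maps report non-bonded contact only.
Heat maps collect per-residue minimum distances over frames; a reference
crystal structure may occupy column 0. Distances above a display cap
(default 10 Å, configurable — the cap is cosmetic, only the 5-Å
inclusion rule is normative) are exported as "absent". Residues
interfacial in ≥ 50 % of analyzed frames are classified *stable*,
otherwise *transient*; the 50 % cutoff is an operational choice and is
configurable. Nearest-neighbor queries use a k-d tree; correctness is
pinned by exhaustive all-pairs oracle tests.

## Surface areas and buried interface area

Per-atom exposed areas use Shrake–Rupley quadrature: for each atom,
the fraction of quasi-uniform points on its inflated sphere
(radius = r_vdw + probe) lying outside every neighbor's inflated sphere,
times 4π(r + p)². Points come from a Fibonacci lattice (deterministic,
near-uniform), default n = 960; the 50-atom convergence check
(960 → 1920 points) moves totals by < 1 %. Because the lattice is fixed
in space, individual atom areas are rotation-invariant only up to
quadrature noise (≈ 1–2 % per atom, ≈ 0.05 % on totals) — tests assert
at those tolerances. Van der Waals radii are a bundled Bondi-style
element table; unknown elements fall back to 1.70 Å with a warning.

The buried area between two disjoint regions is

    buried = (A_A + A_B − A_complex) / 2,

with each area computed over heavy atoms, the regions in isolation and
jointly. The default probe radius is **0** (van der Waals surface),
because the interface-area comparison is defined on vdW surfaces; a
1.4-Å water-probe SASA mode is available.

## Groove volume between the EF and BG loops

The phosphopeptide cleft volume is estimated on a grid. The measuring
envelope is a finite **cylinder** around the axis joining the Cα
centroids of the two mouth loops (default radius 6 Å; a signed axial
margin can lengthen or shorten it). A grid cell (default 0.5 Å spacing)
counts when its center is (i) inside the envelope, (ii) outside every
atom sphere (r_vdw + probe), and (iii) connected to the envelope
boundary by a 6-neighbor flood fill — sealed interior voids are not
groove. A cylinder rather than a rounded capsule was chosen because it
admits an exact closed-form oracle on the clamp fixture (see below);
the absolute volume of a groove is in any case definition-dependent, and
only ordinal comparisons across constructs (closed < mutants < open) are
treated as meaningful. Ensemble averages take one snapshot per
nanosecond across the analysis window (default 3–30 ns, i.e. 28
snapshots), reported as mean ± sd.

## Loop-separation distributions and joint deconvolution

Distance observables (the EF/BG gate Gly67 Cα–Asn92 Cα, plus
Pro38 Cα–Thr59 Cα, Thr59 N–Tyr62 O, Lys55 O–Tyr66 N, Ser36 Cα–Lys55 Cα)
are summarized as conformer-fraction curves: the fraction of all frames
whose value falls in a sliding window of width 1.5 Å (0.15 nm). The
default step is width/5 for smooth curves; with step = width the windows
tile disjointly and the fractions sum to exactly 1. Fractions are
normalized per total frame count.

Several constructs' curves for the same observable form a *column* and
are fit jointly: K Gaussians with centers and widths **shared across all
curves** and per-curve non-negative amplitudes, minimizing the summed
squared error. This synchronization makes ensemble populations
comparable across constructs through the amplitudes of corresponding
components. The optimizer is bounded trust-region least squares with
multi-start (default 20 seeded starts; centers initialized at quantiles
of the pooled curve mass, amplitudes re-initialized per start by
non-negative least squares). Results are deterministic for a fixed seed;
non-convergence is flagged on the result, not raised. K is fixed by the
caller (no model selection). Note that a fraction curve is the
underlying distribution convolved with the window boxcar, so a width
fitted to sampled-frame curves estimates sqrt(σ² + w²/12), not σ; tests
that assert exact width recovery therefore construct curves directly
from the Gaussian model.

## Cation–pi detection

A lysine/tyrosine cation–pi contact holds in a frame when
L ≤ L_max and θ ≤ θ_max, with L the distance from the lysine Nζ to the
centroid of the six tyrosine ring atoms (CG, CD1, CD2, CE1, CE2, CZ) and
θ the angle between the ring normal and the Nζ–centroid segment, folded
into [0°, 90°]. The normal is the smallest-eigenvalue eigenvector of the
ring atoms' centered covariance, robust to slight non-planarity.
Defaults are L_max = 8.0 Å and θ_max = 60°. The literature quotes both
8 Å (in methods prose) and 7 Å (in a figure caption) for the L
criterion; this package defaults to the methods value and emits a
warning naming the ambiguity on every call, so a deliberate choice is
always on the record.

## Averaged conformers

Frames are superposed onto the first frame over an alignment selection
(backbone N/CA/C/O by default; "backbone" is the standard four-atom
set), positions averaged, and the per-residue Cα RMSD about the mean
stored in the B-factor column — the quantity rendered as ribbon
thickness in sausage plots. RMSD is unweighted. Superposition is the
SVD Kabsch solution with determinant sign correction, so a reflection is
never returned, including for degenerate (collinear) selections.

## Outcome test

For a suite of n simulations of which g are wild-type, the probability
that all g closed-conformation retainers are exactly the wild-type runs
is the hypergeometric point probability C(g,m)·C(n−g,g−m)/C(n,g) at the
observed m; for n = 6, g = m = 3 this is 1/20 = 0.05. The point
probability (not a tail) is the default because only that reading yields
0.05 for the perfect split; an upper-tail option exists. In the
pipeline, a construct "retains closed" when its median EF/BG separation
over the analysis window is below a cutoff, default 11.0 Å — the
midpoint between the upper edge of closed-ensemble separations
(≈ 10.4 Å) and the lowest mutant intermediate (≈ 11.7 Å).

## The synthetic generator

The generator produces pseudo-domains with standard atom names so every
selector works unchanged, and it plants ground truth exactly:

* the EF/BG separation of each frame is drawn from a prescribed Gaussian
  mixture (or a two-state Markov chain) and then imposed exactly by
  placing the BG marker along a fixed axis;
* the cation–pi geometry is satisfied in an exactly rounded fraction of
  frames, with (L, θ) placed analytically relative to the jittered ring;
* per-residue isotropic jitter has configurable σ (an isotropic σ
  implies a Cα RMSD about the mean of σ√3);
* clamp fixtures (two atom walls) have closed-form cavity volumes:
  V = πR²s − n_inside·(2/3)πr³, wall atoms non-overlapping and rim atoms
  omitted so every interior intrusion is exactly a half-ball;
* two-domain complexes have an exact closest heavy-atom gap, optionally
  bridged by a strap segment contacting both sides within 5 Å.

Default ensemble sizes mirror the analyzed recording protocol: 5-ps
conformers over a 3–30 ns window (5400 frames). What the generator does
**not** emulate: force-field energetics, solvent, realistic protein
packing and density, correlated loop motions, or secondary structure.
Passing tests therefore demonstrate that the measurement pipeline
recovers known inputs at the stated tolerances — not that any particular
biological system behaves this way.

A specific consequence: the crystallographic anchor check (8.2 Å closed
/ 14.8 Å open at the Gly67/Asn92 Cα pair) is run on synthetic stand-in
domains that plant those separations by construction, exercising the
parse → select → measure path end to end. Verifying the anchors against
the real crystal structures requires downloading the corresponding PDB
entries and measuring the same atom pair with `shp2md distances`.

## Numerical and I/O choices

* PDB author numbering throughout; 1-based inclusive residue ranges.
* Alternate locations: highest occupancy kept; insertion codes rejected
  with a clear error.
* Multi-model files: one frame per MODEL; topological identity enforced;
  frame times default to index × 0.005 ns.
* Series exports are tab-separated text; structure annotations ride the
  B-factor column of standard PDB output.
* All randomness flows through `numpy.random.default_rng(seed)`; the
  pipeline summary is serialized with sorted keys and rounded floats so
  identical seed + config gives byte-identical summaries.

## Problem sizes used in the shipped checks

The shipped test-suite and acceptance-script runs use deliberately
desk-scale inputs: 960-point quadrature, 0.4–0.8 Å volume grids,
ensembles of 300–5400 frames, and a six-construct suite of 300-frame
ensembles. These sizes already put every estimator well inside its
asymptotic regime for the planted conditions; larger inputs change
runtimes, not conclusions.

## Known limitations

* Absolute groove volumes depend on the envelope definition and are not
  comparable across tools; only within-definition comparisons are valid.
* Shrake–Rupley areas carry fixed-lattice quadrature noise (see above).
* The closed/open classification is a single-observable median cutoff;
  ensembles straddling the cutoff (fitted mass split near 50/50 around
  11 Å) would need the full column fit, which the summary also reports.
* mmCIF, binary trajectory formats, solvent/ion handling, mass-weighted
  RMSD, and hydrogen-bond/salt-bridge typing are out of scope.
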