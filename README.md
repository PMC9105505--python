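# shp2md

Post-simulation analysis of the closed/open conformational equilibrium
of the SHP2 N-SH2 domain from molecular-dynamics conformer streams.

## The problem

SHP2 (gene *PTPN11*) is a tandem-SH2 tyrosine phosphatase that
self-inhibits by docking its N-SH2 domain (residues 1–103) onto the
catalytic PTP domain (253–529). Independently of that docking, N-SH2
switches between a **closed** and an **open** conformation, gated by the
separation of its EF (66–68) and BG (89–92) loops: the Gly67 Cα–Asn92 Cα
distance is ≈ 8.2 Å in the closed crystal arrangement and ≈ 14.8 Å in
the open one, and only the open state admits phosphotyrosine (pY)
peptides into the binding cleft. The exon-6-encoded region (E6, residues
215–252) bridges N-SH2, C-SH2 and PTP in the self-inhibited enzyme and
modulates the stability of the closed state.

`shp2md` is for structural bioinformaticians who have such conformer
ensembles (multi-model PDB) and want reproducible, tested measurements
of:

* **interfaces** — residues of one region within 5 Å (heavy atoms) of a
  partner region, tracked per frame as heat-map matrices;
* **buried interface area** — A = (A₁ + A₂ − A₁₂)/2 from Shrake–Rupley
  van der Waals surfaces (probe 0 by default; SASA mode available);
* **groove volume** — grid estimate of the pY-peptide cleft between the
  BG and EF loops, inside a cylindrical envelope, flood-filled so sealed
  voids never count, averaged over 1-ns snapshots;
* **loop-separation distributions** — fraction of conformers per 0.15-nm
  sliding window, deconvolved with **column-synchronized Gaussians**:
  centers and widths shared across all constructs of a column, per-curve
  non-negative amplitudes, so ensemble populations are directly
  comparable across constructs;
* **cation–pi contacts** — lysine Nζ to tyrosine ring centroid, counted
  when L ≤ 8 Å and θ ≤ 60° (θ measured from the ring normal);
* **averaged conformers** — Kabsch-aligned mean structures with
  per-residue Cα RMSD in the B-factor column;
* **outcome statistics** — the hypergeometric point probability that all
  closed-conformation retainers in a simulation suite are exactly the
  wild-type runs: C(g,m)·C(n−g,g−m)/C(n,g); for 6 runs with a perfect
  3/3 split, p = 1/C(6,3) = 0.05.

A first-class synthetic-data module generates ensembles with *planted*
ground truth (mixture-distributed loop separations, exact cation–pi
contact fractions, clamp fixtures with closed-form cavity volumes), so
every stage is testable without MD engines or downloads.

## Worked example

Generate a 1200-frame synthetic ensemble whose EF/BG loop separation is
a 60/40 mixture of closed (8.8 Å) and open (13.6 Å) states, with a
cation–pi contact planted in 40 % of frames; then measure it back:

```
$ shp2md simulate --n-frames 1200 --mixture 0.6:8.8:0.6 0.4:13.6:0.8 \
      --cation-pi-fraction 0.4 --seed 11 --out ensemble.pdb --truth truth.txt
$ shp2md distances ensemble.pdb --pair A:67:CA A:92:CA --out sep.tsv
$ head -4 sep.tsv
# A67(CA)-A92(CA)
time_ns	distance_A
0	8.2750
0.005	9.8200
```

Build the conformer-fraction curve and deconvolve it with two Gaussians
(in a multi-construct study all curves of a column are fit jointly):

```
$ shp2md fit curve.tsv -k 2 --seed 1 --out fit.tsv
centers: [8.799, 13.626] widths: [0.748, 0.938] residual: 0.000893549
```

The shared centers land on the planted 8.8/13.6 Å states (the fitted
widths include the 1.5-Å window smearing, √(σ² + w²/12)). The detectors
recover the planted contact fraction exactly, and the perfect-split
outcome probability is 0.05:

```
$ shp2md cation-pi ensemble.pdb
cation_pi_fraction	0.400000
$ shp2md test --n-total 6 --n-group 3 --matches 3
hypergeometric_p	0.05
```

`shp2md all` runs the full pipeline (RMSD, distances, curves, joint
fits, groove volumes, cation–pi, averaged conformers, outcome test) on a
YAML manifest of constructs — by default a six-construct suite of three
wild-type-like runs that retain the closed conformation and three
mutant-like runs that convert to open — writing per-construct TSV/PDB
outputs and a deterministic `summary.json`.

Other subcommands: `rmsd`, `interface`, `buried-area`, `volume`,
`average`, `simulate`. Region definitions are plain text
(`name: chain:start-end`); the built-in map carries the SHP2 domain and
loop boundaries.

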