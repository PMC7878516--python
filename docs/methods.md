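# Methods

This note records the models, conventions and numerical choices behind
`ccpocage`, and what the synthetic fixtures do and do not establish.

## Topology model

A cage graph is a simple connected graph; every edge is one CC dimer.
A **double trace** is a closed walk covering each edge exactly twice.
Admissibility adds one local rule: the walk never immediately retraces
the edge it just used (`u→v` directly followed by `v→u`), including
across the closed walk's wrap-around. Immediate reversal is permitted
only at degree-1 vertices, where it is the only continuation, so the
single-edge graph keeps its unique trace. This rule is a minimal
stand-in for the vertex-stability conditions used by full design
pipelines; a stricter predicate can be injected through the
`stability_filter` hook of `enumerate_double_traces`. Enumeration is
exhaustive depth-first search with rotation canonicalisation; a
`max_count` cut-off is reported distinctly (`TraceLimitExceeded`) from
an empty result, so truncation can never masquerade as non-existence.

**Orientation.** An edge whose two traversals run in the same vertex
direction is a parallel dimer; opposite directions are antiparallel.

**TCO.** For a chain topology the score is the mean of |i − j| over
intra-chain paired segment indices, divided by the total segment count.
Inter-chain (interface) pairs are excluded from the mean and reported
separately; only the *ranking* of permutations is treated as
meaningful, so the normalisation convention (segment count rather than
residue count) matters only for cross-design comparisons, which we do
not make. Ties are broken by lexicographic segment order, making every
ranking deterministic for a fixed vertex labelling.

**The reference bipyramid design** is found by search, not hard-coded:
among all double traces of the trigonal bipyramid, keep circular
permutations whose half-way cut leaves exactly three inter-half pairs,
all parallel (a hetero-oligomerisation interface needs parallel
heterodimers), whose halves are pseudo-mirror images (index translation
or reflection of the intra-half pairing), and whose per-half demand for
distinct antiparallel modules fits the toolkit budget (two orthogonal
antiparallel homodimer modules). Candidates are ranked by TCO. The
winner has 18 segments, 9 + 9 mirrored halves, and seven parallel plus
two antiparallel dimers. The module-budget constraint is decisive: the
TCO optimum is degenerate between a 7 + 2 and a 3 + 6
parallel/antiparallel composition, and only the former is assignable
from a library with two antiparallel modules.

**Splits.** `trim_terminal(k)` detaches the C-terminal k segments
(16 + 2 for k = 2). `symmetric_split` cuts at the midpoint and requires
exactly three crossing pairs. `masked_switch` starts from the symmetric
split and, per chain, appends C-terminal masking segments that pair
intramolecularly with all but one interface segment, leaving a single
exposed segment per chain unpaired (its intermolecular partner is kept
as *latent* pairing) and placing a protease cleavage junction between
the 9th and 10th segments. The two studied permutations of the
symmetric split ("a": interface segments buried in loops; "b":
interface segments adjacent to free termini) are generated by
re-opening each tetrahedral subunit — a closed sub-walk — at every
vertex and taking the extremes of an interface-burial score.

## Sequence layer

The packaged CC library is synthetic: 32-residue idealised heptad
peptides (4 heptads with Ile/Leu cores, E/K charge patterns and
module-specific b/c/f surface palettes, plus short caps). "SH" variants
re-use the orthogonality group of their parent module with charged
surface positions. Assignment is a deterministic backtracking search:
orientation must match, a module group may appear once per
orthogonality scope, mirrored pairs of a pseudo-symmetric design share
one module (`mirror_reuse`), and interface pairs prefer the
higher-helicity variant when `interface_variant="SH"`.

Masses are average isotopic residue masses plus one water
(18.0153 Da), via Biopython. The TEV convention is ENLYFQ↓(G/S); the
scissile bond follows the Q. The default inter-segment linker is
`GSGPG` (5 residues) and the default N-tag a His8 stand-in; both are
configuration, not science.

## Coarse-grained builder

Each segment is an ideal poly-CA helix (1.5 Å rise, 2.3 Å radius,
100°/residue) moved as a rigid body. The energy is

* **pairing restraints** between registry-matched CAs (index-reversed
  for antiparallel dimers). Targets are the distances measured in an
  explicit ideal dimer: a constant 10 Å for parallel (in-phase helices
  at 10 Å axis separation) and the flipped-helix construction for
  antiparallel. Using geometrically attainable targets lets the
  restraint energy reach zero, which a uniform 10 Å antiparallel target
  cannot;
* **linker springs**: flat-bottom quadratic on each junction gap above
  the loop contour length (5 residues × 3.8 Å);
* **soft-sphere clashes**: quadratic penalty below 4 Å between beads of
  non-adjacent segments.

The protocol replaces molecular dynamics with seeded Metropolis
Monte-Carlo: pairs are activated one at a time in chain order, the
newly activated partner is docked near its mate in ideal dimer
geometry, and all touched segments are annealed (10 temperatures,
geometric 4 → 0.25 kT, 10 sweeps each; 35% of moves translate/rotate a
formed dimer as one unit so packing can relax without breaking
pairing). A final polish re-anneals everything and quenches downhill,
re-docking any dimer whose restraint RMS exceeds the 1.0 Å convergence
threshold (up to three repair rounds). Identical seeds give bitwise
identical coordinates; ensembles draw replica seeds from a spawned
`SeedSequence`. Non-converged replicas are returned flagged, never
silently dropped.

Linker residues are not explicit during optimisation; for scattering
and output they are interpolated as straight-line beads so the bead
count matches the sequence. The cavity radius is the largest
bead-free sphere centred at the bead centroid (probe 2 Å).

Under the default study conditions (32-residue segments, 5-residue
loops) converged bipyramid replicas land at R<sub>g</sub> ≈ 2.8–4.8 nm
and D<sub>max</sub> ≈ 10–16 nm. Experimental values for the real cage
are somewhat larger, as the measured construct carries tags and
disordered termini that the coarse model does not, and solution
profiles weight expanded conformers.

## SAXS

Canonical units are nm⁻¹/nm; file readers auto-detect Å⁻¹ grids
(q<sub>max</sub> < 1 heuristic, overridable) and synthesise a flagged
2% σ column when absent. The Debye sum uses a uniform per-CA form
factor evaluated through a 0.005 nm distance histogram; this
dummy-residue model has no hydration shell or excluded-volume term, so
its χ against real data is biased at q ≳ 2 nm⁻¹ and model/data χ values
are treated as brackets, not point estimates. Guinier fits are weighted
linear fits of ln I vs q² on a window shrunk iteratively until
q<sub>max</sub>·R<sub>g</sub> ≤ 1.3; the sphere identity
R<sub>g</sub> = √(3/5)·R is recovered within 2% (the residual bias is
the curvature of the sphere profile inside the admissible window). The
IFT solves non-negative least squares for p(r) with pinned endpoints
and a second-difference smoothness penalty; the regularisation weight
is scaled from the *median* data-row power so heavily down-weighted
high-q rows cannot dominate, and D<sub>max</sub> is the smallest scan
value whose misfit is within 5% of the scan minimum (the plateau
onset). χ uses the closed-form optimal scale and an N − 1 denominator.

V<sub>r</sub> evaluates the ratio of two profiles on the union of their
grids in 0.15–1.5 nm⁻¹ (log-linear interpolation), averages it in bins
of width π/40 nm⁻¹ anchored at 0.15 (17 full bins plus the kept partial
bin), and sums the normalised adjacent-bin differences divided by the
number of bins. Per-bin *geometric* means make the statistic exactly
symmetric and scale-invariant — the choice among binning conventions
was made for these provable invariances. Note that the statistic
diverges where a profile passes through zero (scattering minima of
ideal bodies); experimental profiles are noise-filled and do not
trigger this.

## CD, melting, ITC, FRET

Helicity uses the infinite-helix reference −39,500 deg cm² dmol⁻¹ with
the 1 − 2.57/n finite-length correction; values are reported unclamped.
The MRE conversion divides by the full residue count n (pass n − 1 for
the peptide-bond convention).

Melting fits are van 't Hoff equilibrium models with ΔC<sub>p</sub> = 0
and linear folded/unfolded baselines; the three-state model is
sequential N ⇌ I ⇌ D with the intermediate's signal a free fraction
s<sub>I</sub> ∈ [0, 1] between the baselines. Fitting is seeded
multi-start least squares (gradient-peak T<sub>m</sub> guesses plus
random perturbations); uncertainties come from the covariance of the
best run, and transitions at the data boundary are flagged.

The ITC model is the exact 1:1 quadratic-root bound fraction with
standard displaced-volume dilution per injection; free parameters are
n, log₁₀K<sub>d</sub>, ΔH and a constant per-injection offset, the
customary small first injection is excluded by default, and the Wiseman
c = n·M<sub>t</sub>/K<sub>d</sub> is reported with a 5–500 reliability
flag. The FRET ratio interpolates the emission spectrum linearly at
668 and 566 nm.

## Synthetic data

Generators are pure functions of (parameters, seed) with Gaussian noise
(relative + floor) and bit-identical regeneration from their manifests;
truth parameters live in the manifest, never in the data file. Defaults
mirror the measurement protocols: 5–92 °C melting grids at 1 °C
spacing (a 1 °C/min ramp read every minute), VP-ITC-like titrations
(1.4 ml cell, ~1 µM analyte, 28 injections of 10 µl at 10 µM with a
2 µl first injection), 548–800 nm emission grids. They deliberately
omit instrument baselines, buffer-subtraction artefacts, inter-particle
scattering, aggregation and photobleaching — so recovery tests
demonstrate correctness and identifiability of the fitters under the
stated noise model, not robustness to real-instrument systematics.

## Known limitations

* The builder's energy has no attractive non-specific term, so
  phenomena driven by non-specific association — notably the collapsed
  conformation of the loop-constrained split-cage permutation — are
  outside its reach; ensembles differ between split permutations only
  through connectivity geometry, and the internal-cavity statistics of
  the two variants overlap.
* The packaged peptide library is synthetic; sequence-level constants
  (chain masses, fragment masses) reproduce the *structure* of the
  published calculations, not their numerical values.
* The Debye model is reliable at low/mid q only; no absolute-scale
  calibration is attempted.
* Double-trace enumeration is exponential in edge count; graphs beyond
  ~12 edges require `max_count` truncation (the bipyramid's full set of
  20,440 canonical traces enumerates in seconds).
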