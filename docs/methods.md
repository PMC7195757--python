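# Methods

## The cardinality model

Fragment-assembly prediction draws insertion candidates from per-window,
rank-ordered fragment lists (25 9-mers, 200 3-mers per window in the
standard protocol). `fragcard` conditions the number of *available*
candidates on the window's predicted 3-state secondary structure. A
k-residue window starting at position w (1-based; windows run
1 … L−k+1) is classified as

- **pure helix** — all k residues predicted H,
- **pure strand** — all k residues predicted E,
- **mixed** — everything else, including any window touching coil.

The default policy maps (k, class) → maximum count as 9-mers: 1 / 25 / 25
and 3-mers: 5 / 25 / 200 for helix / strand / mixed. Truncation keeps the
*first* n candidates in file order. This relies on the assumption that
file order is the picker's score order; no re-scoring is attempted, and
windows are never re-populated. With all counts at 25/200
(`CardinalityPolicy.standard()`), customization is the identity.

The rationale is empirical and reproducible with the `quality` module:
when candidate quality degrades with rank, the best-of-top-m RMSD curve
flattens quickly for helical windows and slowly for coil, so most of a
helix window's list contributes nothing but search-budget dilution.

### Count selection

For a set of windows of one class, `gain_table` computes, for consecutive
set sizes n < m (default grid 1, 5, 10, …, 40),

    gain(n→m) = mean over windows of 100 · (best_n − best_m) / best_n ,

where best_n is the minimum candidate RMSD among the top n. Gains are
≥ 0 by construction. `select_count` returns the smallest m beyond which
every subsequent consecutive gain falls below a negligibility threshold
τ. Two thresholds are exposed because both appear as decision rules in
practice: τ = 1.5 % ("further candidates improve the helix best by less
than 1.5 %", yielding 5 for helix 3-mers) and τ = 0.2 % (tail
negligibility, yielding 25 for strand 3-mers on curves where the 5→10
gain is still ≈ 4 %). The *relative* form of the gain (percentage of the
smaller set's best RMSD) is this package's definition; an absolute
percentage-point reading would need a normalized score and is not
implemented.

Candidate RMSD is measured on N/CA/C atoms (3k points per k-mer) between
the candidate's ideal-geometry rebuild and the native window, after
Kabsch superposition. Three points per residue keep 3-mer superpositions
well conditioned; CA-only RMSD on 3 points is nearly degenerate.

## Geometry

- **Superposition** is delegated to
  `scipy.spatial.transform.Rotation.align_vectors` (Kabsch with the
  determinant correction, so reflections are excluded). The test suite
  cross-checks it against an independent brute-force oracle: an
  Euler-angle grid (20° steps) followed by Nelder–Mead refinement,
  agreeing to 1e-3 Å on small point sets.
- **GDT_TS** is CA-based: for each threshold (1, 2, 4, 8 Å) the reported
  percentage is the best found by an LGA-style iterate-and-trim
  heuristic — seed superpositions from all residues and from every
  contiguous 20-residue segment; per seed, superpose on the kept set,
  re-select residues under threshold, repeat to convergence or 10
  rounds. The heuristic is deterministic. A `fixed_frame` mode skips
  superposition entirely (testing hook). This approximates, but is not,
  the exhaustive LGA search used by MaxCluster-style tools.
- **Torsion → Cartesian** building uses natural-extension (NeRF)
  placement with fixed ideal covalent geometry: bonds N–CA 1.458,
  CA–C 1.525, C–N 1.329 Å; angles N–CA–C 111.2°, CA–C–N 116.2°,
  C–N–CA 121.7°; ω defaults to 180°. Residue 1 is seeded canonically (N
  at origin, CA on +x, C in the xy plane); φ₁ and ψ_L/ω_L are inert and
  reported as NaN by `extract_torsions`. The round trip is exact to well
  below 1e-6°. Bond lengths and angles are never perturbed, so "RMSD ≈ 0"
  for a native-torsion fragment holds only against natives built with the
  same ideal geometry — which is what the synthetic module produces.

## Assembly simulator

`run_protocol` starts from a fully extended chain (φ, ψ, ω = −135, 135,
180) and performs two phases of random fragment insertion — 9-mers then
3-mers, defaults 28,000 and 8,000 attempts matching the standard
protocol; desk-scale experiments here use reduced budgets (300 + 100 for
the benchmark, 2,000 + 2,000 for the convergence check; chosen as the
smallest budgets at which the policy signal and the convergence property
are comfortably reproducible). Each attempt draws a window uniformly,
then a candidate uniformly among that window's available candidates
(uniformity is an assumption, stated here, not a claim about any
particular production tool), splices the candidate's torsions in, and
accepts by the Metropolis criterion: always if ΔE ≤ 0, else with
probability exp(−ΔE/T). Temperature decays geometrically from 2.0 to 0.1
across each phase — the shape of the schedule matters more than the
endpoints for the comparisons made here, and these values keep
early exploration and late quenching at desk scale.

The energy is a deliberate surrogate (production coarse-grained energies
are out of scope) with three terms on the CA trace and torsions:

- **clash**: Σ over CA pairs |i−j| ≥ 3 of max(0, 4.0 Å − d)², weight 1.0;
- **compactness**: (Rg − 2.2·L^0.38)², weight 0.1 — the power law is a
  standard globular-protein radius-of-gyration scaling;
- **SS agreement**: fraction of residues whose (φ, ψ) bin (helix:
  φ ∈ (−100, −30), ψ ∈ (−80, −5); strand: φ ∈ (−180, −90), ψ ∈ (90, 180);
  else coil) disagrees with the target annotation, weight 1.0.

This score makes fragment choice matter and folds 30–60-residue synthetic
targets to their natives when given native-torsion fragments; it has no
pretension to rank conformations of real proteins.

Reproducibility: each decoy runs on its own `numpy` PCG64 stream seeded
with `base_seed + i`, so a decoy set is identical regardless of execution
order or worker count.

## Blind assessment

`blind_report` mimics CASP submission scoring over a decoy set: decoys
are ranked by ascending energy (ties broken by seed); the **first model**
is the GDT_TS of the lowest-energy decoy, **best of 5** the maximum GDT
among the five lowest-energy decoys, **top-5 average** their mean, and
**best decoy** the score-blind maximum over the whole set. Only
best_decoy ≥ best_of_5 ≥ top5_avg are structural invariants; the first
model may be any of the five. `compare_runs` reports both the relative
change of mean GDT (percent of run A's mean) and the absolute
point difference, because "+x %" summaries are ambiguous between the two
readings; both columns are labeled.

## Synthetic data

The generators define the study conditions for every test and benchmark:

- **Natives** (`ideal_structure`): helix residues at (−57, −47), strand
  at (−119, 113), coil φ ~ U(−160, −50) and ψ uniform over
  (60, 180) ∪ (−180, −150) — a crude Ramachandran coil proxy of this
  package's own choosing — all with ω = 180, built through the geometry
  module. Coil sampling is seeded; targets without coil are
  seed-independent.
- **Libraries** (`noisy_library`): candidate rank r carries the native
  window torsions plus Gaussian noise of sd σ₀·(1 + α·(r−1)) degrees,
  wrapped to (−180, 180]. With probability `decoy_fraction` a candidate
  of rank ≥ 2 is instead drawn from the wrong-SS torsion basin; rank 1 is
  always basin-correct, emulating the observed reliability of top-ranked
  picker output for regular secondary structure. Record SS labels always
  match the native annotation. Homolog exclusion is not modeled — the
  libraries are non-homologous by construction.
- **Benchmark suite** (`toy_target_suite`): 12 targets, lengths 30–60,
  spanning helix-rich, strand-rich and mixed compositions, with 25 9-mers
  and 50 3-mers per window under σ₀ = 2°, α = 0.4, decoy_fraction = 0.05.
  The 3-mer count is a scaled-down stand-in for 200 (the mixed-class
  truncation is then a no-op, which biases the benchmark *against* the
  customized policy if anything); σ₀ = 2° makes rank-1 candidates
  near-native, and α = 0.4 spreads deep ranks over tens of degrees so
  rank actually encodes quality.

What passing tests on these data do and do not show: the synthetic
libraries make rank a clean proxy for quality and the natives obey ideal
covalent geometry, so the benchmark demonstrates that the cardinality
mechanism exploits rank-quality correlation — the direction of the
effect — not that any particular GDT improvement would be obtained with
real picker output, real energies, or real structures.

The packaged 24-row dataset table (lengths, SS compositions, and the
relative sizes of customized fragment files, with five hard targets
flagged) is a transcription fixture; its column means are asserted
against the printed average row (length 88.7, helix 42.3 %, strand
20.7 %, coil 37.0 %, 9-mer size 82.1 %, 3-mer size 49.0 %).

## Numerical choices and degenerate inputs

- Angles are stored in degrees and normalized to (−180, 180]; angle
  comparisons in tests are circular where ±180 wrapping can occur.
- Reported relative sizes are rounded half-up to one decimal.
- `kabsch_superpose` requires ≥ 3 points; perfectly degenerate
  (collinear/symmetric) sets still return the optimal proper rotation up
  to the unresolved axis, which does not affect the RMSD.
- Fragment files must declare `neighbors:` counts consistent with their
  actual candidate blocks; candidate length must be constant per file;
  duplicate window headers are format errors with position context.
- Windows shorter than k do not exist (window set is exactly 1 … L−k+1);
  gain tables flag positions with fewer candidates than max(m_list) and
  use what is available.
- PSIPRED `.ss2` ties break H > E > C; the plain-string SS input
  sidesteps tie-breaking entirely.

## Known limitations

- The GDT search heuristic can in principle under-report GDT relative to
  an exhaustive LGA search; it is deterministic and adequate for the
  package's comparative use.
- The surrogate energy's SS term penalizes native coil residues whose
  torsions fall in the strand bin, so even a native conformation has
  nonzero energy; this does not affect policy comparisons, which hold the
  score fixed across arms.
- The assembly simulator rebuilds the full CA trace per attempt (O(L) per
  move); this is simple and fast enough at desk scale but would not scale
  to production chain lengths without incremental updates.
- The N/CA/C choice for fragment RMSD is this package's documented
  convention; CA-only numbers would differ slightly.
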