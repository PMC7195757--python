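# fragcard

Secondary-structure-conditioned fragment cardinality for fragment-based
protein structure prediction.

## The problem

Fragment-assembly predictors (Rosetta being the canonical example) fold a
protein by repeatedly splicing short backbone fragments — 9-mers for the
core build-up, 3-mers for refinement — into a growing conformation. For
each k-residue window of the target, a fragment picker supplies a
rank-ordered list of candidates, by default **25 9-mers and 200 3-mers**
per window, and the assembly loop draws from those lists uniformly at
random.

The sequence–structure relationship is not equally hard everywhere.
Helical fragments are structurally monotonous — the top-ranked candidate
is almost always near-optimal — while coil regions genuinely need
diversity. Keeping 25 (or 200) candidates at helix windows spends the
limited insertion budget re-sampling interchangeable fragments and
diffuses the search away from the regions that actually need exploration.

`fragcard` implements the remedy: classify every window by its predicted
3-state secondary structure and truncate its candidate list to an
SS-dependent maximum,

| k | pure helix | pure strand | mixed / coil |
|---|-----------:|------------:|-------------:|
| 9 | 1          | 25          | 25           |
| 3 | 5          | 25          | 200          |

where a window is *pure* when all k residues share the same state, and
"top n" means the first n candidates in picker-rank (file) order. The
package provides, as separately usable modules:

- **io** — a Rosetta-dialect fragment-file parser/writer, secondary
  structure readers (plain H/E/C, PSIPRED `.ss2`, 8-state DSSP), and a
  backbone (N/CA/C) PDB reader/writer;
- **cardinality** — window classification, count assignment, library
  truncation, and relative-size reporting (the core method);
- **geometry** — Kabsch superposition, RMSD, GDT_TS, and torsion ↔
  Cartesian backbone conversion with ideal covalent geometry;
- **quality** — the empirical machinery that justifies the counts:
  per-window candidate-RMSD statistics (first/best/worst/mean),
  best-of-top-m gain curves, and threshold-driven count selection;
- **assembly** — a desk-scale simulated-annealing fragment-assembly
  simulator (extended chain → 9-mer phase → 3-mer phase, Metropolis
  acceptance, documented surrogate energy);
- **assessment** — CASP-style blind-assessment reports (First model /
  Best of 5 / Top-5 average GDT) and run-vs-run comparisons;
- **synthetic** — generators for ideal native backbones and rank-degrading
  noisy fragment libraries, plus the transcribed 24-target study table.

## Worked example

Generate a 38-residue synthetic target (one helix, two strands) with
standard-size libraries, customize them, fold, and assess:

```sh
fragcard customize --frag9 target_frag9.txt --frag3 target_frag3.txt \
    --ss target.ss --out-dir custom --target demo
```

```
9-mer file: 80.8% of original size
3-mer file: 48.1% of original size
```

The report TSV breaks this down per fragment length: of the thirty 9-mer
windows, 6 are pure helix and keep a single candidate each (hence
(24·25 + 6·1)/(30·25) = 80.8%); of the thirty-six 3-mer windows, 12 are
pure helix (5 candidates each) and 8 pure strand (25 each), shrinking the
3-mer file to 48.1%.

```sh
fragcard assemble --frag9 custom/demo_frag9.txt --frag3 custom/demo_frag3.txt \
    --ss target.ss --n-decoys 10 --seed 11 --attempts9 1000 --attempts3 300 \
    --native target.pdb --out decoys.tsv --pdb-dir decoys
fragcard assess --decoys decoys --scores decoys.tsv --native target.pdb
```

```
first_model_gdt  best_of_5_gdt  top5_avg_gdt  best_decoy_gdt  n_decoys
43.4             43.4           29.7          46.7            10
```

Here the lowest-energy decoy (the "first model") happens to be the best
of the five lowest-energy ones, with a GDT_TS of 43.4 against the known
native; the best decoy regardless of score reaches 46.7. The analogous
run with untruncated libraries gives a weaker first model at the same
decoy budget — the end-to-end comparison across the full synthetic
benchmark is run by the test suite.

`fragcard quality` prints the evidence behind the counts for any target
with a known native: per-window first/best/worst/mean candidate RMSDs, the
average gain from enlarging the candidate set (1→5→10→…), and the smallest
set size beyond which further gains fall below a negligibility threshold.

## Scope

The package deliberately does **not** include Rosetta's energy functions,
the all-atom relax phase, or the fragment picker's scoring (profile,
Ramachandran, quota protocol); the assembly simulator uses a documented
surrogate energy and is a test bed for cardinality policies, not a
protein structure predictor. See `docs/methods.md` for the model details,
parameter choices, and limitations.
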