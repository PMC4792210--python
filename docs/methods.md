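# Methods

## Model and assumptions

DSA treats an ensemble of M structures of one protein (or of aligned homologs)
as M observations of the same fixed set of N Cα positions.  The only input per
chain is its Cα coordinates laid out over a common bundle definition; all
statistics are functions of intramolecular Cα–Cα distances, so they are exactly
invariant under any per-chain rigid motion and require no prior superposition.
For pair (i, j), with d₁..d_M the per-chain distances (Å):

- mean μ = Σd/M′, std σ over the M′ chains where both residues are present,
- score = μ/σ, the inverse coefficient of variation (dimensionless).

Assumptions: the residue correspondence across chains (the mapping of author
residue numbers to common labels) is correct and fixed; chains are treated as
exchangeable observations (no weighting by resolution, method, or redundancy);
distances are compared raw, with no distance-dependent baseline correction
(an optional concern for comparisons across very different mean distances —
deliberately left to the analyst rather than applied automatically).

## Common numbering

Bundle positions carry labels `h.pp` stored internally as (helix letter,
integer minor) — never as floats — with the `*.50` anchor at the most conserved
position of each helix.  Within a helix, the first mapped author residue takes
the first label of the helix's common range and numbering ascends toward the
carboxyl terminus, so label = common_start + (residue − author_start); the
operation is exactly invertible.  Declared-missing labels are skipped in
order, shortening the author range by one per missing residue, which keeps
downstream positions on their correct labels.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| std convention | population (÷M′) | — | the spread estimator; switchable to sample (÷(M′−1)), which scales all stds by √(M′/(M′−1)) and rescales scores uniformly — ranks are unchanged for fully present ensembles |
| min chains per pair | 3 | chains | below this a pair's score is undefined (a CV over 2 points is meaningless); mean/std are still reported where computable |
| zero-std tolerance | 1e-9 | Å | σ at or below this is treated as exactly 0 and the score as +inf; rigid copies differ only by rotation round-off (~1e-15 Å), six orders below the 1e-3 Å precision of coordinate files |
| top_n | 1000 | ranks | depth of the cumulative-ratio curves |
| cumulative denominator | per-group | — | curve value = group hits among top r over the group's total pair count, so every curve can reach 1; a grand-total option exists for partition-style reading |

Ranking is by descending score; +inf scores rank first.  All ties (including
among +inf) break by canonical pair order — row-major (i < j) over bundle
positions in helix order A→G, the same condensed order scipy's `pdist` uses —
so rankings are bit-stable across runs.

## Structure input

PDB and mmCIF are parsed with gemmi.  Residues are addressed by author
numbering; insertion codes raise an error (none occur in the target family's
entries).  Alternate locations resolve to the highest-occupancy Cα, ties to
the lowest altloc identifier.  A mapped author range that extends beyond the
chain's observed residue span is a hard error (a mapping bug), whereas a
residue inside the span that simply lacks a Cα is masked with a warning
(missing density) — pairs touching masked positions are computed over the
chains that do have them.

## Superposition and correlation diagnostics

Pairwise RMSD uses the closed-form Kabsch solution (SVD of the cross
covariance) over the positions present in both chains, with the reflection
corrected by flipping the smallest singular direction, so the returned
rotation always has determinant +1.  Fewer than 3 common points, or a
collinear configuration (second singular value ≤ 1e-12 relative), is an error.
The distance-vector correlation is the plain Pearson r between two chains'
condensed distance vectors over mutually defined pairs; it needs no
superposition at all and is the cheaper, mask-insensitive similarity check of
the two.

## Conservation profiling

Profiles are exact per-column counts over the 20 amino acids, gap, and X (any
other character).  By default gaps stay in the percentage denominator — a
column that is half gaps can be at most 50% conserved — because that is the
conservative reading when alignments contain fragmentary sequences; a flag
excludes them.  Anchor selection takes the column with the maximal top-residue
percentage in a user-supplied helix window, ties to the lowest column index
(with a warning).  Windows are user input: automatic transmembrane-helix
detection is out of scope, as is the alignment itself.

## Synthetic generator

The generator emulates the *shape of the data*, not rhodopsin physics: seven
ideal helical Cα traces (rise 1.5 Å, twist 100° per residue, helix radius
2.3 Å — consecutive Cα spacing ≈ 3.83 Å) placed on an 11 Å circle with
alternating up/down orientation, with helix lengths 22, 24, 22, 24, 28, 25, 25
matching the 170-residue reference bundle.  An ensemble adds isotropic
per-residue Gaussian noise (per-helix σ) plus one random rigid motion per
chain (bounded rotation and translation), all drawn from a single
explicitly-seeded generator, so identical specs and seeds give bit-identical
output.  Ensemble defaults — 10 chains, σ = 0.3 Å, jitter ≤ 10° / 5 Å — were
fixed once: a dozen chains is the ensemble size the method is designed for,
and 0.3 Å is the order of coordinate uncertainty in 1.8–3.5 Å crystal
structures.  Under these defaults synthetic ensembles sit within ~0.8 Å
pairwise RMSD and r > 0.996 distance correlation, the same regime as real
single-protein ensembles.

What the generator does **not** reproduce: native helix tilts, kinks and the
π-bulge of helix G, side chains and the retinal, correlated (rather than
isotropic independent) coordinate error, crystal-contact effects, and sequence
variation.  Passing tests therefore demonstrate that the statistics, ranking
and I/O behave correctly and that noise asymmetries are detected with the
right ordering — not that any particular helix of real rhodopsins will score
high.  Synthetic MSAs plant a designated top residue per column at a chosen
expected frequency, with other residues uniform; they model conservation
levels only, not phylogenetic correlation.

## Numerical and degenerate-input choices

- Undefined entries (masked residues, < min-chains pairs, < 2-pair overlap in
  correlations) propagate as NaN and are excluded from ranking with a logged
  count, never silently dropped.
- Empty groups in cumulative curves yield a zero curve plus a warning rather
  than an error, so a helix with no ranked pairs still plots.
- Pair tables round-trip through TSV at full float precision (pandas default
  repr), including +inf and NaN.
- Writing synthetic chains to PDB quantises coordinates to 1e-3 Å; round-trip
  tests compare at 5e-3 Å accordingly.

## Problem sizes in the test suite

Property and Monte-Carlo tests run on the full 170-position bundle with 6–10
chains and 20 seeds per condition (a few hundred ensemble evaluations, seconds
in total); oracle-equivalence tests use ≤ 15-residue bundles with ≤ 5 chains so
the brute-force double loop stays readable.  These sizes were chosen to match
the regime the method targets (~10–20 chains, ~10⁴ pairs) while keeping the
suite fast.

## Known limitations

- Scores on a real, curated structure set depend on the manual bundle ranges
  and mappings supplied; residue-level disagreements with other curations will
  shift individual pair statistics.
- No resolution/quality weighting of chains; redundant near-identical chains
  inflate scores for their shared conformation.
- Insertion codes and multi-model (NMR-style) files are not handled; only the
  first model of a file is read.
- The maximum-RMSD bound for the real 13-protein structure set requires the
  external coordinate files and a curated mapping; the pipeline supports it
  (`dsa rmsd`), but the repository ships no coordinates.
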