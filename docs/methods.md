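# Methods

## Problem and scope

`memddg` estimates the change in binding free energy, ΔΔG = ΔG_mutant −
ΔG_wild-type (kcal/mol), caused by a single amino-acid substitution in one
chain of a dimeric membrane protein–protein complex, using sequence
information only. Positive ΔΔG means the mutation weakens binding. The
package covers four stages: curation of raw affinity tables, feature
extraction, the training/evaluation protocol, and prediction; a
synthetic-fixture generator supplies every input format so the whole
workflow runs and is tested offline.

## Curation model

Raw tables mix three conventions — dissociation constants (K_D, molar),
absolute binding free energies (ΔG), and stated ΔΔG values — and contain
replicate disagreements, missing identifiers and structure-based residue
numbering. The pipeline applies, in order:

1. **Thermodynamic reconciliation.** ΔG = RT·ln(K_D) with R = 1.987×10⁻³
   kcal/(mol·K) and T = 298.15 K (both configurable; a measurement
   temperature is rarely reported, so the standard temperature is assumed).
   Whenever both ΔG values are derivable, ΔΔG is recomputed as their
   difference and overrides any stated ΔΔG, which is treated as the less
   reliable entry on conflict.
2. **Pseudonyms.** Complexes without an identifier get a deterministic
   pseudonym (stable hash of the sorted partner-identifier pair), so
   replicate grouping works and reruns are reproducible.
3. **Missing ΔΔG** records are dropped.
4. **Replicate spread.** Groups keyed by (complex, mutated chain, mutation)
   whose ΔΔG sample standard deviation (n−1 denominator; singleton groups
   have SD 0) exceeds 1.0 kcal/mol are removed whole. The estimator choice
   is a package decision; the n−1 form is the unbiased-variance convention.
5. **Sign conflicts** at a 0.5 kcal/mol threshold: pairs of opposite sign
   with both magnitudes above threshold are removed; groups of 3–4 with
   mixed signs and any magnitude above threshold are removed; in groups of
   ≥5, one or two values deviating from the group median by more than the
   threshold are trimmed and the rest kept. "Deviates significantly" is
   operationalized as distance from the group median exceeding the same
   0.5 kcal/mol cutoff — the median is the natural robust center for
   trimming 1–2 outliers.
6. **Duplicate merging** to the arithmetic mean ΔΔG (order-invariant);
   merged records drop their K_D/ΔG fields since the mean no longer
   corresponds to one measured pair.
7. **Sequence requirements.** Records whose mutated chain lacks an
   identifier or a supplied sequence are dropped; mutation strings must
   parse as `A123G` or `A 123 G` (1-based positions); structure numbering
   is translated through a caller-supplied map (absent map = identity) and
   the stated wild-type residue must match the sequence.
8. **Dimer filter.** Only 2-chain complexes are retained.

Every stage records (records_in, removed, records_out) with machine-readable
removal reasons; conservation (in − removed = out) and stage chaining are
enforced at construction. Re-curating a curated set removes nothing
(idempotence, covered by tests). A report-diff helper returns per-stage
(observed, expected) pairs so comparisons against an external accounting are
reported rather than silently asserted.

## Feature extraction

The canonical internal residue order is alphabetical one-letter
(ACDEFGHIKLMNPQRSTVWY); every file dialect (PSI-BLAST header order,
AAIndex orders) is re-mapped at parse time, so feature order never depends
on the input dialect.

**PSSM descriptors.** The PSI-BLAST ASCII parser keeps the first 20-column
log-odds block and recovers the sequence from the residue column. Scores
are normalized with the sigmoid f(x) = 1/(1+e^(−x)) (clamped away from 0/1
at float precision to guard overflow for extreme scores). From the
normalized L×20 profile:

* averaged PSSM: columnwise mean (20 values, length-independent);
* Row-PSSM: the row at the mutation site (20 values);
* pseudo-PSSM: φ_j^φ = (1/(L−φ)) Σ_{i=1}^{L−φ} (P_ij − P_(i+φ),j)², lags
  φ = 1..10; requires L > φ. The pseudo-PSSM is computed on the normalized
  scores, matching the normalization applied to every other PSSM block.

**Other descriptors.** AAIndex1 contributes attr(mut) − attr(wt) per
complete index (indices with NA values load but are unusable); AAIndex2
contributes score(wt→mut) per matrix, with lower-triangular matrices
symmetrized on load. NeighborAA encodes the five residues on each side of
the site as integer codes 1–20, 0 past either terminus. The mutation-type
label maps ordered residue pairs bijectively to 0..379 (row-major,
diagonal skipped). Five side-chain category schemes (chemical: 7 classes;
size: 5; polarity: 4; hydrogen bonding: 4; hydrophobicity: 3) each yield
one transition label wt_class·n + mut_class. Database features are pH
(default 7.0 when unreported) and integer-coded functional/structural
class, with vocabularies fixed at fit time and a reserved code 0 for
unseen labels.

**Feature sets.**

| set | content | length |
|---|---|---|
| ONLY_10_PLUS | avg-PSSM (mut, int) + lag-10 pseudo-PSSM (mut, int) + Row-PSSM | 100 |
| PHYSICOCHEMICAL | AAIndex1 diffs + NeighborAA + categories + mutation type | n₁+16 |
| EVOLUTIONARY | AAIndex2 + avg-PSSM (both) + Row-PSSM + pseudo-PSSM φ=1..10 (both) | n₂+460 |
| ALL_MPAD | union + database features | above+3 |

The compact set uses the lag-10 block only; this is what makes the count
exactly 100 (2·20 averaged + 2·20 lag-10 + 20 row). In the evolutionary
set the averaged block appears once even though the full pseudo-PSSM
vector formally begins with it — feature names are unique by construction.
With the official AAIndex release, n₁ = 547 usable indices and n₂ = 94
matrices; the package computes its lengths from whatever tables are
loaded rather than hard-coding those counts.

## Training protocol

The regressor is XGBoost (`tree_method="hist"`, single thread, seeded).
k-fold cross-validation (k = 5 or 10) refits the model k times and pools
the out-of-fold predictions; PCC and RMSE are computed on the pooled
vector. Pooled PCC (rather than a mean of per-fold PCCs) is used because it
is well-defined for small folds and matches how joint experimental-vs-
predicted scatter is usually presented. Randomized hyperparameter search
draws independently (with replacement) from a finite dictionary — tree
count, depth, learning rate, row/column subsampling, L1/L2 weights,
minimum child weight — scoring each draw by CV PCC; ties break by lower
RMSE, then draw order. Default protocol sizes are 1000 search draws and 50
evaluation repeats; the test suite and acceptance script run smaller
instances (single CV runs, 2 repeats, small search grids), chosen to keep
the full offline demonstration in the minutes range while exercising every
code path.

Feature importance is the total split gain a feature contributes across
the ensemble (its cumulative training-loss reduction), averaged over every
fold model of repeated k-fold fits and normalized to sum to 1. Total gain
is the additive measure appropriate for the class-level roll-ups the
protocol reports; per-split average gain over-weights rarely used
features.

The final model is fitted on all rows and persisted (joblib) together
with its feature layout and a SHA-256 hash of the ordered feature names;
loading verifies the hash and prediction refuses matrices assembled under
a different layout. Prediction for a new mutation takes the two chain
sequences, the mutation, and the two PSSMs, validates the wild-type
residue against the mutating sequence, assembles the model's feature set
and returns ΔΔG in kcal/mol.

Determinism: all randomness (fold assignment, hyperparameter draws,
XGBoost) derives from explicit integer seeds; identical seeds reproduce
splits, draws, models and predictions bit-for-bit on a fixed platform.

## Synthetic fixtures and what they show

The generator emulates the input formats, not membrane-protein biology:
sequences are uniform over the 20 residues; PSSM log-odds are rounded
normals clamped to [−16, 13] (the range of real PSI-BLAST output) with the
true residue's column up-weighted to mimic conservation; affinity tables
plant controlled defects with construction-known per-stage removal counts.

The planted-signal dataset defines the study conditions for learnability:
n = 800 records, chain lengths 30–60, ΔΔG = Σ w·feature + N(0, 0.3²)
kcal/mol with five informative Row-PSSM features at w = 2.0. Row-PSSM
components were chosen as the planted support because they have the widest
marginal variance of the compact set (sigmoid of a single score, versus
length-averaged blocks), giving a signal-to-noise ratio representative of
a clearly learnable problem; weights and noise were fixed once with the
generator's defaults. Passing the planted benchmarks shows the pipeline is
internally consistent — features are computed as defined, the protocol
leaks nothing across folds, the learner recovers a signal expressed in its
own feature space — but says nothing about accuracy on real mutation data,
whose ΔΔG distribution (heavily enriched near zero, alanine-dominated) and
feature correlations are far harsher.

## Numerical choices and edge cases

* Sigmoid outputs are clipped to [1e−300, 1−1e−16] so extreme scores stay
  strictly inside (0, 1).
* Pseudo-PSSM with L ≤ φ raises (the denominator vanishes); position
  arguments are 1-based and range-checked.
* PCC on constant vectors raises rather than returning NaN.
* Sample SD (n−1) everywhere; singleton replicate groups pass the SD
  filter.
* Group trimming in stage 5 leaves groups with ≥3 median-outliers
  untouched (no rule claims them); they then merge by mean.
* Seeds derived from a master seed are reduced modulo 2³¹−1.

## Known limitations

* The curation rules for sign conflicts codify an explicit reading of an
  under-specified procedure; other record-for-record reconstructions of
  the same counts exist, which is why report comparisons are emitted as
  per-stage diffs.
* No PSSM generation is embedded: real-data use requires externally
  computed PSI-BLAST profiles (three iterations, E = 0.001, UniRef50).
* Database-feature encoding is a plain integer code; with many classes an
  ordinal encoding can mislead tree splits less than a one-hot would, but
  the class counts here are small.
* The documented feature-set lengths follow from the loaded AAIndex
  tables; totals under other table versions will differ.
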