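# memddg

Sequence-based prediction of the binding free-energy change (ΔΔG) caused by
a single point mutation in a membrane protein–protein complex.

Most ΔΔG predictors are structure-based and trained on affinity databases
dominated by soluble complexes; they transfer poorly to membrane
protein–protein interactions, for which few 3D structures exist. `memddg`
implements a sequence-only workflow for this setting: it curates raw
mutation binding-affinity tables into a clean training set, describes each
mutation with evolutionary profile features, and trains a gradient-boosted
regressor under a repeated cross-validation protocol. It is a library
first (Python API plus `examples/` scripts) with a thin `memddg` CLI over
the same functions.

## Model

Binding free energies follow from measured dissociation constants,

    ΔG = RT·ln(K_D),        ΔΔG = ΔG_mutant − ΔG_wild-type,

so ΔΔG > 0 means the mutation destabilizes the complex (R = 1.987×10⁻³
kcal/(mol·K), T = 298.15 K by default). Curation reconciles stated ΔΔG
values against this cycle, filters replicate groups with sample SD > 1.0
kcal/mol, resolves opposite-sign replicate conflicts at a 0.5 kcal/mol
threshold, merges duplicates to their mean, and keeps single-mutation
dimeric records whose stated wild-type residue is present in the partner
sequence.

Features come from the L×20 position-specific scoring matrix (PSSM) of
each chain, sigmoid-normalized elementwise via f(x) = 1/(1+e^(−x)):

* averaged PSSM  P̄_j = (1/L) Σ_i P_ij — a length-independent 20-vector per chain;
* Row-PSSM — the normalized PSSM row at the mutation site;
* pseudo-PSSM  φ_j^φ = (1/(L−φ)) Σ_i (P_ij − P_(i+φ),j)² — lag-φ
  sequence-order descriptors, φ = 1..10.

The compact `ONLY_10_PLUS` set (exactly 100 features) is the averaged PSSM
and lag-10 pseudo-PSSM of both chains plus the mutation site's Row-PSSM.
Larger sets add AAIndex1 attribute differences, AAIndex2 substitution
scores, neighboring-residue codes, amino-acid category transitions, the
mutation-type label (380 ordered pairs), and database features (pH,
membrane-protein class). The regressor is XGBoost; hyperparameters are
drawn at random from a finite dictionary and scored by k-fold
cross-validated Pearson correlation (PCC) on pooled out-of-fold
predictions, and performance is reported as mean ± SD over repeated CV
runs.

## Worked example

Everything runs offline on synthetic fixtures. `python
examples/train_and_evaluate.py` builds a planted-signal dataset — 300
mutations whose ΔΔG is a known linear map of five Row-PSSM features plus
0.3 kcal/mol Gaussian noise — and evaluates the regressor:

```
dataset: 300 mutations x 100 features, noise SD 0.3 kcal/mol
repeated 5-fold CV: PCC 0.934 +/- 0.005 over 3 runs
best run: PCC 0.938, RMSE 0.794 kcal/mol
```

The PCC is between experimental and pooled out-of-fold predicted ΔΔG; a
value near the noise ceiling shows the planted signal is fully recovered.
The other examples curate a defect-laden affinity table
(`curate_affinity_table.py`), print the PSSM descriptors for one mutation
(`extract_features.py`), and fit-persist-predict for a single query
(`predict_mutation.py`). The same pipeline is available as subcommands:

```
memddg simulate --out-dir fix --n 100 --seed 1
memddg curate   --table fix/table.csv --fasta fix/sequences.fasta \
                --out-table clean.csv --out-report report.json
memddg featurize --table clean.csv --fasta fix/sequences.fasta \
                 --pssm-dir fix/pssms --out features.tsv
memddg train    --matrix features.tsv --out-model model.joblib \
                --out-report train.json
memddg predict  --model model.joblib --mutating-fasta mut.fasta \
                --interacting-fasta int.fasta --mutating-pssm m.pssm \
                --interacting-pssm i.pssm --mutation A123G
```

For real data, per-chain PSSMs are produced externally with PSI-BLAST
(three iterations, E-value 0.001, against UniRef50) and supplied as the
standard ASCII matrix files.

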