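"""Fit a final model and predict ddG for a single new mutation.

Trains on a planted dataset, persists the model (bundled with its feature
layout so prediction refuses mismatched inputs), and scores one mutation
from sequences and PSSMs alone — the prediction-time contract.
"""

import tempfile
from pathlib import Path

from memddg.protocol import TrainedModel, fit_final, predict_ddg
from memddg.synthetic import PlantedDatasetSpec, planted_dataset

ds = planted_dataset(PlantedDatasetSpec(n_records=300, seed=11))
model = fit_final(ds.X, ds.y, seed=1)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "model.joblib"
    model.save(path)
    model = TrainedModel.load(path)  # round trip through the artifact

rec = ds.records[0]
mut_id, int_id = rec.partner_a_id, rec.partner_b_id
ddg = predict_ddg(
    model,
    interacting_sequence=ds.sequences[int_id],
    mutating_sequence=ds.sequences[mut_id],
    mutation=rec.mutation,
    pssm_pair=(ds.pssms[mut_id], ds.pssms[int_id]),
)
print(f"mutation {rec.mutation} in complex {rec.complex_id}")
print(f"predicted ddG: {ddg:+.3f} kcal/mol (measured: {rec.ddg:+.3f})")
print("Positive ddG = mutation predicted to destabilize the complex.")
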