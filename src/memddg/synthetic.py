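"""Synthetic inputs for exercising every stage of the toolkit offline.

Provides deterministic generators for random protein sequences, integer
log-odds PSSMs rendered in the PSI-BLAST ASCII dialect, AAIndex-style flat
files, planted-signal ΔΔG datasets whose ground truth is an exact linear
function of features the toolkit itself computes, and deliberately messy
affinity tables that plant one instance of every curation defect together
with the stage-by-stage removal counts the curation report must show.

All generators are pure in (spec, seed): identical inputs give
byte-identical artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .alphabet import CANONICAL_AA, PSIBLAST_AA
from .curation import AffinityRecord, Mutation
from .features import FeatureSetId, assemble_features, make_feature_spec
from .pssm import PSSMatrix, write_ascii_pssm

__all__ = [
    "random_sequence",
    "synthetic_pssm",
    "synthetic_aaindex1",
    "synthetic_aaindex2",
    "PlantedDatasetSpec",
    "PlantedDataset",
    "planted_dataset",
    "DefectPlan",
    "MessyTable",
    "messy_affinity_table",
]


def random_sequence(length: int, seed: int) -> str:
    """Uniform random sequence over the 20 standard residues."""
    if length < 1:
        raise ValueError(f"length must be >= 1, got {length}")
    rng = np.random.default_rng(seed)
    return "".join(rng.choice(list(CANONICAL_AA), size=length))


def synthetic_pssm(
    sequence: str, conservation_weight: float = 1.5, seed: int = 0
) -> tuple:
    """Integer log-odds profile for a sequence, plus its ASCII rendering.

    Scores are drawn from a rounded normal and clamped to [−16, 13], the
    range seen in real PSI-BLAST output; the column of the position's true
    residue is up-weighted by ``conservation_weight`` so profiles look
    conserved. Returns ``(PSSMatrix, ascii_text)``; the text round-trips
    exactly through the parser.
    """
    if conservation_weight < 0:
        raise ValueError("conservation_weight must be >= 0")
    rng = np.random.default_rng(seed)
    L = len(sequence)
    raw = rng.normal(0.0, 4.0, size=(L, 20))
    for i, aa in enumerate(sequence):
        raw[i, CANONICAL_AA.index(aa)] += 2.0 * conservation_weight
    scores = np.clip(np.round(raw), -16, 13)
    matrix = PSSMatrix(sequence=sequence, scores=scores)
    return matrix, write_ascii_pssm(matrix, header_order=PSIBLAST_AA)


def synthetic_aaindex1(n_indices: int = 566, n_missing: int = 19, seed: int = 0) -> str:
    """Synthetic AAIndex1 flat file in the official record layout.

    ``n_missing`` of the ``n_indices`` records carry an ``NA`` value and
    should be flagged unusable by the parser. The defaults mirror the
    official release's proportions (566 indices, 547 complete).
    """
    if not 0 <= n_missing <= n_indices:
        raise ValueError("need 0 <= n_missing <= n_indices")
    rng = np.random.default_rng(seed)
    missing_at = set(rng.choice(n_indices, size=n_missing, replace=False).tolist())
    out = []
    for idx in range(n_indices):
        vals = np.round(rng.normal(0.0, 2.0, size=20), 3).astype(object)
        if idx in missing_at:
            vals[rng.integers(20)] = "NA"
        out.append(f"H SYN{idx:06d}")
        out.append(f"D synthetic attribute scale {idx}")
        out.append("I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V")
        out.append("   " + "  ".join(str(v) for v in vals[:10]))
        out.append("   " + "  ".join(str(v) for v in vals[10:]))
        out.append("//")
    return "\n".join(out) + "\n"


def synthetic_aaindex2(n_matrices: int = 5, seed: int = 0, triangular: bool = True) -> str:
    """Synthetic AAIndex2 flat file of symmetric substitution matrices."""
    rng = np.random.default_rng(seed)
    order = PSIBLAST_AA
    out = []
    for idx in range(n_matrices):
        m = np.round(rng.normal(0.0, 2.0, size=(20, 20)))
        m = (m + m.T) / 2.0
        out.append(f"H SYM{idx:06d}")
        out.append(f"D synthetic substitution matrix {idx}")
        out.append(f"M rows = {order}, cols = {order}")
        for i in range(20):
            stop = i + 1 if triangular else 20
            out.append("   " + " ".join(f"{m[i, j]:6.1f}" for j in range(stop)))
        out.append("//")
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# planted-signal dataset
# ---------------------------------------------------------------------------

_DEFAULT_INFORMATIVE = {
    "row_site_A": 2.0,
    "row_site_D": 2.0,
    "row_site_F": 2.0,
    "row_site_K": 2.0,
    "row_site_S": 2.0,
}


@dataclass(frozen=True)
class PlantedDatasetSpec:
    """Conditions of the planted-signal study.

    ΔΔG is an exact linear function of named compact-set features plus
    Gaussian noise, so the learnable signal is analytic. Defaults: 800
    records, five informative Row-PSSM features at 2.0 kcal/mol per unit
    feature, noise SD 0.3 kcal/mol.
    """

    n_records: int = 800
    seq_length_range: tuple = (30, 60)
    informative_features: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_INFORMATIVE)
    )
    noise_sd: float = 0.3
    conservation_weight: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        spec_names = set(make_feature_spec(FeatureSetId.ONLY_10_PLUS).names)
        unknown = set(self.informative_features) - spec_names
        if unknown:
            raise ValueError(f"informative features not in the compact feature set: {unknown}")


@dataclass
class PlantedDataset:
    """A planted-signal dataset with its analytic ground truth."""

    records: list
    sequences: dict  # partner id -> residue string
    pssms: dict  # partner id -> PSSMatrix
    pssm_texts: dict  # partner id -> ASCII rendering
    X: np.ndarray  # feature matrix under the compact layout
    y: np.ndarray  # noisy ΔΔG targets (== record.ddg)
    y_clean: np.ndarray  # noise-free planted values
    feature_names: tuple
    spec: PlantedDatasetSpec


def planted_dataset(spec: PlantedDatasetSpec = PlantedDatasetSpec()) -> PlantedDataset:
    """Generate records whose ΔΔG is a planted linear map of real features.

    Features are computed by the feature-extraction code itself, so the
    planted map is exactly learnable from the emitted artifacts and the
    returned ground truth is self-consistent with them.
    """
    rng = np.random.default_rng(spec.seed)
    fspec = make_feature_spec(FeatureSetId.ONLY_10_PLUS)
    name_idx = {n: i for i, n in enumerate(fspec.names)}
    lo, hi = spec.seq_length_range
    records, X_rows, y, y_clean = [], [], [], []
    sequences: dict = {}
    pssms: dict = {}
    pssm_texts: dict = {}
    for i in range(spec.n_records):
        mut_id, int_id = f"MUTP{i:05d}", f"INTP{i:05d}"
        L_mut = int(rng.integers(lo, hi + 1))
        L_int = int(rng.integers(lo, hi + 1))
        seq_mut = "".join(rng.choice(list(CANONICAL_AA), size=L_mut))
        seq_int = "".join(rng.choice(list(CANONICAL_AA), size=L_int))
        pos = int(rng.integers(1, L_mut + 1))
        wt = seq_mut[pos - 1]
        mut_aa = str(rng.choice([a for a in CANONICAL_AA if a != wt]))
        pssm_mut, text_mut = synthetic_pssm(
            seq_mut, spec.conservation_weight, seed=int(rng.integers(2**31 - 1))
        )
        pssm_int, text_int = synthetic_pssm(
            seq_int, spec.conservation_weight, seed=int(rng.integers(2**31 - 1))
        )
        record = AffinityRecord(
            complex_id=f"CPX{i:05d}",
            partner_a_id=mut_id,
            partner_b_id=int_id,
            mutated_partner="A",
            mutation=Mutation(wt, pos, mut_aa),
            ph=7.4,
            protein_class_functional="synthetic",
            protein_class_structural="synthetic",
            n_chains=2,
            source_tag="planted",
        )
        fv = assemble_features(
            record, {mut_id: seq_mut, int_id: seq_int}, (pssm_mut, pssm_int), fspec
        )
        clean = sum(w * fv.values[name_idx[n]] for n, w in spec.informative_features.items())
        noisy = clean + rng.normal(0.0, spec.noise_sd)
        record.ddg = float(noisy)
        records.append(record)
        X_rows.append(fv.values)
        y.append(noisy)
        y_clean.append(clean)
        sequences[mut_id] = seq_mut
        sequences[int_id] = seq_int
        pssms[mut_id] = pssm_mut
        pssms[int_id] = pssm_int
        pssm_texts[mut_id] = text_mut
        pssm_texts[int_id] = text_int
    return PlantedDataset(
        records=records,
        sequences=sequences,
        pssms=pssms,
        pssm_texts=pssm_texts,
        X=np.array(X_rows),
        y=np.array(y, dtype=float),
        y_clean=np.array(y_clean, dtype=float),
        feature_names=fspec.names,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# messy affinity tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DefectPlan:
    """How many instances of each curation defect to plant."""

    missing_ddg: int = 1
    replicate_sd: int = 1  # replicate pairs with SD > 1.0 kcal/mol
    opposite_sign_pair: int = 1  # pairs of opposite sign, both |ΔΔG| > 0.5
    bad_format: int = 1
    wt_mismatch: int = 1
    non_dimer: int = 1
    missing_ids: int = 1
    duplicate_groups: int = 0  # benign replicate pairs that merge to their mean
    n_clean: int = 10

    def __post_init__(self) -> None:
        if any(getattr(self, f) < 0 for f in self.__dataclass_fields__):
            raise ValueError("all defect counts must be >= 0")


@dataclass
class MessyTable:
    records: list
    sequences: dict
    expected_counts: dict  # stage name -> expected removal count


def _base_record(i: int, rng: np.random.Generator, sequences: dict, **kw) -> AffinityRecord:
    pid = f"UPROT{i:05d}"
    seq = "".join(rng.choice(list(CANONICAL_AA), size=25))
    pos = int(rng.integers(1, 26))
    wt = seq[pos - 1]
    mut_aa = str(rng.choice([a for a in CANONICAL_AA if a != wt]))
    sequences[pid] = seq
    defaults = dict(
        complex_id=f"C{i:05d}",
        partner_a_id=pid,
        partner_b_id=f"PARTB{i:05d}",
        mutated_partner="A",
        mutation_raw=f"{wt}{pos}{mut_aa}",
        ddg=float(np.round(rng.uniform(-0.45, 0.45), 3)),
        ph=7.0,
        n_chains=2,
        source_tag="synthetic",
    )
    defaults.update(kw)
    return AffinityRecord(**defaults)


def messy_affinity_table(plan: DefectPlan = DefectPlan(), seed: int = 0) -> MessyTable:
    """Emit a raw table planting exactly the defects in ``plan``.

    Returns the records, the matching partner sequences, and the per-stage
    removal counts that curating the table must report. Each defect is
    built to survive every stage before its own, so counts are exact by
    construction.
    """
    rng = np.random.default_rng(seed)
    sequences: dict = {}
    records: list = []
    i = 0

    for _ in range(plan.n_clean):
        records.append(_base_record(i, rng, sequences))
        i += 1
    for _ in range(plan.missing_ddg):
        records.append(_base_record(i, rng, sequences, ddg=None))
        i += 1
    for _ in range(plan.replicate_sd):
        rec = _base_record(i, rng, sequences, ddg=0.0)
        twin = AffinityRecord(
            **{
                **_record_kwargs(rec),
                "ddg": 2.0,  # pair {0.0, 2.0}: sample SD ≈ 1.414 > 1.0
            }
        )
        records.extend([rec, twin])
        i += 1
    for _ in range(plan.opposite_sign_pair):
        rec = _base_record(i, rng, sequences, ddg=0.6)
        twin = AffinityRecord(**{**_record_kwargs(rec), "ddg": -0.6})
        # {+0.6, −0.6}: SD ≈ 0.85 passes the SD filter, sign rule removes both
        records.extend([rec, twin])
        i += 1
    for _ in range(plan.bad_format):
        records.append(_base_record(i, rng, sequences, mutation_raw=f"{int(rng.integers(1, 99))}AG"))
        i += 1
    for _ in range(plan.wt_mismatch):
        rec = _base_record(i, rng, sequences)
        seq = sequences[rec.partner_a_id]
        pos = rec.mutation.position
        wrong_wt = str(rng.choice([a for a in CANONICAL_AA if a not in (seq[pos - 1], rec.mutation.mut_aa)]))
        rec.mutation = None
        rec.mutation_raw = f"{wrong_wt}{pos}{rec.mutation_raw[-1]}"
        rec.__post_init__()
        records.append(rec)
        i += 1
    for _ in range(plan.non_dimer):
        records.append(_base_record(i, rng, sequences, n_chains=3))
        i += 1
    for _ in range(plan.missing_ids):
        rec = _base_record(i, rng, sequences)
        sequences.pop(rec.partner_a_id)
        rec.partner_a_id = None
        records.append(rec)
        i += 1
    for _ in range(plan.duplicate_groups):
        rec = _base_record(i, rng, sequences, ddg=1.0)
        twin = AffinityRecord(**{**_record_kwargs(rec), "ddg": 1.2})
        records.extend([rec, twin])
        i += 1

    order = rng.permutation(len(records))
    records = [records[j] for j in order]
    expected = {
        "recompute_ddg": 0,
        "assign_pseudonyms": 0,
        "drop_missing_ddg": plan.missing_ddg,
        "filter_replicate_sd": 2 * plan.replicate_sd,
        "resolve_sign_conflicts": 2 * plan.opposite_sign_pair,
        "merge_duplicates": plan.duplicate_groups,
        "require_sequence": plan.missing_ids,
        "mutation_format": plan.bad_format,
        "renumber_validate": plan.wt_mismatch,
        "require_dimer": plan.non_dimer,
    }
    return MessyTable(records=records, sequences=sequences, expected_counts=expected)


def _record_kwargs(rec: AffinityRecord) -> dict:
    return dict(
        complex_id=rec.complex_id,
        partner_a_id=rec.partner_a_id,
        partner_b_id=rec.partner_b_id,
        mutated_partner=rec.mutated_partner,
        mutation_raw=rec.mutation_raw,
        kd_wt=rec.kd_wt,
        kd_mut=rec.kd_mut,
        dg_wt=rec.dg_wt,
        dg_mut=rec.dg_mut,
        ddg=rec.ddg,
        ph=rec.ph,
        protein_class_functional=rec.protein_class_functional,
        protein_class_structural=rec.protein_class_structural,
        n_chains=rec.n_chains,
        source_tag=rec.source_tag,
    )
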