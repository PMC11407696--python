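"""Mutation descriptors and feature-set assembly.

Each curated record is described by a fixed-order numeric vector drawn from
three broad categories:

* physicochemical — AAIndex1 attribute differences, neighboring-residue
  codes, amino-acid category transition labels, and the mutation-type label;
* evolutionary — AAIndex2 substitution scores plus the PSSM-derived blocks
  (averaged PSSM, Row-PSSM, pseudo-PSSM lags) for both the mutating and the
  interacting chain;
* database — experimental pH and the functional/structural class of the
  membrane complex, which cannot be derived from sequence.

Four named feature sets are assembled here. ``ONLY_10_PLUS`` is the compact
100-feature set: averaged PSSM (both chains), the lag-10 pseudo-PSSM block
(both chains) and the Row-PSSM of the mutation site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np

from .aaindex import AAIndex1Table, AAIndex2Table, aaindex1_features, aaindex2_features
from .alphabet import AA_CODE, CANONICAL_AA, validate_residue
from .curation import AffinityRecord
from .pssm import NormalizedPSSM, PSSMatrix, average_pssm, pse_pssm, row_pssm, sigmoid_normalize

__all__ = [
    "FeatureSetId",
    "FeatureSetSpec",
    "FeatureVector",
    "FeatureTables",
    "ClassVocabulary",
    "neighbor_features",
    "mutation_type_label",
    "category_features",
    "database_features",
    "assemble_features",
    "CATEGORY_SCHEMES",
]


class FeatureSetId(str, Enum):
    ALL_MPAD = "ALL_MPAD"
    ONLY_10_PLUS = "ONLY_10_PLUS"
    PHYSICOCHEMICAL = "PHYSICOCHEMICAL"
    EVOLUTIONARY = "EVOLUTIONARY"


# side-chain classification schemes; label = index(wt class) * n + index(mut class)
CATEGORY_SCHEMES: dict = {
    "chemical": ["HKR", "NQ", "DE", "CM", "ST", "FWY", "AGILPV"],
    "size": ["CDNPT", "EHQV", "IKLMR", "FWY", "AGS"],
    "polarity": ["HKR", "NQSTY", "DE", "ACFGILMPVW"],
    "hbond": ["KRW", "DE", "HNQSTY", "ACFGILMPV"],
    "hydrophobicity": ["ACFILMVW", "GHPSTY", "DEKRNQ"],
}

_CLASS_OF = {
    scheme: {aa: idx for idx, group in enumerate(groups) for aa in group}
    for scheme, groups in CATEGORY_SCHEMES.items()
}

PSE_PHI_MAX = 10


def neighbor_features(sequence: str, position: int) -> np.ndarray:
    """Integer codes of the five residues before and after a mutation site.

    Codes are 1–20 in canonical alphabet order; positions that fall off
    either end of the sequence are coded 0. Always returns 10 values:
    leading window (site−5 .. site−1) then lagging window (site+1 .. site+5).
    """
    if not 1 <= position <= len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    codes = []
    for offset in list(range(-5, 0)) + list(range(1, 6)):
        i = position + offset
        codes.append(AA_CODE[sequence[i - 1]] if 1 <= i <= len(sequence) else 0)
    return np.array(codes, dtype=float)


def mutation_type_label(wt_aa: str, mut_aa: str) -> int:
    """Bijective label in {0..379} for the ordered (wild-type, mutant) pair.

    Row-major over the canonical alphabet with the diagonal skipped, so the
    first off-diagonal pair (A, C) gets label 0.
    """
    wt_aa, mut_aa = validate_residue(wt_aa), validate_residue(mut_aa)
    if wt_aa == mut_aa:
        raise ValueError("mutation type undefined for identical residues")
    i, j = CANONICAL_AA.index(wt_aa), CANONICAL_AA.index(mut_aa)
    return i * 19 + (j if j < i else j - 1)


def category_features(wt_aa: str, mut_aa: str) -> np.ndarray:
    """One transition label per classification scheme (5 integers).

    Per scheme the label is ``index(wt class) * n_classes + index(mut class)``,
    so e.g. the chemical scheme (7 classes) takes at most 49 distinct values.
    Scheme order: chemical, size, polarity, hydrogen bonding, hydrophobicity.
    """
    wt_aa, mut_aa = validate_residue(wt_aa), validate_residue(mut_aa)
    labels = []
    for scheme, groups in CATEGORY_SCHEMES.items():
        n = len(groups)
        labels.append(_CLASS_OF[scheme][wt_aa] * n + _CLASS_OF[scheme][mut_aa])
    return np.array(labels, dtype=float)


@dataclass
class ClassVocabulary:
    """Deterministic integer coding of categorical class labels.

    Codes are assigned 1..n over the sorted distinct labels seen at fit
    time; absent or unseen labels map to the reserved code 0.
    """

    codes: dict = field(default_factory=dict)

    @classmethod
    def fit(cls, labels: Sequence) -> "ClassVocabulary":
        distinct = sorted({str(x) for x in labels if x is not None})
        return cls(codes={lab: i + 1 for i, lab in enumerate(distinct)})

    def encode(self, label) -> int:
        if label is None:
            return 0
        return self.codes.get(str(label), 0)


@dataclass
class FeatureTables:
    """Lookup tables required by the non-PSSM feature groups."""

    aaindex1: Optional[AAIndex1Table] = None
    aaindex2: Optional[AAIndex2Table] = None
    functional_vocab: ClassVocabulary = field(default_factory=ClassVocabulary)
    structural_vocab: ClassVocabulary = field(default_factory=ClassVocabulary)

    @classmethod
    def fit_vocabularies(cls, records: Sequence[AffinityRecord], **kw) -> "FeatureTables":
        return cls(
            functional_vocab=ClassVocabulary.fit(
                [r.protein_class_functional for r in records]
            ),
            structural_vocab=ClassVocabulary.fit(
                [r.protein_class_structural for r in records]
            ),
            **kw,
        )


def database_features(record: AffinityRecord, tables: FeatureTables) -> np.ndarray:
    """pH (default 7.0 when unreported) plus coded functional/structural class."""
    ph = record.ph if record.ph is not None else 7.0
    return np.array(
        [
            ph,
            tables.functional_vocab.encode(record.protein_class_functional),
            tables.structural_vocab.encode(record.protein_class_structural),
        ],
        dtype=float,
    )


@dataclass(frozen=True)
class FeatureSetSpec:
    """Named, ordered feature layout for one of the four feature sets."""

    set_id: FeatureSetId
    names: tuple

    @property
    def expected_length(self) -> int:
        return len(self.names)

    def header(self) -> str:
        return "\t".join(self.names)


@dataclass(frozen=True)
class FeatureVector:
    spec: FeatureSetSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.shape != (self.spec.expected_length,):
            raise ValueError(
                f"feature vector length {values.shape} != spec length {self.spec.expected_length}"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("feature vector contains missing values")

    def as_dict(self) -> dict:
        return dict(zip(self.spec.names, self.values))


def _pssm_block_names() -> dict:
    aa = list(CANONICAL_AA)
    names = {
        "avg_mut": [f"avg_mut_{a}" for a in aa],
        "avg_int": [f"avg_int_{a}" for a in aa],
        "row_site": [f"row_site_{a}" for a in aa],
    }
    for phi in range(1, PSE_PHI_MAX + 1):
        names[f"pse{phi}_mut"] = [f"pse{phi}_mut_{a}" for a in aa]
        names[f"pse{phi}_int"] = [f"pse{phi}_int_{a}" for a in aa]
    return names


def _physicochemical_names(tables: FeatureTables) -> list:
    if tables.aaindex1 is None:
        raise ValueError("PHYSICOCHEMICAL features require an AAIndex1 table")
    names = [f"aa1_{ix}" for ix in tables.aaindex1.usable_ids]
    names += [f"neighbor_m{k}" for k in range(5, 0, -1)]
    names += [f"neighbor_p{k}" for k in range(1, 6)]
    names += [f"cat_{scheme}" for scheme in CATEGORY_SCHEMES]
    names += ["mutation_type"]
    return names


def _evolutionary_names(tables: FeatureTables) -> list:
    if tables.aaindex2 is None:
        raise ValueError("EVOLUTIONARY features require an AAIndex2 table")
    blocks = _pssm_block_names()
    names = [f"aa2_{mx}" for mx in tables.aaindex2.usable_ids]
    names += blocks["avg_mut"] + blocks["avg_int"] + blocks["row_site"]
    for phi in range(1, PSE_PHI_MAX + 1):
        names += blocks[f"pse{phi}_mut"] + blocks[f"pse{phi}_int"]
    return names


def make_feature_spec(set_id: FeatureSetId, tables: Optional[FeatureTables] = None) -> FeatureSetSpec:
    """Build the ordered feature layout for a feature set.

    ``ONLY_10_PLUS`` needs no lookup tables and always has length 100; the
    other sets size themselves from the usable AAIndex entries.
    """
    set_id = FeatureSetId(set_id)
    blocks = _pssm_block_names()
    if set_id is FeatureSetId.ONLY_10_PLUS:
        names = (
            blocks["avg_mut"]
            + blocks["avg_int"]
            + blocks[f"pse{PSE_PHI_MAX}_mut"]
            + blocks[f"pse{PSE_PHI_MAX}_int"]
            + blocks["row_site"]
        )
    elif set_id is FeatureSetId.PHYSICOCHEMICAL:
        names = _physicochemical_names(tables or FeatureTables())
    elif set_id is FeatureSetId.EVOLUTIONARY:
        names = _evolutionary_names(tables or FeatureTables())
    else:  # ALL_MPAD
        t = tables or FeatureTables()
        names = (
            _physicochemical_names(t)
            + _evolutionary_names(t)
            + ["db_ph", "db_functional_class", "db_structural_class"]
        )
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in spec")
    return FeatureSetSpec(set_id=set_id, names=tuple(names))


def _norm(p: PSSMatrix | NormalizedPSSM) -> NormalizedPSSM:
    return p if isinstance(p, NormalizedPSSM) else sigmoid_normalize(p)


def assemble_features(
    record: AffinityRecord,
    sequences: Mapping[str, str],
    pssm_pair: tuple,
    spec: FeatureSetSpec,
    tables: Optional[FeatureTables] = None,
) -> FeatureVector:
    """Assemble one record's feature vector under a feature-set layout.

    ``pssm_pair`` is ``(mutating_pssm, interacting_pssm)`` — the profile of
    the chain carrying the mutation first. The mutation's wild-type residue
    is validated against the mutating chain's sequence before any PSSM row
    is read.
    """
    tables = tables or FeatureTables()
    mut = record.mutation
    if mut is None:
        raise ValueError(f"record {record.complex_id} has no parsed mutation")
    seq = sequences.get(record.mutated_partner_id or "")
    if seq is None:
        raise ValueError(f"no sequence for mutated partner of {record.complex_id}")
    if not 1 <= mut.position <= len(seq):
        raise ValueError(f"mutation position {mut.position} outside sequence")
    if seq[mut.position - 1] != mut.wt_aa:
        raise ValueError(
            f"wild-type residue mismatch at position {mut.position}: "
            f"sequence has {seq[mut.position - 1]}, mutation states {mut.wt_aa}"
        )
    mut_pssm, int_pssm = pssm_pair
    if mut_pssm is None or (spec.set_id is not FeatureSetId.PHYSICOCHEMICAL and int_pssm is None):
        raise ValueError("missing PSSM for one of the partner chains")
    needs_pssm = spec.set_id is not FeatureSetId.PHYSICOCHEMICAL
    blocks: dict = {}
    if needs_pssm:
        nm, ni = _norm(mut_pssm), _norm(int_pssm)
        if nm.sequence != seq:
            raise ValueError("mutating-chain PSSM sequence disagrees with FASTA sequence")
        blocks["avg_mut"] = average_pssm(nm)
        blocks["avg_int"] = average_pssm(ni)
        blocks["row_site"] = row_pssm(nm, mut.position)
        phis = (
            (PSE_PHI_MAX,)
            if spec.set_id is FeatureSetId.ONLY_10_PLUS
            else tuple(range(1, PSE_PHI_MAX + 1))
        )
        for phi in phis:
            blocks[f"pse{phi}_mut"] = pse_pssm(nm, phi=phi)
            blocks[f"pse{phi}_int"] = pse_pssm(ni, phi=phi)

    parts = []
    if spec.set_id is FeatureSetId.ONLY_10_PLUS:
        parts = [
            blocks["avg_mut"],
            blocks["avg_int"],
            blocks[f"pse{PSE_PHI_MAX}_mut"],
            blocks[f"pse{PSE_PHI_MAX}_int"],
            blocks["row_site"],
        ]
    else:
        if spec.set_id in (FeatureSetId.PHYSICOCHEMICAL, FeatureSetId.ALL_MPAD):
            parts.append(aaindex1_features(tables.aaindex1, mut.wt_aa, mut.mut_aa))
            parts.append(neighbor_features(seq, mut.position))
            parts.append(category_features(mut.wt_aa, mut.mut_aa))
            parts.append(np.array([mutation_type_label(mut.wt_aa, mut.mut_aa)], dtype=float))
        if spec.set_id in (FeatureSetId.EVOLUTIONARY, FeatureSetId.ALL_MPAD):
            parts.append(aaindex2_features(tables.aaindex2, mut.wt_aa, mut.mut_aa))
            parts.append(blocks["avg_mut"])
            parts.append(blocks["avg_int"])
            parts.append(blocks["row_site"])
            for phi in range(1, PSE_PHI_MAX + 1):
                parts.append(blocks[f"pse{phi}_mut"])
                parts.append(blocks[f"pse{phi}_int"])
        if spec.set_id is FeatureSetId.ALL_MPAD:
            parts.append(database_features(record, tables))
    values = np.concatenate(parts)
    return FeatureVector(spec=spec, values=values)
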