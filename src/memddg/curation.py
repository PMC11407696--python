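"""Curation of mutation binding-affinity tables.

Turns a raw membrane protein-protein affinity table (one row per measured
wild-type/mutant pair) into a training-ready set of single-mutation, dimeric
records with one consensus binding free-energy change per (complex, mutation).

The pipeline stages, applied in order by :func:`curate`:

1.  recompute ΔΔG from ΔG or K_D where derivable (ΔG = RT·ln K_D;
    ΔΔG = ΔG_mutant − ΔG_wild-type, positive = destabilizing);
2.  assign deterministic pseudonyms to complexes lacking an identifier;
3.  drop records without a numeric ΔΔG;
4.  drop replicate groups whose ΔΔG sample standard deviation exceeds a
    cutoff (default 1.0 kcal/mol);
5.  resolve sign conflicts among replicates (0.5 kcal/mol threshold rules);
6.  merge remaining duplicates to their mean ΔΔG;
7.  drop records whose mutated partner has no identifier or no importable
    sequence;
8.  drop records whose mutation string is not in standard format;
9.  translate structure residue numbering to sequence numbering and check
    the stated wild-type residue against the sequence;
10. retain dimeric complexes only.

Every removal is recorded with a machine-readable reason in a
:class:`CurationReport` whose per-stage counts always satisfy
``records_in - records_removed = records_out``.
"""

from __future__ import annotations

import hashlib
import json
import math
import re
import statistics
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .alphabet import AA_SET

__all__ = [
    "Mutation",
    "AffinityRecord",
    "CurationConfig",
    "CurationReport",
    "StageReport",
    "RemovalReason",
    "delta_g_from_kd",
    "recompute_ddg",
    "assign_pseudonyms",
    "drop_missing_ddg",
    "filter_replicate_sd",
    "resolve_sign_conflicts",
    "merge_duplicates",
    "renumber_and_validate",
    "curate",
    "parse_mutation",
    "read_affinity_table",
    "write_affinity_table",
    "compare_reports",
]

# Accepts the "A123G" and "A 123 G" dialects only.
_MUTATION_RE = re.compile(r"^\s*([A-Za-z])\s?(\d+)\s?([A-Za-z])\s*$")


@dataclass(frozen=True)
class Mutation:
    """A single point mutation: wild-type residue, 1-based position, mutant residue."""

    wt_aa: str
    position: int
    mut_aa: str

    def __post_init__(self) -> None:
        if self.wt_aa not in AA_SET or self.mut_aa not in AA_SET:
            raise ValueError(f"non-standard residue in mutation {self}")
        if self.wt_aa == self.mut_aa:
            raise ValueError(f"wild-type and mutant residue identical: {self}")
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")

    def __str__(self) -> str:
        return f"{self.wt_aa}{self.position}{self.mut_aa}"


def parse_mutation(text: str) -> Mutation:
    """Parse ``"A123G"`` or ``"A 123 G"`` into a :class:`Mutation`.

    Raises ``ValueError`` for any other dialect, non-standard residues,
    or identical wild-type and mutant residues.
    """
    m = _MUTATION_RE.match(text or "")
    if not m:
        raise ValueError(
            f"unrecognized mutation format {text!r}; accepted dialects: 'A123G', 'A 123 G'"
        )
    return Mutation(m.group(1).upper(), int(m.group(2)), m.group(3).upper())


class RemovalReason(str, Enum):
    """Machine-readable reason a record was removed during curation."""

    MISSING_DDG = "missing_ddg"
    REPLICATE_SD = "replicate_sd_exceeded"
    SIGN_CONFLICT_PAIR = "sign_conflict_pair"
    SIGN_CONFLICT_SMALL_GROUP = "sign_conflict_small_group"
    SIGN_CONFLICT_OUTLIER = "sign_conflict_outlier"
    MERGED_DUPLICATE = "merged_duplicate"
    MISSING_SEQUENCE = "missing_id_or_sequence"
    BAD_MUTATION_FORMAT = "bad_mutation_format"
    RESIDUE_MISMATCH = "residue_mismatch"
    UNMAPPABLE_POSITION = "unmappable_position"
    NON_DIMER = "non_dimer"


@dataclass
class AffinityRecord:
    """One wild-type/mutant binding-affinity measurement.

    Thermodynamic fields are optional because raw tables mix K_D, ΔG and
    ΔΔG conventions; :func:`recompute_ddg` reconciles them. ``mutation_raw``
    holds the table's original mutation string; ``mutation`` is populated
    once the string passes the format filter.
    """

    complex_id: str = ""
    partner_a_id: Optional[str] = None
    partner_b_id: Optional[str] = None
    mutated_partner: str = "A"  # "A" or "B"
    mutation_raw: str = ""
    mutation: Optional[Mutation] = None
    kd_wt: Optional[float] = None  # molar
    kd_mut: Optional[float] = None  # molar
    dg_wt: Optional[float] = None  # kcal/mol
    dg_mut: Optional[float] = None  # kcal/mol
    ddg: Optional[float] = None  # kcal/mol, positive = destabilizing
    ph: Optional[float] = None
    protein_class_functional: Optional[str] = None
    protein_class_structural: Optional[str] = None
    n_chains: int = 2
    source_tag: str = ""
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mutated_partner not in ("A", "B"):
            raise ValueError(f"mutated_partner must be 'A' or 'B', got {self.mutated_partner!r}")
        for kd in (self.kd_wt, self.kd_mut):
            if kd is not None and kd <= 0:
                raise ValueError(f"dissociation constant must be > 0, got {kd}")
        if self.mutation is None and self.mutation_raw:
            try:
                self.mutation = parse_mutation(self.mutation_raw)
            except ValueError:
                self.mutation = None
        if not self.mutation_raw and self.mutation is not None:
            self.mutation_raw = str(self.mutation)

    @property
    def mutated_partner_id(self) -> Optional[str]:
        return self.partner_a_id if self.mutated_partner == "A" else self.partner_b_id

    def group_key(self) -> tuple:
        """Replicate-group key: same complex, same mutated chain, same mutation."""
        mut = str(self.mutation) if self.mutation is not None else self.mutation_raw.replace(" ", "")
        return (self.complex_id, self.mutated_partner, mut)


@dataclass(frozen=True)
class CurationConfig:
    """Constants and cutoffs of the curation pipeline.

    ``gas_constant_R`` is in kcal/(mol·K) and ``temperature_T`` in kelvin so
    that RT·ln(K_D) lands in kcal/mol. Cutoffs are in kcal/mol.
    """

    gas_constant_R: float = 1.987e-3
    temperature_T: float = 298.15
    replicate_sd_cutoff: float = 1.0
    sign_conflict_cutoff: float = 0.5
    require_dimer: bool = True

    def __post_init__(self) -> None:
        for name in ("gas_constant_R", "temperature_T", "replicate_sd_cutoff", "sign_conflict_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class StageReport:
    stage_name: str
    records_in: int
    records_removed: int
    records_out: int
    removal_reasons: Counter
    distinct_protein_count: int

    def __post_init__(self) -> None:
        assert self.records_in - self.records_removed == self.records_out


@dataclass
class CurationReport:
    """Per-stage accounting of one curation run."""

    stages: list = field(default_factory=list)

    def add(self, name: str, kept: Sequence[AffinityRecord], removed: Sequence) -> None:
        n_in = len(kept) + len(removed)
        reasons = Counter(reason.value for _, reason in removed)
        stage = StageReport(
            stage_name=name,
            records_in=n_in,
            records_removed=len(removed),
            records_out=len(kept),
            removal_reasons=reasons,
            distinct_protein_count=len({r.complex_id for r in kept}),
        )
        if self.stages and self.stages[-1].records_out != n_in:
            raise ValueError("stage chain broken: records_out of previous stage != records_in")
        self.stages.append(stage)

    def counts(self) -> dict:
        """Stage name -> removed count, the comparable core of the report."""
        return {s.stage_name: s.records_removed for s in self.stages}

    def to_dict(self) -> dict:
        return {
            "stages": [
                {
                    "stage_name": s.stage_name,
                    "records_in": s.records_in,
                    "records_removed": s.records_removed,
                    "records_out": s.records_out,
                    "removal_reasons": dict(s.removal_reasons),
                    "distinct_protein_count": s.distinct_protein_count,
                }
                for s in self.stages
            ]
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def compare_reports(observed: CurationReport, expected_counts: Mapping[str, int]) -> dict:
    """Diff observed per-stage removal counts against expected ones.

    Returns ``{stage: (observed, expected)}`` for stages that disagree —
    an empty dict means exact agreement. Intended for reporting per-stage
    discrepancies instead of opaque boolean assertions.
    """
    obs = observed.counts()
    diffs = {}
    for stage in set(obs) | set(expected_counts):
        o, e = obs.get(stage, 0), expected_counts.get(stage, 0)
        if o != e:
            diffs[stage] = (o, e)
    return diffs


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------

def delta_g_from_kd(kd: float, config: CurationConfig = CurationConfig()) -> float:
    """Binding free energy ΔG = RT·ln(K_D) in kcal/mol; K_D in molar."""
    if kd <= 0:
        raise ValueError(f"dissociation constant must be > 0, got {kd}")
    return config.gas_constant_R * config.temperature_T * math.log(kd)


def recompute_ddg(record: AffinityRecord, config: CurationConfig = CurationConfig()) -> AffinityRecord:
    """Reconcile the stated ΔΔG with the thermodynamic cycle.

    When both ΔG values are derivable (directly or from K_D via RT·ln K_D),
    ΔΔG is replaced by ΔG_mutant − ΔG_wild-type — the stated value is treated
    as erroneous on conflict. Otherwise the stated ΔΔG is retained. Records
    with no value source at all are left for the missing-ΔΔG filter.
    """
    dg_wt = record.dg_wt
    dg_mut = record.dg_mut
    if dg_wt is None and record.kd_wt is not None:
        dg_wt = delta_g_from_kd(record.kd_wt, config)
    if dg_mut is None and record.kd_mut is not None:
        dg_mut = delta_g_from_kd(record.kd_mut, config)
    if dg_wt is not None and dg_mut is not None:
        return replace(record, dg_wt=dg_wt, dg_mut=dg_mut, ddg=dg_mut - dg_wt)
    return record


def assign_pseudonyms(records: Sequence[AffinityRecord]) -> list:
    """Give every complex lacking an identifier a deterministic pseudonym.

    Records sharing the same (unordered) partner-identifier pair share the
    same pseudonym; existing identifiers are untouched. The pseudonym is a
    stable hash of the sorted partner pair, so reruns reproduce it.
    """
    out = []
    for rec in records:
        if rec.complex_id:
            out.append(rec)
            continue
        partners = sorted([rec.partner_a_id or "", rec.partner_b_id or ""])
        digest = hashlib.sha1(("|".join(partners)).encode()).hexdigest()[:8].upper()
        out.append(replace(rec, complex_id=f"PSX-{digest}"))
    return out


def drop_missing_ddg(records: Sequence[AffinityRecord]) -> tuple:
    kept, removed = [], []
    for rec in records:
        if rec.ddg is None or not math.isfinite(rec.ddg):
            removed.append((rec, RemovalReason.MISSING_DDG))
        else:
            kept.append(rec)
    return kept, removed


def _groups(records: Sequence[AffinityRecord]) -> dict:
    grouped: dict = {}
    for rec in records:
        grouped.setdefault(rec.group_key(), []).append(rec)
    return grouped


def filter_replicate_sd(
    records: Sequence[AffinityRecord], config: CurationConfig = CurationConfig()
) -> tuple:
    """Remove whole replicate groups whose ΔΔG sample SD exceeds the cutoff.

    Sample (n−1) standard deviation; singleton groups have SD 0 and pass.
    Surviving groups pass through unmerged.
    """
    kept, removed = [], []
    for recs in _groups(records).values():
        values = [r.ddg for r in recs]
        sd = statistics.stdev(values) if len(values) > 1 else 0.0
        if sd > config.replicate_sd_cutoff:
            removed.extend((r, RemovalReason.REPLICATE_SD) for r in recs)
        else:
            kept.extend(recs)
    return kept, removed


def resolve_sign_conflicts(
    records: Sequence[AffinityRecord], config: CurationConfig = CurationConfig()
) -> tuple:
    """Apply the sign-conflict rules to each replicate group.

    (i) two replicates of opposite sign, both exceeding the threshold in
    magnitude: the whole group is removed; (ii) three or four replicates with
    mixed signs and any value exceeding the threshold: the whole group is
    removed; (iii) five or more replicates with one or two values deviating
    from the group median by more than the threshold: only those outliers are
    removed. Anything else passes unchanged.
    """
    cutoff = config.sign_conflict_cutoff
    kept, removed = [], []
    for recs in _groups(records).values():
        values = [r.ddg for r in recs]
        n = len(values)
        has_pos = any(v > 0 for v in values)
        has_neg = any(v < 0 for v in values)
        mixed = has_pos and has_neg
        if n == 2 and mixed and all(abs(v) > cutoff for v in values):
            removed.extend((r, RemovalReason.SIGN_CONFLICT_PAIR) for r in recs)
        elif 3 <= n <= 4 and mixed and any(abs(v) > cutoff for v in values):
            removed.extend((r, RemovalReason.SIGN_CONFLICT_SMALL_GROUP) for r in recs)
        elif n >= 5:
            med = statistics.median(values)
            outliers = [r for r in recs if abs(r.ddg - med) > cutoff]
            if 1 <= len(outliers) <= 2:
                out_ids = {id(r) for r in outliers}
                removed.extend((r, RemovalReason.SIGN_CONFLICT_OUTLIER) for r in outliers)
                kept.extend(r for r in recs if id(r) not in out_ids)
            else:
                kept.extend(recs)
        else:
            kept.extend(recs)
    return kept, removed


def merge_duplicates(records: Sequence[AffinityRecord]) -> tuple:
    """Collapse each replicate group to one record with the mean ΔΔG.

    ΔG/K_D fields are dropped on merged records (a mean ΔΔG no longer
    corresponds to a single measured pair). Returns (merged records,
    removed duplicates) so report conservation holds.
    """
    kept, removed = [], []
    for recs in _groups(records).values():
        if len(recs) == 1:
            kept.append(recs[0])
            continue
        mean_ddg = sum(r.ddg for r in recs) / len(recs)
        rep = replace(recs[0], ddg=mean_ddg, kd_wt=None, kd_mut=None, dg_wt=None, dg_mut=None)
        kept.append(rep)
        removed.extend((r, RemovalReason.MERGED_DUPLICATE) for r in recs[1:])
    return kept, removed


def _require_sequence(records: Sequence[AffinityRecord], sequences: Mapping[str, str]) -> tuple:
    kept, removed = [], []
    for rec in records:
        pid = rec.mutated_partner_id
        if not pid or pid not in sequences:
            removed.append((rec, RemovalReason.MISSING_SEQUENCE))
        else:
            kept.append(rec)
    return kept, removed


def _filter_mutation_format(records: Sequence[AffinityRecord]) -> tuple:
    kept, removed = [], []
    for rec in records:
        try:
            mut = parse_mutation(rec.mutation_raw)
        except ValueError:
            removed.append((rec, RemovalReason.BAD_MUTATION_FORMAT))
            continue
        kept.append(replace(rec, mutation=mut))
    return kept, removed


def renumber_and_validate(
    record: AffinityRecord,
    sequence: str,
    structure_to_sequence_map: Optional[Mapping[int, int]] = None,
) -> tuple:
    """Translate the structure residue number to the sequence coordinate.

    Returns ``(record, reason)`` where ``reason`` is ``None`` on success.
    A missing map means the numbering is already sequence-based (identity).
    The record is flagged (never raised) when the position has no mapping,
    maps outside the sequence, or the sequence residue disagrees with the
    stated wild-type residue.
    """
    mut = record.mutation
    if mut is None:
        return record, RemovalReason.BAD_MUTATION_FORMAT
    pos = mut.position
    if structure_to_sequence_map is not None:
        if pos not in structure_to_sequence_map:
            return record, RemovalReason.UNMAPPABLE_POSITION
        pos = structure_to_sequence_map[pos]
    if not 1 <= pos <= len(sequence):
        return record, RemovalReason.UNMAPPABLE_POSITION
    if sequence[pos - 1] != mut.wt_aa:
        return record, RemovalReason.RESIDUE_MISMATCH
    new_mut = Mutation(mut.wt_aa, pos, mut.mut_aa)
    return replace(record, mutation=new_mut, mutation_raw=str(new_mut)), None


def curate(
    records: Iterable[AffinityRecord],
    sequences: Mapping[str, str],
    maps: Optional[Mapping[str, Mapping[int, int]]] = None,
    config: CurationConfig = CurationConfig(),
) -> tuple:
    """Run the full curation chain; returns (clean records, CurationReport).

    ``sequences`` maps partner identifiers to residue strings; ``maps``
    optionally maps partner identifiers to structure→sequence renumbering
    dictionaries (absent entry = identity numbering). All failures are
    recorded removals, never exceptions.
    """
    maps = maps or {}
    report = CurationReport()
    recs = [recompute_ddg(r, config) for r in records]
    report.add("recompute_ddg", recs, [])
    recs = assign_pseudonyms(recs)
    report.add("assign_pseudonyms", recs, [])
    recs, removed = drop_missing_ddg(recs)
    report.add("drop_missing_ddg", recs, removed)
    recs, removed = filter_replicate_sd(recs, config)
    report.add("filter_replicate_sd", recs, removed)
    recs, removed = resolve_sign_conflicts(recs, config)
    report.add("resolve_sign_conflicts", recs, removed)
    recs, removed = merge_duplicates(recs)
    report.add("merge_duplicates", recs, removed)
    recs, removed = _require_sequence(recs, sequences)
    report.add("require_sequence", recs, removed)
    recs, removed = _filter_mutation_format(recs)
    report.add("mutation_format", recs, removed)
    kept, removed = [], []
    for rec in recs:
        seq = sequences[rec.mutated_partner_id]
        new_rec, reason = renumber_and_validate(rec, seq, maps.get(rec.mutated_partner_id))
        if reason is None:
            kept.append(new_rec)
        else:
            removed.append((rec, reason))
    report.add("renumber_validate", kept, removed)
    recs = kept
    if config.require_dimer:
        kept = [r for r in recs if r.n_chains == 2]
        removed = [(r, RemovalReason.NON_DIMER) for r in recs if r.n_chains != 2]
    else:
        kept, removed = recs, []
    report.add("require_dimer", kept, removed)
    return kept, report


# ---------------------------------------------------------------------------
# table I/O
# ---------------------------------------------------------------------------

_KNOWN_COLUMNS = [
    "complex_id",
    "partner_a_id",
    "partner_b_id",
    "mutated_partner",
    "mutation",
    "kd_wt",
    "kd_mut",
    "dg_wt",
    "dg_mut",
    "ddg",
    "ph",
    "functional_class",
    "structural_class",
    "n_chains",
    "source_tag",
]


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return float(value)


def _opt_str(value) -> Optional[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return str(value)


def read_affinity_table(path, sep: Optional[str] = None) -> list:
    """Read a CSV/TSV affinity table into :class:`AffinityRecord` objects.

    The separator is sniffed from the extension unless given. Unknown columns
    are preserved in ``record.extra`` as passthrough metadata.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    records = []
    for _, row in df.iterrows():
        d = row.to_dict()
        extra = {k: v for k, v in d.items() if k not in _KNOWN_COLUMNS}
        records.append(
            AffinityRecord(
                complex_id=_opt_str(d.get("complex_id")) or "",
                partner_a_id=_opt_str(d.get("partner_a_id")),
                partner_b_id=_opt_str(d.get("partner_b_id")),
                mutated_partner=_opt_str(d.get("mutated_partner")) or "A",
                mutation_raw=_opt_str(d.get("mutation")) or "",
                kd_wt=_opt_float(d.get("kd_wt")),
                kd_mut=_opt_float(d.get("kd_mut")),
                dg_wt=_opt_float(d.get("dg_wt")),
                dg_mut=_opt_float(d.get("dg_mut")),
                ddg=_opt_float(d.get("ddg")),
                ph=_opt_float(d.get("ph")),
                protein_class_functional=_opt_str(d.get("functional_class")),
                protein_class_structural=_opt_str(d.get("structural_class")),
                n_chains=int(d.get("n_chains", 2) if _opt_float(d.get("n_chains")) is not None else 2),
                source_tag=_opt_str(d.get("source_tag")) or "",
                extra=extra,
            )
        )
    return records


def write_affinity_table(records: Sequence[AffinityRecord], path, sep: str = ",") -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "complex_id": r.complex_id,
                "partner_a_id": r.partner_a_id,
                "partner_b_id": r.partner_b_id,
                "mutated_partner": r.mutated_partner,
                "mutation": r.mutation_raw,
                "kd_wt": r.kd_wt,
                "kd_mut": r.kd_mut,
                "dg_wt": r.dg_wt,
                "dg_mut": r.dg_mut,
                "ddg": r.ddg,
                "ph": r.ph,
                "functional_class": r.protein_class_functional,
                "structural_class": r.protein_class_structural,
                "n_chains": r.n_chains,
                "source_tag": r.source_tag,
                **r.extra,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep=sep, index=False)
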