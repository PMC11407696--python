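"""Parsers for the AAIndex database of amino-acid attribute scales.

AAIndex1 holds per-residue physicochemical attributes (one value per
standard residue); AAIndex2 holds substitution score matrices for residue
pairs. Both ship as flat text files of ``H``/``D``/``I``/``M`` record lines
terminated by ``//``. Indices with missing (``NA``) values are loaded but
flagged unusable; lower-triangular AAIndex2 matrices are symmetrized on
load, and rows/columns for gap or ambiguity codes are ignored.

Feature semantics: an AAIndex1 attribute contributes
``attr(mutant) − attr(wild-type)``; an AAIndex2 matrix contributes
``score(wild-type → mutant)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import AA_SET, validate_residue

__all__ = [
    "AAIndex1Table",
    "AAIndex2Table",
    "parse_aaindex1",
    "parse_aaindex2",
    "aaindex1_features",
    "aaindex2_features",
]

# residue order of the AAIndex1 "I" record: first value row then second
_AAINDEX1_ROW1 = "ARNDCQEGHI"
_AAINDEX1_ROW2 = "LKMFPSTWYV"


@dataclass
class AAIndex1Table:
    """Loaded AAIndex1 indices: (id, residue→value map, usable flag)."""

    entries: list = field(default_factory=list)  # (index_id, {aa: value} or partial, usable)

    @property
    def n_loaded(self) -> int:
        return len(self.entries)

    @property
    def usable_ids(self) -> list:
        return sorted(ix for ix, _, usable in self.entries if usable)

    def values_for(self, index_id: str) -> dict:
        for ix, vals, _ in self.entries:
            if ix == index_id:
                return vals
        raise KeyError(index_id)


@dataclass
class AAIndex2Table:
    """Loaded AAIndex2 substitution matrices keyed by matrix id."""

    entries: list = field(default_factory=list)  # (matrix_id, {(wt, mut): score}, usable)

    @property
    def n_loaded(self) -> int:
        return len(self.entries)

    @property
    def usable_ids(self) -> list:
        return sorted(mx for mx, _, usable in self.entries if usable)

    def scores_for(self, matrix_id: str) -> dict:
        for mx, scores, _ in self.entries:
            if mx == matrix_id:
                return scores
        raise KeyError(matrix_id)


def _records(text: str):
    """Split a flat file into records on '//' terminators."""
    record: list = []
    for line in text.splitlines():
        if line.startswith("//"):
            if record:
                yield record
            record = []
        elif line.strip():
            record.append(line)
    if record:
        yield record


def parse_aaindex1(text: str) -> AAIndex1Table:
    """Parse an AAIndex1 flat file.

    Each record's ``I`` line is followed by two rows of ten values
    (residue order ``ARNDCQEGHI`` / ``LKMFPSTWYV``); ``NA`` marks a missing
    value and makes the index unusable without discarding it.
    """
    table = AAIndex1Table()
    for record in _records(text):
        index_id = None
        values: dict = {}
        saw_i = False
        value_rows: list = []
        for line in record:
            tag = line[0]
            if tag == "H":
                index_id = line[1:].strip()
            elif tag == "I" and line[1] in (" ", "\t"):
                saw_i = True
            elif saw_i and line[:1] in (" ", "\t"):
                value_rows.append(line.split())
        if index_id is None:
            raise ValueError("AAIndex1 record without an H (identifier) line")
        if not saw_i or len(value_rows) < 2:
            raise ValueError(f"AAIndex1 record {index_id}: missing or truncated I value rows")
        flat = value_rows[0] + value_rows[1]
        if len(flat) != 20:
            raise ValueError(
                f"AAIndex1 record {index_id}: expected 20 values, got {len(flat)}"
            )
        usable = True
        for aa, tok in zip(_AAINDEX1_ROW1 + _AAINDEX1_ROW2, flat):
            if tok.upper() == "NA":
                usable = False
                continue
            try:
                values[aa] = float(tok)
            except ValueError:
                raise ValueError(
                    f"AAIndex1 record {index_id}: unparseable value {tok!r}"
                ) from None
        usable = usable and len(values) == 20 and all(np.isfinite(v) for v in values.values())
        table.entries.append((index_id, values, usable))
    return table


def parse_aaindex2(text: str) -> AAIndex2Table:
    """Parse an AAIndex2 flat file of substitution matrices.

    The ``M rows = ..., cols = ...`` line declares the residue orders; the
    following lines carry either a lower-triangular or a full square matrix.
    Triangular matrices are mirrored to symmetric form; rows or columns for
    non-standard codes (gaps, ambiguity symbols) are ignored. A matrix that
    cannot resolve every ordered standard pair after symmetrization is
    flagged unusable at load time.
    """
    table = AAIndex2Table()
    for record in _records(text):
        matrix_id = None
        row_order = col_order = None
        value_rows: list = []
        in_matrix = False
        for line in record:
            tag = line[0]
            if tag == "H":
                matrix_id = line[1:].strip()
                in_matrix = False
            elif tag == "M" and "rows" in line:
                spec = line[1:].replace(",", " ")
                parts = spec.split()
                try:
                    row_order = parts[parts.index("rows") + 2]
                    col_order = parts[parts.index("cols") + 2]
                except (ValueError, IndexError):
                    raise ValueError(
                        f"AAIndex2 record {matrix_id}: malformed M line {line!r}"
                    ) from None
                in_matrix = True
            elif in_matrix and line[:1] in (" ", "\t"):
                value_rows.append(line.split())
        if matrix_id is None:
            raise ValueError("AAIndex2 record without an H (identifier) line")
        if row_order is None:
            # record without a matrix body (rare annotation-only entries)
            table.entries.append((matrix_id, {}, False))
            continue
        scores: dict = {}
        missing = False
        for i, row in enumerate(value_rows):
            if i >= len(row_order):
                break
            r_aa = row_order[i]
            for j, tok in enumerate(row):
                if j >= len(col_order):
                    break
                c_aa = col_order[j]
                if r_aa not in AA_SET or c_aa not in AA_SET:
                    continue
                if tok.upper() == "NA" or tok == "-":
                    missing = True
                    continue
                scores[(r_aa, c_aa)] = float(tok)
        # triangular matrices: mirror to full symmetric form
        for (r, c), v in list(scores.items()):
            scores.setdefault((c, r), v)
        usable = (not missing) and all(
            (r, c) in scores for r in AA_SET for c in AA_SET
        )
        table.entries.append((matrix_id, scores, usable))
    return table


def aaindex1_features(table: AAIndex1Table, wt_aa: str, mut_aa: str) -> np.ndarray:
    """Per usable index: attribute(mutant) − attribute(wild-type), id-sorted."""
    wt_aa, mut_aa = validate_residue(wt_aa), validate_residue(mut_aa)
    ids = table.usable_ids
    if not ids:
        raise ValueError("AAIndex1 table has no usable indices")
    by_id = {ix: vals for ix, vals, usable in table.entries if usable}
    return np.array([by_id[ix][mut_aa] - by_id[ix][wt_aa] for ix in ids], dtype=float)


def aaindex2_features(table: AAIndex2Table, wt_aa: str, mut_aa: str) -> np.ndarray:
    """Per usable matrix: substitution score(wild-type → mutant), id-sorted."""
    wt_aa, mut_aa = validate_residue(wt_aa), validate_residue(mut_aa)
    ids = table.usable_ids
    if not ids:
        raise ValueError("AAIndex2 table has no usable matrices")
    by_id = {mx: scores for mx, scores, usable in table.entries if usable}
    return np.array([by_id[mx][(wt_aa, mut_aa)] for mx in ids], dtype=float)
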