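"""Position-specific scoring matrices and the descriptors derived from them.

A PSSM is the L×20 log-odds profile produced by iterative profile search
(PSI-BLAST against a clustered sequence database; conventionally three
iterations at E-value 0.001 against UniRef50). This module parses the
ASCII PSSM dialect PSI-BLAST emits, normalizes scores with a sigmoid into
(0, 1), and computes three families of sequence descriptors:

* averaged PSSM — the columnwise mean, a length-independent 20-vector;
* Row-PSSM — the normalized row at the mutation site, the site's
  substitution profile;
* pseudo-PSSM — lag-φ mean squared differences between entries φ positions
  apart, capturing sequence-order information:
  φ_j^φ = (1/(L−φ)) Σ_{i=1}^{L−φ} (P_{i,j} − P_{i+φ,j})².

Columns are re-mapped from the file's header order to the canonical
alphabetical ordering at parse time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .alphabet import AA_SET, CANONICAL_AA

__all__ = [
    "PSSMatrix",
    "NormalizedPSSM",
    "parse_ascii_pssm",
    "write_ascii_pssm",
    "sigmoid_normalize",
    "average_pssm",
    "row_pssm",
    "pse_pssm",
]


@dataclass(frozen=True)
class PSSMatrix:
    """Raw L×20 log-odds profile with canonical column order."""

    sequence: str
    scores: np.ndarray  # shape (L, 20), canonical column order

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(f"PSSM must be L x 20, got shape {scores.shape}")
        if scores.shape[0] != len(self.sequence):
            raise ValueError(
                f"row count {scores.shape[0]} != sequence length {len(self.sequence)}"
            )
        if not np.all(np.isfinite(scores)):
            raise ValueError("PSSM contains non-finite entries")

    @property
    def length(self) -> int:
        return len(self.sequence)

    column_order: str = CANONICAL_AA


@dataclass(frozen=True)
class NormalizedPSSM:
    """Sigmoid-normalized profile; every entry strictly in (0, 1)."""

    sequence: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if np.any(scores <= 0.0) or np.any(scores >= 1.0):
            raise ValueError("normalized PSSM entries must lie strictly in (0, 1)")

    @property
    def length(self) -> int:
        return len(self.sequence)


def parse_ascii_pssm(text: str) -> PSSMatrix:
    """Parse the ASCII PSSM written by PSI-BLAST into a :class:`PSSMatrix`.

    The first 20-score block (log-odds) is captured; the weighted-percentage
    block and the trailing per-row statistics are ignored. Columns are
    re-mapped from the header's amino-acid order to the canonical internal
    ordering, so files with any header permutation parse identically.
    """
    lines = text.splitlines()
    header_order = None
    rows = []
    residues = []
    for lineno, line in enumerate(lines, start=1):
        fields = line.split()
        if header_order is None:
            # header: 40 single-letter AA tokens (two 20-column blocks)
            if len(fields) >= 20 and all(f in AA_SET for f in fields[:20]):
                header_order = "".join(fields[:20])
                if len(set(header_order)) != 20:
                    raise ValueError(f"line {lineno}: header does not list 20 distinct residues")
            continue
        if not fields:
            continue
        if not fields[0].isdigit():
            break  # footer (K/Lambda statistics)
        if len(fields) < 42:
            raise ValueError(
                f"line {lineno}: expected 40 score fields after position and residue, "
                f"got {len(fields) - 2}"
            )
        residues.append(fields[1])
        try:
            rows.append([float(x) for x in fields[2:22]])
        except ValueError as err:
            raise ValueError(f"line {lineno}: unparseable score field ({err})") from None
    if header_order is None:
        raise ValueError("no PSSM header line found")
    if not rows:
        raise ValueError("no PSSM data rows found")
    raw = np.array(rows, dtype=float)
    perm = [header_order.index(aa) for aa in CANONICAL_AA]
    return PSSMatrix(sequence="".join(residues), scores=raw[:, perm])


def write_ascii_pssm(matrix: PSSMatrix, header_order: str = "ARNDCQEGHILKMFPSTWYV") -> str:
    """Render a :class:`PSSMatrix` in the PSI-BLAST ASCII dialect.

    Emits the two-block header, per-row log-odds (in ``header_order``), a
    dummy percentage block, trailing statistics, and a footer — everything
    :func:`parse_ascii_pssm` tolerates in real PSI-BLAST output.
    """
    perm = [CANONICAL_AA.index(aa) for aa in header_order]
    out = [
        "",
        "Last position-specific scoring matrix computed, weighted observed percentages "
        "rounded down, information per position, and relative weight of gapless real "
        "matches to pseudocounts",
    ]
    hdr = "           " + "  ".join(header_order) + "   " + "  ".join(header_order)
    out.append(hdr)
    for i, aa in enumerate(matrix.sequence):
        scores = matrix.scores[i, perm]
        score_str = " ".join(f"{int(round(s)):3d}" for s in scores)
        pct_str = " ".join(f"{0:3d}" for _ in range(20))
        out.append(f"{i + 1:5d} {aa} {score_str}  {pct_str}  0.00 0.00")
    out.append("")
    out.append("                      K         Lambda")
    out.append("Standard Ungapped    0.1337     0.3176")
    return "\n".join(out) + "\n"


def sigmoid_normalize(matrix: PSSMatrix) -> NormalizedPSSM:
    """Map every log-odds score through f(x) = 1/(1+e^{-x}) into (0, 1)."""
    with np.errstate(over="ignore"):
        norm = 1.0 / (1.0 + np.exp(-matrix.scores))
    # guard float under/overflow for extreme scores so entries stay in (0, 1)
    norm = np.clip(norm, 1e-300, 1.0 - 1e-16)
    return NormalizedPSSM(sequence=matrix.sequence, scores=norm)


def average_pssm(norm: NormalizedPSSM) -> np.ndarray:
    """Columnwise mean of the normalized profile — a length-independent 20-vector."""
    if norm.length < 1:
        raise ValueError("cannot average an empty PSSM")
    return norm.scores.mean(axis=0)


def row_pssm(norm: NormalizedPSSM, position: int) -> np.ndarray:
    """The normalized row at a 1-based sequence position (the mutation site)."""
    if not 1 <= position <= norm.length:
        raise ValueError(f"position {position} outside sequence of length {norm.length}")
    return norm.scores[position - 1].copy()


def pse_pssm(norm: NormalizedPSSM, phi: int | None = None, phi_max: int | None = None) -> np.ndarray:
    """Pseudo-PSSM sequence-order descriptors.

    With ``phi`` set, returns the 20 lag-φ terms
    φ_j^φ = (1/(L−φ)) Σ_i (P_{i,j} − P_{i+φ,j})².  With ``phi_max`` set,
    returns the full descriptor: the 20 averaged scores followed by the
    lag blocks for φ = 1..phi_max (20·(1+phi_max) values).
    """
    if (phi is None) == (phi_max is None):
        raise ValueError("specify exactly one of phi or phi_max")

    def lag_block(lag: int) -> np.ndarray:
        if not 1 <= lag < norm.length:
            raise ValueError(f"lag {lag} requires sequence length > {lag}, got {norm.length}")
        diff = norm.scores[:-lag] - norm.scores[lag:]
        return (diff**2).mean(axis=0)

    if phi is not None:
        return lag_block(phi)
    blocks = [average_pssm(norm)]
    blocks.extend(lag_block(lag) for lag in range(1, phi_max + 1))
    return np.concatenate(blocks)
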