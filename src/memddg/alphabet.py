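"""Canonical amino-acid alphabet shared by every module.

The internal column/feature order is the alphabetical one-letter alphabet.
File dialects (e.g. the PSI-BLAST ``ARNDCQEGHILKMFPSTWYV`` header order) are
re-mapped to this order at parse time so they never leak into feature order.
"""

from __future__ import annotations

#: Canonical internal ordering of the 20 standard residues.
CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"

#: PSI-BLAST / AAIndex2 conventional ordering, kept for writers and fixtures.
PSIBLAST_AA = "ARNDCQEGHILKMFPSTWYV"

AA_SET = frozenset(CANONICAL_AA)

#: 1-based integer code per residue in canonical order (A=1 .. Y=20).
AA_CODE = {aa: i + 1 for i, aa in enumerate(CANONICAL_AA)}

AA_INDEX = {aa: i for i, aa in enumerate(CANONICAL_AA)}


def validate_residue(aa: str) -> str:
    """Return ``aa`` upper-cased, or raise ``ValueError`` for non-standard codes."""
    aa = aa.upper()
    if aa not in AA_SET:
        raise ValueError(f"non-standard amino-acid code: {aa!r}")
    return aa
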