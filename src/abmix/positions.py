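"""IMGT position labels, ordering conventions and the residue alphabet.

Antibody variable regions are mapped onto the IMGT coordinate system:
positions 1-128, with insertion codes placed around the 111/112 slot in the
middle of CDR3.  Insertion letters ascend outward from 111 (111A, 111B, ...)
and descend toward 112 (..., 112B, 112A), so the full CDR3 ordering is::

    ... 110, 111, 111A, 111B, ..., 112B, 112A, 112, 113 ...

All modules share a fixed 21-symbol alphabet: the 20 standard amino acids in
alphabetical one-letter order followed by the gap symbol ``-``.
"""

from __future__ import annotations

import re
from typing import Sequence

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
GAP: str = "-"
ALPHABET: tuple[str, ...] = tuple(AMINO_ACIDS) + (GAP,)
GAP_CODE: int = 20

AA_TO_CODE: dict[str, int] = {a: i for i, a in enumerate(ALPHABET)}

IMGT_MIN = 1
IMGT_MAX = 128
CDR3_INSERTION_SLOT = (111, 112)

_LABEL_RE = re.compile(r"^([0-9]+)([A-Z]?)$")


def parse_label(label: str) -> tuple[int, str]:
    """Split a position label into (number, insertion letter or '')."""
    m = _LABEL_RE.match(label)
    if m is None:
        raise ValueError(f"malformed position label: {label!r}")
    return int(m.group(1)), m.group(2)


def label_sort_key(label: str) -> tuple[int, int]:
    """Sort key realizing the IMGT insertion-code ordering.

    For every position except 112, insertion letters sort after the base
    label in ascending alphabetical order.  At position 112 the letters sort
    *before* the base label in descending order, so that 111A < 112B < 112A
    < 112, matching the IMGT CDR3 convention.
    """
    num, ins = parse_label(label)
    rank = 0 if not ins else ord(ins) - ord("A") + 1
    if num == CDR3_INSERTION_SLOT[1]:
        rank = -rank
    return (num, rank)


def canonical_positions(insertion_cap: int = 10) -> list[str]:
    """IMGT 1-128 plus up to ``insertion_cap`` CDR3 insertion codes.

    Insertion codes are distributed symmetrically over the 111/112 slot:
    cap 10 yields 111A-111E and 112E-112A.
    """
    if insertion_cap < 0:
        raise ValueError("insertion_cap must be >= 0")
    n_111 = (insertion_cap + 1) // 2
    n_112 = insertion_cap // 2
    out: list[str] = []
    for n in range(IMGT_MIN, IMGT_MAX + 1):
        out.append(str(n))
        if n == CDR3_INSERTION_SLOT[0]:
            out.extend(f"111{chr(ord('A') + i)}" for i in range(n_111))
            out.extend(f"112{chr(ord('A') + i)}" for i in reversed(range(n_112)))
    return out


def insertion_labels(n_insertions: int, cap: int = 10) -> list[str]:
    """Labels for ``n_insertions`` extra residues between IMGT 111 and 112.

    Letters ascend from 111 for the first half and descend into 112 for the
    second half (111A, 111B, ..., 112B, 112A), the IMGT CDR3 convention.
    """
    if n_insertions > cap:
        raise ValueError(
            f"{n_insertions} CDR3 insertions exceed the insertion cap ({cap})"
        )
    n_111 = (n_insertions + 1) // 2
    n_112 = n_insertions // 2
    labels = [f"111{chr(ord('A') + i)}" for i in range(n_111)]
    labels += [f"112{chr(ord('A') + i)}" for i in reversed(range(n_112))]
    return labels


def labels_strictly_increasing(labels: Sequence[str]) -> bool:
    keys = [label_sort_key(l) for l in labels]
    return all(a < b for a, b in zip(keys, keys[1:]))


def encode_residue(residue: str) -> int:
    """Map a residue character (or gap) to its integer code."""
    try:
        return AA_TO_CODE[residue]
    except KeyError:
        raise ValueError(f"unknown residue symbol {residue!r}") from None
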