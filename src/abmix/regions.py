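"""Region definitions on the IMGT coordinate system.

Two families of CDR definitions are supported:

* **IMGT** regions, which partition positions 1-128 identically for every
  chain type: FR1 1-26, CDR1 27-38, FR2 39-55, CDR2 56-65, FR3 66-104,
  CDR3 105-117, FR4 118-128.  CDR3 insertion codes (111A...112A) belong to
  CDR3.
* **Kabat** CDRs, expressed here in IMGT coordinates through a packaged
  translation table.  Kabat boundaries were defined on the Kabat numbering
  and differ between heavy and light chains; the translation below follows
  the standard anchor correspondences (e.g. heavy Kabat 36 Trp = IMGT 41,
  Kabat 92 Cys = IMGT 104).

Key-residue and Vernier-zone position lists ship as editable CSV tables
(``chain_type,position``) under ``abmix/data``; callers may override both
per call anywhere they are consumed.
"""

from __future__ import annotations

import csv
from functools import lru_cache
from importlib import resources

from .positions import canonical_positions, parse_label

IMGT_REGION_BOUNDS: dict[str, tuple[int, int]] = {
    "framework_1": (1, 26),
    "cdr1": (27, 38),
    "framework_2": (39, 55),
    "cdr2": (56, 65),
    "framework_3": (66, 104),
    "cdr3": (105, 117),
    "framework_4": (118, 128),
}

# Kabat CDR boundaries translated to IMGT coordinates.
KABAT_CDR_BOUNDS: dict[str, dict[str, tuple[int, int]]] = {
    "H": {"cdr1": (36, 40), "cdr2": (55, 74), "cdr3": (107, 117)},
    "K": {"cdr1": (24, 40), "cdr2": (56, 69), "cdr3": (105, 117)},
    "L": {"cdr1": (24, 40), "cdr2": (56, 69), "cdr3": (105, 117)},
}

CHAIN_TYPES = ("H", "K", "L")


def _check_chain(chain_type: str) -> str:
    if chain_type not in CHAIN_TYPES:
        raise ValueError(
            f"unknown chain type {chain_type!r}; expected one of {CHAIN_TYPES}"
        )
    return chain_type


def _positions_in_range(
    lo: int, hi: int, positions: list[str], include_insertions: bool
) -> set[str]:
    out = set()
    for label in positions:
        num, ins = parse_label(label)
        if lo <= num <= hi and (include_insertions or not ins):
            out.add(label)
    return out


def region_mask(
    chain_type: str,
    region_spec: str,
    positions: list[str] | None = None,
) -> set[str]:
    """Resolve a region name to a set of IMGT position labels.

    Supported names: ``imgt_cdr1|2|3``, ``imgt_cdrs``, ``framework_1|2|3|4``
    (also accepted with an ``imgt_`` prefix), ``kabat_cdr1|2|3`` and
    ``kabat_cdrs``.  CDR3 masks include any insertion codes present in
    ``positions`` (default: the canonical position set).
    """
    _check_chain(chain_type)
    if positions is None:
        positions = canonical_positions()
    spec = region_spec.lower().strip()
    valid = (
        [f"imgt_cdr{i}" for i in (1, 2, 3)]
        + ["imgt_cdrs"]
        + [f"framework_{i}" for i in (1, 2, 3, 4)]
        + [f"imgt_framework_{i}" for i in (1, 2, 3, 4)]
        + [f"kabat_cdr{i}" for i in (1, 2, 3)]
        + ["kabat_cdrs"]
    )
    if spec.startswith("imgt_framework"):
        spec = spec[len("imgt_") :]

    if spec == "imgt_cdrs":
        return set().union(
            *(region_mask(chain_type, f"imgt_cdr{i}", positions) for i in (1, 2, 3))
        )
    if spec == "kabat_cdrs":
        return set().union(
            *(region_mask(chain_type, f"kabat_cdr{i}", positions) for i in (1, 2, 3))
        )
    if spec.startswith("imgt_cdr"):
        name = spec[len("imgt_") :]
        if name in IMGT_REGION_BOUNDS:
            lo, hi = IMGT_REGION_BOUNDS[name]
            return _positions_in_range(lo, hi, positions, name == "cdr3")
    if spec.startswith("framework_"):
        if spec in IMGT_REGION_BOUNDS:
            lo, hi = IMGT_REGION_BOUNDS[spec]
            return _positions_in_range(lo, hi, positions, False)
    if spec.startswith("kabat_cdr"):
        name = spec[len("kabat_") :]
        bounds = KABAT_CDR_BOUNDS[chain_type]
        if name in bounds:
            lo, hi = bounds[name]
            return _positions_in_range(lo, hi, positions, name == "cdr3")
    raise ValueError(
        f"unknown region {region_spec!r}; valid names: {', '.join(sorted(set(valid)))}"
    )


@lru_cache(maxsize=None)
def _load_table(filename: str) -> dict[str, frozenset[str]]:
    out: dict[str, set[str]] = {c: set() for c in CHAIN_TYPES}
    text = resources.files("abmix.data").joinpath(filename).read_text()
    for row in csv.DictReader(text.splitlines()):
        out[row["chain_type"]].add(row["position"])
    return {c: frozenset(v) for c, v in out.items()}


def key_residues(chain_type: str) -> set[str]:
    """Default framework key-residue positions (editable packaged table)."""
    _check_chain(chain_type)
    return set(_load_table("key_residues.csv")[chain_type])


def vernier_positions(chain_type: str) -> set[str]:
    """Default Vernier-zone positions (editable packaged table)."""
    _check_chain(chain_type)
    return set(_load_table("vernier_zones.csv")[chain_type])
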