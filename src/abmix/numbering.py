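"""Profile-based IMGT numbering of antibody variable regions.

A chain-type profile is a position-specific scoring table built from a
reference alignment: one column per canonical IMGT position, log-odds match
scores from column residue frequencies, and a two-tier gap-penalty scheme
(expensive to delete conserved framework columns, cheap to delete or insert
inside the CDRs).  A query sequence is numbered by semi-global dynamic
programming against each candidate chain profile; the best-scoring chain
wins and the alignment path is converted to IMGT position labels, with CDR3
insertion codes assigned symmetrically around the 111/112 slot.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .positions import (
    AMINO_ACIDS,
    GAP,
    GAP_CODE,
    canonical_positions,
    encode_residue,
    insertion_labels,
    label_sort_key,
    labels_strictly_increasing,
    parse_label,
)
from .regions import CHAIN_TYPES, IMGT_REGION_BOUNDS, region_mask

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: Conserved IMGT anchor residues checked during numbering validation.
CONSERVED_RESIDUES: dict[str, str] = {"23": "C", "41": "W", "104": "C"}


@dataclass
class ChainProfile:
    """Position-specific scoring profile for one chain type.

    Attributes
    ----------
    chain_type : {"H", "K", "L"}
    positions : list of canonical position labels, one per column.
    score_table : (L_p, 20) array of log-odds match scores.
    gap_penalty_template : (L_p,) nonnegative penalties for skipping a column.
    gap_penalty_query : (L_p + 1,) nonnegative penalties for inserting a
        query residue in each inter-column slot.
    terminal_gap_policy : "free" leaves terminal gaps unpenalized
        (semi-global alignment); "penalized" charges them like interior gaps.
    """

    chain_type: str
    positions: list[str]
    score_table: np.ndarray
    gap_penalty_template: np.ndarray
    gap_penalty_query: np.ndarray
    terminal_gap_policy: str = "free"

    def __post_init__(self) -> None:
        if self.chain_type not in CHAIN_TYPES:
            raise ValueError(f"unknown chain type {self.chain_type!r}")
        if len(self.positions) < 1:
            raise ValueError("profile needs at least one position")
        self.score_table = np.asarray(self.score_table, dtype=float)
        self.gap_penalty_template = np.asarray(self.gap_penalty_template, dtype=float)
        self.gap_penalty_query = np.asarray(self.gap_penalty_query, dtype=float)
        lp = len(self.positions)
        if self.score_table.shape != (lp, 20):
            raise ValueError("score_table must be (L_p, 20)")
        if not np.all(np.isfinite(self.score_table)):
            raise ValueError("score_table must be finite")
        if self.gap_penalty_template.shape != (lp,):
            raise ValueError("gap_penalty_template must be (L_p,)")
        if self.gap_penalty_query.shape != (lp + 1,):
            raise ValueError("gap_penalty_query must be (L_p + 1,)")
        if (self.gap_penalty_template < 0).any() or (self.gap_penalty_query < 0).any():
            raise ValueError("gap penalties must be nonnegative")
        keys = [label_sort_key(p) for p in self.positions]
        if any(a >= b for a, b in zip(keys, keys[1:])):
            raise ValueError("positions must be strictly increasing")
        if self.terminal_gap_policy not in ("free", "penalized"):
            raise ValueError("terminal_gap_policy must be 'free' or 'penalized'")

    @property
    def consensus(self) -> str:
        """Most probable residue per column."""
        return "".join(AMINO_ACIDS[j] for j in np.argmax(self.score_table, axis=1))


@dataclass
class NumberedSequence:
    """A sequence with per-residue IMGT labels and validation flags."""

    sequence: str
    labels: list[str]
    chain_type: str
    alignment_score: float
    percent_identity: float
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequence):
            raise ValueError("labels must match sequence length")
        if not labels_strictly_increasing(self.labels):
            raise ValueError("labels must be strictly increasing")

    def gapped(self, positions: list[str]) -> str:
        """Project onto a fixed position set, gap-filling unoccupied slots."""
        by_label = dict(zip(self.labels, self.sequence))
        return "".join(by_label.get(p, GAP) for p in positions)


@dataclass
class EncodedRepertoire:
    """Fixed-length integer encoding of numbered sequences.

    ``codes`` is an (N, L) array over the shared 21-symbol alphabet
    (20 amino acids + gap, code 20).
    """

    positions: list[str]
    codes: np.ndarray
    chain_type: str
    alphabet: tuple[str, ...] = tuple(AMINO_ACIDS) + (GAP,)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.positions):
            raise ValueError("codes must be (N, len(positions))")
        if self.codes.size and (self.codes.min() < 0 or self.codes.max() > 20):
            raise ValueError("codes must lie in [0, 20]")

    @property
    def n_sequences(self) -> int:
        return self.codes.shape[0]

    def decode(self, row: int) -> str:
        return "".join(self.alphabet[c] for c in self.codes[row])


def build_chain_profile(
    reference_alignment: list[str],
    positions: list[str],
    chain_type: str,
    pseudocount: float = 0.1,
    gap_penalty_high: float = 8.0,
    gap_penalty_low: float = 0.5,
    terminal_gap_policy: str = "free",
) -> ChainProfile:
    """Build a scoring profile from a gapped reference alignment.

    Match scores are per-column log-odds against a uniform background:
    ``log((count + pc) / (total + 20 pc)) - log(1/20)``.  Columns that are
    conserved (gap fraction < 0.01 and majority residue frequency > 0.95)
    take the high template-gap tier; columns inside or adjacent to a CDR
    take the low tier.  Template penalties are scaled by column occupancy so
    that rarely occupied columns are nearly free to skip.  Query-insertion
    penalties are low in slots bordering CDR columns and high elsewhere.
    All-gap columns are dropped from the profile.
    """
    if not reference_alignment:
        raise ValueError("reference alignment is empty")
    width = len(positions)
    for r, row in enumerate(reference_alignment):
        if len(row) != width:
            raise ValueError(
                f"ragged alignment: row {r} has length {len(row)}, expected {width}"
            )
    rows = np.array([[c for c in row] for row in reference_alignment])
    n_rows = rows.shape[0]

    counts = np.zeros((width, 20))
    for j, aa in enumerate(AMINO_ACIDS):
        counts[:, j] = (rows == aa).sum(axis=0)
    nongap = counts.sum(axis=1)
    keep = nongap > 0
    kept_positions = [p for p, k in zip(positions, keep) if k]
    counts = counts[keep]
    nongap = nongap[keep]
    lp = len(kept_positions)

    freqs = (counts + pseudocount) / (nongap + 20.0 * pseudocount)[:, None]
    score_table = np.log(freqs) - np.log(1.0 / 20.0)

    cdr = region_mask(chain_type, "imgt_cdrs", positions=kept_positions)
    cdr_idx = {i for i, p in enumerate(kept_positions) if p in cdr}
    cdr_adjacent = set()
    for i in cdr_idx:
        cdr_adjacent.update((i - 1, i, i + 1))

    gap_fraction = 1.0 - nongap / n_rows
    majority = counts.max(axis=1) / np.maximum(nongap, 1)
    conserved = (gap_fraction < 0.01) & (majority > 0.95)

    occupancy = nongap / n_rows
    tier = np.where(
        conserved, gap_penalty_high,
        np.where([i in cdr_adjacent for i in range(lp)], gap_penalty_low,
                 gap_penalty_high),
    )
    gap_penalty_template = tier * occupancy

    gap_penalty_query = np.full(lp + 1, gap_penalty_high)
    for s in range(lp + 1):
        neighbors = [i for i in (s - 1, s) if 0 <= i < lp]
        if any(i in cdr_idx for i in neighbors):
            gap_penalty_query[s] = gap_penalty_low

    return ChainProfile(
        chain_type=chain_type,
        positions=kept_positions,
        score_table=score_table,
        gap_penalty_template=gap_penalty_template,
        gap_penalty_query=gap_penalty_query,
        terminal_gap_policy=terminal_gap_policy,
    )


@dataclass
class Alignment:
    """Monotone alignment path of a query against a profile.

    ``path`` is a list of steps: ``("match", q, p)`` aligns query residue q
    to profile column p, ``("delete", p)`` skips column p, ``("insert", q)``
    places query residue q in an inter-column slot.
    """

    path: list[tuple]
    score: float


def _validate_query(sequence: str) -> None:
    if not sequence:
        raise ValueError("empty sequence")
    for i, c in enumerate(sequence):
        if c not in _AA_INDEX and c != "X":
            raise ValueError(f"illegal character {c!r} at index {i}")


def align_to_profile(sequence: str, profile: ChainProfile) -> Alignment:
    """Best-scoring monotone alignment of ``sequence`` to ``profile``.

    Semi-global dynamic programming with position-specific match scores,
    per-column deletion penalties and per-slot insertion penalties.
    Terminal gaps (leading/trailing deletions or insertions) are free under
    the ``free`` policy.  Ties are broken deterministically preferring
    match > deletion > insertion.  ``X`` scores 0 against every column.
    """
    _validate_query(sequence)
    n = len(sequence)
    lp = len(profile.positions)
    S = profile.score_table
    dpen = profile.gap_penalty_template
    ipen = profile.gap_penalty_query
    free_ends = profile.terminal_gap_policy == "free"

    res_scores = np.zeros((n, lp))
    for q, c in enumerate(sequence):
        if c != "X":
            res_scores[q] = S[:, _AA_INDEX[c]]

    NEG = -np.inf
    M = np.full((n + 1, lp + 1), NEG)
    # pointers: 0 none, 1 match, 2 delete, 3 insert
    ptr = np.zeros((n + 1, lp + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for q in range(n + 1):
        for p in range(lp + 1):
            if q == 0 and p == 0:
                continue
            best, op = NEG, 0
            if q > 0 and p > 0:
                cand = M[q - 1, p - 1] + res_scores[q - 1, p - 1]
                if cand > best:
                    best, op = cand, 1
            if p > 0:
                pen = 0.0 if free_ends and (q == 0 or q == n) else dpen[p - 1]
                cand = M[q, p - 1] - pen
                if cand > best:
                    best, op = cand, 2
            if q > 0:
                pen = 0.0 if free_ends and (p == 0 or p == lp) else ipen[p]
                cand = M[q - 1, p] - pen
                if cand > best:
                    best, op = cand, 3
            M[q, p] = best
            ptr[q, p] = op

    path: list[tuple] = []
    q, p = n, lp
    while q > 0 or p > 0:
        op = ptr[q, p]
        if op == 1:
            path.append(("match", q - 1, p - 1))
            q, p = q - 1, p - 1
        elif op == 2:
            path.append(("delete", p - 1))
            p -= 1
        else:
            path.append(("insert", q - 1))
            q -= 1
    path.reverse()
    return Alignment(path=path, score=float(M[n, lp]))


def _cdr3_slot_window(positions: list[str]) -> tuple[int, int]:
    """Column index range (lo, hi) spanning labels in (111, 112) exclusive,
    given as the first and one-past-last column whose label falls strictly
    between 111 and 113 in sort order but excluding plain 112/113."""
    lo = hi = None
    for i, lab in enumerate(positions):
        num, ins = parse_label(lab)
        if (num == 111 and ins) or (num == 112 and ins):
            if lo is None:
                lo = i
            hi = i + 1
    return lo, hi


def _path_to_labels(
    sequence: str, path: list[tuple], positions: list[str], insertion_cap: int = 10
) -> tuple[list[int], list[str], list[str]]:
    """Convert an alignment path to per-residue labels.

    Returns (query indices kept, labels, warnings).  Terminal insertions
    (query overhang beyond the profile) are trimmed with a warning.
    Interior insertions inside the CDR3 111/112 window — together with any
    residues matched to insertion-code columns — are relabeled as a group
    following the IMGT convention; interior insertions elsewhere get
    ascending letters on the preceding position.
    """
    warnings: list[str] = []
    lp = len(positions)

    # strip terminal insertions (overhang)
    first_anchor = next(
        (i for i, s in enumerate(path) if s[0] != "insert"), len(path)
    )
    last_anchor = next(
        (i for i in range(len(path) - 1, -1, -1) if path[i][0] != "insert"), -1
    )
    lead = [s for s in path[:first_anchor]]
    trail = [s for s in path[last_anchor + 1 :]]
    if lead:
        warnings.append(f"trimmed {len(lead)} unaligned N-terminal residue(s)")
    if trail:
        warnings.append(f"trimmed {len(trail)} unaligned C-terminal residue(s)")
    core = path[first_anchor : last_anchor + 1]

    # tentative labels; None marks interior insertions to resolve
    kept_q: list[int] = []
    tentative: list[tuple[str | None, int]] = []  # (label or None, slot column)
    cursor = 0  # profile column after the last consumed column
    for step in core:
        if step[0] == "match":
            _, q, p = step
            kept_q.append(q)
            tentative.append((positions[p], p))
            cursor = p + 1
        elif step[0] == "delete":
            cursor = step[1] + 1
        else:  # interior insert
            kept_q.append(step[1])
            tentative.append((None, cursor))

    # group: residues in the CDR3 insertion window (matched insertion-code
    # columns and interior insertions whose slot lies in the window)
    base111 = next((i for i, p in enumerate(positions) if p == "111"), None)
    base112 = next((i for i, p in enumerate(positions) if p == "112"), None)

    def in_cdr3_window(label: str | None, slot: int) -> bool:
        if label is not None:
            num, ins = parse_label(label)
            return bool(ins) and num in (111, 112)
        if base111 is None or base112 is None:
            return False
        return base111 < slot <= base112

    group_idx = [i for i, (lab, slot) in enumerate(tentative) if in_cdr3_window(lab, slot)]
    labels: list[str | None] = [lab for lab, _ in tentative]
    if group_idx:
        codes = insertion_labels(len(group_idx), cap=insertion_cap)
        for i, lab in zip(group_idx, codes):
            labels[i] = lab

    # remaining interior insertions: letters ascending on the preceding label
    pending: list[int] = []
    for i, lab in enumerate(labels):
        if lab is None:
            pending.append(i)
            continue
        if pending:
            prev = labels[pending[0] - 1] if pending[0] > 0 else None
            if prev is None:
                raise ValueError("cannot assign insertion codes before position 1")
            num, ins = parse_label(prev)
            if num == 112:
                raise ValueError(
                    "cannot assign insertion codes between positions 112 and 113"
                )
            start = ord(ins) + 1 - ord("A") if ins else 0
            for k, j in enumerate(pending):
                labels[j] = f"{num}{chr(ord('A') + start + k)}"
            warnings.append(
                f"insertion outside the CDR3 111/112 slot at position {num}"
            )
            pending = []
    if pending:
        raise ValueError("cannot assign insertion codes after the final position")

    assert all(l is not None for l in labels)
    return kept_q, [l for l in labels if l is not None], warnings


def number_sequence(
    sequence: str,
    profiles: list[ChainProfile],
    score_floor: float = 0.0,
    insertion_cap: int = 10,
) -> NumberedSequence:
    """Assign IMGT labels by aligning against each profile and keeping the
    best chain.

    The winning chain maximizes the length-normalized alignment score
    (ties prefer H > K > L).  Warnings flag missing conserved anchors
    (IMGT 23/104 cysteines, IMGT 41 tryptophan) and trimmed overhang.
    A best normalized score below ``score_floor`` raises an error.
    """
    if not profiles:
        raise ValueError("at least one profile is required")
    _validate_query(sequence)

    chain_rank = {c: i for i, c in enumerate(CHAIN_TYPES)}
    best: tuple[float, int, ChainProfile, Alignment] | None = None
    for prof in profiles:
        aln = align_to_profile(sequence, prof)
        norm = aln.score / max(len(aln.path), 1)
        key = (norm, -chain_rank[prof.chain_type])
        if best is None or key > (best[0], best[1]):
            best = (norm, -chain_rank[prof.chain_type], prof, aln)
    norm_score, _, profile, aln = best
    if norm_score < score_floor:
        raise ValueError(
            f"not an antibody variable region (normalized score {norm_score:.3f} "
            f"< floor {score_floor:.3f})"
        )

    kept_q, labels, warnings = _path_to_labels(
        sequence, aln.path, profile.positions, insertion_cap=insertion_cap
    )
    kept_seq = "".join(sequence[q] for q in kept_q)

    consensus = profile.consensus
    col_of = {p: i for i, p in enumerate(profile.positions)}
    by_label = dict(zip(labels, kept_seq))
    n_match = sum(1 for l in labels if l in col_of)
    n_ident = sum(
        1 for l, r in zip(labels, kept_seq)
        if l in col_of and consensus[col_of[l]] == r
    )
    pid = n_ident / n_match if n_match else 0.0

    for pos, expected in CONSERVED_RESIDUES.items():
        observed = by_label.get(pos)
        if observed != expected:
            what = f"found {observed}" if observed else "position absent"
            warnings.append(
                f"conserved residue {expected} expected at IMGT {pos}: {what}"
            )
    if "X" in kept_seq:
        warnings.append("sequence contains ambiguous residue X")

    return NumberedSequence(
        sequence=kept_seq,
        labels=labels,
        chain_type=profile.chain_type,
        alignment_score=aln.score,
        percent_identity=pid,
        warnings=warnings,
    )


def encode_repertoire(
    numbered: list[NumberedSequence],
    positions: list[str],
    overflow: str = "error",
) -> EncodedRepertoire:
    """Stack numbered sequences into a fixed-length integer matrix.

    Unoccupied positions take the gap code; residues whose labels fall
    outside ``positions`` are an error by default (``overflow="drop"``
    drops them silently per sequence).  ``X`` encodes as gap.
    """
    if not numbered:
        raise ValueError("no sequences to encode")
    chains = {ns.chain_type for ns in numbered}
    if len(chains) > 1:
        raise ValueError(f"mixed chain types: {sorted(chains)}")
    if overflow not in ("error", "drop"):
        raise ValueError("overflow must be 'error' or 'drop'")
    col_of = {p: i for i, p in enumerate(positions)}
    codes = np.full((len(numbered), len(positions)), GAP_CODE, dtype=np.int64)
    for r, ns in enumerate(numbered):
        for lab, res in zip(ns.labels, ns.sequence):
            if lab not in col_of:
                if overflow == "error":
                    raise ValueError(
                        f"label {lab} of sequence {r} outside the canonical "
                        f"position set"
                    )
                continue
            codes[r, col_of[lab]] = GAP_CODE if res == "X" else encode_residue(res)
    return EncodedRepertoire(
        positions=list(positions), codes=codes, chain_type=chains.pop()
    )


__all__ = [
    "ChainProfile",
    "NumberedSequence",
    "EncodedRepertoire",
    "Alignment",
    "build_chain_profile",
    "align_to_profile",
    "number_sequence",
    "encode_repertoire",
    "canonical_positions",
    "CONSERVED_RESIDUES",
]
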