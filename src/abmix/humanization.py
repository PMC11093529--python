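"""Closest-cluster humanization with greedy back-mutation.

The workflow mirrors CDR grafting: find the mixture component that assigns
the parent sequence the highest probability, replace every position outside
the (Kabat-defined, by default) CDRs and outside a user-supplied preserved
set with that component's most probable residue (the "straight graft"),
then walk back toward the parent.  Back-mutation greedily restores parent
residues — at each step the candidate whose restoration leaves the highest
full-mixture score — for as long as the score stays at or above a threshold,
typically expressed as a fraction of the straight-graft score.  Scores are
natural-log probabilities and therefore negative, so a fraction of 1.10
permits a 10% decrease in log-probability relative to the graft.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .mixture import CategoricalMixture, closest_cluster, score_sequence
from .numbering import ChainProfile, encode_repertoire, number_sequence
from .positions import GAP_CODE, encode_residue, label_sort_key
from .regions import key_residues, region_mask, vernier_positions


@dataclass
class HumanizationConfig:
    """Knobs for the graft + back-mutation procedure.

    ``preserve_positions=None`` selects the packaged key-residue list for
    the model's chain type; pass an explicit (possibly empty) set to
    override.  ``threshold_fraction=None`` performs a straight graft with
    no back-mutation.
    """

    cdr_definition: str = "kabat_cdrs"
    preserve_positions: set[str] | None = None
    threshold_fraction: float | None = 1.10

    def __post_init__(self) -> None:
        if self.threshold_fraction is not None and self.threshold_fraction <= 0:
            raise ValueError("threshold_fraction must be > 0")


@dataclass
class HumanizationResult:
    parent: str
    grafted: str
    final: str
    mutations: list[tuple[str, str, str]]
    scores: tuple[float, float, float]  # (parent, graft, final)
    threshold: float
    cluster_used: int
    warnings: list[str] = field(default_factory=list)


def _encode_gapped(model: CategoricalMixture, gapped: str) -> np.ndarray:
    if len(gapped) != model.seq_length:
        raise ValueError(
            f"gapped sequence length {len(gapped)} does not match the model's "
            f"{model.seq_length} positions"
        )
    return np.array([encode_residue(c) for c in gapped], dtype=np.int64)


def _decode(model: CategoricalMixture, codes: np.ndarray) -> str:
    return "".join(model.alphabet[c] for c in codes)


def _frozen_positions(
    model: CategoricalMixture, config: HumanizationConfig
) -> set[str]:
    cdrs = region_mask(model.chain_type, config.cdr_definition,
                       positions=list(model.positions))
    preserve = (key_residues(model.chain_type)
                if config.preserve_positions is None
                else set(config.preserve_positions))
    return cdrs | (preserve & set(model.positions))


def straight_graft(
    model: CategoricalMixture,
    encoded_parent: np.ndarray,
    config: HumanizationConfig | None = None,
) -> tuple[np.ndarray, int, list[str]]:
    """Graft the closest component's argmax residues outside the CDRs.

    Every position not in the CDR set and not preserved takes the
    component's most probable symbol (emission-table argmax; ties go to the
    alphabetically first residue).  When the argmax is the gap symbol at a
    framework position the parent residue is kept and a warning emitted.
    Returns (grafted codes, component index, warnings).
    """
    config = config or HumanizationConfig()
    parent = np.asarray(encoded_parent, dtype=np.int64)
    cluster = closest_cluster(model, parent)
    frozen = _frozen_positions(model, config)
    grafted = parent.copy()
    warnings: list[str] = []
    for i, label in enumerate(model.positions):
        if label in frozen:
            continue
        best = int(np.argmax(model.emission_probs[cluster, i]))
        if best == GAP_CODE and parent[i] != GAP_CODE:
            warnings.append(
                f"component argmax at position {label} is a gap; parent "
                f"residue kept"
            )
            continue
        grafted[i] = best
    return grafted, cluster, warnings


def back_mutate(
    model: CategoricalMixture,
    encoded_parent: np.ndarray,
    grafted: np.ndarray,
    threshold: float,
) -> np.ndarray:
    """Greedily restore parent residues while the score stays >= threshold.

    At every step each remaining grafted position is trialed; the candidate
    whose restored sequence scores highest (ties: lowest position label) is
    applied if that score clears the threshold, otherwise the search stops —
    no other candidate can clear it either.
    """
    parent = np.asarray(encoded_parent, dtype=np.int64)
    current = np.asarray(grafted, dtype=np.int64).copy()
    graft_score = score_sequence(model, current)
    if threshold > graft_score:
        raise ValueError(
            f"infeasible threshold {threshold:.6f} > graft score "
            f"{graft_score:.6f}"
        )
    candidates = sorted(
        (i for i in range(current.size) if current[i] != parent[i]),
        key=lambda i: label_sort_key(model.positions[i]),
    )
    while candidates:
        scores = []
        for i in candidates:
            trial = current.copy()
            trial[i] = parent[i]
            scores.append(score_sequence(model, trial))
        best_j = int(np.argmax(scores))
        if scores[best_j] < threshold:
            break
        current[candidates[best_j]] = parent[candidates[best_j]]
        candidates.pop(best_j)
    return current


def humanize(
    model: CategoricalMixture,
    sequence: str,
    config: HumanizationConfig | None = None,
    profiles: list[ChainProfile] | None = None,
) -> HumanizationResult:
    """Number, graft and back-mutate one parent sequence.

    ``sequence`` is either a raw amino-acid string (numbered against
    ``profiles``) or, when no profiles are given, a gapped string already
    aligned to the model's position set.  The back-mutation threshold is
    ``threshold_fraction * score(graft)`` on the natural-log scale.
    """
    config = config or HumanizationConfig()
    warnings: list[str] = []
    if profiles is not None:
        numbered = number_sequence(sequence, profiles)
        warnings.extend(numbered.warnings)
        rep = encode_repertoire([numbered], list(model.positions))
        parent_codes = rep.codes[0]
    else:
        parent_codes = _encode_gapped(model, sequence)

    parent_score = score_sequence(model, parent_codes)
    grafted_codes, cluster, graft_warnings = straight_graft(
        model, parent_codes, config
    )
    warnings.extend(graft_warnings)
    graft_score = score_sequence(model, grafted_codes)

    if config.threshold_fraction is None:
        final_codes = grafted_codes
        threshold = -math.inf
    else:
        threshold = config.threshold_fraction * graft_score
        final_codes = back_mutate(model, parent_codes, grafted_codes, threshold)
    final_score = score_sequence(model, final_codes)

    mutations = [
        (label, model.alphabet[parent_codes[i]], model.alphabet[final_codes[i]])
        for i, label in enumerate(model.positions)
        if parent_codes[i] != final_codes[i]
    ]
    return HumanizationResult(
        parent=_decode(model, parent_codes),
        grafted=_decode(model, grafted_codes),
        final=_decode(model, final_codes),
        mutations=mutations,
        scores=(parent_score, graft_score, final_score),
        threshold=threshold,
        cluster_used=cluster,
        warnings=warnings,
    )


def preservation_metrics(
    parent: str,
    candidate: str,
    positions: list[str],
    reference_mutations: set[str] | None = None,
    vernier: set[str] | None = None,
    chain_type: str | None = None,
) -> tuple[float, float | None, float]:
    """Preservation and overlap statistics for a humanized candidate.

    Returns (percent identity over all positions, overlap fraction with a
    reference mutation set or None, percent identity over the Vernier
    zone).  ``vernier`` defaults to the packaged table for ``chain_type``.
    """
    if len(parent) != len(candidate):
        raise ValueError("parent and candidate must have equal length")
    if len(parent) != len(positions):
        raise ValueError("positions must match the sequence length")
    n = len(parent)
    identical = sum(1 for a, b in zip(parent, candidate) if a == b)
    pct_identity = 100.0 * identical / n

    overlap = None
    if reference_mutations is not None:
        muts = {lab for lab, a, b in zip(positions, parent, candidate) if a != b}
        overlap = (len(muts & set(reference_mutations)) / len(reference_mutations)
                   if reference_mutations else 0.0)

    if vernier is None:
        vernier = vernier_positions(chain_type) if chain_type else set()
    v_idx = [i for i, lab in enumerate(positions) if lab in vernier]
    if v_idx:
        v_ident = sum(1 for i in v_idx if parent[i] == candidate[i])
        vernier_identity = 100.0 * v_ident / len(v_idx)
    else:
        vernier_identity = 100.0
    return pct_identity, overlap, vernier_identity


__all__ = [
    "HumanizationConfig",
    "HumanizationResult",
    "straight_graft",
    "back_mutate",
    "humanize",
    "preservation_metrics",
]
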