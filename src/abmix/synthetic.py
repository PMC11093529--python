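"""Synthetic ground-truth generators for every other module.

Real antibody repertoires are large, access-controlled or expensive to
curate; all tests and examples in this package instead run on synthetic
data with known truth.  The generators emulate three things:

* a "human" repertoire: sequences drawn from a known categorical mixture
  whose components are near-one-hot (well-separated clusters standing in
  for germline-driven sequence families);
* an evolutionarily related "other species": the same mixture with a
  fraction of emission rows redrawn (divergence), producing the kind of
  score separation generative humanness models show between species;
* toy reference alignments for profile-based numbering, built from a
  per-chain consensus with seeded substitutions and CDR-localized indels.

Every generator is a pure function of its arguments and seed: identical
inputs give identical outputs, and truth labels ride alongside all
generated data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .mixture import CategoricalMixture, sample_codes
from .numbering import EncodedRepertoire
from .positions import AMINO_ACIDS, GAP, canonical_positions, insertion_labels
from .regions import CHAIN_TYPES, region_mask

#: Anchor residues planted in every toy consensus (IMGT label -> residue).
_ANCHORS = {"23": "C", "41": "W", "104": "C"}

#: Canonical positions left unoccupied by the toy consensus, per chain.
_TOY_GAPS = {
    "H": {"10", "32", "33", "34", "60", "61", "62", "73"},
    "K": {"10", "32", "33", "34", "35", "58", "59", "60", "61", "62", "63", "81"},
    "L": {"10", "33", "34", "35", "59", "60", "61", "62", "81", "82"},
}

_TOY_SEED = {"H": 11, "K": 12, "L": 13}


@dataclass
class SyntheticScenario:
    """Study conditions for the synthetic benchmarks.

    ``separation`` controls cluster distinctness: emission rows are drawn
    from a symmetric Dirichlet with concentration ``1 / separation``, so
    large values give near-one-hot, well-separated components.
    ``divergence`` is the fraction of emission rows redrawn for the shifted
    species.  ``substitution_rate`` adds per-position uniform substitution
    noise on top of sampled sequences.
    """

    seed: int = 0
    K_true: int = 5
    L: int = 50
    n_train: int = 20000
    n_test: int = 2000
    separation: float = 20.0
    divergence: float = 0.3
    substitution_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.separation <= 0:
            raise ValueError("separation must be > 0")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must lie in [0, 1]")

    @property
    def concentration(self) -> float:
        return 1.0 / self.separation


def make_ground_truth_mixture(
    scenario: SyntheticScenario, chain_type: str = "H"
) -> CategoricalMixture:
    """Draw a ground-truth mixture for the scenario.

    Weights come from a symmetric Dirichlet(5) (sizable clusters, no
    near-empty components); each (component, position) emission row comes
    from a symmetric Dirichlet with the scenario's concentration.
    """
    rng = np.random.default_rng(scenario.seed)
    K, L = scenario.K_true, scenario.L
    pi = rng.dirichlet(np.full(K, 5.0))
    theta = rng.dirichlet(np.full(21, scenario.concentration), size=(K, L))
    return CategoricalMixture(
        positions=canonical_positions()[:L],
        mixture_weights=pi,
        emission_probs=theta,
        chain_type=chain_type,
        meta={"synthetic": True, "seed": scenario.seed,
              "concentration": scenario.concentration},
    )


def sample_repertoire(
    model: CategoricalMixture,
    n: int,
    seed: int,
    substitution_rate: float = 0.0,
) -> tuple[EncodedRepertoire, np.ndarray]:
    """Sample n sequences from the mixture; returns data + true components.

    Optional substitution noise replaces each symbol independently with a
    uniform random one at the given rate.
    """
    codes, labels = sample_codes(model, n, seed=seed)
    if substitution_rate > 0:
        rng = np.random.default_rng([seed, 104729])
        hit = rng.random(codes.shape) < substitution_rate
        codes = np.where(hit, rng.integers(0, 21, size=codes.shape), codes)
    rep = EncodedRepertoire(
        positions=list(model.positions), codes=codes, chain_type=model.chain_type
    )
    return rep, labels


def make_shifted_species(
    model: CategoricalMixture, divergence: float, seed: int
) -> CategoricalMixture:
    """Perturb a mixture into a related 'other species'.

    For each component an independent random subset of positions (expected
    fraction ``divergence``) has its emission row replaced by a fresh
    Dirichlet draw at the same concentration scale; the rest are copied.
    """
    if not 0.0 <= divergence <= 1.0:
        raise ValueError("divergence must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    K, L, A = model.emission_probs.shape
    theta = model.emission_probs.copy()
    concentration = model.meta.get("concentration", 0.05)
    redraw = rng.random((K, L)) < divergence
    n_redraw = int(redraw.sum())
    if n_redraw:
        theta[redraw] = rng.dirichlet(np.full(A, concentration), size=n_redraw)
    return CategoricalMixture(
        positions=list(model.positions),
        mixture_weights=model.mixture_weights.copy(),
        emission_probs=theta,
        chain_type=model.chain_type,
        meta=dict(model.meta, divergence=divergence, shift_seed=seed),
    )


def match_components(
    truth: CategoricalMixture, fitted: CategoricalMixture
) -> tuple[np.ndarray, float]:
    """Optimal component matching by mean per-position total variation.

    Returns ``(perm, mean_tv)`` where fitted component k corresponds to
    truth component ``perm[k]`` and ``mean_tv`` is the mean (over matched
    pairs and positions) total-variation distance between emission rows.
    """
    Kt, Kf = truth.n_clusters, fitted.n_clusters
    cost = np.empty((Kf, Kt))
    for k in range(Kf):
        diff = np.abs(fitted.emission_probs[k][None] - truth.emission_probs)
        cost[k] = 0.5 * diff.sum(axis=2).mean(axis=1)
    rows, cols = linear_sum_assignment(cost)
    perm = np.empty(Kf, dtype=np.int64)
    perm[rows] = cols
    return perm, float(cost[rows, cols].mean())


def toy_consensus(chain_type: str) -> dict[str, str]:
    """Deterministic toy consensus: occupied IMGT label -> residue.

    Residues are a seeded draw per chain type with the conserved anchors
    (Cys 23/104, Trp 41) planted; CDR-typical positions are left
    unoccupied so that profiles built from it show realistic gap structure.
    """
    if chain_type not in CHAIN_TYPES:
        raise ValueError(f"unknown chain type {chain_type!r}")
    rng = np.random.default_rng(_TOY_SEED[chain_type])
    gaps = _TOY_GAPS[chain_type]
    out: dict[str, str] = {}
    for label in canonical_positions(insertion_cap=0):
        draw = AMINO_ACIDS[rng.integers(0, 20)]  # drawn even for gaps: stable
        if label in gaps:
            continue
        out[label] = _ANCHORS.get(label, draw)
    return out


@dataclass
class ToyAlignment:
    """Reference alignment rows with per-row numbering truth."""

    chain_type: str
    positions: list[str]
    gapped_rows: list[str]
    sequences: list[str]
    labels: list[list[str]]


def make_toy_reference_alignment(
    chain_type: str,
    n_rows: int,
    indel_rate: float,
    seed: int,
    substitution_rate: float = 0.03,
    insertion_cap: int = 10,
) -> ToyAlignment:
    """Generate reference rows from the toy consensus with known labels.

    Each row applies seeded substitutions (anchors exempt) and up to two
    indel events, each occurring with probability ``indel_rate``: a
    deletion of an occupied CDR position or an insertion in the CDR3
    111/112 slot, labeled by the IMGT insertion convention.
    """
    if n_rows < 1:
        raise ValueError("n_rows must be >= 1")
    rng = np.random.default_rng(seed)
    consensus = toy_consensus(chain_type)
    positions = canonical_positions(insertion_cap=insertion_cap)
    cdr = region_mask(chain_type, "imgt_cdrs", positions=positions)
    cdr_occupied = sorted(
        (p for p in consensus if p in cdr), key=positions.index
    )
    gapped_rows, sequences, labels = [], [], []
    for _ in range(n_rows):
        row = dict(consensus)
        for label in list(row):
            if label in _ANCHORS:
                continue
            if rng.random() < substitution_rate:
                row[label] = AMINO_ACIDS[rng.integers(0, 20)]
        n_ins = 0
        for _event in range(2):
            if rng.random() >= indel_rate:
                continue
            if rng.random() < 0.5 and len(cdr_occupied) > 1:
                victim = cdr_occupied[rng.integers(0, len(cdr_occupied))]
                row.pop(victim, None)
            else:
                n_ins += 1
        for label in insertion_labels(n_ins, cap=insertion_cap):
            row[label] = AMINO_ACIDS[rng.integers(0, 20)]
        gapped_rows.append("".join(row.get(p, GAP) for p in positions))
        ordered = [p for p in positions if p in row]
        labels.append(ordered)
        sequences.append("".join(row[p] for p in ordered))
    return ToyAlignment(
        chain_type=chain_type,
        positions=positions,
        gapped_rows=gapped_rows,
        sequences=sequences,
        labels=labels,
    )


def toy_profiles(
    chains: tuple[str, ...] = ("H", "K", "L"),
    n_rows: int = 200,
    indel_rate: float = 0.02,
    seed: int = 0,
):
    """Chain profiles built from toy reference alignments (demo numbering).

    Stands in for profiles built from curated germline reference
    alignments; suitable for the packaged examples and tests.
    """
    from .numbering import build_chain_profile

    profiles = []
    for offset, chain in enumerate(chains):
        aln = make_toy_reference_alignment(
            chain, n_rows=n_rows, indel_rate=indel_rate, seed=seed + offset
        )
        profiles.append(
            build_chain_profile(aln.gapped_rows, aln.positions, chain)
        )
    return profiles


__all__ = [
    "SyntheticScenario",
    "toy_profiles",
    "make_ground_truth_mixture",
    "sample_repertoire",
    "make_shifted_species",
    "match_components",
    "toy_consensus",
    "ToyAlignment",
    "make_toy_reference_alignment",
]
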