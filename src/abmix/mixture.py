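"""Categorical mixture model over fixed-length numbered antibody sequences.

The generative model treats a numbered variable region as a length-L vector
of categories (20 amino acids + gap).  A sequence x has probability

    p(x) = sum_k pi_k  prod_i  theta[k, i, x_i]

with K mixture components: each component is a product of independent
per-position categorical distributions, but the mixture as a whole captures
dependence between positions.  Fitting is by expectation-maximization on
integer-encoded repertoires; the number of components is chosen by a BIC
grid search.  The log-probability of a sequence under a model fit to human
repertoires serves as a humanness score; per-component scores support
cluster assignment, component-wise generation and Bayes-rule species
classification.

All likelihood arithmetic is carried out in log space with log-sum-exp;
log 0 is represented as -inf and handled explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .numbering import EncodedRepertoire
from .positions import ALPHABET
from .regions import region_mask  # noqa: F401  (re-exported for convenience)

_SIMPLEX_TOL = 1e-9


@dataclass
class CategoricalMixture:
    """Mixture weights plus per-cluster, per-position emission tables.

    ``mixture_weights`` is a (K,) simplex vector; ``emission_probs`` is a
    (K, L, 21) tensor whose (k, i) slices are simplex vectors over the
    shared 21-symbol alphabet.
    """

    positions: list[str]
    mixture_weights: np.ndarray
    emission_probs: np.ndarray
    chain_type: str = "H"
    alphabet: tuple[str, ...] = ALPHABET
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mixture_weights = np.asarray(self.mixture_weights, dtype=float)
        self.emission_probs = np.asarray(self.emission_probs, dtype=float)
        K = self.mixture_weights.shape[0]
        L = len(self.positions)
        if K < 1:
            raise ValueError("need at least one cluster")
        if self.emission_probs.shape != (K, L, len(self.alphabet)):
            raise ValueError(
                f"emission_probs shape {self.emission_probs.shape} inconsistent "
                f"with K={K}, L={L}, alphabet={len(self.alphabet)}"
            )
        if (self.mixture_weights < 0).any() or (self.emission_probs < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(self.mixture_weights.sum() - 1.0) > _SIMPLEX_TOL:
            raise ValueError("mixture weights must sum to 1")
        rowsums = self.emission_probs.sum(axis=2)
        if np.abs(rowsums - 1.0).max() > _SIMPLEX_TOL:
            raise ValueError("each (cluster, position) emission row must sum to 1")

    @property
    def n_clusters(self) -> int:
        return self.mixture_weights.shape[0]

    @property
    def seq_length(self) -> int:
        return len(self.positions)

    def log_emissions(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.emission_probs)

    def log_weights(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log(self.mixture_weights)


@dataclass
class FitConfig:
    """EM fitting knobs.

    ``smoothing`` is a pseudocount added to every M-step category count so
    no emission probability is exactly zero (a single unseen residue would
    otherwise send a whole-sequence score to -inf).  ``shard_size`` bounds
    the number of rows processed per E-step chunk; sufficient statistics are
    accumulated identically regardless of sharding.

    ``init`` selects the initializer: ``"points"`` (default) seeds each
    component from a data row chosen by farthest-point Hamming traversal
    and is markedly more reliable on well-separated repertoires;
    ``"random"`` draws per-row responsibilities from a symmetric
    Dirichlet(1).
    """

    max_iter: int = 300
    tol: float = 1e-5
    seed: int = 0
    smoothing: float = 1e-6
    n_restarts: int = 3
    shard_size: int = 65536
    init: str = "points"

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.smoothing < 0:
            raise ValueError("smoothing must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_restarts < 1 or self.shard_size < 1:
            raise ValueError("n_restarts and shard_size must be >= 1")
        if self.init not in ("points", "random"):
            raise ValueError("init must be 'points' or 'random'")


@dataclass
class FitDiagnostics:
    loglik_trajectory: list[float]
    n_iter: int
    converged: bool
    bic: float
    seed_used: int


def _check_data(model: CategoricalMixture, data: EncodedRepertoire) -> None:
    if list(data.positions) != list(model.positions):
        raise ValueError("data positions do not match model positions")
    if tuple(data.alphabet) != tuple(model.alphabet):
        raise ValueError("data alphabet does not match model alphabet")


def _cluster_logliks(
    logt: np.ndarray, logpi: np.ndarray, codes: np.ndarray,
    keep: np.ndarray | None = None,
) -> np.ndarray:
    """(N, K) matrix of log pi_k + sum_i log theta[k, i, x_ni].

    ``keep`` optionally restricts the position sum to a boolean subset.
    """
    n = codes.shape[0]
    ll = np.tile(logpi, (n, 1))
    cols = range(codes.shape[1]) if keep is None else np.flatnonzero(keep)
    for i in cols:
        ll += logt[:, i, codes[:, i]].T
    return ll


def e_step_statistics(
    model: CategoricalMixture, data: EncodedRepertoire, shard_size: int
) -> tuple[np.ndarray, float]:
    """One E-step pass: responsibility-weighted counts and total log-likelihood.

    Counts have shape (L, 21, K) and are accumulated in row order with
    unbuffered indexed addition, so the result is bitwise identical for any
    shard size.
    """
    K, L = model.n_clusters, model.seq_length
    logt, logpi = model.log_emissions(), model.log_weights()
    counts = np.zeros((L, len(model.alphabet), K))
    total = 0.0
    codes = data.codes
    for start in range(0, codes.shape[0], shard_size):
        chunk = codes[start : start + shard_size]
        ll = _cluster_logliks(logt, logpi, chunk)
        lse = logsumexp(ll, axis=1)
        resp = np.exp(ll - lse[:, None])
        total += float(lse.sum())
        for i in range(L):
            np.add.at(counts[i], chunk[:, i], resp)
    return counts, total


def _m_step(
    counts: np.ndarray, smoothing: float
) -> tuple[np.ndarray, np.ndarray]:
    """Weights and emissions from responsibility-weighted counts."""
    # counts: (L, 21, K); cluster totals are identical at every position
    nk = counts[0].sum(axis=0)
    pi = nk / nk.sum()
    smoothed = counts + smoothing
    theta = smoothed / smoothed.sum(axis=1, keepdims=True)  # (L, 21, K)
    return pi, np.ascontiguousarray(np.transpose(theta, (2, 0, 1)))


def _init_model(
    data: EncodedRepertoire, K: int, smoothing: float,
    rng: np.random.Generator, init: str = "points",
) -> CategoricalMixture:
    """Initial parameters for one EM restart.

    ``points``: pick K seed rows by farthest-point (max-min Hamming
    distance) traversal from a random start and center each component's
    emissions on its seed row (0.6 on the observed symbol, the rest
    uniform), uniform weights.  ``random``: per-row Dirichlet(1)
    responsibilities followed by one M-step.
    """
    n = data.n_sequences
    L = len(data.positions)
    A = len(data.alphabet)
    if init == "points":
        codes = data.codes
        seeds = [int(rng.integers(n))]
        dist = (codes != codes[seeds[0]]).sum(axis=1)
        for _ in range(1, K):
            nxt = int(np.argmax(dist))
            seeds.append(nxt)
            dist = np.minimum(dist, (codes != codes[nxt]).sum(axis=1))
        theta = np.full((K, L, A), 0.4 / A)
        for k, s in enumerate(seeds):
            theta[k, np.arange(L), codes[s]] += 0.6
        pi = np.full(K, 1.0 / K)
    else:
        resp = rng.gamma(1.0, size=(n, K))
        resp /= resp.sum(axis=1, keepdims=True)
        counts = np.zeros((L, A, K))
        for i in range(L):
            np.add.at(counts[i], data.codes[:, i], resp)
        pi, theta = _m_step(counts, smoothing)
    return CategoricalMixture(
        positions=list(data.positions),
        mixture_weights=pi,
        emission_probs=theta,
        chain_type=data.chain_type,
        alphabet=tuple(data.alphabet),
    )


def em_fit(
    data: EncodedRepertoire, K: int, config: FitConfig | None = None
) -> tuple[CategoricalMixture, FitDiagnostics]:
    """Fit a K-component mixture by EM with random restarts.

    Each restart initializes responsibilities from a per-row symmetric
    Dirichlet(1) draw and iterates E/M until the relative log-likelihood
    change drops below ``config.tol`` or ``config.max_iter`` is reached.
    The restart with the highest final log-likelihood wins.
    """
    config = config or FitConfig()
    if data.n_sequences == 0:
        raise ValueError("empty data")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > data.n_sequences:
        raise ValueError(f"K={K} exceeds the number of sequences ({data.n_sequences})")

    best: tuple[CategoricalMixture, FitDiagnostics] | None = None
    best_ll = -np.inf
    for restart in range(config.n_restarts):
        seed = [int(config.seed), restart]
        rng = np.random.default_rng(seed)
        model = _init_model(data, K, config.smoothing, rng, config.init)
        traj: list[float] = []
        converged = False
        for _ in range(config.max_iter):
            counts, loglik = e_step_statistics(model, data, config.shard_size)
            traj.append(loglik)
            pi, theta = _m_step(counts, config.smoothing)
            model = CategoricalMixture(
                positions=model.positions,
                mixture_weights=pi,
                emission_probs=theta,
                chain_type=model.chain_type,
                alphabet=model.alphabet,
            )
            if len(traj) > 1:
                rel = abs(traj[-1] - traj[-2]) / max(abs(traj[-1]), 1e-300)
                if rel < config.tol:
                    converged = True
                    break
        final_ll = log_likelihood(model, data)
        model.meta = {
            "n": data.n_sequences,
            "seed": int(config.seed),
            "restart": restart,
            "iterations": len(traj),
            "smoothing": config.smoothing,
        }
        diag = FitDiagnostics(
            loglik_trajectory=traj,
            n_iter=len(traj),
            converged=converged,
            bic=_bic_from_loglik(final_ll, K, len(data.positions), data.n_sequences),
            seed_used=int(config.seed),
        )
        if best is None or final_ll > best_ll:
            best_ll = final_ll
            best = (model, diag)
    return best


def log_likelihood(model: CategoricalMixture, data: EncodedRepertoire) -> float:
    """Total log p(data) = sum_n log sum_k pi_k prod_i theta[k, i, x_ni]."""
    _check_data(model, data)
    logt, logpi = model.log_emissions(), model.log_weights()
    total = 0.0
    for start in range(0, data.n_sequences, 65536):
        chunk = data.codes[start : start + 65536]
        total += float(logsumexp(_cluster_logliks(logt, logpi, chunk), axis=1).sum())
    return total


def n_free_parameters(K: int, L: int, n_categories: int = 21) -> int:
    """(K - 1) mixture weights plus K*L*(n_categories - 1) emission params."""
    return (K - 1) + K * L * (n_categories - 1)


def _bic_from_loglik(loglik: float, K: int, L: int, n: int) -> float:
    return n_free_parameters(K, L) * np.log(n) - 2.0 * loglik


def bic(model: CategoricalMixture, data: EncodedRepertoire) -> float:
    """Bayesian information criterion: p ln N - 2 log L."""
    return _bic_from_loglik(
        log_likelihood(model, data), model.n_clusters, model.seq_length,
        data.n_sequences,
    )


def grid_select(
    data: EncodedRepertoire, K_grid: list[int], config: FitConfig | None = None
) -> tuple[CategoricalMixture, FitDiagnostics, pd.DataFrame]:
    """Fit every K in the grid and keep the BIC minimizer (ties: smallest K)."""
    if not K_grid:
        raise ValueError("K_grid is empty")
    rows = []
    best = None
    for K in sorted(K_grid):
        model, diag = em_fit(data, K, config)
        rows.append(
            {"K": K, "loglik": diag.loglik_trajectory[-1], "bic": diag.bic,
             "n_iter": diag.n_iter, "converged": diag.converged}
        )
        if best is None or diag.bic < best[1].bic:
            best = (model, diag)
    return best[0], best[1], pd.DataFrame(rows)


def prune(
    model: CategoricalMixture, weight_threshold: float = 1e-12
) -> CategoricalMixture:
    """Drop clusters with weights below the threshold and renormalize.

    Returns the model unchanged (same object) when nothing is pruned.
    """
    keep = model.mixture_weights >= weight_threshold
    if not keep.any():
        raise ValueError("all mixture weights fall below the pruning threshold")
    if keep.all():
        return model
    w = model.mixture_weights[keep]
    return CategoricalMixture(
        positions=model.positions,
        mixture_weights=w / w.sum(),
        emission_probs=model.emission_probs[keep],
        chain_type=model.chain_type,
        alphabet=model.alphabet,
        meta=dict(model.meta, pruned_from=model.n_clusters),
    )


def _mask_to_keep(model: CategoricalMixture, mask: set[str]) -> np.ndarray:
    unknown = set(mask) - set(model.positions)
    if unknown:
        raise ValueError(f"mask contains unknown position labels: {sorted(unknown)}")
    return np.array([p not in mask for p in model.positions])


def score_sequence(
    model: CategoricalMixture,
    encoded_row: np.ndarray,
    mask: set[str] | frozenset[str] = frozenset(),
    per_cluster: bool = False,
):
    """Log-probability of one encoded sequence, optionally masked.

    ``mask`` lists position labels to *exclude* from the product.  With
    ``per_cluster`` the K-vector log pi_k + sum_i log theta is returned
    without the final log-sum-exp aggregation.
    """
    row = np.asarray(encoded_row, dtype=np.int64).reshape(1, -1)
    if row.shape[1] != model.seq_length:
        raise ValueError("encoded row length does not match model positions")
    keep = _mask_to_keep(model, set(mask))
    ll = _cluster_logliks(model.log_emissions(), model.log_weights(), row, keep)[0]
    if per_cluster:
        return ll
    if not keep.any():
        return 0.0  # empty product: total probability mass is exactly 1
    return float(logsumexp(ll))


def score_repertoire(
    model: CategoricalMixture,
    data: EncodedRepertoire,
    mask: set[str] | frozenset[str] = frozenset(),
) -> np.ndarray:
    """Vector of per-sequence log-probabilities (see ``score_sequence``)."""
    _check_data(model, data)
    keep = _mask_to_keep(model, set(mask))
    logt, logpi = model.log_emissions(), model.log_weights()
    out = []
    for start in range(0, data.n_sequences, 65536):
        chunk = data.codes[start : start + 65536]
        out.append(logsumexp(_cluster_logliks(logt, logpi, chunk, keep), axis=1))
    return np.concatenate(out)


def closest_cluster(model: CategoricalMixture, encoded_row: np.ndarray) -> int:
    """Index of the component assigning the highest probability to the row."""
    ll = score_sequence(model, encoded_row, per_cluster=True)
    return int(np.argmax(ll))


def sample_codes(
    model: CategoricalMixture,
    n: int,
    cluster: int | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n encoded sequences; returns (codes, component labels).

    With ``cluster`` given, every draw comes from that component; otherwise
    components are drawn from the mixture weights first.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    K, L = model.n_clusters, model.seq_length
    if cluster is not None and not (0 <= cluster < K):
        raise ValueError(f"invalid cluster index {cluster} for K={K}")
    rng = np.random.default_rng(seed)
    if cluster is None:
        labels = rng.choice(K, size=n, p=model.mixture_weights)
    else:
        labels = np.full(n, cluster, dtype=np.int64)
    codes = np.empty((n, L), dtype=np.int64)
    n_sym = len(model.alphabet)
    for k in np.unique(labels):
        rows = np.flatnonzero(labels == k)
        for i in range(L):
            codes[rows, i] = rng.choice(n_sym, size=rows.size,
                                        p=model.emission_probs[k, i])
    return codes, labels


def sample(
    model: CategoricalMixture,
    n: int,
    cluster: int | None = None,
    seed: int = 0,
) -> list[str]:
    """Generate n gapped sequences from the mixture (or one component)."""
    codes, _ = sample_codes(model, n, cluster=cluster, seed=seed)
    alpha = model.alphabet
    return ["".join(alpha[c] for c in row) for row in codes]


def classify(
    models: dict[str, CategoricalMixture],
    priors: dict[str, float],
    encoded_row: np.ndarray,
) -> dict[str, float]:
    """Posterior species probabilities by Bayes' rule, computed in log space."""
    if set(models) != set(priors):
        raise ValueError("models and priors must cover the same species")
    names = sorted(models)
    ref = models[names[0]]
    for name in names[1:]:
        if list(models[name].positions) != list(ref.positions):
            raise ValueError("all models must share the same position set")
        if tuple(models[name].alphabet) != tuple(ref.alphabet):
            raise ValueError("all models must share the same alphabet")
    pvec = np.array([priors[name] for name in names], dtype=float)
    if (pvec < 0).any() or abs(pvec.sum() - 1.0) > _SIMPLEX_TOL:
        raise ValueError("priors must form a probability simplex")
    with np.errstate(divide="ignore"):
        logjoint = np.array(
            [score_sequence(models[name], encoded_row) + np.log(priors[name])
             for name in names]
        )
    post = np.exp(logjoint - logsumexp(logjoint))
    post /= post.sum()
    return dict(zip(names, post.tolist()))


def score_percentile(reference_scores: np.ndarray, score: float) -> float:
    """Empirical percentile of ``score`` with midpoint tie handling."""
    ref = np.asarray(reference_scores, dtype=float)
    if ref.size == 0:
        raise ValueError("reference score list is empty")
    less = float(np.count_nonzero(ref < score))
    equal = float(np.count_nonzero(ref == score))
    return 100.0 * (less + 0.5 * equal) / ref.size


__all__ = [
    "CategoricalMixture",
    "FitConfig",
    "FitDiagnostics",
    "em_fit",
    "e_step_statistics",
    "log_likelihood",
    "bic",
    "n_free_parameters",
    "grid_select",
    "prune",
    "score_sequence",
    "score_repertoire",
    "region_mask",
    "closest_cluster",
    "sample",
    "sample_codes",
    "classify",
    "score_percentile",
]
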