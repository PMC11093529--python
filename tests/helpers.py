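"""Independent brute-force oracles used across the test suite.

Everything here is deliberately written the slow, obvious way — probability
domain products, explicit path enumeration, naive counting — so it shares
no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from abmix.numbering import ChainProfile
from abmix.positions import AMINO_ACIDS

# ---------------------------------------------------------------- mixtures


def random_mixture_params(rng, K, L, n_categories=21):
    pi = rng.dirichlet(np.ones(K))
    theta = rng.dirichlet(np.ones(n_categories), size=(K, L))
    return pi, theta


def naive_sequence_prob(pi, theta, row, keep=None):
    """p(x) = sum_k pi_k prod_i theta[k, i, x_i], probability domain."""
    K, L, _ = theta.shape
    idx = range(L) if keep is None else [i for i in range(L) if keep[i]]
    total = 0.0
    for k in range(K):
        prod = pi[k]
        for i in idx:
            prod *= theta[k, i, row[i]]
        total += prod
    return total


def naive_log_likelihood(pi, theta, codes):
    return math.fsum(
        math.log(naive_sequence_prob(pi, theta, row)) for row in codes
    )


def naive_per_cluster_logprob(pi, theta, row, keep=None):
    K, L, _ = theta.shape
    idx = range(L) if keep is None else [i for i in range(L) if keep[i]]
    out = np.empty(K)
    for k in range(K):
        prod = pi[k]
        for i in idx:
            prod *= theta[k, i, row[i]]
        with np.errstate(divide="ignore"):
            out[k] = np.log(prod)
    return out


def naive_posterior(models_pt, priors, row):
    """models_pt: dict name -> (pi, theta)."""
    joint = {
        name: naive_sequence_prob(pi, theta, row) * priors[name]
        for name, (pi, theta) in models_pt.items()
    }
    z = sum(joint.values())
    return {name: v / z for name, v in joint.items()}


def reference_em(codes, K, seed, smoothing, n_iter, n_categories=21):
    """Plain-loop EM replicating the package's initialization contract:
    per-row Dirichlet(1) responsibilities from default_rng([seed, 0])."""
    codes = np.asarray(codes)
    n, L = codes.shape
    rng = np.random.default_rng([seed, 0])
    resp = rng.gamma(1.0, size=(n, K))
    resp /= resp.sum(axis=1, keepdims=True)

    def m_step(resp):
        nk = resp.sum(axis=0)
        pi = nk / nk.sum()
        theta = np.zeros((K, L, n_categories))
        for row, r in zip(codes, resp):
            for i in range(L):
                theta[:, i, row[i]] += r
        theta += smoothing
        theta /= theta.sum(axis=2, keepdims=True)
        return pi, theta

    pi, theta = m_step(resp)
    traj = []
    for _ in range(n_iter):
        probs = np.array(
            [[pi[k] * math.prod(theta[k, i, row[i]] for i in range(L))
              for k in range(K)] for row in codes]
        )
        traj.append(math.fsum(math.log(p.sum()) for p in probs))
        resp = probs / probs.sum(axis=1, keepdims=True)
        pi, theta = m_step(resp)
    return pi, theta, traj


# --------------------------------------------------------------- alignment


def enumerate_alignment_score(seq: str, prof: ChainProfile) -> float:
    """Best score over all monotone alignment paths, by full recursion."""
    n, lp = len(seq), len(prof.positions)
    free = prof.terminal_gap_policy == "free"
    best = [-np.inf]

    def rec(q, p, score):
        if q == n and p == lp:
            best[0] = max(best[0], score)
            return
        if p < lp:
            pen = 0.0 if free and (q == 0 or q == n) else prof.gap_penalty_template[p]
            rec(q, p + 1, score - pen)
        if q < n:
            pen = 0.0 if free and (p == 0 or p == lp) else prof.gap_penalty_query[p]
            rec(q + 1, p, score - pen)
        if q < n and p < lp:
            rec(q + 1, p + 1, score + prof.score_table[p, AMINO_ACIDS.index(seq[q])])

    rec(0, 0, 0.0)
    return best[0]


def score_from_path(seq: str, aln, prof: ChainProfile) -> float:
    """Recompute an alignment score by summing its per-step contributions."""
    n, lp = len(seq), len(prof.positions)
    free = prof.terminal_gap_policy == "free"
    consumed_q = 0  # query residues consumed so far
    slot = 0  # profile columns consumed so far
    total = 0.0
    for step in aln.path:
        if step[0] == "match":
            _, q, p = step
            total += prof.score_table[p, AMINO_ACIDS.index(seq[q])]
            consumed_q, slot = q + 1, p + 1
        elif step[0] == "delete":
            p = step[1]
            terminal = consumed_q == 0 or consumed_q == n
            total -= 0.0 if free and terminal else prof.gap_penalty_template[p]
            slot = p + 1
        else:
            q = step[1]
            terminal = slot == 0 or slot == lp
            total -= 0.0 if free and terminal else prof.gap_penalty_query[slot]
            consumed_q = q + 1
    return total


def all_sequences(alphabet: str, max_len: int):
    for length in range(1, max_len + 1):
        for tup in itertools.product(alphabet, repeat=length):
            yield "".join(tup)


# ------------------------------------------------------------ humanization


def greedy_backmutation_oracle(score_fn, parent, grafted, threshold, labels,
                               label_key):
    """Re-derive the greedy restoration trajectory by exhaustive evaluation.

    At each step every remaining candidate is scored after restoration; the
    best (ties: lowest label) is applied if it clears the threshold.
    Returns (final sequence, trajectory of applied positions).
    """
    current = list(grafted)
    candidates = sorted(
        (i for i in range(len(parent)) if current[i] != parent[i]),
        key=lambda i: label_key(labels[i]),
    )
    applied = []
    while candidates:
        scored = []
        for i in candidates:
            trial = list(current)
            trial[i] = parent[i]
            scored.append((score_fn(trial), i))
        best_score = max(s for s, _ in scored)
        # ties -> lowest label; candidates already in label order
        best_i = next(i for s, i in scored if s == best_score)
        if best_score < threshold:
            break
        current[best_i] = parent[best_i]
        candidates.remove(best_i)
        applied.append(best_i)
    return current, applied
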