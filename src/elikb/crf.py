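"""Linear-chain conditional random field primitives.

A sequence scores as

    score(y) = start[y_0] + sum_t emissions[t, y_t]
             + sum_t transitions[y_{t-1}, y_t] + end[y_{T-1}]

All computations are in log space.  ``forward_backward`` returns the node
and edge marginals needed for the maximum-likelihood gradient, and
``viterbi`` the exact argmax path (optionally under a transition mask that
forbids structurally invalid tag bigrams).
"""

from __future__ import annotations

import numpy as np


def _logsumexp(a: np.ndarray, axis: int) -> np.ndarray:
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


def path_score(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    path: np.ndarray,
) -> float:
    s = start[path[0]] + emissions[0, path[0]]
    for t in range(1, len(path)):
        s += transitions[path[t - 1], path[t]] + emissions[t, path[t]]
    return float(s + end[path[-1]])


def log_partition(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
) -> float:
    alpha = start + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha = _logsumexp(alpha[:, None] + transitions, axis=0) + emissions[t]
    return float(_logsumexp(alpha + end, axis=0))


def forward_backward(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Return (node marginals (T,L), expected transition counts (L,L), logZ)."""
    T, L = emissions.shape
    alphas = np.empty((T, L))
    alphas[0] = start + emissions[0]
    for t in range(1, T):
        alphas[t] = _logsumexp(alphas[t - 1][:, None] + transitions, axis=0) + emissions[t]
    betas = np.empty((T, L))
    betas[-1] = end
    for t in range(T - 2, -1, -1):
        betas[t] = _logsumexp(transitions + (emissions[t + 1] + betas[t + 1])[None, :], axis=1)
    log_z = float(_logsumexp(alphas[-1] + end, axis=0))
    node = np.exp(alphas + betas - log_z)
    edge = np.zeros((L, L))
    for t in range(1, T):
        m = (
            alphas[t - 1][:, None]
            + transitions
            + (emissions[t] + betas[t])[None, :]
            - log_z
        )
        edge += np.exp(m)
    return node, edge, log_z


def viterbi(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
    mask: np.ndarray | None = None,
    start_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Exact best path. ``mask``/``start_mask`` hold 0 for allowed and -inf
    for forbidden transitions / initial tags."""
    T, L = emissions.shape
    trans = transitions if mask is None else transitions + mask
    alpha = start + emissions[0]
    if start_mask is not None:
        alpha = alpha + start_mask
    back = np.empty((T, L), dtype=np.int64)
    for t in range(1, T):
        scores = alpha[:, None] + trans
        back[t] = np.argmax(scores, axis=0)
        alpha = scores[back[t], np.arange(L)] + emissions[t]
    last = int(np.argmax(alpha + end))
    path = np.empty(T, dtype=np.int64)
    path[-1] = last
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def brute_force_best(
    emissions: np.ndarray,
    transitions: np.ndarray,
    start: np.ndarray,
    end: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exhaustive argmax over all L**T paths (test oracle for small inputs)."""
    from itertools import product

    T, L = emissions.shape
    best_path, best_score = None, -np.inf
    for path in product(range(L), repeat=T):
        s = path_score(emissions, transitions, start, end, np.asarray(path))
        if s > best_score:
            best_path, best_score = np.asarray(path), s
    assert best_path is not None
    return best_path, best_score
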