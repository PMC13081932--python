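"""Shared test utilities: event matching and brute-force oracles."""

import numpy as np


def match_events(detected_s, true_s, tol_s):
    """Greedy one-to-one matching of detected to true event times.

    Returns (n_true_positive, n_true, n_detected).
    """
    detected_s = np.asarray(detected_s, dtype=float)
    true_s = np.asarray(true_s, dtype=float)
    used = set()
    tp = 0
    for t in true_s:
        if detected_s.size == 0:
            break
        d = np.abs(detected_s - t)
        order = np.argsort(d)
        for j in order:
            if d[j] > tol_s:
                break
            if j not in used:
                used.add(j)
                tp += 1
                break
    return tp, true_s.size, detected_s.size


def chain_clusters_oracle(onsets, eps):
    """Connected components of the |dt| <= eps adjacency graph (brute force)."""
    onsets = np.asarray(onsets, dtype=float)
    n = onsets.size
    adj = np.abs(onsets[:, None] - onsets[None, :]) <= eps
    labels = -np.ones(n, dtype=int)
    nxt = 0
    for i in range(n):
        if labels[i] >= 0:
            continue
        stack = [i]
        labels[i] = nxt
        while stack:
            k = stack.pop()
            for j in np.flatnonzero(adj[k]):
                if labels[j] < 0:
                    labels[j] = nxt
                    stack.append(j)
        nxt += 1
    return labels
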