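"""Independent brute-force oracles used by the test suite.

Everything here is deliberately written against the *definitions* (exhaustive
enumeration, flat edge scans, direct products of exponentials) and shares no
code path with the package implementation it checks.
"""

import itertools
import math

import numpy as np

import glowtree as gt


def enumeration_loglik_and_marginals(tree, traits, params, prior=(0.5, 0.5)):
    """Sum over every joint state assignment of all nodes (tips included, so
    missing data is handled by summation); returns (loglik, P(state 1) per node)."""
    flat = tree.flat
    P = {v: gt.transition_matrix(params, flat.blen[v]) for v in range(flat.n_nodes - 1)}
    tipl = np.ones((flat.n_tips, 2))
    for i, lab in enumerate(flat.labels):
        st = traits.states[lab]
        if st == 0:
            tipl[i, 1] = 0.0
        elif st == 1:
            tipl[i, 0] = 0.0
    internals = flat.internal_postorder
    total = 0.0
    marg = np.zeros(flat.n_nodes)
    for assign in itertools.product([0, 1], repeat=len(internals)):
        st = dict(zip(internals, assign))
        for tipassign in itertools.product([0, 1], repeat=flat.n_tips):
            pr = prior[st[flat.root]]
            for i in range(flat.n_tips):
                pr *= tipl[i, tipassign[i]]
            if pr == 0.0:
                continue
            full = {**st, **{i: tipassign[i] for i in range(flat.n_tips)}}
            for v in range(flat.n_nodes - 1):
                pr *= P[v][full[int(flat.parent[v])], full[v]]
            total += pr
            for v in range(flat.n_nodes):
                if full[v] == 1:
                    marg[v] += pr
    return math.log(total), marg / total


def edge_scan_transitions(flat, states):
    """Flat loop over an explicit edge list; counts (gains, losses)."""
    edges = [(int(flat.parent[c]), c) for c in range(flat.n_nodes - 1)]
    gains = sum(1 for p, c in edges if states[p] == 0 and states[c] == 1)
    losses = sum(1 for p, c in edges if states[p] == 1 and states[c] == 0)
    return gains, losses


def yule_loglik_direct(flat, lam):
    """Product-of-exponentials pure-birth log-likelihood: every lineage segment
    contributes exp(-lam * span) and every non-root split a factor lam."""
    ll = 0.0
    for v in range(flat.n_nodes - 1):
        ll += -lam * float(flat.blen[v])
        if v >= flat.n_tips:
            ll += math.log(lam)
    return ll


def clade_frequencies(sample):
    """Brute-force clade tabulation over a tree sample (hash-set counting)."""
    freq = {}
    for t in sample:
        flat = t.flat
        clades = flat.clades()
        for v in flat.internal_postorder:
            freq[clades[v]] = freq.get(clades[v], 0) + 1
    return freq


def mcc_pick_oracle(sample):
    """Index of the tree maximising the product of clade frequencies."""
    freq = clade_frequencies(sample)
    n = len(sample)
    best, best_score = 0, -math.inf
    for i, t in enumerate(sample):
        flat = t.flat
        clades = flat.clades()
        score = sum(math.log(freq[clades[v]] / n) for v in flat.internal_postorder)
        if score > best_score:
            best, best_score = i, score
    return best
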