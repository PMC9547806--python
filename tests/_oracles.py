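"""Independent reference implementations used only by the tests.

These deliberately avoid the package's own code paths: plain-loop entropy
maximisation, a hand-rolled union-find, and exhaustive enumeration of
attachment-event sequences with exact probabilities.
"""

from __future__ import annotations

import math
from collections import defaultdict

import numpy as np


def brute_force_renyi_threshold(hist, rho):
    """Exhaustive search over all 255 candidate thresholds, naive formulas."""
    hist = np.asarray(hist, dtype=float)
    total = hist.sum()
    p = hist / total
    best_t, best_score = None, -math.inf
    for t in range(255):
        if hist[t] <= 0:
            continue  # empty bin t ties with t-1; keep the plateau's lowest member
        p_bg = p[: t + 1].sum()
        p_fg = p[t + 1 :].sum()
        if p_bg <= 0 or p_fg <= 0:
            continue
        if abs(rho - 1.0) < 1e-12:
            h_bg = -sum(q / p_bg * math.log(q / p_bg) for q in p[: t + 1] if q > 0)
            h_fg = -sum(q / p_fg * math.log(q / p_fg) for q in p[t + 1 :] if q > 0)
        else:
            s_bg = sum((q / p_bg) ** rho for q in p[: t + 1] if q > 0)
            s_fg = sum((q / p_fg) ** rho for q in p[t + 1 :] if q > 0)
            h_bg = math.log(s_bg) / (1.0 - rho)
            h_fg = math.log(s_fg) / (1.0 - rho)
        score = h_bg + h_fg
        if score > best_score:  # strict: keeps the first (lowest) maximiser
            best_score, best_t = score, t
    return best_t


def union_find_component_sizes(n_receptors, edges):
    """Component sizes over receptors via an independent union-find."""
    parent = list(range(n_receptors))

    def find(x):
        root = x
        while parent[root] != root:
            root = parent[root]
        while parent[x] != root:
            parent[x], x = root, parent[x]
        return root

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra
    sizes = defaultdict(int)
    for r in range(n_receptors):
        sizes[find(r)] += 1
    return sorted(sizes.values(), reverse=True)


def enumerate_attachment_outcomes(
    n_receptors,
    stoichiometry,
    species,
    k_on=1.0,
    k_cross=5.0,
    allow_intra=False,
):
    """Exact outcome distribution over all attachment-event sequences.

    ``species`` is a list of ``(target_subunit, molecule_count)``.  Events and
    weights mirror the model definition: a solution molecule of species ``i``
    binds a specific free epitope with weight ``k_on`` (times the number of
    remaining molecules), and a specific singly-bound antibody binds a
    specific free compatible epitope on another receptor (or the same one if
    ``allow_intra``) with weight ``k_cross``.  Returns a dict mapping the
    sorted tuple of receptor component sizes to its exact probability.
    """
    epitopes = []
    for r in range(n_receptors):
        for sub, copies in stoichiometry.items():
            for k in range(copies):
                epitopes.append((r, sub, k))

    outcomes = defaultdict(float)

    def component_signature(abs_state):
        edges = []
        for _, atts in abs_state:
            if len(atts) == 2 and atts[0][0] != atts[1][0]:
                edges.append((atts[0][0], atts[1][0]))
        return tuple(union_find_component_sizes(n_receptors, edges))

    def recurse(free, sol, abs_state, prob):
        events = []
        for i, (sub, _) in enumerate(species):
            if sol[i] > 0:
                for e in free:
                    if e[1] == sub:
                        events.append(("on", i, e, k_on * sol[i]))
        for j, (i, atts) in enumerate(abs_state):
            if len(atts) == 1:
                sub = species[i][0]
                anchor = atts[0][0]
                for e in free:
                    if e[1] == sub and (allow_intra or e[0] != anchor):
                        events.append(("cross", j, e, k_cross))
        if not events:
            outcomes[component_signature(abs_state)] += prob
            return
        total = sum(w for *_, w in events)
        for kind, idx, e, w in events:
            p = prob * w / total
            new_free = tuple(x for x in free if x != e)
            if kind == "on":
                new_sol = list(sol)
                new_sol[idx] -= 1
                recurse(new_free, tuple(new_sol),
                        abs_state + ((idx, (e,)),), p)
            else:
                new_abs = list(abs_state)
                i, atts = new_abs[idx]
                new_abs[idx] = (i, atts + (e,))
                recurse(new_free, sol, tuple(new_abs), p)

    recurse(tuple(epitopes), tuple(c for _, c in species), tuple(), 1.0)
    return dict(outcomes)
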