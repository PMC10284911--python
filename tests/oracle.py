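"""Independent naive reference implementations used to cross-check the model.

Deliberately written with per-node python loops over dictionaries (no shared
code or vectorization with the implementation under test).
"""

import math


def naive_propagate(interactome, weights_by_edge, stimulus, damping, tol, max_iter):
    """Damped tanh fixed point computed edge-by-edge with plain dicts."""
    acts = {n: 0.0 for n in interactome.nodes}
    clamped = {n: float(v) for n, v in stimulus.items() if n in acts}
    acts.update(clamped)
    for _ in range(max_iter):
        new = {}
        for n in interactome.nodes:
            if n in clamped:
                new[n] = clamped[n]
                continue
            total = 0.0
            for e in interactome.edges.values():
                w = weights_by_edge[e.key] * e.sign
                if e.target == n:
                    total += w * acts[e.source]
                elif e.source == n and not e.directed:
                    total += w * acts[e.target]
            new[n] = (1 - damping) * acts[n] + damping * math.tanh(total)
        delta = max((abs(new[n] - acts[n]) for n in acts), default=0.0)
        acts = new
        if delta < tol:
            break
    return acts


def reachable_from(interactome, sources):
    """Breadth-first reachability ignoring direction and signs."""
    seen = set(s for s in sources if s in interactome.nodes)
    frontier = list(seen)
    while frontier:
        nxt = []
        for n in frontier:
            for m in interactome.neighbors(n):
                if m not in seen:
                    seen.add(m)
                    nxt.append(m)
        frontier = nxt
    return seen
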