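"""Small built-in example networks.

The centerpiece is a 10-node weighted network with three communities and
two planted cycles — a pentagon (nodes 2-6) and a square (nodes 7-10) —
whose five distinct weight levels stage a complete filtration story: the
pentagon's cycle is born first and filled last, the square's cycle is born
second and filled first, and the final level bridges the three communities
into one component.  Scanning its six threshold stages (the empty graph
plus the five weight levels) gives Betti sequences

    b0 = 10, 6, 3, 3, 3, 1        (components, graph == clique complex)
    b1 =  0, 1, 2, 1, 0, 0        (clique-complex cycles)

making it a compact end-to-end check for thresholding, persistence, and
super-graph consolidation (its 3-community partition contracts it to 3
super-nodes).
"""

from __future__ import annotations

import numpy as np

from .connectome import FCMatrix, Partition

__all__ = [
    "two_cycle_toy_network",
    "TOY_STAGE_WEIGHTS",
    "TOY_B0",
    "TOY_CLIQUE_B1",
]

#: the five distinct positive weight levels, in filtration (decreasing) order
TOY_STAGE_WEIGHTS = (0.9, 0.8, 0.7, 0.6, 0.5)

#: components at the six stages: empty graph then one stage per weight level
TOY_B0 = (10, 6, 3, 3, 3, 1)

#: clique-complex first Betti number at the same six stages
TOY_CLIQUE_B1 = (0, 1, 2, 1, 0, 0)


def two_cycle_toy_network() -> tuple[FCMatrix, Partition]:
    """The 10-node, three-community, two-cycle example network.

    Edges by weight level (region labels are "1".."10"):

    * 0.9 — pentagon 2-3-4-5-6 (cycle born at dissimilarity 0.1)
    * 0.8 — square 7-8-10-9 (cycle born at 0.2)
    * 0.7 — square chords 7-10 and 8-9 (square cycle filled at 0.3)
    * 0.6 — pentagon chords 2-4 and 2-5 (pentagon cycle filled at 0.4)
    * 0.5 — bridges 1-2 and 6-7 (the three communities merge)

    All other pairs have weight 0.  The partition assigns node 1 to FN1,
    nodes 2-6 to FN2 and nodes 7-10 to FN3.
    """
    edges = {
        (2, 3): 0.9, (3, 4): 0.9, (4, 5): 0.9, (5, 6): 0.9, (2, 6): 0.9,
        (7, 8): 0.8, (8, 10): 0.8, (9, 10): 0.8, (7, 9): 0.8,
        (7, 10): 0.7, (8, 9): 0.7,
        (2, 4): 0.6, (2, 5): 0.6,
        (1, 2): 0.5, (6, 7): 0.5,
    }
    W = np.zeros((10, 10))
    for (u, v), w in edges.items():
        W[u - 1, v - 1] = W[v - 1, u - 1] = w
    np.fill_diagonal(W, 1.0)
    ids = tuple(str(i) for i in range(1, 11))
    fc = FCMatrix(W, ids)
    sigma = np.array([0, 1, 1, 1, 1, 1, 2, 2, 2, 2])
    part = Partition(sigma, ("FN1", "FN2", "FN3"), ids)
    return fc, part
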