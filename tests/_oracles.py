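"""Independent brute-force reference implementations used only by tests.

Each oracle deliberately re-derives its result from first principles (plain
loops, no shared helpers with the package) so agreement with the package is
a genuine cross-check rather than a tautology.
"""

import math

import numpy as np


def naive_effective(pair, target, threshold: float) -> bool:
    tx, ty = target.position
    dl = math.sqrt((tx - pair.left[0]) ** 2 + (ty - pair.left[1]) ** 2)
    dr = math.sqrt((tx - pair.right[0]) ** 2 + (ty - pair.right[1]) ** 2)
    return dl < threshold or dr < threshold


def brute_force_rasterize(session, size: int) -> np.ndarray:
    """(size, size, 3) GaDe array built pair-by-pair with explicit loops."""

    def dist(p, t):
        return math.sqrt((t[0] - p[0]) ** 2 + (t[1] - p[1]) ** 2)

    def pixel(p):
        x = min(max(p[0], 0.0), 1.0 - 1e-12)
        y = min(max(p[1], 0.0), 1.0 - 1e-12)
        return int(y * size), int(x * size)

    triples = []
    for p in session.pairs:
        t = session.protocol.target(p.target_index).position
        c = ((p.left[0] + p.right[0]) / 2, (p.left[1] + p.right[1]) / 2)
        triples.append(
            (
                (p.left, dist(p.left, t)),
                (p.right, dist(p.right, t)),
                (c, dist(c, t)),
            )
        )
    out = np.zeros((size, size, 3), dtype=np.int64)
    for chan in range(3):
        d_max = max(tr[chan][1] for tr in triples)
        if d_max == 0:
            continue
        for tr in triples:
            point, d = tr[chan]
            v = math.floor(d / d_max * 255 + 0.5)
            r, c = pixel(point)
            out[r, c, chan] = max(out[r, c, chan], v)
    return out
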