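"""Independent brute-force oracles shared by the test modules."""

import math

import numpy as np


def brute_force_yen(image: np.ndarray) -> float:
    """Exhaustive maximization of the Yen criterion over every histogram split.

    Direct per-split sums (no cumulative-sum tricks), so it is an independent
    check of the production implementation.
    """
    img = np.asarray(image)
    levels = np.arange(int(img.min()), int(img.max()) + 1)
    counts = np.bincount((img.ravel() - levels[0]).astype(int), minlength=len(levels))
    p = counts / counts.sum()
    best_c, best_t = -np.inf, None
    for s in range(len(levels)):
        p1 = p[: s + 1].sum()
        s1 = (p[: s + 1] ** 2).sum()
        s2 = (p[s + 1 :] ** 2).sum()
        if not (0 < p1 < 1) or s1 <= 0 or s2 <= 0:
            continue
        c = 2.0 * math.log(p1 * (1.0 - p1)) - math.log(s1 * s2)
        if c > best_c + 1e-12:
            best_c, best_t = c, float(levels[s])
    return best_t
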