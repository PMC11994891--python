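"""Independent brute-force oracles shared by the test suite.

Everything here is written directly from the mathematical definitions,
with plain loops and no code shared with the package implementation.
"""

import math
from collections import deque

import numpy as np

from satquant.imaging import IntensityHistogram


def mean_threshold_oracle(counts):
    total = sum(counts)
    return int(sum(k * c for k, c in enumerate(counts)) / total)


def renyi_candidate_oracle(counts, alpha):
    """Smallest t maximizing H_A^alpha(t) + H_B^alpha(t), scored per t."""
    total = sum(counts)
    p = [c / total for c in counts]
    best_t, best_val = None, -math.inf
    for t in range(256):
        pa = sum(p[: t + 1])
        pb = 1.0 - pa
        if pa <= 0 or pb <= 0:
            continue
        if alpha == 1.0:
            ha = -sum(pi / pa * math.log(pi / pa) for pi in p[: t + 1] if pi > 0)
            hb = -sum(pi / pb * math.log(pi / pb) for pi in p[t + 1:] if pi > 0)
        else:
            sa = sum((pi / pa) ** alpha for pi in p[: t + 1])
            sb = sum((pi / pb) ** alpha for pi in p[t + 1:])
            if sa <= 0 or sb <= 0:
                continue
            ha = math.log(sa) / (1.0 - alpha)
            hb = math.log(sb) / (1.0 - alpha)
        val = ha + hb
        if val > best_val:
            best_t, best_val = t, val
    return best_t


def renyi_combined_oracle(counts):
    """Three-alpha fusion re-derived independently from the published rule."""
    total = sum(counts)
    p = [c / total for c in counts]
    cum = []
    acc = 0.0
    for pi in p:
        acc += pi
        cum.append(acc)
    ts = sorted(renyi_candidate_oracle(counts, a) for a in (0.5, 1.0, 2.0))
    t1, t2, t3 = ts
    if abs(t1 - t2) <= 5:
        beta = (1, 2, 1) if abs(t2 - t3) <= 5 else (0, 1, 3)
    else:
        beta = (3, 1, 0) if abs(t2 - t3) <= 5 else (1, 2, 1)
    omega = cum[t3] - cum[t1]
    return int(
        t1 * (cum[t1] + 0.25 * omega * beta[0])
        + 0.25 * t2 * omega * beta[1]
        + t3 * ((1.0 - cum[t3]) + 0.25 * omega * beta[2])
    )


def intermodes_oracle(counts, max_iter=10_000):
    """Run the stated smoothing loop with its own peak finder."""
    h = [float(c) for c in counts]

    def modes(hh):
        out = []
        if hh[0] > hh[1]:
            out.append(0)
        out += [k for k in range(1, 255) if hh[k - 1] < hh[k] > hh[k + 1]]
        if hh[255] > hh[254]:
            out.append(255)
        return out

    for _ in range(max_iter + 1):
        m = modes(h)
        if len(m) == 2:
            return (m[0] + m[1]) // 2
        h = [(h[max(i - 1, 0)] + h[i] + h[min(i + 1, 255)]) / 3.0 for i in range(256)]
    return None


def random_lobe_histogram(rng):
    """Mixture of 1-3 discrete Gaussian-shaped lobes plus sparse noise."""
    counts = np.zeros(256, dtype=np.int64)
    for _ in range(rng.integers(1, 4)):
        center = rng.integers(5, 251)
        sigma = rng.uniform(2, 25)
        mass = rng.integers(50, 5000)
        samples = np.clip(np.round(rng.normal(center, sigma, mass)), 0, 255).astype(int)
        counts += np.bincount(samples, minlength=256)
    noise = rng.integers(0, 3, 256)
    return IntensityHistogram(counts + noise)


def flood_fill_label_oracle(mask, connectivity=8):
    """Independent BFS connected-component labeling."""
    mask = np.asarray(mask, dtype=bool)
    if connectivity == 8:
        nbrs = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    labels = np.zeros(mask.shape, dtype=int)
    n = 0
    for r in range(mask.shape[0]):
        for c in range(mask.shape[1]):
            if mask[r, c] and labels[r, c] == 0:
                n += 1
                queue = deque([(r, c)])
                labels[r, c] = n
                while queue:
                    y, x = queue.popleft()
                    for dr, dc in nbrs:
                        yy, xx = y + dr, x + dc
                        if (0 <= yy < mask.shape[0] and 0 <= xx < mask.shape[1]
                                and mask[yy, xx] and labels[yy, xx] == 0):
                            labels[yy, xx] = n
                            queue.append((yy, xx))
    return labels, n
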