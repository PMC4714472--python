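"""Independent brute-force oracles used by the test suite only."""

import numpy as np


def average_ranks(values):
    """Average ranks with midrank ties, by explicit enumeration."""
    values = list(values)
    ranks = []
    for v in values:
        smaller = sum(1 for u in values if u < v)
        equal = sum(1 for u in values if u == v)
        # positions smaller+1 .. smaller+equal, averaged
        ranks.append(smaller + (equal + 1) / 2.0)
    return np.array(ranks)


def rank_pearson(x, y):
    """Spearman's rho as the Pearson correlation of average-rank vectors."""
    rx = average_ranks(x)
    ry = average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def brute_force_pairs(mask, spacing, r_max):
    """All unordered in-mask voxel pairs with 0 < d <= r_max, by O(M^2) loop."""
    coords = np.argwhere(mask)
    spacing = np.asarray(spacing, dtype=float)
    pairs = []
    for i in range(len(coords)):
        for j in range(i + 1, len(coords)):
            d = np.linalg.norm((coords[i] - coords[j]) * spacing)
            if 0 < d <= r_max:
                pairs.append((tuple(coords[i]), tuple(coords[j]), d))
    return pairs
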