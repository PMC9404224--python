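"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def otsu_within_class_variance(values, threshold, n_bins=128):
    """Within-class variance of a bin-edge threshold, straight from the data."""
    values = np.asarray(values, dtype=float)
    counts, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    low = centers < threshold
    out = []
    for sel in (low, ~low):
        w, c = counts[sel], centers[sel]
        if w.sum() == 0:
            return np.inf
        m = (w * c).sum() / w.sum()
        out.append((w.sum(), (w * (c - m) ** 2).sum() / w.sum()))
    (n0, v0), (n1, v1) = out
    return (n0 * v0 + n1 * v1) / counts.sum()


def otsu_brute_force_min(values, n_bins=128):
    """Minimal within-class variance over every interior bin-edge threshold."""
    values = np.asarray(values, dtype=float)
    _, edges = np.histogram(values, bins=n_bins, range=(values.min(), values.max()))
    return min(otsu_within_class_variance(values, t, n_bins) for t in edges[1:-1])
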