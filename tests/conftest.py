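"""Shared fixtures and brute-force reference implementations.

The reference implementations are deliberately naive (pure-python loops,
O(N^2)) and independent of the package's vectorized code paths; they serve
as oracles on small instances.
"""

from __future__ import annotations

import numpy as np
import pytest


def brute_min_image_dist(a, b, box):
    d = np.asarray(b) - np.asarray(a)
    d = d - box * np.round(d / box)
    return float(np.sqrt((d**2).sum()))


def brute_rdf(pos_i, pos_j, box, dr, r_max, like):
    """All-pairs histogram RDF with the package's stated conventions:
    half-open bins, minimum image, N_j/V normalization, self-exclusion."""
    n_bins = int(np.floor(r_max / dr + 1e-9))
    counts = np.zeros(n_bins)
    for a in range(len(pos_i)):
        for b in range(len(pos_j)):
            if like and a == b:
                continue
            d = brute_min_image_dist(pos_i[a], pos_j[b], box)
            k = int(d // dr)
            if k < n_bins and d < r_max:
                counts[k] += 1
    vol = float(np.prod(box))
    edges = dr * np.arange(n_bins + 1)
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = len(pos_i) * len(pos_j) / vol * shell
    return counts / ideal


def brute_excess_counts(pos_i, pos_j, box, r_grid, like):
    rho = len(pos_j) / float(np.prod(box))
    out = np.zeros(len(r_grid))
    for k, r in enumerate(r_grid):
        total = 0
        for a in range(len(pos_i)):
            for b in range(len(pos_j)):
                if like and a == b:
                    continue
                if brute_min_image_dist(pos_i[a], pos_j[b], box) < r:
                    total += 1
        out[k] = total / len(pos_i) - rho * 4.0 / 3.0 * np.pi * r**3
    return out


def brute_hbond_count(donors, hydrogens, acceptors, box, d_max, angle_max):
    """Strict geometric hydrogen-bond count, donor-vertex convention."""
    n = 0
    for k in range(len(donors)):
        for a in range(len(acceptors)):
            dv = acceptors[a] - donors[k]
            dv = dv - box * np.round(dv / box)
            d = np.linalg.norm(dv)
            if np.allclose(acceptors[a], donors[k]):
                continue
            hv = hydrogens[k] - donors[k]
            hv = hv - box * np.round(hv / box)
            cosang = hv.dot(dv) / (np.linalg.norm(hv) * d)
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if d < d_max and ang < angle_max:
                n += 1
    return n


@pytest.fixture
def rng():
    return np.random.default_rng(20260901)
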