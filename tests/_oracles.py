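"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (BFS flood fill, explicit risk-set
enumeration, all-pairs scans) and shares no code with the package paths it
checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def neighbor_offsets(connectivity: int) -> list[tuple[int, int, int]]:
    offsets = []
    for d in itertools.product((-1, 0, 1), repeat=3):
        if d == (0, 0, 0):
            continue
        n_nonzero = sum(1 for x in d if x)
        if connectivity == 6 and n_nonzero == 1:
            offsets.append(d)
        elif connectivity == 18 and n_nonzero <= 2:
            offsets.append(d)
        elif connectivity == 26:
            offsets.append(d)
    return offsets


def flood_fill_components(hot: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components of a boolean grid by BFS, as voxel-tuple sets."""
    offsets = neighbor_offsets(connectivity)
    shape = hot.shape
    remaining = {tuple(v) for v in np.argwhere(hot)}
    components = []
    while remaining:
        seed = remaining.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            x, y, z = frontier.pop()
            for dx, dy, dz in offsets:
                nb = (x + dx, y + dy, z + dz)
                if nb in remaining:
                    remaining.discard(nb)
                    comp.add(nb)
                    frontier.append(nb)
        components.append(frozenset(comp))
    return components


def cox_loglik_enumerated(beta: float, x: np.ndarray, time: np.ndarray,
                          event: np.ndarray) -> float:
    """Cox partial log-likelihood with explicit risk sets (distinct times,
    single covariate)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = time >= time[i]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def logrank_chi2_enumerated(time: np.ndarray, event: np.ndarray,
                            group: np.ndarray) -> float:
    """Two-group log-rank chi-square by direct enumeration of event times."""
    labels = np.unique(group)
    assert labels.size == 2
    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(time[event == 1]):
        at_risk = time >= t
        n = float(at_risk.sum())
        n1 = float((at_risk & (group == labels[0])).sum())
        d = float(((time == t) & (event == 1)).sum())
        d1 = float(((time == t) & (event == 1) & (group == labels[0])).sum())
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return obs_minus_exp ** 2 / var


def km_survival_product(time: np.ndarray, event: np.ndarray) -> float:
    """Kaplan-Meier survival at the largest event time, closed form
    prod(1 - d_i / n_i)."""
    surv = 1.0
    for t in np.unique(time[event == 1]):
        n_at_risk = float((time >= t).sum())
        d = float(((time == t) & (event == 1)).sum())
        surv *= 1.0 - d / n_at_risk
    return surv


def dmax_all_pairs(lesion_voxels: list[np.ndarray], spacing,
                   mode: str) -> float:
    """Maximum inter-lesion distance (mm) over all pairs, brute force."""
    spacing = np.asarray(spacing, dtype=float)
    best = 0.0
    for a, b in itertools.combinations(lesion_voxels, 2):
        if mode == "centroid":
            ca = (a * spacing).mean(axis=0)
            cb = (b * spacing).mean(axis=0)
            best = max(best, float(np.linalg.norm(ca - cb)))
        else:
            for va in a:
                d = np.linalg.norm(b * spacing - va * spacing, axis=1).max()
                best = max(best, float(d))
    return best


def youden_exhaustive(values: np.ndarray, labels: np.ndarray):
    """Best Youden J over every midpoint cutoff, brute force."""
    pos, neg = values[labels == 1], values[labels == 0]
    distinct = np.unique(values)
    best = (-np.inf, None)
    for cut in (distinct[:-1] + distinct[1:]) / 2.0:
        j = np.mean(pos > cut) + np.mean(neg <= cut) - 1.0
        if j > best[0] + 1e-12:
            best = (j, cut)
    return best
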