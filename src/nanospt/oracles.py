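"""Small brute-force reference implementations.

Deliberately naive, enumeration-based routines used to compute expected
values for fixtures and to cross-check the production code paths in the test
suite.  They share no code with the modules they check.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def brute_force_msd(frames, xy, dt_s, lag_frames: int) -> tuple[float, int]:
    """Mean squared displacement at one lag by explicit pair enumeration."""
    frames = np.asarray(frames)
    xy = np.asarray(xy, dtype=float)
    vals = []
    for i in range(len(frames)):
        for j in range(len(frames)):
            if frames[j] - frames[i] == lag_frames:
                vals.append(float(np.sum((xy[j] - xy[i]) ** 2)))
    if not vals:
        return float("nan"), 0
    return float(np.mean(vals)), len(vals)


def exhaustive_linking(frame_locs: list[np.ndarray], max_disp: float
                       ) -> list[list[tuple[int, int]]]:
    """Minimal-total-displacement frame-to-frame assignment by enumeration.

    ``frame_locs[f]`` is the (n_f, 2) array of positions in frame f.  For
    each consecutive frame pair, all injective assignments respecting
    ``max_disp`` are enumerated and the one with the smallest summed
    displacement is kept.  Returns, per frame transition, the list of
    (index_in_f, index_in_f+1) links.  Exponential; only for tiny instances.
    """
    links_per_transition = []
    for f in range(len(frame_locs) - 1):
        a, b = frame_locs[f], frame_locs[f + 1]
        best, best_cost = [], float("inf")
        nb = len(b)
        for k in range(min(len(a), nb), -1, -1):
            # choose k sources and an ordered k-subset of targets
            for src in combinations(range(len(a)), k):
                for dst in permutations(range(nb), k):
                    d = [float(np.hypot(*(a[s] - b[t])))
                         for s, t in zip(src, dst)]
                    if any(x > max_disp for x in d):
                        continue
                    cost = sum(d)
                    if len(src) > len(best) or (len(src) == len(best)
                                                and cost < best_cost):
                        best, best_cost = list(zip(src, dst)), cost
            if best:
                break
        links_per_transition.append(best)
    return links_per_transition


def brute_force_components(xy: np.ndarray, pairs: np.ndarray,
                           seed_mask: np.ndarray) -> list[frozenset[int]]:
    """Connected components of seed points by repeated flood fill."""
    adj: dict[int, set[int]] = {}
    seeds = set(np.flatnonzero(seed_mask).tolist())
    for i, j in pairs:
        if i in seeds and j in seeds:
            adj.setdefault(int(i), set()).add(int(j))
            adj.setdefault(int(j), set()).add(int(i))
    comps = []
    unseen = set(seeds)
    while unseen:
        start = unseen.pop()
        comp = {start}
        frontier = [start]
        while frontier:
            node = frontier.pop()
            for nb in adj.get(node, ()):
                if nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        unseen -= comp
        comps.append(frozenset(comp))
    return comps


def nn_distance_median(xy: np.ndarray) -> float:
    """Median nearest-neighbour distance by the quadratic scan."""
    xy = np.asarray(xy, dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return float(np.median(d.min(axis=1)))


def permutation_test_p(a, b, n_perm: int = 100_000, seed: int = 0) -> float:
    """Two-sided permutation p-value for a difference in means."""
    rng = np.random.default_rng(seed)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    pooled = np.concatenate([a, b])
    obs = abs(a.mean() - b.mean())
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        diff = abs(pooled[:len(a)].mean() - pooled[len(a):].mean())
        if diff >= obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)
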