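"""Independent reference implementations used only by the tests.

Each oracle is deliberately written in the most naive correct way
(explicit loops, recursion-free flood fill, closed forms) so it shares
no code path with the package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_pulses(cn, threshold: float = 0.20, mode: str = "smaller") -> list[int]:
    """Naive pulse caller: walk out from each strict local maximum to its
    nearest flanking troughs (series endpoints count as troughs) and call
    a pulse when the peak exceeds the reference trough by ``threshold``.

    Plateaus are represented by their first frame, matching the stated
    tie-break.
    """
    cn = list(cn)
    n = len(cn)
    called = []
    i = 1
    while i < n - 1:
        # candidate: strictly rises into i, strictly falls after any plateau
        if not cn[i] > cn[i - 1]:
            i += 1
            continue
        j = i
        while j + 1 < n and cn[j + 1] == cn[i]:
            j += 1
        if j + 1 >= n or not cn[j + 1] < cn[i]:
            i = j + 1
            continue
        # walk left to the nearest trough (or the series start)
        a = i
        while a > 0 and cn[a - 1] <= cn[a]:
            a -= 1
        # walk right from the plateau end to the nearest trough (or end)
        b = j
        while b < n - 1 and cn[b + 1] <= cn[b]:
            b += 1
        m_left, m_right = cn[a], cn[b]
        ref = min(m_left, m_right) if mode == "smaller" else max(m_left, m_right)
        if cn[i] >= (1.0 + threshold) * ref:
            called.append(i)
        i = j + 1
    return called


def flood_fill_components(mask: np.ndarray, connectivity: int) -> list[frozenset]:
    """Connected components of an nD boolean mask via explicit BFS.

    ``connectivity`` counts neighbours: 6/26 in 3D, 4/8 in 2D (faces only
    vs full neighbourhood).
    """
    mask = np.asarray(mask, dtype=bool)
    ndim = mask.ndim
    full = {3: 26, 2: 8}[ndim]
    if connectivity == full:
        offsets = [
            off for off in np.ndindex(*([3] * ndim))
            if any(o != 1 for o in off)
        ]
        offsets = [tuple(o - 1 for o in off) for off in offsets]
    else:
        offsets = []
        for ax in range(ndim):
            for s in (-1, 1):
                off = [0] * ndim
                off[ax] = s
                offsets.append(tuple(off))
    seen = np.zeros(mask.shape, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        queue = [start]
        seen[start] = True
        comp = set()
        while queue:
            p = queue.pop()
            comp.add(p)
            for off in offsets:
                q = tuple(pi + oi for pi, oi in zip(p, off))
                if all(0 <= qi < si for qi, si in zip(q, mask.shape)) \
                        and mask[q] and not seen[q]:
                    seen[q] = True
                    queue.append(q)
        comps.append(frozenset(comp))
    return comps


def otsu_exhaustive(values: np.ndarray) -> int:
    """Exhaustive-search Otsu: the integer threshold minimizing the
    weighted intra-class variance of ``values > t`` vs ``values <= t``."""
    values = np.asarray(values).ravel()
    best_t, best_var = None, math.inf
    for t in range(int(values.min()), int(values.max())):
        lo, hi = values[values <= t], values[values > t]
        if len(lo) == 0 or len(hi) == 0:
            continue
        var = len(lo) * lo.var() + len(hi) * hi.var()
        if var < best_var:
            best_var, best_t = var, t
    return best_t


def transient_auc_closed_form(
    baseline_cn: float,
    response_peak: float,
    decay_halflife_min: float,
    frame_interval_min: float,
    stim_frame: int,
    n_frames: int,
    window: tuple[float, float],
    baseline_halfwidth_min: float = 10.0,
) -> float:
    """Closed-form AUC of a sampled exponential step-decay trajectory.

    The trajectory is ``b`` before the stimulus and ``b + A r^k`` at the
    k-th post-stimulus frame with ``r = 2^(-dt/h)``.  The baseline is the
    mean over frames within ``baseline_halfwidth_min`` of the stimulus,
    and the AUC the sum of baseline-subtracted values over frames with
    stimulus-relative time in ``(lo, hi]`` — all expressed via geometric
    sums.
    """
    dt = frame_interval_min
    r = 2.0 ** (-dt / decay_halflife_min)
    A, b = response_peak, baseline_cn
    k_bl = int(math.floor(baseline_halfwidth_min / dt))
    lo_f = max(stim_frame - k_bl, 0)
    hi_f = min(stim_frame + k_bl, n_frames - 1)
    n_win = hi_f - lo_f + 1
    n_post = hi_f - stim_frame + 1  # post-stim frames inside the window (incl. k=0)
    geom = (1.0 - r ** n_post) / (1.0 - r)
    baseline = b + A * geom / n_win
    lo, hi = window
    k_min = int(math.floor(lo / dt)) + 1
    while (k_min * dt) <= lo:
        k_min += 1
    k_max = int(math.floor(hi / dt))
    k_max = min(k_max, n_frames - 1 - stim_frame)
    if k_max < k_min:
        raise ValueError("empty window")
    m = k_max - k_min + 1
    geom_win = r ** k_min * (1.0 - r ** m) / (1.0 - r)
    return A * geom_win + m * (b - baseline)


def thinned_pulse_count_mean(
    rate_per_hr: float,
    n_frames: int,
    frame_interval_min: float,
    min_gap_frames: int,
    margin_frames: int,
    n_draws: int,
    seed: int,
) -> float:
    """Monte-Carlo expectation of the dead-time-thinned pulse count.

    Simulates the generating process naively: Poisson number of events,
    uniform times, rounding to frames, rejection of frames within
    ``margin_frames`` of the ends, left-to-right thinning with the
    minimum gap.
    """
    rng = np.random.default_rng(seed)
    duration = n_frames * frame_interval_min
    lam = rate_per_hr * duration / 60.0
    total = 0
    for _ in range(n_draws):
        times = sorted(rng.uniform(0.0, duration, size=rng.poisson(lam)))
        last = -10 * min_gap_frames
        count = 0
        for t in times:
            f = min(int(round(t / frame_interval_min)), n_frames - 1)
            if f < margin_frames or f > n_frames - 1 - margin_frames:
                continue
            if f - last >= min_gap_frames:
                count += 1
                last = f
        total += count
    return total / n_draws
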