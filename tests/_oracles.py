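"""Independent brute-force re-implementations used to cross-check the
production code on random instances.  Deliberately naive: plain loops,
re-deriving every decision from the written rules rather than calling the
package."""

import numpy as np

FRACTION = 0.4


def brute_force_match(m, n):
    """Naive re-derivation of the one-to-one peak pairing.

    Returns (m_valid, n_valid, decisions) where decisions[j] is
    ("matched", ni) or ("discarded", reason) for every ECG peak index j.
    """
    m = list(map(float, m))
    n = list(map(float, n))
    m_valid, n_valid, decisions = [], [], []
    used = []
    for j, mj in enumerate(m):
        if j == 0:
            lo, hi = 0.0, m[0] + FRACTION * (m[1] - m[0])
        elif j < len(m) - 1:
            lo = mj - FRACTION * (mj - m[j - 1])
            hi = mj + FRACTION * (m[j + 1] - mj)
        else:
            lo, hi = mj - FRACTION * (mj - m[j - 1]), mj
        candidates = [(abs(mj - ni), k, ni) for k, ni in enumerate(n)
                      if lo <= ni <= hi]
        if not candidates:
            decisions.append(("discarded", "empty interval"))
            continue
        candidates.sort()  # nearest first; index breaks ties toward earlier
        _, k, ni = candidates[0]
        if k in used:
            decisions.append(("discarded", "candidate already selected"))
            continue
        used.append(k)
        m_valid.append(mj)
        n_valid.append(ni)
        decisions.append(("matched", ni))
    return m_valid, n_valid, decisions


def brute_force_select_ibis(all_ecg, m_valid, n_valid):
    """Naive false-interval exclusion: keep a consecutive pair only if no
    originally detected R peak strictly inside it was discarded."""
    kept_ecg, kept_sv, kept_idx = [], [], []
    for i in range(len(m_valid) - 1):
        a, b = m_valid[i], m_valid[i + 1]
        spans_discarded = any(a < p < b and p not in m_valid for p in all_ecg)
        if not spans_discarded:
            kept_ecg.append(b - a)
            kept_sv.append(n_valid[i + 1] - n_valid[i])
            kept_idx.append(i)
    return kept_ecg, kept_sv, kept_idx


def brute_force_translation(ref, mov):
    """Integer translation by exhaustive circular cross-correlation."""
    ref = ref - ref.mean()
    mov = mov - mov.mean()
    best, best_shift = -np.inf, (0, 0)
    nr, nc = ref.shape
    for dy in range(nr):
        for dx in range(nc):
            c = np.sum(ref * np.roll(mov, (-dy, -dx), axis=(0, 1)))
            if c > best:
                best, best_shift = c, (dx, dy)
    dx, dy = best_shift
    if dx > nc // 2:
        dx -= nc
    if dy > nr // 2:
        dy -= nr
    return dx, dy


def random_peak_instance(rng, n_beats=40, drop=0.1, clutter=0.1, jitter=0.05):
    """A random ECG/SV peak-list pair: jittered copies with dropouts and
    clutter, as a matcher stress instance."""
    m = np.cumsum(rng.uniform(0.5, 1.5, n_beats))
    keep = rng.random(n_beats) > drop
    n = m[keep] + rng.normal(0.0, jitter, int(keep.sum()))
    extra = rng.uniform(m[0], m[-1], rng.poisson(clutter * n_beats))
    n = np.unique(np.concatenate([n, extra]))
    return m, n
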