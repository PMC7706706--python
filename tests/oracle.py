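"""Brute-force reference implementations used only to cross-check the
vectorized pipeline.  Deliberately naive: per-base scans, iterated
pairwise merging, direct windowed sums."""

import numpy as np


def oracle_hann_smooth(values: np.ndarray, window_bp: int) -> np.ndarray:
    """Direct windowed weighted average with edge renormalization,
    via explicit per-position slices (no convolution)."""
    k = np.arange(window_bp)
    w = 0.5 * (1.0 - np.cos(2.0 * np.pi * k / (window_bp - 1)))
    w = w / w.sum()
    half = (window_bp - 1) // 2
    n = values.size
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        ww = w[lo - (i - half) : window_bp - ((i + half + 1) - hi)]
        out[i] = float(values[lo:hi] @ ww) / float(ww.sum())
    return out


def oracle_call(raw, smoothed, threshold, merge_gap, min_width, min_total):
    """Scan every base, label runs, merge by repeated pairwise gap test
    until fixed point, filter.  Returns [(start, end, total)] 1-based."""
    runs = []
    cur = None
    for i in range(len(smoothed)):
        if smoothed[i] > threshold:
            if cur is None:
                cur = [i, i]
            else:
                cur[1] = i
        else:
            if cur is not None:
                runs.append(cur)
                cur = None
    if cur is not None:
        runs.append(cur)

    changed = True
    while changed:
        changed = False
        for j in range(len(runs) - 1):
            if runs[j + 1][0] - runs[j][1] - 1 <= merge_gap:
                runs[j] = [runs[j][0], runs[j + 1][1]]
                del runs[j + 1]
                changed = True
                break

    out = []
    for s, e in runs:
        width = e - s + 1
        total = float(sum(raw[s : e + 1]))
        if width >= min_width and total >= min_total:
            out.append((s + 1, e + 1, total))
    return out
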