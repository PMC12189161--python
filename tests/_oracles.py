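"""Independent window-walk oracle shared by unit and acceptance tests.

Plain-Python re-implementation of the frozen scan semantics; shares no code
with the production scanner.
"""

import statistics


def oracle_window_walk(depth, params, baseline):
    """Literal re-implementation of the frozen scan semantics."""
    depth = list(depth)
    L, w, step, run = len(depth), params.window, params.step, params.run_length
    if L < w:
        return []
    n_windows = (L - w) // step + 1

    def window_bases(idx):
        return depth[idx * step: idx * step + w]

    def seg_bases(w_first, w_last):
        return depth[w_first * step: w_last * step + w]

    peaks = []
    i = 0
    while i + run <= n_windows:
        start_fold_ok = all(
            sum(window_bases(j)) / w > params.start_fold * baseline
            for j in range(i, i + run)
        )
        start_median_ok = (
            statistics.median(seg_bases(i, i + run - 1)) > params.median_start
        )
        if not (start_fold_ok or start_median_ok):
            i += 1
            continue
        j = i + run
        running_max = max(seg_bases(i, j - 1))
        terminated = False
        while j < n_windows:
            running_max = max(running_max, max(window_bases(j)))
            trailing = seg_bases(j - run + 1, j)
            if sum(trailing) / len(trailing) < params.stop_fraction * running_max:
                terminated = True
                break
            j += 1
        last_w = (j - run) if terminated else (n_windows - 1)
        body = seg_bases(i, last_w)
        peaks.append(
            {
                "start": i * step,
                "end": last_w * step + w,
                "max": max(body),
                "median": statistics.median(body),
            }
        )
        i = j + 1 if terminated else n_windows
    return peaks
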