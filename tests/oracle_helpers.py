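"""Independent brute-force oracles shared by the test modules."""

import numpy as np


def brute_force_metric(data, row_valid, column, v, half_window, min_rows):
    """Explicit-loop morph-and-std metric for one column and candidate.

    Mirrors the estimator's definition — shift the column at window
    offset δ by round(v·δ), keep rows fully valid across the window,
    average the per-row standard deviation — with none of its
    vectorisation.
    """
    n_rows, n_cols = data.shape
    offsets = [d for d in range(-half_window, half_window + 1)
               if 0 <= column + d < n_cols]
    rows = []
    for r in range(n_rows):
        vals = []
        ok = True
        for d in offsets:
            s = int(round(v * d))
            if not (0 <= r + s < n_rows) or not row_valid[r + s]:
                ok = False
                break
            vals.append(data[r + s, column + d])
        if ok:
            rows.append(np.std(vals))
    if len(rows) < min_rows:
        return np.nan
    return float(np.mean(rows))
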