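"""Independent reference implementations used as test oracles.

These are deliberately naive (flood fill, explicit enumeration) and share
no code with the package's implementations.
"""

from itertools import product

import numpy as np


def flood_fill_clusters(values, threshold):
    """Suprathreshold 4-connected clusters by breadth-first flood fill.

    Returns a list of (frozenset of (i, j) coords, summed value, sign),
    positive and negative excursions clustered separately.
    """
    values = np.nan_to_num(np.asarray(values, dtype=float), nan=0.0)
    nrow, ncol = values.shape
    out = []
    for sign in (1, -1):
        supra = (sign * values) > threshold
        seen = np.zeros_like(supra, dtype=bool)
        for i in range(nrow):
            for j in range(ncol):
                if not supra[i, j] or seen[i, j]:
                    continue
                stack, members = [(i, j)], []
                seen[i, j] = True
                while stack:
                    a, b = stack.pop()
                    members.append((a, b))
                    for da, db in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                        na, nb = a + da, b + db
                        if (0 <= na < nrow and 0 <= nb < ncol
                                and supra[na, nb] and not seen[na, nb]):
                            seen[na, nb] = True
                            stack.append((na, nb))
                total = float(sum(values[a, b] for a, b in members))
                out.append((frozenset(members), total, sign))
    return out


def enumerate_signflip_null(diffs, threshold):
    """Max-cluster null over all 2**n subject sign patterns, by brute force.

    ``diffs`` is (n_subjects, nrow, ncol); the statistic per pattern is the
    largest absolute summed-t of any flood-fill cluster of the one-sample
    t map of the sign-flipped differences.
    """
    diffs = np.asarray(diffs, dtype=float)
    n = diffs.shape[0]
    stats = []
    for pattern in product((1.0, -1.0), repeat=n):
        flipped = diffs * np.asarray(pattern)[:, None, None]
        mean = flipped.mean(axis=0)
        sd = flipped.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = np.where(sd > 0, mean / (sd / np.sqrt(n)), 0.0)
        clusters = flood_fill_clusters(t, threshold)
        stats.append(max((abs(c[1]) for c in clusters), default=0.0))
    return np.array(stats)


def trapezoid_auci(times, conc):
    """Hand trapezoid AUCi: sum of panel areas minus baseline rectangle."""
    area = 0.0
    for k in range(len(times) - 1):
        area += (conc[k] + conc[k + 1]) / 2.0 * (times[k + 1] - times[k])
    return area - conc[0] * (times[-1] - times[0])
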