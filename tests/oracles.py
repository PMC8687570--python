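"""Independent reference computations used only by the test suite.

Each oracle recomputes a quantity by a different route than the package:
exhaustive enumeration for event matching, explicit sums of squares for the
ICC mean-squares decomposition, and the closed-form magnitude response of a
bilinear-transform Butterworth for the filter contract.
"""

import itertools

import numpy as np


def exhaustive_min_pairing_cost(pose, manual):
    """Minimum summed |dt| over all order-preserving complete pairings.

    Enumerates every way to discard surplus events from the longer series,
    pairs the remainder index-wise, and returns the cheapest total.
    """
    pose, manual = np.asarray(pose, float), np.asarray(manual, float)
    short, lng = (pose, manual) if len(pose) <= len(manual) else (manual, pose)
    return min(
        float(np.abs(lng[list(keep)] - short).sum())
        for keep in itertools.combinations(range(len(lng)), len(short))
    )


def icc_sums_of_squares(table):
    """ICC(C,1) and ICC(A,1) from first-principles sums of squares.

    Explicit elementwise loops over the two-way ANOVA decomposition of an
    n x k table with one observation per cell.
    """
    table = np.asarray(table, float)
    n, k = table.shape
    grand = sum(table[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_mean = [sum(table[i, j] for j in range(k)) / k for i in range(n)]
    col_mean = [sum(table[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_mean)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_mean)
    ss_tot = sum(
        (table[i, j] - grand) ** 2 for i in range(n) for j in range(k)
    )
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc_c = (msr - mse) / (msr + (k - 1) * mse)
    icc_a = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    return icc_c, icc_a


def digital_butter_gain(f, cutoff, fs, order, passes=2):
    """Closed-form magnitude of a bilinear-transform Butterworth low-pass.

    |H(f)|^passes with the prewarped frequency ratio
    tan(pi f / fs) / tan(pi cutoff / fs).
    """
    ratio = np.tan(np.pi * f / fs) / np.tan(np.pi * cutoff / fs)
    return float((1.0 / np.sqrt(1.0 + ratio ** (2 * order))) ** passes)


def match_case(rng, max_core=6):
    """One realistic matching scenario: jittered common events + boundary extras.

    Both methods observe the same metronome-paced core events with small
    timing jitter; one method additionally reports up to two surplus events
    before and/or after the trial (the boundary-extra situation event
    matching exists to resolve).
    """
    period = rng.uniform(0.25, 1.0)
    n_core = int(rng.integers(2, max_core + 1))
    core = rng.uniform(0, 0.5) + np.arange(n_core) * period
    manual = np.sort(core + rng.normal(0, 0.04 * period, n_core))
    pose = np.sort(core + rng.normal(0, 0.04 * period, n_core))
    extras = []
    for i in range(int(rng.integers(0, 3))):
        extras.append(core[0] - (i + 1) * period + rng.normal(0, 0.04 * period))
    for i in range(int(rng.integers(0, 3))):
        extras.append(core[-1] + (i + 1) * period + rng.normal(0, 0.04 * period))
    if rng.random() < 0.5:
        pose = np.sort(np.r_[pose, extras])
    else:
        manual = np.sort(np.r_[manual, extras])
    return pose, manual
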