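"""Independent brute-force oracles used only by the tests."""

import numpy as np


def grid_episode(times, temps, threshold=38.0, step=0.001):
    """Dense-grid brute-force onset/offset oracle.

    Evaluates the linear interpolant on a regular grid and takes the first
    and last febrile grid points; agrees with exact crossing inversion to
    within one grid step. Returns ``(onset, offset, censored)`` or ``None``.
    """
    times = np.asarray(times, float)
    temps = np.asarray(temps, float)
    # include the reading instants so that curves touching the threshold
    # exactly at a reading are seen by the scan
    grid = np.union1d(np.arange(times[0], times[-1] + step / 2, step), times)
    vals = np.interp(grid, times, temps)
    febrile = vals >= threshold
    if not febrile.any() or temps[-1] >= threshold:
        return None
    censored = temps[0] >= threshold
    onset = times[0] if censored else float(grid[np.argmax(febrile)])
    last = len(febrile) - 1 - int(np.argmax(febrile[::-1]))
    offset = float(grid[last])
    return onset, offset, censored


def random_reading_set(rng, threshold=38.0):
    """Random windowed reading set: sorted distinct times, plausible temps."""
    k = int(rng.integers(5, 15))
    times = np.sort(rng.uniform(0.5, 48.0, k))
    while np.any(np.diff(times) < 1e-3):
        times = np.sort(rng.uniform(0.5, 48.0, k))
    temps = np.round(rng.uniform(36.5, 39.5, k), 2)
    return times, temps
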