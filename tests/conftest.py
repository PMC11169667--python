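"""Shared fixtures and independently coded reference implementations.

The reference implementations here are deliberately written in a different
style from the package code (explicit nested scans, effect-decomposition
algebra) so that agreement between the two is evidence of correctness
rather than of shared bugs.
"""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np
import pytest

from vestib import GazeHeadSample


# ---------------------------------------------------------------------------
# Reference: chain assembly over signed velocity values
# ---------------------------------------------------------------------------

def reference_chains(
    values: Sequence[float],
    opposite_tolerance: int = 1,
    min_chain_len: int = 2,
) -> List[Tuple[str, Tuple[int, ...]]]:
    """Brute-force chain segmentation by explicit lookahead scanning.

    A chain starts at any nonzero sample not already consumed.  Its
    direction is the sign of its first member.  The scan extends the chain
    rightward over same-sign samples, absorbing up to ``opposite_tolerance``
    opposite-sign samples, and stops at a zero, at an opposite-sign sample
    beyond the tolerance, or at the end.  Chains with fewer than
    ``min_chain_len`` members are dropped.
    """
    signs = [0 if v == 0 else (1 if v > 0 else -1) for v in values]
    out: List[Tuple[str, Tuple[int, ...]]] = []
    i, n = 0, len(signs)
    while i < n:
        if signs[i] == 0:
            i += 1
            continue
        d = signs[i]
        members = [i]
        budget = opposite_tolerance
        j = i + 1
        while j < n:
            if signs[j] == d:
                members.append(j)
            elif signs[j] == 0:
                break
            elif budget > 0:
                members.append(j)
                budget -= 1
            else:
                break
            j += 1
        if len(members) >= min_chain_len:
            out.append(("cw" if d > 0 else "ccw", tuple(members)))
        # next chain starts at the first sample not consumed by this one
        i = members[-1] + 1
    return out


def all_sign_strings(max_len: int):
    """Every (+1, -1) string of length 1..max_len."""
    for length in range(1, max_len + 1):
        for code in range(2 ** length):
            yield [1 if (code >> b) & 1 else -1 for b in range(length)]


# ---------------------------------------------------------------------------
# Reference: ICC(2,1) by two-way effect decomposition
# ---------------------------------------------------------------------------

def reference_icc_2_1(matrix) -> float:
    """ICC(A,1) from an explicit additive-effects decomposition.

    Decomposes each cell into grand mean + subject effect + rater effect +
    residual, forms the mean squares from the effect sums of squares, and
    applies the single-measure absolute-agreement definition.
    """
    m = np.asarray(matrix, dtype=float)
    n, k = m.shape
    mu = m.mean()
    subj = m.mean(axis=1) - mu
    rater = m.mean(axis=0) - mu
    resid = m - mu - subj[:, None] - rater[None, :]
    msr = k * (subj ** 2).sum() / (n - 1)
    msc = n * (rater ** 2).sum() / (k - 1)
    mse = (resid ** 2).sum() / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


# ---------------------------------------------------------------------------
# Stream construction helpers
# ---------------------------------------------------------------------------

def make_stream(
    times: Sequence[float],
    yaw: Sequence[float] | None = None,
    pitch: Sequence[float] | None = None,
    gaze_x: Sequence[float] | float = 0.5,
    gaze_y: Sequence[float] | float = 0.5,
    valid: Sequence[bool] | bool = True,
) -> List[GazeHeadSample]:
    n = len(times)

    def col(v, default):
        if v is None:
            return [default] * n
        if np.isscalar(v):
            return [v] * n
        return list(v)

    yaw = col(yaw, 0.0)
    pitch = col(pitch, 0.0)
    gx = col(gaze_x, 0.5)
    gy = col(gaze_y, 0.5)
    va = col(valid, True)
    return [
        GazeHeadSample(
            t=float(times[i]), gaze_x=float(gx[i]), gaze_y=float(gy[i]),
            gaze_valid=bool(va[i]), head_pitch=float(pitch[i]),
            head_yaw=float(yaw[i]), head_roll=0.0,
        )
        for i in range(n)
    ]


def sine_positions(amplitude: float, freq_hz: float, rate_hz: float,
                   duration_s: float, phase_lag_s: float = 0.0):
    """(t, angle) trace of A*sin(2*pi*f*(t - lag)) sampled at rate_hz."""
    t = np.arange(int(round(duration_s * rate_hz)) + 1) / rate_hz
    th = amplitude * np.sin(2 * math.pi * freq_hz * (t - phase_lag_s))
    return list(zip(t.tolist(), th.tolist()))


@pytest.fixture
def geometry():
    from vestib import ScreenGeometry

    return ScreenGeometry()
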