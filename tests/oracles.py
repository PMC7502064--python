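"""Independent oracles used to check the package's numerics.

These implementations deliberately avoid the code paths they verify: the DFT
oracle multiplies by an explicitly constructed O(N^2) transform matrix rather
than calling an FFT, the EMA oracle is the loop-free closed form, and the
error metrics are naive Python loops.
"""

import math

import numpy as np


def dft_magnitude_oracle(x: np.ndarray) -> np.ndarray:
    """Brute-force O(N^2) DFT magnitude of a real vector, first half of bins."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    j = np.arange(n)
    matrix = np.exp(-2j * np.pi * np.outer(j[: n // 2], j) / n)
    return np.abs(matrix @ x)


def dominant_bin_oracle(x: np.ndarray, skip_dc: int = 4) -> int:
    """Index of the strongest positive-frequency bin, excluding near-DC bins."""
    mags = dft_magnitude_oracle(x)
    return int(np.argmax(mags[skip_dc:])) + skip_dc


def ema_closed_form(x0: np.ndarray, c: np.ndarray, d: float, t: int) -> np.ndarray:
    """EMA estimate after t constant-input updates: c + (1-d)^t (x0 - c)."""
    return c + (1.0 - d) ** t * (np.asarray(x0, float) - np.asarray(c, float))


def naive_mse(y_true, y_pred) -> float:
    """Two-pass summation MSE with a plain Python loop."""
    total = 0.0
    n = 0
    for a, b in zip(y_true, y_pred):
        total += (float(a) - float(b)) ** 2
        n += 1
    return total / n


def naive_mae_mN(y_true, y_pred) -> float:
    """Plain-loop mean absolute error, converted N -> mN."""
    total = 0.0
    n = 0
    for a, b in zip(y_true, y_pred):
        total += abs(float(a) - float(b))
        n += 1
    return 1000.0 * total / n


def hann_energy_oracle(n: int) -> float:
    """Direct summation of sum_i w[i]^2 for the symmetric Hann window."""
    total = 0.0
    for i in range(n):
        w = 0.5 * (1.0 - math.cos(2.0 * math.pi * i / (n - 1)))
        total += w * w
    return total
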