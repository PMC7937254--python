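"""Independent oracles used by the test suite.

These are deliberately coded from first principles, separate from the
package implementation: a closed-form expected-mean-squares ANOVA solver
for the balanced nested design, a brute-force amplitude scan, and a 1-D
smoothed-gradient edge localiser.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def ems_nested_anova(df: pd.DataFrame) -> tuple[float, float, float]:
    """Variance components (va, vb, ve) of a *balanced* nested design by
    solving the expected-mean-squares equations directly.

    E[MS_patient]  = ve + K*vb + F*K*va
    E[MS_fraction] = ve + K*vb
    E[MS_within]   = ve
    """
    pivot = df.set_index(["patient_id", "fraction", "frame"])["error_mm"]
    p_levels = df["patient_id"].nunique()
    f_levels = df["fraction"].nunique()
    k_levels = len(df) // (p_levels * f_levels)
    y = pivot.sort_index().to_numpy().reshape(p_levels, f_levels, k_levels)

    grand = y.mean()
    patient_means = y.mean(axis=(1, 2))
    cell_means = y.mean(axis=2)
    ms_a = f_levels * k_levels * np.sum((patient_means - grand) ** 2) / (p_levels - 1)
    ms_b = k_levels * np.sum((cell_means - patient_means[:, None]) ** 2) \
        / (p_levels * (f_levels - 1))
    ms_w = np.sum((y - cell_means[:, :, None]) ** 2) \
        / (p_levels * f_levels * (k_levels - 1))
    return ((ms_a - ms_b) / (f_levels * k_levels), (ms_b - ms_w) / k_levels, ms_w)


def brute_force_amplitude(position: np.ndarray) -> float:
    """Exhaustive max/min scan over all samples."""
    best_max = -np.inf
    best_min = np.inf
    for value in np.asarray(position, dtype=float):
        if value > best_max:
            best_max = value
        if value < best_min:
            best_min = value
    return best_max - best_min


def gradient_profile_argmax(frame: np.ndarray, roi, sigma: float) -> float:
    """Edge position as the argmax of the mean 1-D smoothed-gradient profile.

    Uses direct Gaussian-kernel convolution per row (no shared code with the
    2-D detector) and integer-pixel resolution.
    """
    r0, r1, c0, c1 = roi
    sub = np.asarray(frame, dtype=float)[r0:r1, c0:c1]
    half = int(np.ceil(4 * sigma))
    x = np.arange(-half, half + 1)
    kernel = np.exp(-0.5 * (x / sigma) ** 2)
    kernel /= kernel.sum()
    profile = np.zeros(sub.shape[1])
    for row in sub:
        smooth = np.convolve(np.pad(row, half, mode="edge"), kernel, mode="valid")
        profile += np.abs(np.gradient(smooth))
    return c0 + float(np.argmax(profile / sub.shape[0]))


def margin_by_hand(sigma_pt, sigma_fr, sigma_intra, n):
    """Eq-by-eq arithmetic for the effective errors and margin."""
    sys_eff = (sigma_pt**2 + sigma_fr**2 / n) ** 0.5
    rand_eff = ((1 - 1 / n) * sigma_fr**2 + sigma_intra**2) ** 0.5
    return sys_eff, rand_eff, 2.5 * sys_eff + 0.7 * rand_eff
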