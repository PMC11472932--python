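"""Numba inner loop for the trial-by-trial endpoint recursion.

The kernel is deliberately a straight transcription of the generative
equations, batched over individuals.  All randomness is drawn outside and
passed in as standard-normal deviates so the recursion is a pure function
of its inputs.
"""
import numpy as np
from numba import njit


@njit(cache=True)
def lag1_columns(mat):
    """Column-wise lag-1 pearson autocorrelation of an (n_trials, batch) matrix.

    Each lagged copy is standardized by its own mean and sum of squares;
    a constant column yields nan.
    """
    n, batch = mat.shape
    out = np.empty(batch)
    m = n - 1
    for i in range(batch):
        mean_a = 0.0
        mean_b = 0.0
        for t in range(m):
            mean_a += mat[t, i]
            mean_b += mat[t + 1, i]
        mean_a /= m
        mean_b /= m
        saa = 0.0
        sbb = 0.0
        sab = 0.0
        for t in range(m):
            da = mat[t, i] - mean_a
            db = mat[t + 1, i] - mean_b
            saa += da * da
            sbb += db * db
            sab += da * db
        denom = np.sqrt(saa * sbb)
        if denom == 0.0:
            out[i] = np.nan
        else:
            acf = sab / denom
            out[i] = min(1.0, max(-1.0, acf))
    return out


@njit(cache=True)
def simulate_paths(z, theta, half_width, half_length, r0):
    """Run the endpoint recursion for a batch of individuals.

    Parameters
    ----------
    z : float64[n_trials, 4, batch]
        Standard-normal deviates in the fixed draw order
        (motor-x, motor-y, explore-x, explore-y) for every trial.
    theta : float64[10, batch]
        Per-individual parameters in canonical order
        (sigma_M_x, sigma_M_y, sigma_E_x, sigma_E_y,
         alpha_x, alpha_y, beta_aim_x, beta_aim_y,
         beta_target_x, beta_target_y).
    half_width, half_length : float64[batch]
        Target half-extents along the minor (x) and major (y) axes.
    r0 : int8[batch]
        Success flag assumed for the trial before the first one.

    Returns
    -------
    x, y, aim_x, aim_y : float64[n_trials, batch]
    reward : int8[n_trials, batch]
    """
    n_trials = z.shape[0]
    batch = z.shape[2]
    x = np.empty((n_trials, batch))
    y = np.empty((n_trials, batch))
    aim_x_out = np.empty((n_trials, batch))
    aim_y_out = np.empty((n_trials, batch))
    reward = np.empty((n_trials, batch), dtype=np.int8)

    # trial-major loops keep the per-individual recursion sequential while
    # letting the compiler vectorize across the batch
    aim_x = np.zeros(batch)
    aim_y = np.zeros(batch)
    r_prev = np.empty(batch)
    for i in range(batch):
        r_prev[i] = r0[i]
    for t in range(n_trials):
        for i in range(batch):
            # exploratory noise only after a miss (target center at origin)
            e_x = (1.0 - r_prev[i]) * theta[2, i] * z[t, 2, i]
            e_y = (1.0 - r_prev[i]) * theta[3, i] * z[t, 3, i]
            px = aim_x[i] + theta[0, i] * z[t, 0, i] + e_x
            py = aim_y[i] + theta[1, i] * z[t, 1, i] + e_y
            r = 1.0 if (abs(px) <= half_width[i] and abs(py) <= half_length[i]) else 0.0
            aim_x_out[t, i] = aim_x[i]
            aim_y_out[t, i] = aim_y[i]
            x[t, i] = px
            y[t, i] = py
            reward[t, i] = np.int8(r)
            aim_x[i] = (
                aim_x[i] + r * theta[4, i] * e_x
                - theta[6, i] * (px - aim_x[i]) - theta[8, i] * px
            )
            aim_y[i] = (
                aim_y[i] + r * theta[5, i] * e_y
                - theta[7, i] * (py - aim_y[i]) - theta[9, i] * py
            )
            r_prev[i] = r
    return x, y, aim_x_out, aim_y_out, reward
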