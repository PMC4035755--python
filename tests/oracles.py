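"""Independent brute-force oracles used only by the test suite."""

import numpy as np


def glm_mixed_anova_oracle(table):
    """2x2 mixed ANOVA by long-format least squares with sum-to-zero
    coding and Type III model comparisons.  Returns (F_valence, F_age,
    F_interaction).  Independent of the package's reduction."""
    des = table["mean_update_desirable"].to_numpy(float)
    und = table["mean_update_undesirable"].to_numpy(float)
    n = len(table)
    y = np.concatenate([des, und])
    V = np.concatenate([np.full(n, 0.5), np.full(n, -0.5)])
    G = np.where(table["age_group"].to_numpy() == "older", 0.5, -0.5)
    G2 = np.tile(G, 2)
    S = np.zeros((2 * n, n))
    for i in range(n):
        S[i, i] = 1.0
        S[n + i, i] = 1.0

    def sse(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    X_full = np.column_stack([S, V, G2 * V])
    sse_full = sse(X_full)
    df_err = n - 2
    ms_err = sse_full / df_err
    f_int = (sse(np.column_stack([S, V])) - sse_full) / ms_err
    f_val = (sse(np.column_stack([S, G2 * V])) - sse_full) / ms_err

    m = (des + und) / 2.0
    Xb = np.column_stack([np.ones(n), G])
    beta, *_ = np.linalg.lstsq(Xb, m, rcond=None)
    sse_b = float(np.sum((m - Xb @ beta) ** 2))
    sse_0 = float(np.sum((m - m.mean()) ** 2))
    f_age = (sse_0 - sse_b) / (sse_b / (n - 2))
    return f_val, f_age, f_int


def pearson_brute(x, y):
    """Product-moment r evaluated directly from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc = x - x.mean()
    yc = y - y.mean()
    return float(np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2)))


def permutation_pearson_p(x, y, n_perm, seed):
    """Two-tailed permutation p-value for the Pearson correlation."""
    rng = np.random.default_rng(seed)
    r_obs = abs(pearson_brute(x, y))
    y = np.asarray(y, float)
    count = 0
    for _ in range(n_perm):
        if abs(pearson_brute(x, rng.permutation(y))) >= r_obs - 1e-12:
            count += 1
    return (count + 1) / (n_perm + 1)


def partial_corr_recursive(r_xy, r_xz, r_yz):
    """First-order partial correlation r_xy.z by the closed form."""
    return (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
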