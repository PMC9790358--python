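"""Independent reference implementations used only to check the package.

These deliberately use a different route than the production code: full
grid-based Bayesian filtering instead of the reduced observer, explicit
sort-based quantiles, exhaustive rank enumeration, and gradient-based least
squares.
"""

import itertools

import numpy as np


def grid_bayes_posterior(outcomes, noise_sd, hazard, n_grid=360):
    """Full Bayesian filtering of the latent mean on a discrete circular grid.

    Returns (posterior over grid after each outcome, grid positions).
    The prior is uniform; each step mixes with the uniform change-point
    distribution with probability ``hazard`` before conditioning on the
    outcome through a circular Gaussian likelihood.
    """
    grid = np.arange(n_grid) * (360.0 / n_grid)
    post = np.full(n_grid, 1.0 / n_grid)
    history = []
    for x in outcomes:
        prior = (1.0 - hazard) * post + hazard / n_grid
        d = np.abs((x - grid + 180.0) % 360.0 - 180.0)
        lik = np.exp(-0.5 * d**2 / noise_sd**2)
        post = prior * lik
        post /= post.sum()
        history.append(post.copy())
    return np.array(history), grid


def circular_mean_var(post, grid):
    """Circular mean (degrees) and linearised variance (deg^2) of a grid pmf."""
    ang = np.deg2rad(grid)
    c = np.sum(post * np.cos(ang))
    s = np.sum(post * np.sin(ang))
    mean = np.rad2deg(np.arctan2(s, c)) % 360.0
    d = (grid - mean + 180.0) % 360.0 - 180.0
    return mean, float(np.sum(post * d**2))


def running_circular_mean(outcomes):
    """Incremental circular mean of a sequence of angles (degrees)."""
    ang = np.deg2rad(np.asarray(outcomes, float))
    c, s = np.cumsum(np.cos(ang)), np.cumsum(np.sin(ang))
    return np.rad2deg(np.arctan2(s, c)) % 360.0


def percentile_sort_interpolate(values, q):
    """Linear-interpolation percentile via explicit sorting (q in [0, 100])."""
    v = np.sort(np.asarray(values, float))
    pos = (v.size - 1) * q / 100.0
    lo, frac = int(np.floor(pos)), pos - np.floor(pos)
    if lo + 1 >= v.size:
        return v[-1]
    return v[lo] * (1 - frac) + v[lo + 1] * frac


def tertile_labels_by_sort(values):
    """Tertile labels via sort-based edges (independent of np.quantile)."""
    lo = percentile_sort_interpolate(values, 100.0 / 3.0)
    hi = percentile_sort_interpolate(values, 200.0 / 3.0)
    return np.where(values <= lo, "small", np.where(values <= hi, "medium", "large"))


def ranksum_exact_p(a, b):
    """Two-sided exact rank-sum p by enumerating all rank assignments."""
    pooled = np.concatenate([a, b])
    n1 = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    w_obs = ranks[:n1].sum()
    e_w = n1 * (len(pooled) + 1) / 2.0
    total = 0
    extreme = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        w = ranks[list(comb)].sum()
        total += 1
        if abs(w - e_w) >= abs(w_obs - e_w) - 1e-12:
            extreme += 1
    return extreme / total


def kruskal_h_by_hand(samples):
    """Kruskal-Wallis H via the explicit rank formula (no ties assumed)."""
    pooled = np.concatenate(samples)
    n = len(pooled)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start:start + len(s)]
        h += r.sum() ** 2 / len(s)
        start += len(s)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)


def ols_by_gradient(y, X, lr=None, n_iter=200000):
    """Least squares by gradient descent on the normal-equations objective."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta = np.zeros(Xd.shape[1])
    if lr is None:
        lr = 1.0 / np.linalg.eigvalsh(Xd.T @ Xd).max()
    for _ in range(n_iter):
        grad = Xd.T @ (Xd @ beta - y)
        beta -= lr * grad
        if np.max(np.abs(grad)) < 1e-12:
            break
    return beta
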