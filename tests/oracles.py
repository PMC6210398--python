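"""Independent oracles used by the test suite (and the acceptance script).

Each oracle recomputes a quantity by a route independent of the package's
implementation: a Biot-Savart + volume-current surface integral for the
sphere forward model, closed-form matrix OLS for the slope statistic, and
exhaustive enumeration for permutation p-values.
"""

from __future__ import annotations

import itertools

import numpy as np

MU0_4PI = 1e-7


def fibonacci_sphere(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the full sphere."""
    i = np.arange(n)
    z = 1 - (2 * i + 1) / n
    golden = np.pi * (3 - np.sqrt(5))
    theta = golden * i
    rho = np.sqrt(np.maximum(0, 1 - z**2))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def sphere_surface_potential(s_hat: np.ndarray, radius: float, r0: np.ndarray,
                             q: np.ndarray, sigma: float = 1.0,
                             n_terms: int = 80) -> np.ndarray:
    """Electric potential on a homogeneous conducting sphere's surface.

    Classic Legendre series for a current dipole q at r0 inside a sphere
    of the given radius; s_hat are unit surface directions.
    """
    b = np.linalg.norm(r0)
    r0h = r0 / b
    x = s_hat @ r0h                        # cos(gamma)
    sin_g = np.sqrt(np.maximum(0.0, 1 - x**2))
    t_hat = s_hat - np.outer(x, r0h)       # tangential direction toward s
    nrm = np.linalg.norm(t_hat, axis=1)
    ok = nrm > 1e-12
    t_hat[ok] /= nrm[ok][:, None]
    q_r = q @ r0h
    q_t = t_hat @ q
    V = np.zeros(len(s_hat))
    Pnm1, Pn = np.ones_like(x), x.copy()
    dPnm1, dPn = np.zeros_like(x), np.ones_like(x)
    for n in range(1, n_terms + 1):
        if n > 1:
            Pnp = ((2 * n - 1) * x * Pn - (n - 1) * Pnm1) / n
            dPnp = dPnm1 + (2 * n - 1) * Pn
            Pnm1, Pn = Pn, Pnp
            dPnm1, dPn = dPn, dPnp
        coef = (2 * n + 1) / n * b ** (n - 1) / radius ** (n + 1)
        V += coef * (n * q_r * Pn + q_t * sin_g * dPn)
    return V / (4 * np.pi * sigma)


def biot_savart_sphere_field(
    sensor_positions: np.ndarray,
    sensor_orientations: np.ndarray,
    radius: float,
    r0: np.ndarray,
    q: np.ndarray,
    n_surface: int = 40_000,
) -> np.ndarray:
    """Numerical field of a dipole in a conducting sphere.

    Primary term: point-dipole Biot-Savart.  Volume-current term:
    Geselowitz surface integral of the surface potential over the
    conductor boundary (uniform quasi-Monte-Carlo quadrature).
    """
    s_hat = fibonacci_sphere(n_surface)
    V = sphere_surface_potential(s_hat, radius, np.asarray(r0, float),
                                 np.asarray(q, float))
    dS = 4 * np.pi * radius**2 / n_surface
    sp = s_hat * radius
    out = np.empty(len(sensor_positions))
    for i, (rp, ori) in enumerate(zip(sensor_positions, sensor_orientations)):
        dp = rp - r0
        B_primary = MU0_4PI * np.cross(q, dp) / np.linalg.norm(dp) ** 3
        d = rp - sp
        dn = np.linalg.norm(d, axis=1)
        integrand = np.cross(s_hat, d) / dn[:, None] ** 3
        B_volume = -MU0_4PI * (V[:, None] * integrand).sum(axis=0) * dS
        out[i] = (B_primary + B_volume) @ ori
    return out


def ols_slope_t(y: np.ndarray, x: np.ndarray) -> float:
    """Slope t from the full matrix OLS solution (independent route)."""
    X = np.column_stack([np.ones_like(x, dtype=float), np.asarray(x, float)])
    beta, res, *_ = np.linalg.lstsq(X, np.asarray(y, float), rcond=None)
    yhat = X @ beta
    ss_res = float(((y - yhat) ** 2).sum())
    n = len(x)
    sigma2 = ss_res / (n - 2)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return float(beta[1] / np.sqrt(cov[1, 1]))


def bh_stepup_reference(pvals, q):
    """Literal step-up rule evaluated by scanning k from m down to 1."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    mask = np.zeros(m, bool)
    for k in range(m, 0, -1):
        if p[order[k - 1]] <= k * q / m:
            mask[order[:k]] = True
            break
    return mask


def distinct_labelings(labels: np.ndarray):
    """All distinct permutations of a label multiset."""
    seen = set()
    for perm in itertools.permutations(labels):
        if perm not in seen:
            seen.add(perm)
            yield np.array(perm)


def exhaustive_cluster_pvalues(values: np.ndarray, labels: np.ndarray,
                               adjacency, threshold: float):
    """Exact permutation p per observed cluster over all distinct labelings.

    p = #{labelings with max cluster mass >= |observed mass|} / #labelings.
    """
    from boundless._cluster import label_clusters, max_cluster_mass, slope_t_vec

    t_obs = slope_t_vec(values, labels)
    _, masses = label_clusters(t_obs, adjacency, threshold)
    all_max = np.array([
        max_cluster_mass(slope_t_vec(values, lab), adjacency, threshold)
        for lab in distinct_labelings(labels)
    ])
    pvals = np.array([np.mean(all_max >= abs(m)) for m in masses])
    return masses, pvals
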