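"""Independent numeric oracles used to cross-check the MPT engine.

These deliberately avoid the closed-form implementation paths: saturated
and equal-prr fits are checked against generic simplex maximization of the
multinomial log-likelihood, and the equal-difference (interaction) fit
against a dense profile grid search.
"""

import numpy as np
from scipy import optimize
from scipy.special import xlogy


def numeric_saturated_fit(counts):
    """Direct numeric maximization of the multinomial log-likelihood."""
    counts = np.asarray(counts, dtype=float)

    def neg_ll(x):
        ci, psc, prr = np.clip(x, 0.0, 1.0)
        p = np.array(
            [
                ci,
                (1 - ci) * psc,
                (1 - ci) * (1 - psc) * prr,
                (1 - ci) * (1 - psc) * (1 - prr),
            ]
        )
        return -float(np.sum(xlogy(counts, p)))

    best = None
    for x0 in ([0.5, 0.5, 0.5], [0.3, 0.6, 0.2], [0.7, 0.2, 0.8]):
        res = optimize.minimize(
            neg_ll,
            x0,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        if best is None or res.fun < best.fun:
            best = res
    return best.x


def numeric_equal_prr_fit(counts_a, counts_b):
    """Constrained 5-parameter numeric fit with a shared prr."""
    ca = np.asarray(counts_a, dtype=float)
    cb = np.asarray(counts_b, dtype=float)

    def tree_probs(ci, psc, prr):
        return np.array(
            [
                ci,
                (1 - ci) * psc,
                (1 - ci) * (1 - psc) * prr,
                (1 - ci) * (1 - psc) * (1 - prr),
            ]
        )

    def neg_ll(x):
        ci_a, psc_a, ci_b, psc_b, prr = np.clip(x, 0.0, 1.0)
        pa = tree_probs(ci_a, psc_a, prr)
        pb = tree_probs(ci_b, psc_b, prr)
        return -float(np.sum(xlogy(ca, pa)) + np.sum(xlogy(cb, pb)))

    res = optimize.minimize(
        neg_ll,
        [0.5, 0.5, 0.5, 0.5, 0.5],
        method="Nelder-Mead",
        options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 50000},
    )
    return res.x, -res.fun


def grid_equal_difference_g2(tables, coarse=1e-3, fine=1e-4):
    """Dense grid-search oracle for the equal-difference restricted fit.

    For fixed d the objective separates by pair, so each inner problem is
    a 1-D grid over the base prr; d is scanned coarsely and refined.
    """
    n3 = {k: t.n_prime_response for k, t in tables.items()}
    n4 = {k: t.n_other for k, t in tables.items()}
    p_grid = np.arange(fine, 1.0, fine)

    def profile(d):
        total = 0.0
        for rel in ("repeated", "changed"):
            pa = p_grid + d
            ok = (pa > 0) & (pa < 1)
            ll = np.full_like(p_grid, -np.inf)
            ll[ok] = (
                xlogy(n3[("IR", rel)], pa[ok])
                + xlogy(n4[("IR", rel)], 1 - pa[ok])
                + xlogy(n3[("C", rel)], p_grid[ok])
                + xlogy(n4[("C", rel)], 1 - p_grid[ok])
            )
            total += ll.max()
        return total

    d_coarse = np.arange(-0.999, 0.999, coarse)
    lls = np.array([profile(d) for d in d_coarse])
    d0 = d_coarse[np.argmax(lls)]
    d_fine = np.arange(d0 - 2 * coarse, d0 + 2 * coarse, fine)
    ll_restricted = max(profile(d) for d in d_fine)

    ll_sat = sum(
        xlogy(n3[k], n3[k] / (n3[k] + n4[k])) + xlogy(n4[k], n4[k] / (n3[k] + n4[k]))
        for k in tables
    )
    return 2.0 * (ll_sat - ll_restricted)


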