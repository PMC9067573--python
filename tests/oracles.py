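"""Independent reference implementations used only by the tests.

Deliberately written as plain scalar loops, straight from the textbook
equations, with no code shared with the package internals.
"""

import math

R_GAS = 8.314462618
Z = 10.0


def uniquac_ln_gamma_reference(r, q, U, x, T):
    """Plain-loop UNIQUAC ln gamma for n components.

    r, q: lists of geometry parameters; U: n x n symmetric energies in
    J/mol; x: mole fractions; T: Kelvin.
    """
    n = len(x)
    tau = [[math.exp(-(U[i][j] - U[j][j]) / (R_GAS * T)) for j in range(n)]
           for i in range(n)]
    sum_rx = sum(r[j] * x[j] for j in range(n))
    sum_qx = sum(q[j] * x[j] for j in range(n))
    phi = [r[i] * x[i] / sum_rx for i in range(n)]
    theta = [q[i] * x[i] / sum_qx for i in range(n)]
    l = [Z / 2.0 * (r[i] - q[i]) - (r[i] - 1.0) for i in range(n)]
    sum_xl = sum(x[j] * l[j] for j in range(n))
    out = []
    for i in range(n):
        comb = (math.log(phi[i] / x[i])
                + Z / 2.0 * q[i] * math.log(theta[i] / phi[i])
                + l[i] - phi[i] / x[i] * sum_xl)
        s_i = sum(theta[j] * tau[j][i] for j in range(n))
        third = 0.0
        for j in range(n):
            s_j = sum(theta[k] * tau[k][j] for k in range(n))
            third += theta[j] * tau[i][j] / s_j
        resid = q[i] * (1.0 - math.log(s_i) - third)
        out.append(comb + resid)
    return out


def antoine_pressure_reference(A, B, C, T):
    return 10.0 ** (A - B / (T + C))


def ideal_bubble_T_grid(P, x, antoine_list, T_lo=150.0, T_hi=700.0):
    """Grid-search bubble temperature of an ideal (gamma = 1) mixture:
    the T minimizing |sum_i x_i p_i^s(T) - P|, refined to a 0.0005 K grid.
    """

    def total(T):
        return sum(xi * antoine_pressure_reference(a.A, a.B, a.C, T)
                   for xi, a in zip(x, antoine_list))

    best = None
    step = 0.5
    lo, hi = T_lo, T_hi
    for _ in range(4):
        n_steps = int((hi - lo) / step) + 1
        grid = [lo + k * step for k in range(n_steps)]
        errs = [abs(total(t) - P) for t in grid]
        best = grid[errs.index(min(errs))]
        lo, hi = best - 2 * step, best + 2 * step
        step /= 10.0
    return best


def ideal_dew_T_grid(P, y, antoine_list, T_lo=150.0, T_hi=700.0):
    """Grid-search dew temperature of an ideal mixture: the T where
    sum_i y_i P / p_i^s(T) = 1."""

    def total(T):
        return sum(yi * P / antoine_pressure_reference(a.A, a.B, a.C, T)
                   for yi, a in zip(y, antoine_list))

    best = None
    step = 0.5
    lo, hi = T_lo, T_hi
    for _ in range(4):
        n_steps = int((hi - lo) / step) + 1
        grid = [lo + k * step for k in range(n_steps)]
        errs = [abs(total(t) - 1.0) for t in grid]
        best = grid[errs.index(min(errs))]
        lo, hi = best - 2 * step, best + 2 * step
        step /= 10.0
    return best
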