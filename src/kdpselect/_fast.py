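"""Compiled numerical kernels for the KdpD/KdpE superstructure.

The right-hand side is evaluated millions of times during a mixed-integer
search, so the scalar algebra lives in numba-jitted functions operating on
flat parameter arrays.  The public, documented surface is in
:mod:`kdpselect.kdp_model`; nothing here validates its inputs.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly by every model test
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap

# Layout of the flat continuous-context vector passed to the kernels.
# Indices 0..18 are kinetic constants, 19..20 are per-experiment context.
I_KTR, I_K, I_DNA0, I_ALPHA, I_KA, I_KZ, I_MU, I_KTL, I_KD, I_KTL2 = range(10)
I_K2, I_KM2, I_K3, I_KD2, I_KTL3, I_KHY, I_KTRANS, I_KDEG, I_KHY2 = range(10, 19)
I_KDPDP, I_S = 19, 20
NC = 21

# Layout of the integer-context vector: structure bits, exponents, strain.
J_BIN1, J_BIN2, J_BIN3, J_N1, J_N2, J_N3, J_N4, J_N5, J_WILD = range(9)
NQ = 9

N_ODE = 5  # mRNA, KdpD0, KdpE0, KdpEP, KdpFABC
N_ALG = 2  # KdpEfP, DNAf


@njit(cache=False)
def ipow(x, n):
    """x**n for small non-negative integer n, with x**0 == 1 even at x == 0."""
    out = 1.0
    for _ in range(n):
        out *= x
    return out


@njit(cache=False)
def solve_algebraic_kernel(EP, K, DNA0, alpha, Ka):
    """Solve the promoter-binding algebraic subsystem for a given total KdpEP.

    Eliminates free DNA (linear) and solves the resulting cubic in free
    phosphorylated regulator E on the bracket [0, EP] by safeguarded Newton.
    Returns (E, DNAf).
    """
    b = 1.0 + 1.0 / K
    cc = (1.0 + 1.0 / (alpha * K)) / Ka
    if EP <= 0.0:
        return 0.0, DNA0 / b
    # g(E) = (EP - E) * (b + cc*E^2) - 2*cc*DNA0*E^2 ; g(0) > 0 >= g(EP)
    lo = 0.0
    hi = EP
    E = EP * 0.5
    for _ in range(200):
        g = (EP - E) * (b + cc * E * E) - 2.0 * cc * DNA0 * E * E
        if g > 0.0:
            lo = E
        else:
            hi = E
        dg = -(b + cc * E * E) + (EP - E) * 2.0 * cc * E - 4.0 * cc * DNA0 * E
        step_ok = dg != 0.0
        if step_ok:
            En = E - g / dg
            step_ok = (En > lo) and (En < hi)
        if step_ok:
            En = E - g / dg
        else:
            En = 0.5 * (lo + hi)
        if abs(En - E) <= 1e-16 * (abs(En) + 1e-300):
            E = En
            break
        E = En
    DNAf = DNA0 / (b + cc * E * E)
    return E, DNAf


@njit(cache=False)
def rhs_kernel(y, c, q, dy):
    """Time-derivatives of the 5 differential states (stimulus pre-folded in c)."""
    m = y[0] if y[0] > 0.0 else 0.0
    D0 = y[1] if y[1] > 0.0 else 0.0
    E0 = y[2] if y[2] > 0.0 else 0.0
    EP = y[3] if y[3] > 0.0 else 0.0
    F = y[4] if y[4] > 0.0 else 0.0

    E, DNAf = solve_algebraic_kernel(EP, c[I_K], c[I_DNA0], c[I_ALPHA], c[I_KA])

    # transcription: fraction of promoter in the active states (RNAP-bound
    # free DNA and the KdpEfP2-activated ternary complex)
    trans = c[I_KTR] * (DNAf / c[I_K]) * (1.0 + E * E / (c[I_ALPHA] * c[I_KA])) / c[I_DNA0]
    dy[0] = trans - (c[I_KZ] + c[I_MU]) * m
    dy[1] = c[I_KTL] * m - (c[I_KD] + c[I_MU]) * D0
    dy[2] = c[I_KTL2] * m - (c[I_KD] + c[I_MU]) * E0

    # stimulus counteraction k3f: mutant lacks the KdpFABC feedback entirely
    k3f = c[I_K3] * c[I_S]
    if q[J_WILD] == 1:
        if q[J_BIN3] == 0:
            k3f += c[I_KHY] * ipow(F, q[J_N4])
        else:
            k3f += c[I_KHY] * ipow(F, q[J_N4]) / (ipow(F, q[J_N5]) + c[I_KHY2])
    Dfree = D0 - c[I_KDPDP]
    if Dfree < 0.0:
        Dfree = 0.0
    dy[3] = c[I_K2] * c[I_KDPDP] * (E0 - EP) - (c[I_KD] + k3f + c[I_KM2] * Dfree) * EP

    # translation / proteolysis regulation of the transport complex
    if q[J_BIN1] == 1:
        R1 = 1.0 / (ipow(F, q[J_N1]) + c[I_KTRANS])
    else:
        R1 = 1.0
    if q[J_BIN2] == 1:
        R2 = ipow(F, q[J_N2]) / (ipow(F, q[J_N3]) + c[I_KDEG])
    else:
        R2 = 1.0
    dy[4] = c[I_KTL3] * m * R1 - (c[I_KD2] * R2 + c[I_MU]) * F
    return dy


@njit(cache=False)
def jac_fd_kernel(y, c, q):
    """Central finite-difference Jacobian of rhs_kernel (for the stiff solver)."""
    n = y.shape[0]
    J = np.empty((n, n))
    d1 = np.empty(n)
    d2 = np.empty(n)
    yp = y.copy()
    for j in range(n):
        h = 1e-7 * (abs(y[j]) + 1e-9)
        yj = y[j]
        yp[j] = yj + h
        rhs_kernel(yp, c, q, d1)
        yp[j] = yj - h
        rhs_kernel(yp, c, q, d2)
        yp[j] = yj
        for i in range(n):
            J[i, j] = (d1[i] - d2[i]) / (2.0 * h)
    return J
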