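"""Compiled dynamics kernels for the built-in benchmark models.

Each ODE right-hand side has the ``f(y, t, p)`` signature expected by
``scipy.integrate.odeint``; the discrete map advances the full orbit in one
call.  All kernels are compiled with numba so that population-based
optimizers, which evaluate the dynamics tens of thousands of times per run,
stay fast on a single core.
"""

import numpy as np
from numba import njit

__all__ = [
    "nonlinear_map_orbit",
    "oscillator_rhs",
    "protease_rhs",
]


@njit(cache=False)
def nonlinear_map_orbit(x0, p, n_steps, w):
    """Iterate the two-state discrete benchmark map.

    State update (one step)::

        x1' = a*x1 + x2/(1 + x2**2) + w1
        x2' = b*x2*(1 - x2)         + w2

    ``a`` (p[0]) is a linear autoregressive gain, ``b`` (p[1]) a logistic
    growth rate; ``w`` is an (n_steps, 2) array of additive zero-mean process
    noise (pass zeros for the deterministic orbit).  Returns the
    (n_steps+1, 2) orbit and the index of the first non-finite step
    (-1 if the whole orbit is finite).
    """
    out = np.empty((n_steps + 1, 2))
    out[0, 0] = x0[0]
    out[0, 1] = x0[1]
    a = p[0]
    b = p[1]
    bad = -1
    for k in range(n_steps):
        x1 = out[k, 0]
        x2 = out[k, 1]
        n1 = a * x1 + x2 / (1.0 + x2 * x2) + w[k, 0]
        n2 = b * x2 * (1.0 - x2) + w[k, 1]
        out[k + 1, 0] = n1
        out[k + 1, 1] = n2
        if bad < 0 and (abs(n1) > 1e12 or abs(n2) > 1e12 or n1 != n1 or n2 != n2):
            bad = k + 1
            break
    return out, bad


@njit(cache=False)
def oscillator_rhs(y, t, p):
    """Two-switch transcriptional oscillator (activator/inhibitor RNAs A, B
    driving the ON-state fractions C, D of switches Sw21 and Sw12).

    Parameters (in order): K_A activation threshold [uM], n_A Hill
    coefficient, K_B inhibition threshold [uM], n_B Hill coefficient,
    k shared RNA production rate.  Time is in units of the RNA decay rate.

        dA/dt = k*C - A
        dB/dt = k*D - B
        dC/dt = 1/(1 + (B/K_B)**n_B) - C      (Sw21 switched OFF by B)
        dD/dt = (A/K_A)**n_A/(1+(A/K_A)**n_A) - D   (Sw12 switched ON by A)
    """
    KA = p[0]
    nA = p[1]
    KB = p[2]
    nB = p[3]
    k = p[4]
    A = y[0]
    B = y[1]
    C = y[2]
    D = y[3]
    if A < 0.0:
        A = 0.0
    if B < 0.0:
        B = 0.0
    # Hill activation by A; n == 0 degenerates to 1/2, K == 0 to full ON.
    if KA <= 0.0:
        act = 1.0
    elif nA == 0.0:
        act = 0.5
    else:
        ra = (A / KA) ** nA
        act = ra / (1.0 + ra)
    if KB <= 0.0:
        inh = 0.0
    elif nB == 0.0:
        inh = 0.5
    else:
        rb = (B / KB) ** nB
        inh = 1.0 / (1.0 + rb)
    out = np.empty(4)
    out[0] = k * C - A
    out[1] = k * D - B
    out[2] = inh - C
    out[3] = act - D
    return out


@njit(cache=False)
def protease_rhs(y, t, p):
    """DegS-DegU two-component network driving extracellular protease
    (AprE) production in B. subtilis.

    States: A=AprE, B=DegU, C=DegU~P, D=DegU~P dimer, E=mAprE, F=mDegU.
    Parameter roles by position (values/bounds in the model registry)::

        p1  mAprE decay              p10 mAprE translation to AprE
        p2  DegU decay               p11 phosphorylation saturation const
        p3  DegU phosphorylation     p12 mDegU decay
        p4  DegU~P dephosphorylation p13 DegU synthesis
        p5  dimerization (2C -> D)   p14 dimer-activated transcription coeff
        p6  dimer dissociation       p15 mDegU synthesis
        p7  DegU~P decay             p16 transcription activation const
        p8  AprE decay/secretion     p17 dephosphorylation saturation const
    """
    A = y[0]
    B = y[1]
    C = y[2]
    D = y[3]
    E = y[4]
    F = y[5]
    if B < 0.0:
        B = 0.0
    if C < 0.0:
        C = 0.0
    if D < 0.0:
        D = 0.0
    phos = p[2] * B * p[10] / (p[10] + B)
    deph = p[3] * C * p[16] / (p[16] + C)
    dim = p[4] * C * C
    und = p[5] * D
    out = np.empty(6)
    out[0] = p[9] * E - p[7] * A
    out[1] = p[12] + deph - phos - p[1] * B
    out[2] = phos - deph - 2.0 * dim + 2.0 * und - p[6] * C
    out[3] = dim - und
    out[4] = p[8] + p[13] * p[15] * D / (p[15] + D) - p[0] * E
    out[5] = p[14] - p[11] * F
    return out
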