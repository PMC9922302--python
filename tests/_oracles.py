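"""Independent oracles used by the test suite.

The energy oracle is a deliberately naive, scalar double-loop transcription
of the bead-model potential definition.  It shares no code with the package
implementation and is kept free of vectorization or cutoff bookkeeping
beyond the plain truncation the model defines.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import quad

from disgen.cg import KB


def naive_energy(coords, letters, ff, box_edge=None):
    """Scalar double-loop evaluation of the four-term potential, kJ/mol."""
    L = len(letters)
    sigma = {a: ff.sigma_per_residue[a] for a in set(letters)}
    charge = {a: ff.charge_per_residue.get(a, 0) for a in set(letters)}
    polar = {a: ff.polarity_table[a] == "polar" for a in set(letters)}

    def dist(i, j):
        d = [coords[i][k] - coords[j][k] for k in range(3)]
        if box_edge is not None:
            d = [x - box_edge * round(x / box_edge) for x in d]
        return math.sqrt(sum(x * x for x in d))

    e_bond = 0.0
    for i in range(L - 1):
        e_bond += 0.5 * ff.k_bond * (dist(i, i + 1) - ff.l0) ** 2

    e_angle = 0.0
    for i in range(L - 2):
        u = [coords[i][k] - coords[i + 1][k] for k in range(3)]
        v = [coords[i + 2][k] - coords[i + 1][k] for k in range(3)]
        nu = math.sqrt(sum(x * x for x in u))
        nv = math.sqrt(sum(x * x for x in v))
        ct = sum(a * b for a, b in zip(u, v)) / (nu * nv)
        ct = max(-1.0, min(1.0, ct))
        e_angle += 0.5 * ff.k_angle * (math.acos(ct) - ff.theta0) ** 2

    e_sr = 0.0
    e_lr = 0.0
    for i in range(L):
        for j in range(i + 2, L):
            r = dist(i, j)
            if r >= ff.cutoff:
                continue
            ai, aj = letters[i], letters[j]
            s = sigma[ai] + sigma[aj]
            eps = ff.eps_polar if (polar[ai] or polar[aj]) else ff.eps_nonpolar
            pair = {ai, aj}
            if (pair & set("RK")) and (pair & set("FYW")):
                eps += ff.eps_cation_pi
            e_sr += 4.0 * eps * ((s / r) ** 10 - (s / r) ** 5)
            qi, qj = charge[ai], charge[aj]
            A_i = math.copysign(math.sqrt(0.75 * abs(qi)), qi) if qi else 0.0
            A_j = math.copysign(math.sqrt(0.75 * abs(qj)), qj) if qj else 0.0
            A0_i = ff.A0_polar if polar[ai] else 0.0
            A0_j = ff.A0_polar if polar[aj] else 0.0
            e_lr += (A_i * A_j + A0_i * A0_j) / r * math.exp(-r / ff.kappa)

    return e_bond + e_angle + e_sr + e_lr


def bond_length_moments(ff, temperature=298.0, lo=0.2, hi=0.6):
    """Mean and variance of the bond length under p(l) ~ l^2 exp(-k(l-l0)^2/2kT)."""
    kT = KB * temperature
    w = lambda l: l**2 * math.exp(-ff.k_bond * (l - ff.l0) ** 2 / (2 * kT))
    Z = quad(w, lo, hi)[0]
    m1 = quad(lambda l: l * w(l), lo, hi)[0] / Z
    m2 = quad(lambda l: l * l * w(l), lo, hi)[0] / Z
    return m1, m2 - m1**2


def bond_angle_cdf(ff, temperature=298.0, n=2001):
    """CDF of the bead angle under p(theta) ~ sin(theta) exp(-k(theta-pi)^2/2kT)."""
    kT = KB * temperature
    theta = np.linspace(1e-6, math.pi - 1e-9, n)
    dens = np.sin(theta) * np.exp(-ff.k_angle * (theta - ff.theta0) ** 2 / (2 * kT))
    cdf = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(theta))])
    cdf /= cdf[-1]
    return theta, cdf
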