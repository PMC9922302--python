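"""Steepest-descent minimization and Langevin dynamics for the bead model.

Unit system: kJ/mol, nm, ps, masses in g/mol, so velocities are nm/ps and
1/2 m v^2 is in kJ/mol directly.  The integrator is a BAOAB-splitting
Langevin scheme; equilibrium ensembles are independent of the (uniform) bead
mass, fixed at 110 g/mol, the average residue mass.

The inner loop is compiled with numba; the kernel evaluates the same
potential as :mod:`disgen.cg.energy` (asserted in tests) with per-pair
parameter tables precomputed per sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from numba import njit

from ..ensembles_io import Conformation, ConformationalEnsemble, ResidueSequence, init_random_coordinates
from .energy import cg_energy, cg_forces
from .params import ForceFieldParameters

KB = 8.3144621e-3  # kJ/mol/K
BEAD_MASS = 110.0  # g/mol

_CHUNK = 10_000  # integrator steps per noise block


@dataclass
class SimulationProtocol:
    """Langevin run settings.

    Defaults reproduce the reference data-generation protocol: friction
    0.01/ps, production timestep 0.02 ps, 298 K, 300 nm cubic box, frames
    every 200 ps, preceded by 5,000 steepest-descent minimization steps and
    20,000 equilibration steps at 0.01 ps.
    """

    timestep: float = 0.02          # ps
    friction: float = 0.01          # 1/ps
    temperature: float = 298.0      # K
    n_steps: int = 500_000
    save_interval_steps: int = 10_000   # 200 ps at the default timestep
    box_edge: Optional[float] = 300.0   # nm
    seed: int = 0
    minimize_steps: int = 5_000
    equil_steps: int = 20_000
    equil_timestep: float = 0.01    # ps

    def __post_init__(self) -> None:
        if self.timestep <= 0 or self.equil_timestep <= 0:
            raise ValueError("timesteps must be positive")
        if self.save_interval_steps <= 0:
            raise ValueError("save_interval_steps must be positive")


@njit(cache=True, fastmath=True, error_model="numpy")
def _kernel_forces(coords, sigma_pair, eps_pair, coef_lr,
                   k_bond, l0, k_angle, theta0, kappa, cutoff, box, forces):
    L = coords.shape[0]
    forces[:] = 0.0
    # bonds
    for i in range(L - 1):
        dx = coords[i + 1, 0] - coords[i, 0]
        dy = coords[i + 1, 1] - coords[i, 1]
        dz = coords[i + 1, 2] - coords[i, 2]
        l = math.sqrt(dx * dx + dy * dy + dz * dz)
        c = k_bond * (l - l0) / l
        forces[i, 0] += c * dx
        forces[i, 1] += c * dy
        forces[i, 2] += c * dz
        forces[i + 1, 0] -= c * dx
        forces[i + 1, 1] -= c * dy
        forces[i + 1, 2] -= c * dz
    # angles
    for i in range(L - 2):
        ux = coords[i, 0] - coords[i + 1, 0]
        uy = coords[i, 1] - coords[i + 1, 1]
        uz = coords[i, 2] - coords[i + 1, 2]
        vx = coords[i + 2, 0] - coords[i + 1, 0]
        vy = coords[i + 2, 1] - coords[i + 1, 1]
        vz = coords[i + 2, 2] - coords[i + 1, 2]
        nu = math.sqrt(ux * ux + uy * uy + uz * uz)
        nv = math.sqrt(vx * vx + vy * vy + vz * vz)
        ct = (ux * vx + uy * vy + uz * vz) / (nu * nv)
        if ct > 1.0:
            ct = 1.0
        elif ct < -1.0:
            ct = -1.0
        theta = math.acos(ct)
        st = math.sqrt(max(1.0 - ct * ct, 0.0))
        if st > 1e-8:
            ratio = (theta - theta0) / st
        else:
            ratio = -1.0  # limit at theta -> pi
        c = k_angle * ratio
        inv_uv = 1.0 / (nu * nv)
        cu = ct / (nu * nu)
        cv = ct / (nv * nv)
        dax = c * (vx * inv_uv - cu * ux)
        day = c * (vy * inv_uv - cu * uy)
        daz = c * (vz * inv_uv - cu * uz)
        dcx = c * (ux * inv_uv - cv * vx)
        dcy = c * (uy * inv_uv - cv * vy)
        dcz = c * (uz * inv_uv - cv * vz)
        forces[i, 0] += dax
        forces[i, 1] += day
        forces[i, 2] += daz
        forces[i + 2, 0] += dcx
        forces[i + 2, 1] += dcy
        forces[i + 2, 2] += dcz
        forces[i + 1, 0] -= dax + dcx
        forces[i + 1, 1] -= day + dcy
        forces[i + 1, 2] -= daz + dcz
    # non-bonded (|i-j| >= 2, minimum image, truncated); the wrap branches
    # almost never fire for a single chain much smaller than the box
    cutoff2 = cutoff * cutoff
    hbox = 0.5 * box
    for i in range(L - 2):
        for j in range(i + 2, L):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            if box > 0.0:
                if dx > hbox:
                    dx -= box * round(dx / box)
                elif dx < -hbox:
                    dx -= box * round(dx / box)
                if dy > hbox:
                    dy -= box * round(dy / box)
                elif dy < -hbox:
                    dy -= box * round(dy / box)
                if dz > hbox:
                    dz -= box * round(dz / box)
                elif dz < -hbox:
                    dz -= box * round(dz / box)
            r2 = dx * dx + dy * dy + dz * dz
            if r2 >= cutoff2:
                continue
            r = math.sqrt(r2)
            sr = sigma_pair[i, j] / r
            sr2 = sr * sr
            sr5 = sr2 * sr2 * sr
            dudr = 4.0 * eps_pair[i, j] * (-10.0 * sr5 * sr5 + 5.0 * sr5) / r
            clr = coef_lr[i, j]
            if clr != 0.0:
                dudr += clr * math.exp(-r / kappa) * (-1.0 / r2 - 1.0 / (kappa * r))
            c = -dudr / r
            forces[i, 0] += c * dx
            forces[i, 1] += c * dy
            forces[i, 2] += c * dz
            forces[j, 0] -= c * dx
            forces[j, 1] -= c * dy
            forces[j, 2] -= c * dz


@njit(cache=True, fastmath=True, error_model="numpy")
def _baoab_chunk(coords, vel, forces, noise, dt, c1, c2, inv_mass,
                 sigma_pair, eps_pair, coef_lr,
                 k_bond, l0, k_angle, theta0, kappa, cutoff, box):
    """Advance noise.shape[0] BAOAB steps in place; forces holds -grad U at coords."""
    n_steps = noise.shape[0]
    L = coords.shape[0]
    half = 0.5 * dt
    for s in range(n_steps):
        for i in range(L):
            for d in range(3):
                vel[i, d] += half * forces[i, d] * inv_mass
                coords[i, d] += half * vel[i, d]
        for i in range(L):
            for d in range(3):
                vel[i, d] = c1 * vel[i, d] + c2 * noise[s, i, d]
                coords[i, d] += half * vel[i, d]
        _kernel_forces(coords, sigma_pair, eps_pair, coef_lr,
                       k_bond, l0, k_angle, theta0, kappa, cutoff, box, forces)
        for i in range(L):
            for d in range(3):
                vel[i, d] += half * forces[i, d] * inv_mass


def _kernel_args(ff: ForceFieldParameters, seq: ResidueSequence, box_edge: Optional[float]):
    sp = ff.sequence_arrays(seq)
    coef_lr = np.outer(sp.A, sp.A) + np.outer(sp.A0, sp.A0)
    box = float(box_edge) if box_edge is not None else -1.0
    return (np.ascontiguousarray(sp.sigma_pair), np.ascontiguousarray(sp.eps_pair),
            np.ascontiguousarray(coef_lr), ff.k_bond, ff.l0, ff.k_angle, ff.theta0,
            ff.kappa, ff.cutoff, box)


def minimize_steepest_descent(
    conf: Conformation,
    seq: ResidueSequence,
    ff: ForceFieldParameters,
    max_steps: int = 5_000,
    step_nm: float = 1e-4,
    gtol: float = 1e-6,
    box_edge: Optional[float] = None,
) -> Conformation:
    """Steepest descent with a backtracking step size; energy never increases.

    ``step_nm`` is the initial displacement of the largest force component.
    Stops after ``max_steps`` accepted/rejected iterations or when the force
    norm drops below ``gtol`` kJ/mol/nm.
    """
    sp = ff.sequence_arrays(seq)
    x = conf.coords.copy()

    def energy(c):
        return cg_energy(Conformation(c), seq, ff, box_edge, sp).total

    e = energy(x)
    if not np.isfinite(e):
        raise FloatingPointError("non-finite energy at minimization start")
    alpha = step_nm
    for _ in range(max_steps):
        f = cg_forces(Conformation(x), seq, ff, box_edge, sp)
        fmax = np.max(np.abs(f))
        if fmax < gtol:
            break
        trial = x + alpha / fmax * f
        e_trial = energy(trial)
        if not np.isfinite(e_trial):
            alpha *= 0.5
            continue
        if e_trial <= e:
            x, e = trial, e_trial
            alpha *= 1.2
        else:
            alpha *= 0.5
            if alpha < 1e-12:
                break
    return Conformation(x, sequence_ref=seq.id)


def langevin_simulate(
    conf: Conformation,
    seq: ResidueSequence,
    ff: ForceFieldParameters,
    protocol: SimulationProtocol,
    return_velocities: bool = False,
) -> ConformationalEnsemble:
    """Run (minimization +) equilibration + production Langevin dynamics.

    Production frames are saved every ``save_interval_steps``; the run is
    deterministic for a fixed protocol seed.  Raises on numerical blow-up
    with the step index at which coordinates became non-finite.
    """
    rng = np.random.default_rng(protocol.seed)
    args = _kernel_args(ff, seq, protocol.box_edge)
    kT = KB * protocol.temperature
    inv_mass = 1.0 / BEAD_MASS

    x = conf.coords.copy()
    if protocol.minimize_steps > 0:
        x = minimize_steepest_descent(
            Conformation(x), seq, ff, max_steps=protocol.minimize_steps,
            box_edge=protocol.box_edge,
        ).coords.copy()

    v = rng.normal(scale=math.sqrt(kT / BEAD_MASS), size=x.shape)
    f = np.empty_like(x)
    _kernel_forces(x, *args, f)

    def run(n_steps: int, dt: float, sample_every: int = 0, collect=None, vels=None):
        c1 = math.exp(-protocol.friction * dt)
        c2 = math.sqrt(kT / BEAD_MASS * (1.0 - c1 * c1))
        block = sample_every if sample_every else _CHUNK
        done = 0
        while done < n_steps:
            n = min(block, n_steps - done)
            noise = rng.standard_normal((n, *x.shape))
            _baoab_chunk(x, v, f, noise, dt, c1, c2, inv_mass, *args)
            done += n
            if not np.all(np.isfinite(x)):
                raise FloatingPointError(f"coordinates non-finite at step {done}")
            if sample_every and n == sample_every and collect is not None:
                collect.append(x.copy())
                if vels is not None:
                    vels.append(v.copy())

    if protocol.equil_steps > 0:
        run(protocol.equil_steps, protocol.equil_timestep)

    frames: list = []
    vels: list = [] if return_velocities else None
    run(protocol.n_steps, protocol.timestep,
        sample_every=protocol.save_interval_steps, collect=frames, vels=vels)
    if not frames:
        raise ValueError(
            "no frames saved: n_steps must be >= save_interval_steps"
        )
    ens = ConformationalEnsemble(seq, np.array(frames), provenance="simulated")
    if return_velocities:
        return ens, np.array(vels)
    return ens


#: full-scale reference protocol: 5 independent runs of 1000 ns production
#: (5e7 steps at 0.02 ps), frames every 200 ps -> 25,000 frames total
_N_RUNS = 5
_FULL_STEPS_PER_RUN = 50_000_000


def reference_protocol(
    seq: ResidueSequence,
    ff: ForceFieldParameters,
    scale: float = 1.0,
    seed: int = 0,
    protocol: Optional[SimulationProtocol] = None,
) -> ConformationalEnsemble:
    """Reference-ensemble generation: independent Langevin runs, concatenated.

    ``scale`` in (0, 1] shrinks each run's production length proportionally
    while preserving the 200 ps frame spacing; at scale=1 the five runs yield
    25,000 frames.  Each run starts from its own seeded self-avoiding walk.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError(f"scale must be in (0, 1], got {scale}")
    base = protocol if protocol is not None else SimulationProtocol()
    steps = int(round(_FULL_STEPS_PER_RUN * scale))
    steps -= steps % base.save_interval_steps
    if steps < base.save_interval_steps:
        raise ValueError("scale too small: fewer than one frame per run")
    parts = []
    ss = np.random.SeedSequence(seed)
    for run_idx, child in enumerate(ss.spawn(_N_RUNS)):
        run_seed = int(child.generate_state(1)[0] % (2**31))
        start = init_random_coordinates(seq, seed=run_seed)
        proto = replace(base, n_steps=steps, seed=run_seed)
        parts.append(langevin_simulate(start, seq, ff, proto).xyz)
    return ConformationalEnsemble(seq, np.concatenate(parts), provenance="simulated")
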