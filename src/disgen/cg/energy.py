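"""Bead-model potential energy and analytic forces.

The potential is a sum of four terms over a C-alpha chain of L beads:

* harmonic bonds, sum_{i} 1/2 k_bond (l_{i,i+1} - l0)^2
* harmonic pseudo-angles, sum_i 1/2 k_angle (theta_{i,i+1,i+2} - theta0)^2
* a 10-5 short-range term, sum_{ij} 4 (eps + eps_cpi) ((s/r)^10 - (s/r)^5)
* a screened long-range term, sum_{ij} (A_i A_j + A0_i A0_j)/r * exp(-r/kappa)

Non-bonded sums run over pairs |i-j| >= 2 (only directly bonded neighbours
are excluded) within the cutoff, under the minimum-image convention when a
periodic box is given.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from ..ensembles_io import Conformation, ResidueSequence
from .params import ForceFieldParameters, SequenceParameters

_SIN_EPS = 1e-8


@dataclass(frozen=True)
class EnergyBreakdown:
    """Potential energy decomposed by term, kJ/mol."""

    bond: float
    angle: float
    short_range: float
    long_range: float

    @property
    def total(self) -> float:
        return self.bond + self.angle + self.short_range + self.long_range


def _nonbonded_pairs(L: int) -> Tuple[np.ndarray, np.ndarray]:
    i, j = np.triu_indices(L, k=2)
    return i, j


def _pair_displacements(coords: np.ndarray, i: np.ndarray, j: np.ndarray,
                        box_edge: Optional[float]) -> np.ndarray:
    disp = coords[i] - coords[j]
    if box_edge is not None:
        disp -= box_edge * np.round(disp / box_edge)
    return disp


def cg_energy(
    conf: Conformation,
    seq: ResidueSequence,
    ff: ForceFieldParameters,
    box_edge: Optional[float] = None,
    seq_params: Optional[SequenceParameters] = None,
) -> EnergyBreakdown:
    """Evaluate the four-term potential for one conformation."""
    coords = conf.coords
    L = coords.shape[0]
    if L != len(seq):
        raise ValueError(f"conformation length {L} != sequence length {len(seq)}")
    sp = seq_params if seq_params is not None else ff.sequence_arrays(seq)

    bond_vec = coords[1:] - coords[:-1]
    bond_len = np.linalg.norm(bond_vec, axis=1)
    e_bond = 0.5 * ff.k_bond * np.sum((bond_len - ff.l0) ** 2)

    e_angle = 0.0
    if L >= 3:
        u = coords[:-2] - coords[1:-1]
        v = coords[2:] - coords[1:-1]
        cos_t = np.sum(u * v, axis=1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        theta = np.arccos(np.clip(cos_t, -1.0, 1.0))
        e_angle = 0.5 * ff.k_angle * np.sum((theta - ff.theta0) ** 2)

    i, j = _nonbonded_pairs(L)
    e_sr = e_lr = 0.0
    if i.size:
        disp = _pair_displacements(coords, i, j, box_edge)
        r = np.linalg.norm(disp, axis=1)
        if np.any(r == 0.0):
            k = int(np.argmin(r))
            raise FloatingPointError(
                f"zero distance between non-bonded beads {i[k]} and {j[k]}"
            )
        within = r < ff.cutoff
        r, ii, jj = r[within], i[within], j[within]
        sr5 = (sp.sigma_pair[ii, jj] / r) ** 5
        e_sr = float(np.sum(4.0 * sp.eps_pair[ii, jj] * (sr5 * sr5 - sr5)))
        coef = sp.A[ii] * sp.A[jj] + sp.A0[ii] * sp.A0[jj]
        e_lr = float(np.sum(coef / r * np.exp(-r / ff.kappa)))

    return EnergyBreakdown(float(e_bond), float(e_angle), e_sr, e_lr)


def cg_forces(
    conf: Conformation,
    seq: ResidueSequence,
    ff: ForceFieldParameters,
    box_edge: Optional[float] = None,
    seq_params: Optional[SequenceParameters] = None,
) -> np.ndarray:
    """Analytic forces -grad U, shape (L, 3), kJ/mol/nm.

    The cutoff is applied consistently with :func:`cg_energy` (plain
    truncation, no shift).
    """
    coords = conf.coords
    L = coords.shape[0]
    if L != len(seq):
        raise ValueError(f"conformation length {L} != sequence length {len(seq)}")
    sp = seq_params if seq_params is not None else ff.sequence_arrays(seq)
    forces = np.zeros_like(coords)

    # bonds
    bond_vec = coords[1:] - coords[:-1]
    bond_len = np.linalg.norm(bond_vec, axis=1)
    fb = (ff.k_bond * (bond_len - ff.l0) / bond_len)[:, None] * bond_vec
    np.add.at(forces, np.arange(1, L), -fb)
    np.add.at(forces, np.arange(0, L - 1), fb)

    # angles (vertex at the middle bead); (theta - theta0)/sin(theta) has the
    # finite limit -1 at theta -> theta0 = pi, used when sin(theta) underflows
    if L >= 3:
        u = coords[:-2] - coords[1:-1]
        v = coords[2:] - coords[1:-1]
        nu = np.linalg.norm(u, axis=1)
        nv = np.linalg.norm(v, axis=1)
        cos_t = np.sum(u * v, axis=1) / (nu * nv)
        cos_t = np.clip(cos_t, -1.0, 1.0)
        theta = np.arccos(cos_t)
        sin_t = np.sqrt(np.maximum(1.0 - cos_t**2, 0.0))
        ratio = np.where(sin_t > _SIN_EPS, (theta - ff.theta0) / np.maximum(sin_t, _SIN_EPS), -1.0)
        coef = ff.k_angle * ratio
        da = coef[:, None] * (v / (nu * nv)[:, None] - (cos_t / nu**2)[:, None] * u)
        dc = coef[:, None] * (u / (nu * nv)[:, None] - (cos_t / nv**2)[:, None] * v)
        np.add.at(forces, np.arange(0, L - 2), da)
        np.add.at(forces, np.arange(2, L), dc)
        np.add.at(forces, np.arange(1, L - 1), -(da + dc))

    # non-bonded
    i, j = _nonbonded_pairs(L)
    if i.size:
        disp = _pair_displacements(coords, i, j, box_edge)
        r = np.linalg.norm(disp, axis=1)
        if np.any(r == 0.0):
            k = int(np.argmin(r))
            raise FloatingPointError(
                f"zero distance between non-bonded beads {i[k]} and {j[k]}"
            )
        within = r < ff.cutoff
        r, ii, jj, disp = r[within], i[within], j[within], disp[within]
        s = sp.sigma_pair[ii, jj]
        eps = sp.eps_pair[ii, jj]
        sr5 = (s / r) ** 5
        dudr = 4.0 * eps * (-10.0 * sr5 * sr5 + 5.0 * sr5) / r
        coef = sp.A[ii] * sp.A[jj] + sp.A0[ii] * sp.A0[jj]
        dudr += coef * np.exp(-r / ff.kappa) * (-1.0 / r**2 - 1.0 / (ff.kappa * r))
        fpair = (-dudr / r)[:, None] * disp
        np.add.at(forces, ii, fpair)
        np.add.at(forces, jj, -fpair)

    return forces
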