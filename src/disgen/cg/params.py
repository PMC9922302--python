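"""Force-field parameter tables for the residue-level C-alpha bead model.

Units throughout: energies kJ/mol, lengths nm, angles rad, charges in units
of the elementary charge.  The electrostatic/solvation coefficients
(A_i A_j + A0_i A0_j) are treated as carrying kJ/mol*nm so that dividing by r
in nm yields kJ/mol directly.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field
from typing import Dict

import numpy as np
import yaml

from ..ensembles_io import AMINO_ACIDS, ResidueSequence


def _default_tables() -> dict:
    ref = importlib.resources.files("disgen").joinpath("data/forcefield.yaml")
    with ref.open("r") as fh:
        return yaml.safe_load(fh)


@dataclass
class ForceFieldParameters:
    """All constants of the bead-model potential.

    The potential has four terms: harmonic bonds between consecutive beads,
    harmonic pseudo-angles centred at 180 deg, a 10-5 short-range interaction
    with per-pair radius sigma_ij = sigma_i + sigma_j, and a screened
    long-range term (A_i A_j + A0_i A0_j)/r * exp(-r/kappa) combining
    Debye-Hueckel-like electrostatics (A_i = sign(q_i) sqrt(0.75 |q_i|)) with
    a solvation repulsion between polar residues (A0_i = 0.05 for polar, 0
    otherwise).
    """

    k_bond: float = 4184.0
    l0: float = 0.38
    k_angle: float = 4.184
    theta0: float = math.pi
    eps_polar: float = 0.40
    eps_nonpolar: float = 0.41
    eps_cation_pi: float = 0.30
    A0_polar: float = 0.05
    kappa: float = 1.0
    cutoff: float = 3.0
    sigma_per_residue: Dict[str, float] = field(default_factory=dict)  # nm
    charge_per_residue: Dict[str, int] = field(default_factory=dict)
    polarity_table: Dict[str, str] = field(default_factory=dict)  # residue -> polar|nonpolar
    cation_residues: frozenset = frozenset("RK")
    aromatic_residues: frozenset = frozenset("FYW")

    @classmethod
    def default(cls, **overrides) -> "ForceFieldParameters":
        tab = _default_tables()
        c = tab["constants"]
        sigma = {
            a: (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0) / 10.0  # A^3 -> radius in nm
            for a, v in tab["residue_volumes_A3"].items()
        }
        charges = {a: int(tab["charges"].get(a, 0)) for a in AMINO_ACIDS}
        polarity = {a: "polar" for a in tab["polar"]}
        polarity.update({a: "nonpolar" for a in tab["nonpolar"]})
        params = dict(
            k_bond=c["k_bond"],
            l0=c["l0"],
            k_angle=c["k_angle"],
            theta0=math.radians(c["theta0_deg"]),
            eps_polar=c["eps_polar"],
            eps_nonpolar=c["eps_nonpolar"],
            eps_cation_pi=c["eps_cation_pi"],
            A0_polar=c["A0_polar"],
            kappa=c["kappa"],
            cutoff=c["cutoff"],
            sigma_per_residue=sigma,
            charge_per_residue=charges,
            polarity_table=polarity,
            cation_residues=frozenset(tab["cation_residues"]),
            aromatic_residues=frozenset(tab["aromatic_residues"]),
        )
        params.update(overrides)
        return cls(**params)

    @classmethod
    def from_yaml(cls, path) -> "ForceFieldParameters":
        """Load a user force-field config with the same layout as the default."""
        with open(path) as fh:
            tab = yaml.safe_load(fh)
        base = cls.default()
        c = tab.get("constants", {})
        for key in ("k_bond", "l0", "k_angle", "eps_polar", "eps_nonpolar",
                    "eps_cation_pi", "A0_polar", "kappa", "cutoff"):
            if key in c:
                setattr(base, key, float(c[key]))
        if "theta0_deg" in c:
            base.theta0 = math.radians(c["theta0_deg"])
        if "residue_volumes_A3" in tab:
            base.sigma_per_residue = {
                a: (3.0 * v / (4.0 * math.pi)) ** (1.0 / 3.0) / 10.0
                for a, v in tab["residue_volumes_A3"].items()
            }
        for key, attr in (("charges", "charge_per_residue"),):
            if key in tab:
                base.charge_per_residue = {a: int(tab[key].get(a, 0)) for a in AMINO_ACIDS}
        if "polar" in tab and "nonpolar" in tab:
            pol = {a: "polar" for a in tab["polar"]}
            pol.update({a: "nonpolar" for a in tab["nonpolar"]})
            base.polarity_table = pol
        return base

    # -- per-sequence parameter vectors ------------------------------------

    def eps_for(self, a: str) -> float:
        kind = self.polarity_table.get(a)
        if kind is None:
            raise KeyError(f"unknown residue {a!r} in polarity table")
        return self.eps_polar if kind == "polar" else self.eps_nonpolar

    def sequence_arrays(self, seq: ResidueSequence) -> "SequenceParameters":
        return SequenceParameters.build(self, seq)


@dataclass(frozen=True)
class SequenceParameters:
    """Per-residue parameter vectors and per-pair tables cached for one sequence.

    eps_pair combines the Lorentz-like polar/nonpolar rule with the cation-pi
    augmentation: eps_ij = eps(min polarity rule) + eps_cpi for basic x
    aromatic pairs.  Pair epsilon without cation-pi uses the polar value if
    either residue is polar.
    """

    sigma: np.ndarray       # (L,) bead radii, nm
    A: np.ndarray           # (L,) signed electrostatic coefficients
    A0: np.ndarray          # (L,) solvation coefficients
    eps_pair: np.ndarray    # (L, L) 10-5 well depths incl. cation-pi
    sigma_pair: np.ndarray  # (L, L) sigma_i + sigma_j

    @classmethod
    def build(cls, ff: ForceFieldParameters, seq: ResidueSequence) -> "SequenceParameters":
        letters = seq.letters
        for a in letters:
            if a not in ff.sigma_per_residue:
                raise KeyError(f"residue {a!r} missing from sigma table")
        sigma = np.array([ff.sigma_per_residue[a] for a in letters])
        q = np.array([ff.charge_per_residue.get(a, 0) for a in letters], dtype=float)
        A = np.sign(q) * np.sqrt(0.75 * np.abs(q))
        A0 = np.array(
            [ff.A0_polar if ff.polarity_table[a] == "polar" else 0.0 for a in letters]
        )
        polar = np.array([ff.polarity_table[a] == "polar" for a in letters])
        # pair well depth: polar value if either partner is polar
        either_polar = polar[:, None] | polar[None, :]
        eps_pair = np.where(either_polar, ff.eps_polar, ff.eps_nonpolar)
        cation = np.array([a in ff.cation_residues for a in letters])
        arom = np.array([a in ff.aromatic_residues for a in letters])
        cpi = (cation[:, None] & arom[None, :]) | (arom[:, None] & cation[None, :])
        eps_pair = eps_pair + ff.eps_cation_pi * cpi
        sigma_pair = sigma[:, None] + sigma[None, :]
        return cls(sigma, A, A0, eps_pair, sigma_pair)
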