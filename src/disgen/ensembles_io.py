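"""Sequence and conformation data model, standard-format I/O and fixture generation.

All coordinates are stored internally in nanometres.  The PDB boundary converts
to/from Angstrom; DCD files written here carry nanometre coordinates through
mdtraj, which handles the format's unit conventions.
"""

from __future__ import annotations


from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, List, Sequence

import mdtraj as md
import numpy as np
from Bio import SeqIO
from Bio.SeqUtils import seq3

#: the 20 standard amino acids, alphabetical one-letter order used for one-hot columns
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: fixed bond length between consecutive C-alpha beads, nm
CA_BOND_LENGTH = 0.38


class SequenceError(ValueError):
    """Raised for sequences containing non-standard residue letters."""


@dataclass(frozen=True)
class ResidueSequence:
    """An amino acid sequence: the conditional input of the generative model."""

    id: str
    letters: str

    def __post_init__(self) -> None:
        letters = self.letters.upper()
        object.__setattr__(self, "letters", letters)
        if len(letters) < 2:
            raise SequenceError(f"sequence {self.id!r}: length must be >= 2, got {len(letters)}")
        for pos, a in enumerate(letters):
            if a not in _AA_INDEX:
                raise SequenceError(
                    f"sequence {self.id!r}: non-standard residue {a!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.letters)

    @property
    def onehot(self) -> np.ndarray:
        """L x 20 one-hot encoding; row i has a single 1 in the column of residue i."""
        enc = np.zeros((len(self.letters), 20))
        enc[np.arange(len(self.letters)), [_AA_INDEX[a] for a in self.letters]] = 1.0
        return enc

    @classmethod
    def from_onehot(cls, id: str, onehot: np.ndarray) -> "ResidueSequence":
        letters = "".join(AMINO_ACIDS[j] for j in np.argmax(onehot, axis=1))
        return cls(id, letters)


@dataclass(frozen=True)
class Conformation:
    """One C-alpha trace: L ordered 3D bead positions in nm."""

    coords: np.ndarray
    sequence_ref: str = ""

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.float64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError(f"coords must be (L, 3), got {coords.shape}")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coords contain non-finite values")
        object.__setattr__(self, "coords", coords)

    def __len__(self) -> int:
        return self.coords.shape[0]


@dataclass
class ConformationalEnsemble:
    """Ordered collection of conformations sharing one sequence.

    The unit on which every ensemble-comparison metric operates.  Frames are
    held as a single (n_frames, L, 3) array in nm for efficiency.
    """

    sequence: ResidueSequence
    xyz: np.ndarray
    provenance: str = "simulated"

    _PROVENANCES = ("simulated", "generated", "fixture")

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.xyz.ndim != 3 or self.xyz.shape[2] != 3:
            raise ValueError(f"xyz must be (n_frames, L, 3), got {self.xyz.shape}")
        if self.xyz.shape[0] == 0:
            raise ValueError("ensemble must contain at least one conformation")
        if self.xyz.shape[1] != len(self.sequence):
            raise ValueError(
                f"frame length {self.xyz.shape[1]} does not match sequence length "
                f"{len(self.sequence)}"
            )
        if self.provenance not in self._PROVENANCES:
            raise ValueError(f"provenance must be one of {self._PROVENANCES}")

    @classmethod
    def from_conformations(
        cls,
        sequence: ResidueSequence,
        conformations: Sequence[Conformation],
        provenance: str = "simulated",
    ) -> "ConformationalEnsemble":
        return cls(sequence, np.stack([c.coords for c in conformations]), provenance)

    def __len__(self) -> int:
        return self.xyz.shape[0]

    def __getitem__(self, i: int) -> Conformation:
        return Conformation(self.xyz[i], sequence_ref=self.sequence.id)

    def __iter__(self) -> Iterator[Conformation]:
        for i in range(len(self)):
            yield self[i]

    def subsample(self, n: int, seed: int) -> "ConformationalEnsemble":
        """Random subset of min(n, len) frames, without replacement, seeded."""
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(self), size=min(n, len(self)), replace=False)
        return ConformationalEnsemble(self.sequence, self.xyz[np.sort(idx)], self.provenance)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_sequences_fasta(path) -> List[ResidueSequence]:
    """Read FASTA records as ResidueSequence objects, order preserved.

    Rejects records containing letters outside the 20-standard alphabet,
    naming the record and position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return [ResidueSequence(rec.id, str(rec.seq).upper()) for rec in records]


def write_sequences_fasta(sequences: Sequence[ResidueSequence], path) -> None:
    with open(path, "w") as fh:
        for seq in sequences:
            fh.write(f">{seq.id}\n{seq.letters}\n")


# ---------------------------------------------------------------------------
# Trajectories (multi-model PDB / DCD + template PDB)
# ---------------------------------------------------------------------------

def _ca_topology(sequence: ResidueSequence) -> md.Topology:
    """C-alpha-only mdtraj topology: one chain 'A', one CA atom per residue."""
    top = md.Topology()
    chain = top.add_chain()
    for i, a in enumerate(sequence.letters):
        res = top.add_residue(seq3(a).upper(), chain, resSeq=i + 1)
        top.add_atom("CA", md.element.carbon, res)
    for i in range(len(sequence) - 1):
        top.add_bond(top.atom(i), top.atom(i + 1))
    return top


def write_ca_trajectory(ensemble: ConformationalEnsemble, path, format: str = "pdb") -> None:
    """Write an ensemble as a multi-model PDB or a DCD plus template PDB.

    ``format='dcd'`` writes ``path`` plus a single-frame template PDB at
    ``path`` with a ``.pdb`` suffix for topology-aware readers.
    """
    path = Path(path)
    traj = md.Trajectory(ensemble.xyz.astype(np.float32), _ca_topology(ensemble.sequence))
    if format == "pdb":
        traj.save_pdb(str(path))
        if len(ensemble) == 1:  # keep the MODEL/ENDMDL-per-frame dialect
            lines = path.read_text().splitlines()
            if not any(l.startswith("MODEL") for l in lines):
                out = []
                wrapped = False
                for l in lines:
                    if not wrapped and l.startswith(("ATOM", "HETATM")):
                        out.append("MODEL        1")
                        wrapped = True
                    if l.startswith("END") and wrapped and "ENDMDL" not in l:
                        out.append("ENDMDL")
                    out.append(l)
                path.write_text("\n".join(out) + "\n")
    elif format == "dcd":
        traj.save_dcd(str(path))
        traj[0].save_pdb(str(path.with_suffix(".pdb")))
    else:
        raise ValueError(f"unknown trajectory format {format!r}")


def read_ca_trajectory(path, sequence: ResidueSequence, provenance: str = "simulated") -> ConformationalEnsemble:
    """Read a multi-model PDB or DCD trajectory written by :func:`write_ca_trajectory`.

    Coordinates are returned in nm.  The file's atom count must equal the
    sequence length (C-alpha-only convention).
    """
    path = Path(path)
    try:
        if path.suffix.lower() == ".dcd":
            traj = md.load_dcd(str(path), top=str(path.with_suffix(".pdb")))
        else:
            traj = md.load(str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with file context
        raise ValueError(f"failed to parse trajectory {path}: {exc}") from exc
    if traj.n_atoms != len(sequence):
        raise ValueError(
            f"{path}: atom count {traj.n_atoms} does not match sequence "
            f"{sequence.id!r} of length {len(sequence)}"
        )
    return ConformationalEnsemble(sequence, traj.xyz.astype(np.float64), provenance)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

def init_random_coordinates(sequence: ResidueSequence, seed: int, max_retries: int = 1000) -> Conformation:
    """Self-avoiding random-walk starting coordinates for a chain.

    Successive beads are placed at exactly 0.38 nm; every bead pair is kept at
    >= 0.38 nm by rejection sampling with a bounded number of retries per bead.
    Deterministic for a fixed seed.
    """
    L = len(sequence)
    rng = np.random.default_rng(seed)
    coords = np.zeros((L, 3))
    for i in range(1, L):
        for attempt in range(max_retries + 1):
            if attempt == max_retries:
                raise RuntimeError(
                    f"self-avoiding walk failed at bead {i} after {max_retries} retries; "
                    "try a different seed"
                )
            v = rng.normal(size=3)
            v *= CA_BOND_LENGTH / np.linalg.norm(v)
            candidate = coords[i - 1] + v
            d = np.linalg.norm(coords[:i] - candidate, axis=1)
            # bonded neighbour sits at exactly 0.38 by construction
            if np.all(d >= CA_BOND_LENGTH - 1e-12):
                coords[i] = candidate
                break
    return Conformation(coords, sequence_ref=sequence.id)


def make_fixture_sequences(preset: str, lengths: Sequence[int], seed: int = 0) -> List[ResidueSequence]:
    """Built-in test sequences spanning the behaviours the simulator resolves.

    ``polyAla``: featureless homopolymer (no charges, no cation-pi pairs) --
    a random linear polymer reference.  ``charge_blocks``: alternating 5-residue
    blocks of glutamate and lysine, emulating charge-segregated disordered
    peptides whose blocks repel/attract through the screened electrostatic
    term.  ``random_mix``: uniform seeded draw over the 20 standard letters.
    """
    for L in lengths:
        if not 20 <= L <= 200:
            raise ValueError(f"fixture lengths must be within [20, 200], got {L}")
    rng = np.random.default_rng(seed)
    out = []
    for L in lengths:
        if preset == "polyAla":
            letters = "A" * L
        elif preset == "charge_blocks":
            letters = "".join(("E" if (i // 5) % 2 == 0 else "K") for i in range(L))
        elif preset == "random_mix":
            letters = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        else:
            raise ValueError(f"unknown fixture preset {preset!r}")
        out.append(ResidueSequence(f"{preset}_{L}", letters))
    return out
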