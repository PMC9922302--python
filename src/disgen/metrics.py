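"""Ensemble-comparison metrics.

The suite used to score a generated ensemble against a simulated reference:
contact-map error (MSE_c), mean-distance error (MSE_d), averaged per-pair
distance KLD (aKLD_d), an earth-mover's distance over conformations with
dRMSD cost (EMD-dRMSD), radius-of-gyration KLD (KLD_r), and the median
potential-energy difference (MED).  All distance-based metrics are invariant
under rigid motions and reflections of every conformation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.decomposition import PCA

from .cg import KB, ForceFieldParameters, cg_energy
from .ensembles_io import Conformation, ConformationalEnsemble, ResidueSequence
from .gan.features import distance_features, pair_indices

CONTACT_THRESHOLD = 0.8   # nm
CONTACT_PSEUDOCOUNT = 0.01
N_BINS = 50
BIN_PSEUDOCOUNT = 0.001


# ---------------------------------------------------------------------------
# contact maps
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ContactMap:
    """Symmetric matrix of contact frequencies p_ij in [0, 1]."""

    frequencies: np.ndarray
    threshold: float = CONTACT_THRESHOLD

    @property
    def L(self) -> int:
        return self.frequencies.shape[0]


def contact_map(ens: ConformationalEnsemble, threshold: float = CONTACT_THRESHOLD) -> ContactMap:
    """Per-pair fraction of frames with d_ij below the contact threshold."""
    L = len(ens.sequence)
    i, j = pair_indices(L)
    feats = distance_features(ens.xyz)
    p = (feats < threshold).mean(axis=0)
    mat = np.zeros((L, L))
    mat[i, j] = p
    mat[j, i] = p
    return ContactMap(mat, threshold)


def mse_c(ref: ContactMap, gen: ContactMap, pseudo: float = CONTACT_PSEUDOCOUNT) -> float:
    """Mean over i<j of (ln p_ij - ln p^_ij)^2; zero frequencies -> pseudo-count."""
    if ref.L != gen.L:
        raise ValueError(f"contact map sizes differ: {ref.L} vs {gen.L}")
    i, j = pair_indices(ref.L)
    p = np.where(ref.frequencies[i, j] == 0, pseudo, ref.frequencies[i, j])
    q = np.where(gen.frequencies[i, j] == 0, pseudo, gen.frequencies[i, j])
    return float(np.mean((np.log(p) - np.log(q)) ** 2))


# ---------------------------------------------------------------------------
# distance-based metrics
# ---------------------------------------------------------------------------

def _check_same_length(a: ConformationalEnsemble, b: ConformationalEnsemble) -> int:
    if len(a.sequence) != len(b.sequence):
        raise ValueError("ensembles have different sequence lengths")
    return len(a.sequence)


def mse_d(ref_ens: ConformationalEnsemble, gen_ens: ConformationalEnsemble) -> float:
    """Mean squared difference of per-pair average distances, nm^2."""
    _check_same_length(ref_ens, gen_ens)
    m = distance_features(ref_ens.xyz).mean(axis=0)
    mhat = distance_features(gen_ens.xyz).mean(axis=0)
    return float(np.mean((m - mhat) ** 2))


def histogram_kld(ref_values: np.ndarray, gen_values: np.ndarray,
                  n_bins: int = N_BINS, pseudo: float = BIN_PSEUDOCOUNT,
                  ) -> float:
    """Binned KLD(P||Q) over the pooled min-max range.

    P comes from the reference sample and Q from the generated one; bins with
    zero frequency take the pseudo-count (without renormalizing the rest).
    Degenerate ranges (min == max) return 0 with a warning.
    """
    ref_values = np.asarray(ref_values, dtype=float).ravel()
    gen_values = np.asarray(gen_values, dtype=float).ravel()
    if ref_values.size == 0 or gen_values.size == 0:
        raise ValueError("empty sample")
    lo = min(ref_values.min(), gen_values.min())
    hi = max(ref_values.max(), gen_values.max())
    if lo == hi:
        warnings.warn("degenerate value range; KLD undefined, returning 0")
        return 0.0
    edges = np.linspace(lo, hi, n_bins + 1)
    p = np.histogram(ref_values, bins=edges)[0] / ref_values.size
    q = np.histogram(gen_values, bins=edges)[0] / gen_values.size
    p = np.where(p == 0, pseudo, p)
    q = np.where(q == 0, pseudo, q)
    return float(np.sum(p * np.log(p / q)))


def akld_d(ref_ens: ConformationalEnsemble, gen_ens: ConformationalEnsemble,
           n_bins: int = N_BINS) -> float:
    """Mean histogram-KLD over all L(L-1)/2 per-pair distance distributions."""
    _check_same_length(ref_ens, gen_ens)
    ref_f = distance_features(ref_ens.xyz)
    gen_f = distance_features(gen_ens.xyz)
    return float(np.mean([
        histogram_kld(ref_f[:, p], gen_f[:, p], n_bins=n_bins)
        for p in range(ref_f.shape[1])
    ]))


def radius_of_gyration(conf) -> float:
    """Unweighted C-alpha radius of gyration, nm.

    Accepts a Conformation, an (L, 3) array, or an (N, L, 3) stack (then
    returns an (N,) array).
    """
    coords = conf.coords if isinstance(conf, Conformation) else np.asarray(conf)
    centered = coords - coords.mean(axis=-2, keepdims=True)
    rg2 = (centered**2).sum(axis=-1).mean(axis=-1)
    return np.sqrt(rg2) if np.ndim(rg2) else float(np.sqrt(rg2))


def kld_r(ref_ens: ConformationalEnsemble, gen_ens: ConformationalEnsemble) -> float:
    """Histogram-KLD between radius-of-gyration distributions."""
    return histogram_kld(radius_of_gyration(ref_ens.xyz), radius_of_gyration(gen_ens.xyz))


def drmsd(a: Conformation, b: Conformation) -> float:
    """Distance RMSD: sqrt of the mean over i<j of (d_ij - d^_ij)^2, nm."""
    if len(a) != len(b):
        raise ValueError("conformations have different lengths")
    return float(np.sqrt(np.mean((distance_features(a) - distance_features(b)) ** 2)))


def _drmsd_matrix(ref_f: np.ndarray, gen_f: np.ndarray) -> np.ndarray:
    """All-pairs dRMSD from two feature matrices, via squared-norm expansion."""
    P = ref_f.shape[1]
    sq = (
        (ref_f**2).sum(axis=1)[:, None]
        + (gen_f**2).sum(axis=1)[None, :]
        - 2.0 * ref_f @ gen_f.T
    )
    return np.sqrt(np.maximum(sq, 0.0) / P)


def emd_drmsd(ref_ens: ConformationalEnsemble, gen_ens: ConformationalEnsemble,
              max_n: int = 1000, seed: int = 0) -> float:
    """Earth-mover's distance approximation over conformations with dRMSD cost.

    Both ensembles are subsampled (seeded) to equal counts of at most
    ``max_n``; the optimal one-to-one pairing is found with the Hungarian
    algorithm and the mean matched dRMSD is returned.
    """
    _check_same_length(ref_ens, gen_ens)
    n = min(len(ref_ens), len(gen_ens), max_n)
    ref = ref_ens.subsample(n, seed)
    gen = gen_ens.subsample(n, seed + 1)
    cost = _drmsd_matrix(distance_features(ref.xyz), distance_features(gen.xyz))
    rows, cols = linear_sum_assignment(cost)
    return float(cost[rows, cols].mean())


def median_energy_difference(ref_ens: ConformationalEnsemble,
                             gen_ens: ConformationalEnsemble,
                             seq: ResidueSequence,
                             ff: ForceFieldParameters) -> float:
    """MED: median potential energy of generated minus median of reference, kJ/mol."""
    sp = ff.sequence_arrays(seq)
    e_ref = np.array([cg_energy(c, seq, ff, seq_params=sp).total for c in ref_ens])
    e_gen = np.array([cg_energy(c, seq, ff, seq_params=sp).total for c in gen_ens])
    return float(np.median(e_gen) - np.median(e_ref))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    """The six-score comparison record for a (reference, generated) ensemble pair."""

    mse_c: float
    mse_d: float
    akld_d: float
    emd_drmsd: float
    kld_r: float
    med: float
    n_ref: int
    n_gen: int
    seed: int = 0

    def as_dict(self) -> dict:
        return {
            "MSE_c": self.mse_c,
            "MSE_d_nm2": self.mse_d,
            "aKLD_d": self.akld_d,
            "EMD_dRMSD_nm": self.emd_drmsd,
            "KLD_r": self.kld_r,
            "MED_kJ_mol": self.med,
            "n_ref": self.n_ref,
            "n_gen": self.n_gen,
            "seed": self.seed,
        }


def metric_report(ref_ens: ConformationalEnsemble, gen_ens: ConformationalEnsemble,
                  seq: ResidueSequence, ff: ForceFieldParameters,
                  emd_max_n: int = 1000, seed: int = 0) -> MetricReport:
    """Compute all six metrics for one ensemble pair."""
    return MetricReport(
        mse_c=mse_c(contact_map(ref_ens), contact_map(gen_ens)),
        mse_d=mse_d(ref_ens, gen_ens),
        akld_d=akld_d(ref_ens, gen_ens),
        emd_drmsd=emd_drmsd(ref_ens, gen_ens, max_n=emd_max_n, seed=seed),
        kld_r=kld_r(ref_ens, gen_ens),
        med=median_energy_difference(ref_ens, gen_ens, seq, ff),
        n_ref=len(ref_ens),
        n_gen=len(gen_ens),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# PCA potentials of mean force
# ---------------------------------------------------------------------------

@dataclass
class PmfMap:
    """Free-energy surface over the first two principal components, kJ/mol.

    Cells never visited are NaN (missing), not zero or infinity.
    """

    free_energy: np.ndarray
    xedges: np.ndarray
    yedges: np.ndarray
    temperature: float = 298.0


def pca_pmf(ref_ens: ConformationalEnsemble, query_ens: ConformationalEnsemble,
            bins: int = 40, temperature: float = 298.0,
            ) -> Tuple[PmfMap, PmfMap]:
    """Potentials of mean force in the PCA space of the reference ensemble.

    PCA is fitted on the reference distance features only; both ensembles are
    projected onto that basis and binned on the reference-spanning grid
    extended to cover the query.  Free energy is -k_B T ln(frequency).
    """
    _check_same_length(ref_ens, query_ens)
    ref_f = distance_features(ref_ens.xyz)
    if ref_f.shape[0] < 3:
        raise ValueError("reference too small to fit 2 principal components")
    pca = PCA(n_components=2)
    ref_p = pca.fit_transform(ref_f)
    if pca.explained_variance_[1] <= 0 or not np.isfinite(pca.explained_variance_).all():
        raise ValueError("reference ensemble is rank-deficient in distance features")
    query_p = pca.transform(distance_features(query_ens.xyz))
    lo = np.minimum(ref_p.min(axis=0), query_p.min(axis=0))
    hi = np.maximum(ref_p.max(axis=0), query_p.max(axis=0))
    xedges = np.linspace(lo[0], hi[0], bins + 1)
    yedges = np.linspace(lo[1], hi[1], bins + 1)

    def pmf(points: np.ndarray) -> PmfMap:
        h = np.histogram2d(points[:, 0], points[:, 1], bins=(xedges, yedges))[0]
        freq = h / points.shape[0]
        with np.errstate(divide="ignore"):
            fe = np.where(freq > 0, -KB * temperature * np.log(freq), np.nan)
        return PmfMap(fe, xedges, yedges, temperature)

    return pmf(ref_p), pmf(query_p)


# ---------------------------------------------------------------------------
# memorization search
# ---------------------------------------------------------------------------

def memorization_search(gen_ens: ConformationalEnsemble,
                        training_ensembles: Sequence[ConformationalEnsemble],
                        crop_len: Optional[int] = None,
                        block: int = 2000) -> np.ndarray:
    """Nearest-neighbour dRMSD of each generated conformation over a training pool.

    All conformations are cropped to ``crop_len`` leading residues (default:
    the shortest length present).  Returns one minimum dRMSD per generated
    conformation; compared against the same search run with held-out
    simulation frames, it gauges whether the generator memorizes training
    geometry.
    """
    if not training_ensembles:
        raise ValueError("empty training pool")
    lengths = [len(e.sequence) for e in training_ensembles] + [len(gen_ens.sequence)]
    crop = crop_len if crop_len is not None else min(lengths)
    if crop > min(lengths):
        raise ValueError("crop_len exceeds the shortest ensemble length")
    gen_f = distance_features(gen_ens.xyz[:, :crop])
    best = np.full(gen_f.shape[0], np.inf)
    for ens in training_ensembles:
        xyz = ens.xyz[:, :crop]
        for start in range(0, xyz.shape[0], block):
            train_f = distance_features(xyz[start:start + block])
            d = _drmsd_matrix(gen_f, train_f)
            best = np.minimum(best, d.min(axis=1))
    return best
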