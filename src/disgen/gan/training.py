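"""GAN training loop, sampling, and checkpointing.

An epoch follows the crop-balancing scheme: sequences are assigned to crop
lengths, ``n_frames`` frames are drawn per assignment with fresh random crop
offsets, and same-length batches alternate discriminator and generator
updates (1:1 for the non-saturated and hinge objectives; ``critic_iters``:1
for the Wasserstein mode).  Each discriminator and the generator have their
own Adam optimizer.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ..ensembles_io import ConformationalEnsemble, ResidueSequence
from ..nn import Adam
from ..nn import autodiff as ad
from ..nn.autodiff import Tensor
from .crops import CropPlan, assign_crops, crop_frames
from .features import (
    FeatureStandardizer,
    clash_fraction,
    distance_features,
    estimate_clash_threshold,
    fit_standardizer,
    pair_indices,
)
from .losses import (
    MODES,
    clash_term,
    loss_discriminator,
    loss_generator,
    topk_count,
    wgan_gradient_penalty,
)
from .models import (
    ConformationGenerator,
    DiscriminatorArchitecture,
    DistanceDiscriminator,
    GeneratorArchitecture,
)


@dataclass
class TrainingConfiguration:
    """Objective and optimization settings.

    ``x_t=None`` estimates the clash threshold (0.1 percentile of training
    non-bonded distances) from the data.  The ``tiny`` preset shrinks network
    widths and epoch counts only; loss definitions are identical across
    presets.
    """

    objective: str = "nonsaturated"
    w_C: float = 0.3
    x_t: Optional[float] = None
    batch: int = 192
    epochs: int = 50
    lr_G: float = 0.00025
    lr_D: float = 0.0004
    beta1: float = 0.0
    beta2: float = 0.9
    topk_gamma: float = 0.99
    topk_nu: float = 0.5
    gp_lambda: float = 10.0
    critic_iters: int = 5
    noise_sigma0: float = 0.025     # nm, coordinate noise at epoch 0
    noise_anneal_frac: float = 0.25  # fraction of epochs over which sigma decays to 0
    add_coordinate_noise: Optional[bool] = None  # default: only in hinge_topk mode
    symmetric_noise: bool = False   # also perturb generated coordinates (instance noise)
    d_steps: int = 1                # discriminator updates per generator update
    pretrain_epochs: int = 0        # moment-matching generator warm-start epochs
    pretrain_lr: float = 1e-3       # warm-start learning rate (momentum Adam)
    pretrain_restarts: int = 3      # generator inits probed before the warm start
    pretrain_probe_epochs: int = 10  # probe length per candidate init
    lr_decay_at: Tuple[float, ...] = ()  # epoch fractions at which lrs halve
    checkpoint_every: int = 0       # epochs between validation checkpoints (0 = off)
    validation_fraction: float = 0.1  # training frames held back for checkpointing
    float32: bool = True            # run training math in single precision
    seed: int = 0
    preset: str = "paper"
    plan: CropPlan = field(default_factory=CropPlan)
    gen_arch: GeneratorArchitecture = field(default_factory=GeneratorArchitecture)
    disc_hidden: Tuple[int, ...] = (256, 256)

    def __post_init__(self) -> None:
        if self.objective not in MODES:
            raise ValueError(f"objective must be one of {MODES}")
        if self.w_C < 0:
            raise ValueError("w_C must be non-negative")
        for name in ("lr_G", "lr_D"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def tiny(cls, sequences_lengths: Sequence[int] = (20,), n_sequences: int = 2,
             **overrides) -> "TrainingConfiguration":
        """Desk-scale preset: shrunken widths and epoch counts, identical losses.

        The default depth (60 warm-start + 400 adversarial epochs, learning
        rates halved at 50% and 75%) is the converged recipe for the two
        length-20 fixture peptides.
        """
        plan = CropPlan(lengths=tuple(sorted(set(sequences_lengths))),
                        c_max=n_sequences, n_frames=1750)
        defaults = dict(
            preset="tiny",
            plan=plan,
            epochs=400,
            pretrain_epochs=60,
            pretrain_restarts=4,
            pretrain_probe_epochs=12,
            lr_decay_at=(0.5, 0.75),
            checkpoint_every=25,
            gen_arch=GeneratorArchitecture.tiny(),
            disc_hidden=(64, 64),
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def noise_enabled(self) -> bool:
        if self.add_coordinate_noise is not None:
            return self.add_coordinate_noise
        return self.objective == "hinge_topk"

    def noise_sigma(self, epoch: int) -> float:
        if not self.noise_enabled or self.noise_sigma0 <= 0:
            return 0.0
        window = max(1, int(math.ceil(self.noise_anneal_frac * self.epochs)))
        return max(0.0, self.noise_sigma0 * (1.0 - epoch / window))

    def config_hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


@dataclass
class TrainedModel:
    """Generator weights plus everything needed to sample and to resume scoring."""

    generator: ConformationGenerator
    discriminators: Dict[int, DistanceDiscriminator]
    standardizer: FeatureStandardizer
    config: TrainingConfiguration
    x_t: float
    log: List[dict] = field(default_factory=list)

    def sample_ensemble(self, seq: ResidueSequence, n: int, seed: int,
                        batch_cap: int = 512) -> ConformationalEnsemble:
        """n independent conformations from fresh latent draws; seed-reproducible."""
        if n < 1:
            raise ValueError("n must be >= 1")
        rng = np.random.default_rng(seed)
        xyz = self.generator.sample(seq, n, rng, batch_cap=batch_cap)
        return ConformationalEnsemble(seq, xyz, provenance="generated")

    # -- checkpoint container ---------------------------------------------

    def save(self, path) -> None:
        arrays = {f"gen.{k}": v for k, v in self.generator.state_dict().items()}
        for L, disc in self.discriminators.items():
            arrays.update({f"disc{L}.{k}": v for k, v in disc.state_dict().items()})
        arrays["std.m"] = self.standardizer.m
        arrays["std.s"] = self.standardizer.s
        meta = {
            "config": _jsonable(asdict(self.config)),
            "config_hash": self.config.config_hash(),
            "x_t": self.x_t,
            "disc_lengths": sorted(self.discriminators),
            "log": _jsonable(self.log),
        }
        np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
                 **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        with np.load(path) as data:
            meta = json.loads(bytes(data["__meta__"]).decode())
            arrays = {k: data[k] for k in data.files if k != "__meta__"}
        cfg_dict = meta["config"]
        cfg_dict["plan"] = CropPlan(lengths=tuple(cfg_dict["plan"]["lengths"]),
                                    c_max=cfg_dict["plan"]["c_max"],
                                    n_frames=cfg_dict["plan"]["n_frames"])
        cfg_dict["gen_arch"] = GeneratorArchitecture(**cfg_dict["gen_arch"])
        cfg_dict["disc_hidden"] = tuple(cfg_dict["disc_hidden"])
        cfg = TrainingConfiguration(**cfg_dict)
        std = FeatureStandardizer(arrays.pop("std.m"), arrays.pop("std.s"))
        gen = ConformationGenerator(cfg.gen_arch)
        gen.load_state_dict({k[4:]: v for k, v in arrays.items() if k.startswith("gen.")})
        darch = DiscriminatorArchitecture(
            hidden=cfg.disc_hidden,
            output="probability" if cfg.objective == "nonsaturated" else "score",
        )
        discs = {}
        for L in meta["disc_lengths"]:
            d = DistanceDiscriminator(L, std, darch)
            pre = f"disc{L}."
            d.load_state_dict({k[len(pre):]: v for k, v in arrays.items()
                               if k.startswith(pre)})
            discs[L] = d
        return cls(gen, discs, std, cfg, meta["x_t"], meta["log"])


def sample_ensemble(model: TrainedModel, seq: ResidueSequence, n: int, seed: int,
                    batch_cap: int = 512) -> ConformationalEnsemble:
    return model.sample_ensemble(seq, n, seed, batch_cap)


def train(
    data: Sequence[ConformationalEnsemble],
    cfg: TrainingConfiguration,
    standardizer: Optional[FeatureStandardizer] = None,
    callback=None,
) -> TrainedModel:
    """Train the conditional GAN on a collection of simulated ensembles.

    Returns the trained model with a per-epoch log (losses, clash fraction
    of generated batches, noise sigma, seed).  Deterministic for a fixed
    configuration seed.
    """
    if not data:
        raise ValueError("no training ensembles")
    with ad.dtype_context(np.float32 if cfg.float32 else np.float64):
        return _train_impl(data, cfg, standardizer, callback)


def _train_impl(data, cfg, standardizer, callback):
    # the standardizer and clash threshold describe the full training set;
    # the validation slice below is held back from batching only
    std = standardizer if standardizer is not None else fit_standardizer(data)
    x_t = cfg.x_t if cfg.x_t is not None else estimate_clash_threshold(data)

    validation: Dict[str, ConformationalEnsemble] = {}
    if cfg.checkpoint_every > 0 and cfg.validation_fraction > 0:
        # hold back a slice of every ensemble for checkpoint selection
        split_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 977]))
        held_data = []
        for ens in data:
            n_val = max(2, int(cfg.validation_fraction * len(ens)))
            idx = split_rng.permutation(len(ens))
            validation[ens.sequence.id] = ConformationalEnsemble(
                ens.sequence, ens.xyz[np.sort(idx[:n_val])], ens.provenance)
            held_data.append(ConformationalEnsemble(
                ens.sequence, ens.xyz[np.sort(idx[n_val:])], ens.provenance))
        data = held_data
    by_id = {e.sequence.id: e for e in data}
    sequences = [e.sequence for e in data]

    ss = np.random.SeedSequence(cfg.seed)
    seeds = ss.generate_state(4)
    rng = np.random.default_rng(seeds[0])
    gen = ConformationGenerator(cfg.gen_arch, seed=int(seeds[1] % 2**31))
    darch = DiscriminatorArchitecture(
        hidden=cfg.disc_hidden,
        output="probability" if cfg.objective == "nonsaturated" else "score",
    )
    discs = {
        L: DistanceDiscriminator(L, std, darch, seed=int((seeds[2] + L) % 2**31))
        for L in cfg.plan.lengths
    }
    opt_G = Adam(gen.parameters(), lr=cfg.lr_G, beta1=cfg.beta1, beta2=cfg.beta2)
    opt_D = {L: Adam(d.parameters(), lr=cfg.lr_D, beta1=cfg.beta1, beta2=cfg.beta2)
             for L, d in discs.items()}

    log: List[dict] = []
    if cfg.pretrain_epochs > 0:
        _pretrain_generator(gen, by_id, sequences, std, cfg, rng, x_t, log)

    best_state = None
    best_score = np.inf
    best_epoch = -1

    def validate(epoch: int) -> None:
        """Checkpoint selection by validation aKLD_d (held-back training frames)."""
        nonlocal best_state, best_score, best_epoch
        from ..metrics import akld_d

        vrng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1811, epoch + 1]))
        scores = []
        for seq_id, val_ens in validation.items():
            seq = val_ens.sequence
            xyz = gen.sample(seq, 400, vrng)
            scores.append(akld_d(val_ens, ConformationalEnsemble(seq, xyz, "generated")))
        score = float(np.mean(scores))
        log.append({"epoch": epoch, "phase": "validation", "akld_d": score,
                    "seed": cfg.seed})
        if score < best_score:
            best_score, best_epoch = score, epoch
            best_state = gen.state_dict()

    decay_epochs = {int(frac * cfg.epochs) for frac in cfg.lr_decay_at}
    if validation:
        validate(-1)  # the warm-started generator is a candidate too
    for epoch in range(cfg.epochs):
        if epoch in decay_epochs and epoch > 0:
            opt_G.lr *= 0.5
            for o in opt_D.values():
                o.lr *= 0.5
        sigma = cfg.noise_sigma(epoch)
        assignment = assign_crops(sequences, cfg.plan, seed=int(rng.integers(2**31)))
        epoch_stats = {"epoch": epoch, "sigma": sigma, "seed": cfg.seed,
                       "loss_D": [], "loss_G": [], "clash_fraction": []}
        for L, members in assignment.items():
            batches = _epoch_batches(by_id, members, L, cfg, rng, sigma)
            disc, optD = discs[L], opt_D[L]
            i_idx, j_idx = pair_indices(L)
            d_per_g = cfg.critic_iters if cfg.objective == "wasserstein_gp" else cfg.d_steps
            pending_critic = 0
            for real_x, real_oh in batches:
                B = real_x.shape[0]
                # one generator forward serves both updates: its detached
                # features feed the discriminator step, and the same graph is
                # then scored against the updated discriminator for the
                # generator step
                z = Tensor(rng.standard_normal((B, L, cfg.gen_arch.n_z)))
                coords = gen(z, real_oh)
                if sigma > 0 and cfg.symmetric_noise:
                    coords = coords + Tensor(rng.normal(scale=sigma, size=(B, L, 3)))
                dists = ad.pairwise_distances(coords, i_idx, j_idx)
                fake_x = dists.data.copy()
                real_feat = distance_features(real_x)
                d_real = disc(Tensor(real_feat), real_oh)
                d_fake = disc(Tensor(fake_x), real_oh, update_power_iter=False)
                if cfg.objective == "wasserstein_gp":
                    eps = rng.uniform(size=(B, 1))
                    interp = eps * real_feat + (1 - eps) * fake_x
                    gp = wgan_gradient_penalty(
                        disc.gradient_norm_expression(Tensor(interp), real_oh))
                    lD = loss_discriminator(d_real, d_fake, cfg.objective,
                                            gradient_penalty=gp, gp_lambda=cfg.gp_lambda)
                else:
                    lD = loss_discriminator(d_real, d_fake, cfg.objective)
                if not np.isfinite(lD.item()):
                    raise FloatingPointError(
                        f"non-finite discriminator loss at epoch {epoch}, L={L}")
                disc.zero_grad()
                lD.backward()
                optD.step()
                epoch_stats["loss_D"].append(lD.item())

                # --- generator step (after d_per_g discriminator updates) ---
                pending_critic += 1
                if pending_critic < d_per_g:
                    continue
                pending_critic = 0
                d_fake = disc(dists, real_oh, update_power_iter=False)
                k = (topk_count(B, cfg.topk_nu, cfg.topk_gamma, epoch)
                     if cfg.objective == "hinge_topk" else None)
                lG = loss_generator(d_fake, dists, L, cfg.objective,
                                    w_C=cfg.w_C, x_t=x_t, topk=k)
                if not np.isfinite(lG.item()):
                    raise FloatingPointError(
                        f"non-finite generator loss at epoch {epoch}, L={L}")
                gen.zero_grad()
                disc.zero_grad()
                lG.backward()
                opt_G.step()
                epoch_stats["loss_G"].append(lG.item())
                epoch_stats["clash_fraction"].append(
                    clash_fraction(dists.data, L, x_t))
        for key in ("loss_D", "loss_G", "clash_fraction"):
            epoch_stats[key] = float(np.mean(epoch_stats[key])) if epoch_stats[key] else float("nan")
        log.append(epoch_stats)
        if validation and ((epoch + 1) % cfg.checkpoint_every == 0
                           or epoch == cfg.epochs - 1):
            validate(epoch)
        if callback is not None:
            callback(epoch, epoch_stats)

    if best_state is not None:
        gen.load_state_dict(best_state)
        log.append({"phase": "selection", "best_epoch": best_epoch,
                    "best_val_akld_d": best_score, "seed": cfg.seed})

    return TrainedModel(gen, discs, std, cfg, float(x_t), log)


def _moment_loss(f: Tensor, target: np.ndarray) -> Tensor:
    """Squared mismatch of per-column batch mean and SD against a target sample."""
    mu = f.mean(axis=0)
    sd = ad.sqrt(((f - mu.reshape(1, -1)) ** 2.0).mean(axis=0) + 1e-8)
    return (((mu - Tensor(target.mean(axis=0))) ** 2.0).mean()
            + ((sd - Tensor(target.std(axis=0))) ** 2.0).mean())


def _rg_quantile_loss(coords: Tensor, real_x: np.ndarray) -> Tensor:
    """Quantile (sorted-value) mismatch of the radius-of-gyration distribution.

    Directly supervises the global compaction modes that per-feature moments
    barely constrain; nm^2 scale.
    """
    mu = coords.mean(axis=1, keepdims=True)
    c = coords - mu
    rg = ad.sqrt((c * c).sum(axis=2).mean(axis=1) + 1e-10)
    rg_sorted = rg[np.argsort(rg.data)]
    centered = real_x - real_x.mean(axis=1, keepdims=True)
    rg_real = np.sort(np.sqrt((centered**2).sum(axis=2).mean(axis=1)))
    return ((rg_sorted - Tensor(rg_real)) ** 2.0).mean()


def _run_pretrain_epochs(gen, opt, n_epochs, by_id, sequences, std, cfg, rng, x_t,
                         log=None) -> float:
    """Run warm-start epochs; returns the mean loss of the final epoch."""
    last = float("inf")
    for epoch in range(n_epochs):
        assignment = assign_crops(sequences, cfg.plan, seed=int(rng.integers(2**31)))
        losses = []
        for L, members in assignment.items():
            i_idx, j_idx = pair_indices(L)
            m_vec, s_vec = std.vectors_for_length(L)
            single = [b for seq in members
                      for b in _epoch_batches(by_id, [seq], L, cfg, rng, 0.0)]
            rng.shuffle(single)
            for real_x, real_oh in single:
                B = real_x.shape[0]
                real_f = (distance_features(real_x) - m_vec) / s_vec
                z = Tensor(rng.standard_normal((B, L, cfg.gen_arch.n_z)))
                coords = gen(z, real_oh)
                dists = ad.pairwise_distances(coords, i_idx, j_idx)
                f = (dists - Tensor(m_vec)) * Tensor(1.0 / s_vec)
                loss = (_moment_loss(f, real_f)
                        + _rg_quantile_loss(coords, real_x)
                        + cfg.w_C * clash_term(dists, L, x_t).mean())
                gen.zero_grad()
                loss.backward()
                opt.step()
                losses.append(loss.item())
        last = float(np.mean(losses))
        if log is not None:
            log.append({"epoch": -n_epochs + epoch, "phase": "pretrain",
                        "loss_G": last, "seed": cfg.seed})
    return last


def _pretrain_generator(gen, by_id, sequences, std, cfg, rng, x_t, log):
    """Moment-matching warm start for the generator, with multi-start probing.

    Per batch (one sequence per batch, so the statistics stay conditional),
    the generated standardized distance features must match the real batch's
    per-feature mean and SD, the generated radius-of-gyration distribution
    must match the real batch's quantiles, and the clash term is included.
    Because matching the spreads is only possible with a live latent path,
    this warm start protects the subsequent adversarial phase from
    collapsing onto a deterministic output.

    The warm-start landscape is init-sensitive, so ``pretrain_restarts``
    candidate initializations are each probed for ``pretrain_probe_epochs``
    and the one with the lowest training loss continues (selection uses the
    warm-start loss only).  Momentum Adam (0.9/0.999): this phase is an
    ordinary regression problem, not an adversarial game.
    """
    from .models import ConformationGenerator

    args = (by_id, sequences, std, cfg, rng, x_t)
    if cfg.pretrain_restarts > 1 and cfg.pretrain_probe_epochs > 0:
        candidates = [gen] + [
            ConformationGenerator(cfg.gen_arch, seed=int(rng.integers(2**31)))
            for _ in range(cfg.pretrain_restarts - 1)
        ]
        scored = []
        for cand in candidates:
            opt = Adam(cand.parameters(), lr=cfg.pretrain_lr, beta1=0.9, beta2=0.999)
            score = _run_pretrain_epochs(cand, opt, cfg.pretrain_probe_epochs, *args)
            scored.append((score, cand, opt))
        score, best, opt = min(scored, key=lambda t: t[0])
        if best is not gen:
            gen.load_state_dict(best.state_dict())
            opt = Adam(gen.parameters(), lr=cfg.pretrain_lr, beta1=0.9, beta2=0.999)
        log.append({"phase": "pretrain", "epoch": -cfg.pretrain_epochs - 1,
                    "probe_losses": [round(s, 4) for s, _, _ in scored],
                    "loss_G": score, "seed": cfg.seed})
    else:
        opt = Adam(gen.parameters(), lr=cfg.pretrain_lr, beta1=0.9, beta2=0.999)
    _run_pretrain_epochs(gen, opt, cfg.pretrain_epochs, *args, log=log)


def _epoch_batches(by_id, members, L, cfg, rng, sigma):
    """Gather one epoch's same-length batches for one crop length."""
    xs, ohs = [], []
    for seq in members:
        ens = by_id[seq.id]
        N = len(ens)
        take = min(cfg.plan.n_frames, N)
        idx = rng.choice(N, size=take, replace=cfg.plan.n_frames > N)
        xyz = ens.xyz[idx]
        if len(seq) == L:
            xs.append(xyz)
            ohs.append(np.broadcast_to(seq.onehot, (take, L, 20)))
        else:
            cropped, oh = crop_frames(xyz, seq.onehot, L, rng)
            xs.append(cropped)
            ohs.append(oh)
    x = np.concatenate(xs)
    oh = np.concatenate(ohs)
    perm = rng.permutation(x.shape[0])
    x, oh = x[perm], oh[perm]
    if sigma > 0:
        x = x + rng.normal(scale=sigma, size=x.shape)
    n_batches = x.shape[0] // cfg.batch
    return [
        (x[b * cfg.batch:(b + 1) * cfg.batch], oh[b * cfg.batch:(b + 1) * cfg.batch])
        for b in range(max(1, n_batches))
    ]


def train_repeated(
    data: Sequence[ConformationalEnsemble],
    cfg: TrainingConfiguration,
    validation: Sequence[ConformationalEnsemble],
    n_runs: int = 3,
    n_sample: int = 1000,
) -> Tuple[TrainedModel, List[float]]:
    """Repeat training with different seeds; keep the best validation aKLD_d."""
    from ..metrics import akld_d

    scores: List[float] = []
    best: Optional[TrainedModel] = None
    for run in range(n_runs):
        model = train(data, replace(cfg, seed=cfg.seed + run))
        vals = []
        for ens in validation:
            gen_ens = model.sample_ensemble(ens.sequence, n_sample, seed=cfg.seed + 7000 + run)
            vals.append(akld_d(ens, gen_ens))
        scores.append(float(np.mean(vals)))
        if best is None or scores[-1] == min(scores):
            best = model
    return best, scores
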