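"""Shared fixtures.

The expensive pipeline pieces (simulated reference ensembles, trained
tiny models) are session-scoped and lazily built, so unit tests stay fast
while distribution-level tests share one set of reference data.  All seeds
are fixed here.
"""

from __future__ import annotations


import pytest

from disgen.cg import ForceFieldParameters, reference_protocol
from disgen.ensembles_io import make_fixture_sequences

# pipeline seeds, fixed once
SIM_SEEDS = {"polyA_train": 101, "cblk_train": 202, "polyA_held": 303, "cblk_held": 404}
GAN_SEEDS = (0, 1, 2)
EVAL_SEED = 505

# problem sizes for the in-suite pipeline test; the package-default training
# depth (TrainingConfiguration.tiny()) is exercised by scripts/acceptance.py
TRAIN_SCALE = 0.08        # 2,000 reference frames per peptide
HELD_SCALE = 0.04         # 1,000 independent held-out frames per peptide
SUITE_GAN_EPOCHS = 60     # shortened adversarial depth for the suite run


@pytest.fixture(scope="session")
def ff():
    return ForceFieldParameters.default()


@pytest.fixture(scope="session")
def fixture_peptides():
    polyA = make_fixture_sequences("polyAla", [20])[0]
    cblk = make_fixture_sequences("charge_blocks", [20])[0]
    return polyA, cblk


@pytest.fixture(scope="session")
def cg_reference_data(ff, fixture_peptides):
    """Simulated ensembles for the pipeline tests: training and independent
    held-out frames for each of the two length-20 fixture peptides."""
    polyA, cblk = fixture_peptides
    return {
        "polyA_train": reference_protocol(polyA, ff, scale=TRAIN_SCALE,
                                          seed=SIM_SEEDS["polyA_train"]),
        "cblk_train": reference_protocol(cblk, ff, scale=TRAIN_SCALE,
                                         seed=SIM_SEEDS["cblk_train"]),
        "polyA_held": reference_protocol(polyA, ff, scale=HELD_SCALE,
                                         seed=SIM_SEEDS["polyA_held"]),
        "cblk_held": reference_protocol(cblk, ff, scale=HELD_SCALE,
                                        seed=SIM_SEEDS["cblk_held"]),
    }


@pytest.fixture(scope="session")
def tiny_gan_runs(cg_reference_data, fixture_peptides):
    """Tiny-preset GAN training runs: three seeds with the clash term and one
    ablation without it, each evaluated against the held-out simulations."""
    from disgen.gan.features import distance_features, nonbonded_feature_mask
    from disgen.gan.training import TrainingConfiguration, train
    from disgen.metrics import akld_d, kld_r

    polyA, cblk = fixture_peptides
    train_data = [cg_reference_data["polyA_train"], cg_reference_data["cblk_train"]]
    held = {"polyAla_20": cg_reference_data["polyA_held"],
            "cblk": cg_reference_data["cblk_held"]}
    mask = nonbonded_feature_mask(20)

    def evaluate(model):
        out = {}
        for seq, held_ens in ((polyA, cg_reference_data["polyA_held"]),
                              (cblk, cg_reference_data["cblk_held"])):
            gen = model.sample_ensemble(seq, 1000, seed=EVAL_SEED)
            feats = distance_features(gen.xyz)
            out[seq.id] = {
                "kld_r": kld_r(held_ens, gen),
                "akld_d": akld_d(held_ens, gen),
                "clash_fraction": float((feats[:, mask] < model.x_t).mean()),
            }
        return out

    runs = []
    for seed in GAN_SEEDS:
        cfg = TrainingConfiguration.tiny(seed=seed, epochs=SUITE_GAN_EPOCHS)
        model = train(train_data, cfg)
        runs.append({"seed": seed, "w_C": cfg.w_C, "x_t": model.x_t,
                     "scores": evaluate(model), "log": model.log})
    cfg0 = TrainingConfiguration.tiny(seed=GAN_SEEDS[0], w_C=0.0,
                                      epochs=SUITE_GAN_EPOCHS)
    ablation = train(train_data, cfg0)
    runs.append({"seed": GAN_SEEDS[0], "w_C": 0.0, "x_t": ablation.x_t,
                 "scores": evaluate(ablation), "log": ablation.log})
    return runs
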