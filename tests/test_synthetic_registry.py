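import dataclasses

import numpy as np
import pytest

from fertiopt import SimulationConfig, default_config, simulate_cohort
from fertiopt.core_registry import registry_tables_equal


def test_determinism_same_config():
    a, _ = simulate_cohort(default_config(n_patients=800, seed=5))
    b, _ = simulate_cohort(default_config(n_patients=800, seed=5))
    assert registry_tables_equal(a, b)


def test_seed_changes_output():
    a, _ = simulate_cohort(default_config(n_patients=800, seed=5))
    b, _ = simulate_cohort(default_config(n_patients=800, seed=6))
    assert not registry_tables_equal(a, b)


def test_patient_prefix_stable_across_cohort_size():
    """The first n patients are identical whether you simulate n or 2n."""
    small, _ = simulate_cohort(default_config(n_patients=400, seed=11))
    large, _ = simulate_cohort(default_config(n_patients=800, seed=11))
    ids = set(small.retrievals["patient_id"])
    lr = large.retrievals[large.retrievals["patient_id"].isin(ids)].reset_index(drop=True)
    lt = large.transfers[large.transfers["patient_id"].isin(ids)].reset_index(drop=True)
    assert registry_tables_equal(small, type(small)(lr, lt))


def test_output_passes_validation(small_cohort):
    tables, _ = small_cohort
    tables.validate()  # raises on failure
    r, t = tables.retrievals, tables.transfers
    # transfers only exist for labelled cycles and match the cycle's label
    key = r.set_index(["patient_id", "cycle_index"])["transfer_day_label"]
    got = key.reindex(list(zip(t["patient_id"], t["retrieval_cycle_index"])))
    assert (got.to_numpy() == t["transfer_day_label"].to_numpy()).all()
    # frozen blastocysts only defined for day-5 cycles
    d5 = r["transfer_day_label"] == "day5"
    assert r.loc[~d5, "n_blastocysts_frozen"].isna().all()
    # cancelled cycles have no transfers
    assert not (got == "none").any()


def test_cycle_indices_start_at_one(small_cohort):
    tables, _ = small_cohort
    first = tables.retrievals.groupby("patient_id")["cycle_index"].min()
    assert (first == 1).all()
    assert tables.retrievals["cycle_index"].max() <= 2


def test_latents_align_with_registry(small_cohort):
    tables, truth = small_cohort
    r = tables.retrievals
    lat = truth.latents
    assert len(lat) == len(r)
    assert (lat["p_day5_true"].between(0, 1)).all()
    d5 = r["transfer_day_label"].to_numpy() == "day5"
    assert np.isfinite(lat["yield_p_true"].to_numpy()[d5]).all()


def test_day5_share_matches_latent_mean(default_cohort):
    """LLN check: among labelled cycles, the empirical day-5 share matches the
    mean latent probability (cancellation is drawn independently)."""
    tables, truth = default_cohort
    r = tables.retrievals
    labelled = r["transfer_day_label"].isin(["day3", "day5"]).to_numpy()
    share = (r["transfer_day_label"].to_numpy()[labelled] == "day5").mean()
    expected = truth.latents["p_day5_true"].to_numpy()[labelled].mean()
    assert abs(share - expected) < 0.01


def test_ground_truth_save(tmp_path, small_cohort):
    _, truth = small_cohort
    truth.save(tmp_path)
    assert (tmp_path / "ground_truth.yaml").exists()
    assert (tmp_path / "region_effects.csv").exists()
    assert (tmp_path / "latents.csv").exists()


def test_config_yaml_roundtrip(tmp_path):
    cfg = default_config(n_patients=123, seed=9)
    cfg.to_yaml(tmp_path / "cfg.yaml")
    back = SimulationConfig.from_yaml(tmp_path / "cfg.yaml")
    assert dataclasses.asdict(back) == dataclasses.asdict(cfg)


@pytest.mark.parametrize("overrides", [
    {"n_patients": 0},
    {"age_group_probs": (0.5, 0.5, 0.0, 0.0, 0.0, 0.5)},
    {"yield_overdispersion": 1.5},
    {"dropout_prob": 1.4},
    {"region_count": 1},
    {"lb_day5_prob_age": (0.5, 0.5, 0.5, 0.5, 0.5, 1.0)},
])
def test_config_validation_rejects(overrides):
    cfg = default_config(n_patients=100, seed=1)
    for k, v in overrides.items():
        setattr(cfg, k, v)
    with pytest.raises(ValueError):
        cfg.validate()
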