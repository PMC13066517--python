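"""The synthetic-cohort generator must honour its own statistical contract."""

import numpy as np
import pandas as pd
import pytest

from aptaprofile import (
    PlantedEffect,
    SimulationConfig,
    generate_cohort,
    generate_library,
)
from aptaprofile.distance import dl_distance
from aptaprofile.simulate import _latent_proportions, _sample_metadata


def test_library_basics():
    cfg = SimulationConfig(n_ancestors=3, seq_length=36, seed=1)
    seqs, props = generate_library(cfg)
    assert len(set(seqs)) == 3
    assert all(len(s) == 36 and set(s) <= set("ACGU") for s in seqs)
    assert props.sum() == pytest.approx(1.0, abs=1e-12)


def test_degenerate_abundance_noise_gives_uniform_proportions():
    cfg = SimulationConfig(n_ancestors=8, abundance_sigma=0.0, seed=3)
    _, props = generate_library(cfg)
    assert np.allclose(props, 1.0 / 8)


def test_same_seed_bit_identical():
    cfg = SimulationConfig(n_ancestors=40, n_participants=3, depth_mean=2000,
                           mutation_rate=0.03, seed=5)
    c1, m1, t1 = generate_cohort(cfg)
    c2, m2, t2 = generate_cohort(cfg)
    pd.testing.assert_frame_equal(c1, c2)
    pd.testing.assert_frame_equal(m1, m2)
    pd.testing.assert_frame_equal(t1.latent_proportions, t2.latent_proportions)
    assert t1.derived_to_ancestor == t2.derived_to_ancestor


def test_well_separated_ancestors_respect_margin():
    cfg = SimulationConfig(n_ancestors=25, seq_length=36, well_separated=True, seed=8)
    seqs, _ = generate_library(cfg, d_max=3)
    for i, a in enumerate(seqs):
        for b in seqs[i + 1:]:
            assert dl_distance(a, b) > 6


def test_infeasible_separation_raises():
    cfg = SimulationConfig(n_ancestors=30, seq_length=3, max_edits_per_read=2,
                           well_separated=True, seed=1)
    with pytest.raises(RuntimeError, match="could not place"):
        generate_library(cfg, d_max=3, max_attempts=5)


def test_no_mutation_observed_equals_ancestors():
    cfg = SimulationConfig(n_ancestors=10, n_participants=2, depth_mean=20000,
                           mutation_rate=0.0, seed=4)
    counts, _, truth = generate_cohort(cfg)
    assert set(counts.index) <= set(truth.ancestors)
    assert truth.derived_to_ancestor == {}


def test_latent_proportions_sum_to_one():
    planted = (PlantedEffect("parity", "primiparous", (0, 1), 2.5),)
    cfg = SimulationConfig(n_ancestors=50, n_participants=6, planted=planted, seed=9)
    _, meta, truth = generate_cohort(cfg)
    sums = truth.latent_proportions.sum(axis=0)
    assert np.allclose(sums, 1.0, atol=1e-12)


def test_planted_fold_change_matches_closed_form():
    """theta=2 on one ancestor for elevated BMI, no noise: the latent
    proportion ratio elevated/normal equals 2 before renormalization, i.e.
    w_elev/w_norm = 2 * Z_norm/Z_elev with Z the normalizers computed
    directly from the baseline."""
    planted = (PlantedEffect("bmi_group", "elevated", (0,), 2.0),)
    cfg = SimulationConfig(
        n_ancestors=5, n_participants=2, biological_sigma=0.0,
        abundance_sigma=0.5, planted=planted, balanced_groups=True,
        p_elevated_bmi=0.5, seed=12,
    )
    _, baseline = generate_library(cfg)
    rng = np.random.default_rng(0)
    meta = _sample_metadata(cfg, rng)
    latent = _latent_proportions(cfg, baseline, meta, rng)
    elev = meta.loc[meta.bmi_group == "elevated", "sample_id"].iloc[0]
    norm = meta.loc[meta.bmi_group == "normal", "sample_id"].iloc[0]
    # closed-form normalizers, independent of the sampler's code path
    z_norm = baseline.sum()
    z_elev = baseline.sum() + baseline[0]
    assert latent[elev][0] == pytest.approx(2.0 * baseline[0] / z_elev, rel=1e-12)
    assert latent[norm][0] == pytest.approx(baseline[0] / z_norm, rel=1e-12)
    assert latent[elev][0] / latent[norm][0] == pytest.approx(
        2.0 * z_norm / z_elev, rel=1e-12
    )


def test_empirical_proportions_converge_at_high_depth():
    """With no noise, observed proportions approach latent ones within
    3 binomial standard errors at depth 10^6."""
    cfg = SimulationConfig(
        n_ancestors=20, n_participants=1, timepoints=("3d",),
        depth_mean=1_000_000, mutation_rate=0.0, biological_sigma=0.0,
        seed=21,
    )
    counts, meta, truth = generate_cohort(cfg)
    sid = meta["sample_id"].iloc[0]
    depth = counts[sid].sum()
    latent = truth.latent_proportions[sid]
    obs = pd.Series(0.0, index=range(len(truth.ancestors)))
    for i, anc in enumerate(truth.ancestors):
        if anc in counts.index:
            obs[i] = counts.loc[anc, sid] / depth
    se = np.sqrt(latent * (1 - latent) / depth)
    assert (np.abs(obs - latent) < 3 * se + 1e-12).all()


def test_derived_sequences_within_edit_budget(small_cohort):
    cfg, counts, meta, truth = small_cohort
    assert truth.derived_to_ancestor  # mutation actually happened
    for derived, anc in truth.derived_to_ancestor.items():
        assert dl_distance(derived, anc) <= cfg.max_edits_per_read


def test_null_simulation_allows_empty_planted():
    cfg = SimulationConfig(n_ancestors=30, n_participants=2, planted=(), seed=6)
    counts, meta, truth = generate_cohort(cfg)
    assert truth.planted == ()
    assert counts.shape[1] == len(meta)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(depth_mean=0)
    with pytest.raises(ValueError):
        SimulationConfig(mutation_rate=1.5)
    with pytest.raises(ValueError):
        SimulationConfig(seq_length=2, max_edits_per_read=3)
    with pytest.raises(ValueError, match="overlap"):
        SimulationConfig(
            planted=(
                PlantedEffect("parity", "primiparous", (0, 1), 2.0),
                PlantedEffect("parity", "multiparous", (1, 2), 2.0),
            )
        )
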