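"""Panel PCA, Wilcoxon rank-sum, and whole-panel validation."""

import numpy as np
import pandas as pd
import pytest

from aptaprofile import (
    PanelPCA,
    PlantedEffect,
    SimulationConfig,
    generate_cohort,
    pca_panel,
    to_percent,
    to_scaled,
    validate_panel,
    wilcoxon_rank_sum,
)


def test_rank_one_structure_explains_all_variance():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    scaled = pd.DataFrame(
        {"A": x, "C": 2.0 - x},  # perfectly anti-correlated
        index=[f"s{i}" for i in range(5)],
    ).T
    scaled.index.name = "sequence"
    pv = pca_panel(scaled, ["A", "C"])
    assert pv.explained_variance_ratio[0] == pytest.approx(1.0)


def test_scores_invariant_to_sample_permutation():
    rng = np.random.default_rng(1)
    scaled = pd.DataFrame(
        rng.normal(1, 0.3, size=(4, 10)),
        index=pd.Index(list("ACGU"), name="sequence"),
        columns=[f"s{i}" for i in range(10)],
    )
    pv = pca_panel(scaled, list("ACGU"))
    perm = rng.permutation(10)
    pv2 = pca_panel(scaled.iloc[:, perm], list("ACGU"))
    a = pv.pc1_scores.sort_index()
    b = pv2.pc1_scores.sort_index()
    assert np.allclose(a, b) or np.allclose(a, -b)


def test_scores_match_eigendecomposition_oracle():
    """PC1 scores agree with an independent eigendecomposition of the
    centered covariance on a 5x4 toy matrix (up to sign)."""
    rng = np.random.default_rng(2)
    scaled = pd.DataFrame(
        rng.normal(1, 0.5, size=(5, 4)),
        index=pd.Index([f"q{i}" for i in range(5)], name="sequence"),
        columns=[f"s{i}" for i in range(4)],
    )
    pv = pca_panel(scaled, list(scaled.index))
    M = scaled.T.to_numpy()
    M = M - M.mean(axis=0)
    cov = M.T @ M / 1.0
    vals, vecs = np.linalg.eigh(cov)
    v1 = vecs[:, np.argmax(vals)]
    expected = M @ v1
    got = pv.pc1_scores.to_numpy()
    assert np.allclose(got, expected, atol=1e-9) or np.allclose(got, -expected, atol=1e-9)
    assert pv.explained_variance_ratio[0] >= pv.explained_variance_ratio[1:].max()
    assert pv.explained_variance_ratio.sum() <= 1 + 1e-12


def test_missing_panel_sequences_warn_and_coverage():
    rng = np.random.default_rng(3)
    scaled = pd.DataFrame(
        rng.normal(1, 0.2, size=(3, 6)),
        index=pd.Index(["AA", "CC", "GG"], name="sequence"),
        columns=[f"s{i}" for i in range(6)],
    )
    with pytest.warns(UserWarning, match="absent"):
        pv = pca_panel(scaled, ["AA", "CC", "UU", "GU"])
    assert pv.panel_coverage == pytest.approx(0.5)
    with pytest.raises(ValueError, match="no panel sequence"):
        pca_panel(scaled, ["UU"])


def test_wilcoxon_exact_small_sample():
    # U = 0; two-sided exact p = 2 / C(6,3) = 0.1
    assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)


def test_wilcoxon_identical_groups_p_one():
    assert wilcoxon_rank_sum([5.0, 5.0], [5.0, 5.0]) == pytest.approx(1.0)


def test_wilcoxon_invariant_under_monotone_transform():
    rng = np.random.default_rng(4)
    x = rng.normal(0, 1, 12)
    y = rng.normal(0.8, 1, 15)
    p1 = wilcoxon_rank_sum(x, y)
    p2 = wilcoxon_rank_sum(np.exp(x), np.exp(y))
    assert p1 == pytest.approx(p2, rel=1e-12)
    with pytest.raises(ValueError):
        wilcoxon_rank_sum([], [1.0])


def _planted_validation(seed):
    planted = (PlantedEffect("bmi_group", "elevated", tuple(range(8)), 1.8),)
    cfg = SimulationConfig(
        n_ancestors=200, n_participants=16, depth_mean=20000,
        mutation_rate=0.0, planted=planted, balanced_groups=True,
        seed=seed, library_seed=900,
    )
    counts, meta, truth = generate_cohort(cfg)
    keep = counts[(counts >= 1).all(axis=1)]
    scaled = to_scaled(to_percent(keep))
    panel = sorted(truth.ancestors[i] for i in range(8))
    return scaled, meta, panel


def test_planted_effect_validates_with_small_p():
    scaled, meta, panel = _planted_validation(31)
    pv = validate_panel(scaled, meta, panel, "bmi_group")
    assert pv.wilcoxon_p["normal_vs_elevated"] < 0.01
    assert pv.panel_coverage == 1.0
    assert set(pv.group_medians) == {"normal", "elevated"}
    assert all(v >= 0 for v in pv.group_variances.values())


def test_sign_convention_repeatable():
    scaled, meta, panel = _planted_validation(32)
    pv1 = validate_panel(scaled, meta, panel, "bmi_group")
    pv2 = validate_panel(scaled, meta, panel, "bmi_group")
    pd.testing.assert_series_equal(pv1.pc1_scores, pv2.pc1_scores)
    # study group oriented to have the larger median
    assert pv1.group_medians["elevated"] >= pv1.group_medians["normal"]


def test_timepoint_grouping_pairs():
    cfg = SimulationConfig(
        n_ancestors=100, n_participants=8, depth_mean=10000,
        mutation_rate=0.0, seed=44,
    )
    counts, meta, _ = generate_cohort(cfg)
    keep = counts[(counts >= 1).all(axis=1)]
    scaled = to_scaled(to_percent(keep))
    panel = sorted(keep.index[:10])
    pv = validate_panel(scaled, meta, panel, "timepoint")
    assert set(pv.wilcoxon_p) == {
        "3d_vs_1m", "3d_vs_2m", "3d_vs_3m", "1m_vs_3m"
    }
    with pytest.raises(ValueError, match="absent"):
        meta_no3d = meta[meta.timepoint != "3d"]
        validate_panel(scaled[meta_no3d.sample_id], meta_no3d, panel, "timepoint")


def test_panel_aggregation_beats_single_sequences():
    """When only the panel carries the group signal, PC1's point-biserial
    correlation with the label exceeds any single sequence's in most
    replicates."""
    wins = 0
    reps = 10
    for r in range(reps):
        scaled, meta, panel = _planted_validation(100 + r)
        labels = meta.set_index("sample_id")["bmi_group"].reindex(scaled.columns)
        y = (labels == "elevated").to_numpy().astype(float)
        pv = validate_panel(scaled, meta, panel, "bmi_group")
        r_pc1 = abs(np.corrcoef(pv.pc1_scores.to_numpy(), y)[0, 1])
        r_best = max(
            abs(np.corrcoef(scaled.loc[s].to_numpy(), y)[0, 1]) for s in panel
        )
        wins += r_pc1 > r_best
    assert wins >= 0.8 * reps
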