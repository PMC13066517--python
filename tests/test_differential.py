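"""OLS contrasts, BH adjustment, and descriptive-panel semantics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aptaprofile import (
    ContrastSpec,
    DescriptiveOLS,
    benjamini_hochberg,
    default_contrasts,
    ols_contrast,
    summarize_contrasts,
    unique_descriptive,
)

from _oracles import bh_stepup_oracle


def _meta(groups):
    return pd.DataFrame(
        {
            "sample_id": [f"s{i}" for i in range(len(groups))],
            "participant_id": [f"p{i}" for i in range(len(groups))],
            "timepoint": "3d",
            "bmi_group": groups,
            "parity": "multiparous",
            "cohort": "discovery",
        }
    )


def test_beta_is_group_mean_difference():
    scaled = pd.DataFrame(
        [[1.0, 1.0, 1.3, 1.3]],
        index=pd.Index(["AAAA"], name="sequence"),
        columns=["s0", "s1", "s2", "s3"],
    )
    meta = _meta(["normal", "normal", "elevated", "elevated"])
    res = ols_contrast(scaled, meta, ContrastSpec("bmi_group", "normal", "elevated"))
    assert res.loc["AAAA", "beta"] == pytest.approx(0.3)
    assert abs(res.loc["AAAA", "beta"]) >= 0.2
    assert res.loc["AAAA", "direction"] == "increased"


def test_identical_groups_not_descriptive():
    scaled = pd.DataFrame(
        [[1.0, 2.0, 1.0, 2.0]],
        index=pd.Index(["AAAA"], name="sequence"),
        columns=["s0", "s1", "s2", "s3"],
    )
    meta = _meta(["normal", "normal", "elevated", "elevated"])
    res = ols_contrast(scaled, meta, ContrastSpec("bmi_group", "normal", "elevated"))
    assert res.loc["AAAA", "beta"] == pytest.approx(0.0)
    assert not res.loc["AAAA", "descriptive"]
    scaled2 = scaled.copy()
    scaled2.loc["AAAA"] = [1.0, 1.0, 1.0, 1.0]
    res2 = ols_contrast(scaled2, meta, ContrastSpec("bmi_group", "normal", "elevated"))
    assert res2.loc["AAAA", "beta"] == 0.0
    assert not res2.loc["AAAA", "descriptive"]


def test_ols_equals_pooled_t_test():
    """beta and p agree with an independent pooled-variance two-sample t
    test to machine precision on random data."""
    rng = np.random.default_rng(17)
    n1, n2, n_seq = 9, 12, 40
    X = pd.DataFrame(
        rng.normal(1.0, 0.4, size=(n1 + n2, n_seq)),
        index=[f"s{i}" for i in range(n1 + n2)],
        columns=[f"q{i}" for i in range(n_seq)],
    )
    y = ["normal"] * n1 + ["elevated"] * n2
    est = DescriptiveOLS(reference="normal", study="elevated").fit(X, y)
    A, B = X.iloc[:n1], X.iloc[n1:]
    t_res = stats.ttest_ind(B, A, equal_var=True)
    np.testing.assert_allclose(
        est.results_["beta"], B.mean() - A.mean(), rtol=1e-12
    )
    np.testing.assert_allclose(est.results_["p_raw"], t_res.pvalue, rtol=1e-10)


def test_constant_sequence_p_is_one_with_warning():
    X = pd.DataFrame(
        {"q0": [1.0] * 6, "q1": [1, 2, 3, 1, 2, 4.0]},
        index=[f"s{i}" for i in range(6)],
    )
    y = ["a"] * 3 + ["b"] * 3
    with pytest.warns(UserWarning, match="zero residual variance"):
        est = DescriptiveOLS(reference="a", study="b").fit(X, y)
    assert est.results_.loc["q0", "p_raw"] == 1.0
    assert not np.isnan(est.results_["p_raw"]).any()


def test_too_small_groups_rejected():
    X = pd.DataFrame({"q0": [1.0, 2.0, 3.0]}, index=["s0", "s1", "s2"])
    with pytest.raises(ValueError, match=">= 2 samples"):
        DescriptiveOLS(reference="a", study="b").fit(X, ["a", "b", "b"])


@pytest.mark.parametrize(
    "p,expected",
    [
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([0.2], [0.2]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
        ([], []),
    ],
)
def test_bh_known_values(p, expected):
    np.testing.assert_allclose(benjamini_hochberg(np.array(p)), expected)


def test_bh_matches_brute_force_stepup():
    rng = np.random.default_rng(5)
    for _ in range(50):
        p = rng.uniform(0, 1, size=rng.integers(1, 51))
        np.testing.assert_allclose(
            benjamini_hochberg(p), bh_stepup_oracle(list(p)), rtol=1e-12
        )


def test_raising_delta_never_enlarges_descriptive_set(planted_cohort):
    from aptaprofile import to_percent, to_scaled

    _, counts, meta, _ = planted_cohort
    keep = counts[(counts >= 1).all(axis=1)]
    scaled = to_scaled(to_percent(keep))
    sets = []
    for delta in (0.05, 0.2, 0.5, 1.0):
        res = ols_contrast(
            scaled, meta, ContrastSpec("bmi_group", "normal", "elevated", delta)
        )
        sets.append(set(res.index[res["descriptive"]]))
    for smaller, larger in zip(sets[1:], sets[:-1]):
        assert smaller <= larger


def test_planted_directions_and_summary(planted_cohort):
    from aptaprofile import to_percent, to_scaled

    _, counts, meta, truth = planted_cohort
    keep = counts[(counts >= 1).all(axis=1)]
    scaled = to_scaled(to_percent(keep))
    res = ols_contrast(
        scaled, meta, ContrastSpec("bmi_group", "normal", "elevated", 0.2)
    )
    planted_seqs = {truth.ancestors[i] for i in truth.planted[0].sequence_indices}
    desc = res[res["descriptive"]]
    hits = desc.loc[desc.index.isin(planted_seqs)]
    assert len(hits) >= 8  # most planted sequences recovered
    assert (hits["direction"] == "increased").all()  # fold > 1 in study group
    summary = summarize_contrasts({"bmi": res})
    row = summary.set_index("contrast").loc["bmi"]
    assert row["n_descriptive"] == row["n_increased"] + row["n_decreased"]


def test_unique_union_counts_sequence_once():
    idx = pd.Index(["AAA", "CCC"], name="sequence")
    r1 = pd.DataFrame({"descriptive": [True, False]}, index=idx)
    r2 = pd.DataFrame({"descriptive": [True, True]}, index=idx)
    union = unique_descriptive({"timepoint:3d_vs_1m": r1, "timepoint:3d_vs_2m": r2},
                               "timepoint")
    assert union == ["AAA", "CCC"]


def test_default_contrast_structure():
    specs = default_contrasts()
    names = [s.name for s in specs]
    assert names[:3] == [
        "timepoint:3d_vs_1m", "timepoint:3d_vs_2m", "timepoint:3d_vs_3m"
    ]
    assert {s.condition: s.coef_threshold for s in specs}["timepoint"] == 1.0
    assert {s.condition: s.coef_threshold for s in specs}["bmi_group"] == 0.2
    assert all(s.fdr_q == 0.05 for s in specs)
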