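"""Reusable benchmark studies on synthetic cohorts.

Each function runs a self-contained simulation experiment against the
pipeline and returns plain numbers: exact family recovery under edit noise,
false-positive calibration of the discovery statistics under the null,
sensitivity/false-discovery of planted-effect recovery with frozen-panel
validation, and motif-detection rates.  They are used by the test suite and
the acceptance script; all randomness flows from the ``seed`` argument.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cluster import FilterConfig, filter_min_count, join_families
from .differential import ContrastSpec, ols_contrast
from .motifs import motif_enrichment, build_families
from .normalize import to_percent, to_scaled
from .simulate import PlantedEffect, SimulationConfig, generate_cohort
from .validation import PanelPCA, validate_panel, wilcoxon_rank_sum

__all__ = [
    "family_recovery",
    "null_calibration",
    "planted_recovery",
    "motif_recovery",
]


def family_recovery(
    seed: int,
    *,
    n_ancestors: int = 1000,
    n_samples: int = 20,
    depth: float = 1e5,
    mutation_rate: float = 0.02,
) -> dict:
    """Joining at d_max=3 on a well-separated mutated cohort must rebuild
    the ancestor set with counts equal to the pre-mutation tallies."""
    assert n_samples % 4 == 0
    cfg = SimulationConfig(
        n_ancestors=n_ancestors,
        n_participants=n_samples // 4,
        depth_mean=depth,
        mutation_rate=mutation_rate,
        well_separated=True,
        seed=seed,
    )
    counts, _, truth = generate_cohort(cfg)
    joined, families = join_families(counts, FilterConfig(d_max=3))
    pre = truth.pre_mutation_counts
    pre = pre[pre.sum(axis=1) > 0]
    exact_set = set(joined.index) == set(pre.index)
    counts_equal = exact_set and joined.loc[pre.index, pre.columns].astype(
        "int64"
    ).equals(pre.astype("int64"))
    return {
        "n_observed_sequences": int(counts.shape[0]),
        "n_families": len(families),
        "exact_family_set": bool(exact_set),
        "counts_equal_pre_mutation": bool(counts_equal),
        "reads_conserved": bool(
            joined.to_numpy().sum() == counts.to_numpy().sum()
        ),
    }


def _two_group_cohort(seed, *, n_seq, n_per_group, depth, planted=(), library_seed=None,
                      cohort="discovery"):
    cfg = SimulationConfig(
        n_ancestors=n_seq,
        n_participants=2 * n_per_group,
        timepoints=("3d",),
        p_elevated_bmi=0.5,
        depth_mean=depth,
        mutation_rate=0.0,
        biological_sigma=0.3,
        planted=tuple(planted),
        balanced_groups=True,
        cohort=cohort,
        seed=seed,
        library_seed=library_seed,
    )
    counts, meta, truth = generate_cohort(cfg)
    filtered = filter_min_count(counts, FilterConfig(c_min=3))
    scaled = to_scaled(to_percent(filtered))
    return scaled, meta, truth


_BMI_SPEC = ContrastSpec("bmi_group", "normal", "elevated", 0.2, 0.05)


def null_calibration(
    seed: int,
    *,
    n_reps: int = 200,
    n_seq: int = 500,
    n_per_group: int = 40,
    depth: float = 2e4,
    panel_size: int = 16,
) -> dict:
    """With nothing planted, the discovery stage should almost never call a
    descriptive sequence, and the PC1 Wilcoxon p of a random panel should
    be uniform."""
    rng = np.random.default_rng(seed)
    any_descriptive = 0
    pvals = []
    for _ in range(n_reps):
        rep_seed = int(rng.integers(2**31))
        scaled, meta, _ = _two_group_cohort(
            rep_seed, n_seq=n_seq, n_per_group=n_per_group, depth=depth
        )
        res = ols_contrast(scaled, meta, _BMI_SPEC)
        any_descriptive += int(res["descriptive"].any())
        panel = list(
            rng.choice(scaled.index, size=min(panel_size, len(scaled)), replace=False)
        )
        labels = meta.set_index("sample_id")["bmi_group"].reindex(scaled.columns)
        est = PanelPCA(panel=panel, reference="normal", study="elevated").fit(
            scaled.T, labels
        )
        pc1 = est.pc1_scores_
        pvals.append(
            wilcoxon_rank_sum(
                pc1[(labels == "normal").to_numpy()],
                pc1[(labels == "elevated").to_numpy()],
            )
        )
    ks_p = float(stats.kstest(pvals, "uniform").pvalue)
    return {
        "n_reps": n_reps,
        "frac_cohorts_with_descriptive": any_descriptive / n_reps,
        "wilcoxon_pvalues": pvals,
        "ks_uniformity_p": ks_p,
    }


def planted_recovery(
    seed: int,
    *,
    n_reps: int = 20,
    n_seq: int = 1000,
    n_planted: int = 20,
    fold: float = 1.5,
    n_per_group: int = 40,
    depth: float = 1e5,
    validation_alpha: float = 0.01,
) -> dict:
    """Recovery of planted elevated-BMI effects: per-replicate sensitivity
    and false-discovery proportion in discovery, then frozen-panel Wilcoxon
    validation on an independently simulated cohort."""
    rng = np.random.default_rng(seed)
    sens, fdp, validated, val_pvals = [], [], 0, []
    for _ in range(n_reps):
        lib_seed = int(rng.integers(2**31))
        planted = (
            PlantedEffect("bmi_group", "elevated", tuple(range(n_planted)), fold),
        )
        scaled, meta, truth = _two_group_cohort(
            int(rng.integers(2**31)), n_seq=n_seq, n_per_group=n_per_group,
            depth=depth, planted=planted, library_seed=lib_seed,
        )
        res = ols_contrast(scaled, meta, _BMI_SPEC)
        called = set(res.index[res["descriptive"]])
        truth_set = {truth.ancestors[i] for i in range(n_planted)}
        tp = len(called & truth_set)
        sens.append(tp / n_planted)
        fdp.append((len(called) - tp) / max(len(called), 1))

        panel = sorted(called)
        if panel:
            v_scaled, v_meta, _ = _two_group_cohort(
                int(rng.integers(2**31)), n_seq=n_seq, n_per_group=n_per_group,
                depth=depth, planted=planted, library_seed=lib_seed,
                cohort="validation",
            )
            pv = validate_panel(v_scaled, v_meta, panel, "bmi_group", ("3d",))
            p = pv.wilcoxon_p["normal_vs_elevated"]
            val_pvals.append(p)
            validated += int(p < validation_alpha)
    return {
        "n_reps": n_reps,
        "mean_sensitivity": float(np.mean(sens)),
        "mean_fdp": float(np.mean(fdp)),
        "n_validated": validated,
        "validation_pvalues": val_pvals,
    }


def motif_recovery(
    seed: int,
    *,
    n_reps: int = 50,
    n_background: int = 500,
    panel_size: int = 12,
    k: int = 7,
    motif: str = "GGAUCCG",
) -> dict:
    """Implanted-motif detection and uniform-background specificity."""
    rng = np.random.default_rng(seed)

    def rand_seq():
        return "".join(rng.choice(list("ACGU"), size=36))

    detected = 0
    members_ok = 0
    null_clean = 0
    for _ in range(n_reps):
        background = [rand_seq() for _ in range(n_background)]
        while any(motif in s for s in background):
            background = [rand_seq() for _ in range(n_background)]
        panel = []
        for _ in range(panel_size):
            s = rand_seq()
            pos = int(rng.integers(0, 37 - k))
            panel.append(s[:pos] + motif + s[pos + k:])
        enr = motif_enrichment(panel, background, k)
        hit = motif in enr.index and bool(enr.loc[motif, "enriched"])
        detected += int(hit)
        if hit:
            fams = build_families(
                enr, {"bmi_group": panel}, pd.Series(1.0, index=panel)
            )
            fam = next((f for f in fams if motif in f.motifs), None)
            members_ok += int(fam is not None and set(panel) <= set(fam.members))
        null_panel = list(rng.choice(background, size=panel_size, replace=False))
        null_enr = motif_enrichment(null_panel, background, k)
        null_clean += int(int(null_enr["enriched"].sum()) == 0)
    return {
        "n_reps": n_reps,
        "frac_motif_detected": detected / n_reps,
        "frac_members_recovered": members_ok / n_reps,
        "frac_null_clean": null_clean / n_reps,
    }
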