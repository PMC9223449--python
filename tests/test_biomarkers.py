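"""Group tests, class sums/ratios, DeLong ROC and the Friedewald formula."""

import itertools
import math
import shutil
import subprocess
import textwrap

import numpy as np
import pytest
from scipy import stats

from mocamet import (
    CohortSpec,
    ConcentrationBlock,
    Group,
    RatioSpec,
    SampleMeta,
    Tissue,
    class_sum,
    evaluate_biomarkers,
    friedewald_ldl,
    generate_cohort,
    group_comparison_table,
    mannwhitney_pairwise,
    ratio_statistic,
    roc_auc_delong,
)
from mocamet.panel import build_panel


def _block(names, values, groups=None):
    values = np.asarray(values, dtype=float)
    m = values.shape[0]
    groups = groups or [Group.SHAM] * m
    samples = [
        SampleMeta(f"s{i}", Group(groups[i]), Tissue.PLASMA) for i in range(m)
    ]
    return ConcentrationBlock(
        samples, build_panel(names), values, np.ones_like(values, dtype=bool)
    )


# ---------------------------------------------------------------------------
# Mann-Whitney


def test_mannwhitney_identical_groups_is_symmetric():
    values = np.array([1.0, 2, 3, 1, 2, 3])
    groups = ["SHAM"] * 3 + ["HCD"] * 3
    (_, (u, p)), = mannwhitney_pairwise(values, groups).items()
    assert u == pytest.approx(4.5)  # n1*n2/2 with ties
    assert p == pytest.approx(1.0)


def test_mannwhitney_complete_separation_exact_p():
    """n1 = n2 = 3 complete separation: p = 2 / C(6,3) = 0.1 exactly."""
    values = np.array([1.0, 2, 3, 10, 11, 12])
    groups = ["SHAM"] * 3 + ["ANG"] * 3
    (_, (u, p)), = mannwhitney_pairwise(values, groups).items()
    assert u in (0.0, 9.0)
    assert p == pytest.approx(2 / math.comb(6, 3), abs=1e-12)


def test_mannwhitney_exact_matches_full_enumeration():
    """Exact p equals enumeration over all label arrangements (n = 4 + 4)."""
    rng = np.random.default_rng(6)
    pooled = rng.normal(size=8)
    groups = np.array(["A"] * 4 + ["B"] * 4)
    (_, (u_obs, p_obs)), = mannwhitney_pairwise(pooled, groups).items()
    count = total = 0
    n1n2 = 16
    for idx in itertools.combinations(range(8), 4):
        x = pooled[list(idx)]
        y = np.delete(pooled, list(idx))
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        count += abs(u - n1n2 / 2) >= abs(u_obs - n1n2 / 2) - 1e-12
        total += 1
    assert p_obs == pytest.approx(count / total, abs=1e-12)


def test_mannwhitney_asymptotic_close_to_permutation():
    rng = np.random.default_rng(9)
    values = np.concatenate([rng.normal(size=10), rng.normal(0.8, size=10)])
    values[3] = values[15]  # force a tie so the asymptotic branch runs
    groups = np.array(["A"] * 10 + ["B"] * 10)
    (_, (u_obs, p_obs)), = mannwhitney_pairwise(values, groups).items()
    draws = 20000
    count = 0
    for _ in range(draws):
        perm = rng.permutation(values)
        x, y = perm[:10], perm[10:]
        u = sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in y)
        count += abs(u - 50) >= abs(u_obs - 50) - 1e-12
    assert p_obs == pytest.approx(count / draws, abs=0.02)


def test_mannwhitney_rejects_tiny_groups():
    with pytest.raises(ValueError, match="< 2 samples"):
        mannwhitney_pairwise(np.arange(4.0), ["A", "A", "A", "B"])


def test_group_comparison_table_shape_and_bh():
    plasma, _, _ = generate_cohort(CohortSpec(seed=2))
    sub = ConcentrationBlock(
        plasma.samples,
        plasma.metabolites[:5],
        np.nan_to_num(plasma.values[:, :5], nan=1.0),
        np.ones((31, 5), dtype=bool),
    )
    table = group_comparison_table(sub)
    assert len(table) == 5 * 3  # five metabolites x three group pairs
    assert set(table.columns) >= {"metabolite", "group1", "group2", "U",
                                  "p_value", "significant"}


# ---------------------------------------------------------------------------
# sums and ratios


def test_class_sum_bcaa_and_lcac():
    block = _block(
        ["Leu", "Ile", "Val", "C2", "C12", "C14", "C18:1"],
        [[100.0, 50.0, 150.0, 1.0, 2.0, 3.0, 4.0]],
    )
    assert class_sum(block, "BCAA")[0] == pytest.approx(300.0)
    # long-chain acylcarnitines: strictly more than 12 carbons
    assert class_sum(block, "LCAC")[0] == pytest.approx(7.0)
    assert class_sum(block, "total_carnitine")[0] == pytest.approx(10.0)
    with pytest.raises(ValueError, match="matches no metabolite"):
        class_sum(block, "PC")


def test_class_sum_matches_masked_oracle():
    plasma, _, _ = generate_cohort(CohortSpec(seed=12))
    block = ConcentrationBlock(
        plasma.samples,
        plasma.metabolites,
        np.nan_to_num(plasma.values, nan=0.5),
        np.ones_like(plasma.valid_mask),
    )
    mask = np.array(
        [d.metabolite_class.value == "sphingomyelin" for d in block.metabolites]
    )
    assert np.allclose(class_sum(block, "SM"), block.values[:, mask].sum(axis=1))


def test_ratio_statistic_and_saturation_partition():
    block = _block(
        ["Leu", "Ile", "Val", "Gly",
         "lysoPC a C18:0", "lysoPC a C16:0",
         "lysoPC a C18:1", "lysoPC a C20:4"],
        [[100.0, 100.0, 100.0, 150.0, 4.0, 1.0, 2.0, 3.0]],
    )
    assert ratio_statistic(
        block, RatioSpec("BCAA/Gly", "BCAA", "Gly")
    )[0] == pytest.approx(2.0)
    # unsaturated (18:1, 20:4) over saturated (18:0, 16:0): (2+3)/(4+1)
    assert ratio_statistic(
        block, RatioSpec("U/S", "LysoPC_unsaturated", "LysoPC_saturated")
    )[0] == pytest.approx(1.0)


def test_ratio_is_per_sample_not_ratio_of_medians():
    rng = np.random.default_rng(21)
    values = rng.lognormal(size=(9, 2))
    block = _block(["Leu", "Gly"], values)
    ratios = ratio_statistic(block, RatioSpec("r", "Leu", "Gly"))
    assert np.allclose(ratios, values[:, 0] / values[:, 1])
    assert np.median(ratios) != pytest.approx(
        np.median(values[:, 0]) / np.median(values[:, 1])
    )


def test_ratio_zero_denominator_reports_sample():
    block = _block(["Leu", "Gly"], [[1.0, 1.0], [1.0, 0.0]])
    with pytest.raises(ValueError, match="s1"):
        ratio_statistic(block, RatioSpec("r", "Leu", "Gly"))


def test_ratios_are_unit_free():
    rng = np.random.default_rng(14)
    values = rng.lognormal(size=(6, 3))
    spec = RatioSpec("r", ("Leu", "Ile"), "Gly")
    a = ratio_statistic(_block(["Leu", "Ile", "Gly"], values), spec)
    b = ratio_statistic(_block(["Leu", "Ile", "Gly"], values * 1000), spec)
    assert np.allclose(a, b)


# ---------------------------------------------------------------------------
# ROC / DeLong


def test_auc_perfect_separation_and_pair_counting():
    roc = roc_auc_delong(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
    assert roc.auc == 1.0 and roc.good_classifier
    roc = roc_auc_delong(np.array([1.0, 3, 2, 4]), np.array([0, 0, 1, 1]))
    assert roc.auc == pytest.approx(3 / 4)  # positives {2,4} vs negatives {1,3}
    assert roc.n_pos == 2 and roc.n_neg == 2


def test_auc_equals_mannwhitney_u_identity():
    rng = np.random.default_rng(1)
    for _ in range(20):
        scores = rng.normal(size=40)
        scores[rng.random(40) < 0.2] = scores[0]  # inject ties
        labels = rng.random(40) < 0.5
        if labels.all() or not labels.any():
            continue
        roc = roc_auc_delong(scores, labels)
        u = stats.mannwhitneyu(
            scores[labels], scores[~labels], alternative="two-sided"
        ).statistic
        assert roc.auc == pytest.approx(
            u / (labels.sum() * (~labels).sum()), abs=1e-12
        )
        assert roc.ci_low <= roc.auc <= roc.ci_high


def test_auc_label_swap_mirrors_interval():
    rng = np.random.default_rng(33)
    scores = rng.normal(size=30)
    labels = np.arange(30) < 12
    a = roc_auc_delong(scores, labels)
    b = roc_auc_delong(scores, ~labels)
    assert a.auc == pytest.approx(1 - b.auc, abs=1e-12)
    assert a.ci_low == pytest.approx(1 - b.ci_high, abs=1e-12)
    assert a.ci_high == pytest.approx(1 - b.ci_low, abs=1e-12)


def test_auc_invariant_under_monotone_transform_and_logistic():
    rng = np.random.default_rng(40)
    scores = rng.normal(size=40)
    labels = rng.random(40) < 0.4
    a = roc_auc_delong(scores, labels).auc
    assert roc_auc_delong(np.exp(scores), labels).auc == pytest.approx(a)
    # single-feature logistic regression is a monotone transform of the score
    from sklearn.linear_model import LogisticRegression

    lr = LogisticRegression().fit(scores[:, None], labels)
    probs = lr.predict_proba(scores[:, None])[:, 1]
    sign = np.sign(lr.coef_[0][0])
    assert roc_auc_delong(sign * probs, labels).auc == pytest.approx(a)


def test_delong_ci_coverage_binormal():
    """~95% coverage of the true AUC under a bi-normal model."""
    rng = np.random.default_rng(55)
    delta = 1.0
    true_auc = stats.norm.cdf(delta / np.sqrt(2))
    covered = 0
    n_rep = 400
    for _ in range(n_rep):
        neg = rng.normal(size=30)
        pos = rng.normal(delta, size=30)
        roc = roc_auc_delong(
            np.concatenate([neg, pos]),
            np.concatenate([np.zeros(30, bool), np.ones(30, bool)]),
        )
        covered += roc.ci_low <= true_auc <= roc.ci_high
    assert covered / n_rep == pytest.approx(0.95, abs=0.03)


def test_delong_ci_matches_r_proc():
    """Cross-check the DeLong interval against R's pROC on a fixed vector."""
    rng = np.random.default_rng(77)
    scores = np.round(rng.normal(size=24), 6)
    labels = (np.arange(24) < 10).astype(int)
    scores[labels == 1] += 0.8
    roc = roc_auc_delong(scores, labels.astype(bool))
    rscript = shutil.which("Rscript")
    assert rscript is not None, "Rscript expected on PATH"
    code = textwrap.dedent(
        f"""
        suppressMessages(library(pROC))
        scores <- c({", ".join(repr(float(v)) for v in scores)})
        labels <- c({", ".join(str(v) for v in labels)})
        r <- roc(labels, scores, quiet=TRUE, direction="<")
        ci <- ci.auc(r, method="delong")
        cat(sprintf("%.10f %.10f %.10f", ci[1], ci[2], ci[3]))
        """
    )
    out = subprocess.run(
        [rscript, "-e", code], capture_output=True, text=True, check=True
    )
    lo, auc, hi = map(float, out.stdout.split())
    assert roc.auc == pytest.approx(auc, abs=1e-9)
    assert roc.ci_low == pytest.approx(lo, abs=1e-9)
    assert roc.ci_high == pytest.approx(hi, abs=1e-9)


def test_roc_rejects_single_class():
    with pytest.raises(ValueError, match="both classes"):
        roc_auc_delong(np.arange(5.0), np.ones(5, bool))


def test_evaluate_biomarkers_indicator_feature():
    plasma, _, _ = generate_cohort(CohortSpec(seed=44))
    rng = np.random.default_rng(0)
    indicator = (plasma.groups == "ANG").astype(float)
    values = np.nan_to_num(plasma.values, nan=1.0)
    values[:, 0] = indicator * 100 + 1 + rng.normal(scale=1e-3, size=31)
    block = ConcentrationBlock(
        plasma.samples, plasma.metabolites, values,
        np.ones_like(plasma.valid_mask),
    )
    name = block.metabolite_names[0]
    report = evaluate_biomarkers(block, specs=[RatioSpec("ind", name, None)])
    row = report[(report.spec == "ind") & (report.contrast == "ANG_vs_rest")]
    assert row["auc"].iloc[0] == pytest.approx(1.0)
    assert bool(row["good_classifier"].iloc[0])


def test_evaluate_biomarkers_auc_always_folded():
    plasma, _, _ = generate_cohort(CohortSpec(seed=45))
    block = ConcentrationBlock(
        plasma.samples, plasma.metabolites,
        np.nan_to_num(plasma.values, nan=1.0),
        np.ones_like(plasma.valid_mask),
    )
    report = evaluate_biomarkers(block)
    assert (report["auc"] >= 0.5).all()
    assert (report["ci_low"] <= report["auc"]).all()
    assert (report["auc"] <= report["ci_high"]).all()


# ---------------------------------------------------------------------------
# Friedewald


def test_friedewald_arithmetic():
    assert friedewald_ldl(5.2, 1.0, 2.2) == pytest.approx(3.2)
    assert friedewald_ldl(5.2, 1.0, 0.0) == pytest.approx(4.2)
    with pytest.raises(ValueError, match="nonnegative"):
        friedewald_ldl(-1.0, 1.0, 1.0)


def test_friedewald_warns_on_high_triglycerides():
    with pytest.warns(UserWarning, match="validity"):
        value = friedewald_ldl(13.96, 1.06, 4.58)
    assert value == pytest.approx(13.96 - 1.06 - 4.58 / 2.2)
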