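import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from csfmir.effects import TARGET_MIRNAS, build_null_effect_table
from csfmir.nanostring import (
    bh_adjust,
    collapse_to_patients,
    fit_f_dist,
    moderated_t_contrast,
    read_counts,
    run_contrasts,
    screen_candidates,
    top100_geomean_normalize,
    trigamma_inverse,
)
from csfmir.simulate import (
    SimulationParams,
    simulate_count_matrix,
    write_counts_tsv,
    write_rcc_like_csv,
)


# --- I/O ------------------------------------------------------------------


def test_counts_tsv_round_trip(tmp_path, design, effects):
    counts, meta = simulate_count_matrix(
        design, effects, SimulationParams(seed=3, panel_size=120))
    write_counts_tsv(counts, meta, tmp_path / "c.tsv", tmp_path / "m.tsv")
    back, bmeta = read_counts(tmp_path / "c.tsv", tmp_path / "m.tsv")
    pd.testing.assert_frame_equal(back, counts)
    assert list(bmeta["sample_id"]) == list(meta["sample_id"])


def test_rcc_like_file_parses_to_same_column(tmp_path, design, effects):
    counts, _ = simulate_count_matrix(
        design, effects, SimulationParams(seed=3, panel_size=120))
    sample = counts.columns[0]
    write_rcc_like_csv(counts, tmp_path / "s.csv", sample)
    back, _ = read_counts(tmp_path / "s.csv")
    pd.testing.assert_series_equal(back[sample], counts[sample],
                                   check_names=False)


def test_duplicate_tags_rejected(tmp_path):
    (tmp_path / "dup.tsv").write_text(
        "mirna\ts1\ns1tag\t3\ns1tag\t4\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_counts(tmp_path / "dup.tsv")


def test_non_numeric_counts_rejected(tmp_path):
    (tmp_path / "bad.tsv").write_text("mirna\ts1\ntagA\txyz\n")
    with pytest.raises(ValueError, match="non-numeric"):
        read_counts(tmp_path / "bad.tsv")


# --- normalization --------------------------------------------------------


def test_identical_samples_get_unit_factors():
    col = np.arange(1.0, 121.0)
    counts = pd.DataFrame({"s1": col, "s2": col, "s3": col})
    norm = top100_geomean_normalize(counts)
    assert np.allclose(norm.factors, 1.0)


def test_doubled_sample_factor_halves_and_matrix_equalizes():
    rng = np.random.default_rng(2)
    col = rng.integers(10, 1000, 150).astype(float)
    counts = pd.DataFrame({"s1": col, "s2": 2 * col})
    norm = top100_geomean_normalize(counts)
    assert norm.factors["s1"] / norm.factors["s2"] == pytest.approx(2.0, rel=1e-12)
    pd.testing.assert_series_equal(norm.counts["s1"], norm.counts["s2"],
                                   check_names=False)


def test_three_tag_toy_matches_hand_computed_geometric_means():
    counts = pd.DataFrame({"s1": [10.0, 100.0, 1000.0],
                           "s2": [20.0, 50.0, 4000.0]})
    norm = top100_geomean_normalize(counts, top_n=3)
    g1 = (10 * 100 * 1000) ** (1 / 3)
    g2 = (20 * 50 * 4000) ** (1 / 3)
    ref = (g1 + g2) / 2
    assert norm.factors["s1"] == pytest.approx(ref / g1, rel=1e-12)
    assert norm.factors["s2"] == pytest.approx(ref / g2, rel=1e-12)


def test_normalization_is_idempotent(design, effects):
    counts, _ = simulate_count_matrix(
        design, effects, SimulationParams(seed=3, panel_size=150))
    norm = top100_geomean_normalize(counts)
    again = top100_geomean_normalize(norm.counts)
    assert np.abs(again.factors - 1.0).max() < 1e-9


def test_top_set_geomean_equalized_across_samples(design, effects):
    counts, _ = simulate_count_matrix(
        design, effects, SimulationParams(seed=3, panel_size=150))
    norm = top100_geomean_normalize(counts)
    g = [np.exp(np.mean(np.log(np.sort(norm.counts[c].to_numpy())[-100:])))
         for c in norm.counts.columns]
    assert np.ptp(g) / np.mean(g) < 1e-9


def test_sample_with_zeros_in_top_set_is_qc_flagged():
    counts = pd.DataFrame({
        "s1": np.arange(1.0, 121.0),
        "s2": np.concatenate([np.zeros(50), np.arange(1.0, 71.0)]),
    })
    norm = top100_geomean_normalize(counts)
    assert "s2" in norm.qc_flags
    assert "s1" not in norm.qc_flags
    assert (norm.factors > 0).all()


def test_too_few_tags_rejected():
    counts = pd.DataFrame(np.ones((99, 3)))
    with pytest.raises(ValueError, match=">= 100"):
        top100_geomean_normalize(counts)


# --- moderated t ----------------------------------------------------------


def _toy_matrix(seed=11, n_tags=80, d0=3.0, s0=0.08, n_a=4, n_b=3):
    rng = np.random.default_rng(seed)
    sig2 = d0 * s0 / rng.chisquare(d0, n_tags)
    y = rng.normal(0, np.sqrt(sig2)[:, None], (n_tags, n_a + n_b))
    df = pd.DataFrame(y, index=[f"t{i:03d}" for i in range(n_tags)])
    groups = pd.Series(["A"] * n_a + ["B"] * n_b, index=df.columns)
    return df, groups


def test_d0_zero_equals_ordinary_pooled_t():
    df, groups = _toy_matrix()
    de = moderated_t_contrast(df, groups, "A", "B", d0_override=0)
    t_ref, p_ref = stats.ttest_ind(df.loc[:, (groups == "A").to_numpy()],
                                   df.loc[:, (groups == "B").to_numpy()],
                                   axis=1, equal_var=True)
    np.testing.assert_allclose(de["t_mod"], t_ref, atol=1e-10)
    np.testing.assert_allclose(de["p"], p_ref, atol=1e-10)


def test_identical_variances_are_shrinkage_fixed_point():
    # every tag has the same sample variance => posterior s2 == s2
    base = np.array([0.0, 1.0, 2.0, 0.5, 1.5, 2.5])
    df = pd.DataFrame(np.tile(base, (50, 1)) + np.arange(50)[:, None])
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=df.columns)
    de = moderated_t_contrast(df, groups, "A", "B")
    np.testing.assert_allclose(de["s2"], de["s2"].iloc[0])
    assert np.isinf(de["d0"].iloc[0])
    np.testing.assert_allclose(de["s0_2"], de["s2"], rtol=1e-9)


def test_hyperparameter_recovery_from_inverse_gamma_truth():
    df, groups = _toy_matrix(seed=5, n_tags=1000, d0=4.0, s0=0.05, n_a=3, n_b=3)
    de = moderated_t_contrast(df, groups, "A", "B")
    assert de["d0"].iloc[0] == pytest.approx(4.0, rel=0.25)
    assert de["s0_2"].iloc[0] == pytest.approx(0.05, rel=0.25)


def test_contrast_antisymmetry():
    df, groups = _toy_matrix()
    ab = moderated_t_contrast(df, groups, "A", "B")
    ba = moderated_t_contrast(df, groups, "B", "A")
    np.testing.assert_allclose(ab["log2fc"], -ba["log2fc"], atol=1e-12)
    np.testing.assert_allclose(ab["t_mod"], -ba["t_mod"], atol=1e-12)
    np.testing.assert_allclose(ab["p"], ba["p"], atol=1e-12)


def test_trigamma_inverse_round_trip():
    from scipy.special import polygamma
    for x in (0.01, 0.5, 2.0, 50.0, 1e4):
        y = float(polygamma(1, x))
        assert trigamma_inverse(y) == pytest.approx(x, rel=1e-6)


def test_moderated_t_matches_limma_oracle(tmp_path):
    """Independent cross-check against the Bioconductor implementation."""
    df, groups = _toy_matrix(seed=11, n_tags=60)
    df.to_csv(tmp_path / "mat.tsv", sep="\t")
    script = textwrap.dedent("""
        suppressMessages(library(limma))
        m <- as.matrix(read.delim("mat.tsv", row.names=1))
        design <- cbind(A=c(1,1,1,1,0,0,0), B=c(0,0,0,0,1,1,1))
        fit <- eBayes(contrasts.fit(lmFit(m, design),
                      makeContrasts(A-B, levels=design)))
        out <- data.frame(t=fit$t[,1], p=fit$p.value[,1],
                          d0=fit$df.prior, s0=fit$s2.prior)
        write.table(out, "limma.tsv", sep="\\t", quote=FALSE)
    """)
    (tmp_path / "check.R").write_text(script)
    subprocess.run(["Rscript", "check.R"], cwd=tmp_path, check=True,
                   capture_output=True)
    ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
    de = moderated_t_contrast(df, groups, "A", "B")
    np.testing.assert_allclose(de["t_mod"], ref["t"], atol=1e-8)
    np.testing.assert_allclose(de["p"], ref["p"], atol=1e-8)
    assert de["d0"].iloc[0] == pytest.approx(ref["d0"].iloc[0], rel=1e-6)
    assert de["s0_2"].iloc[0] == pytest.approx(ref["s0"].iloc[0], rel=1e-6)


def test_null_matrix_p_values_are_uniform(design):
    """KS check at the 1% level on a 1000-tag no-signal matrix."""
    eff = build_null_effect_table()
    params = SimulationParams(seed=7, panel_size=1000,
                              count_baseline_log2_range=(6.0, 12.0))
    counts, meta = simulate_count_matrix(design, eff, params)
    norm = top100_geomean_normalize(counts)
    values, pmeta = collapse_to_patients(norm.log2, meta)
    groups = pmeta.set_index("patient_id").loc[values.columns, "group"]
    de = moderated_t_contrast(values, groups, "Normal", "Benign")
    ks = stats.kstest(de["p"], "uniform").statistic
    assert ks < 1.63 / np.sqrt(len(de))   # 1% critical value


# --- BH -------------------------------------------------------------------


def _bh_oracle(p):
    """Hand step-up: q_(i) = min_{j >= i} m * p_(j) / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)), 1.0)
    return q


@pytest.mark.parametrize("p", [
    [0.04],
    [0.01, 0.02, 0.03, 0.04],
    [1.0, 1.0, 1.0],
    [0.5, 0.001, 0.04, 0.9, 0.02],
    [0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2],
])
def test_bh_matches_hand_step_up_oracle(p):
    np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)


@settings(deadline=None, max_examples=100)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
def test_bh_matches_oracle_on_random_short_lists(p):
    np.testing.assert_allclose(bh_adjust(p), _bh_oracle(p), atol=1e-12)


def test_bh_against_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(1)
    p = rng.uniform(0, 1, 200)
    ref = multipletests(p, method="fdr_bh")[1]
    np.testing.assert_allclose(bh_adjust(p), ref, atol=1e-12)


def test_bh_properties():
    rng = np.random.default_rng(2)
    p = rng.uniform(0, 1, 50)
    q = bh_adjust(p)
    assert (q >= p - 1e-15).all()
    assert (q <= 1.0).all()
    with pytest.raises(ValueError, match="index 1"):
        bh_adjust([0.5, 1.5])


# --- screening ------------------------------------------------------------


def test_screen_excludes_never_significant_and_is_monotone(design, effects):
    counts, meta = simulate_count_matrix(
        design, effects, SimulationParams(seed=42))
    results = run_contrasts(counts, meta)
    strict = screen_candidates(results)
    loose = screen_candidates(results, min_comparisons=1)
    assert set(strict.index) <= set(loose.index)
    # tags significant nowhere are excluded even at min_comparisons=1
    never = set(counts.index) - set(loose.index)
    assert never
    for name, df in results.items():
        assert (df.loc[sorted(never), "q"] >= 0.05).all()


def test_screen_recovers_all_five_validated_mirnas(design, effects):
    counts, meta = simulate_count_matrix(
        design, effects, SimulationParams(seed=42))
    cand = screen_candidates(run_contrasts(counts, meta))
    assert set(TARGET_MIRNAS) <= set(cand.index)


def test_fit_f_dist_handles_degenerate_input():
    d0, s0 = fit_f_dist(np.full(20, 0.25), df=4)
    assert np.isinf(d0)
    assert s0 == pytest.approx(0.25, rel=1e-9)
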