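"""Cumulative comorbidity PRS: counting, normalization, HLA burden, ANCOVA."""

import numpy as np
import pandas as pd
import pytest

from mscomorb.prs import (
    HlaPanel,
    VariantPanel,
    compare_groups,
    compute_profiles,
    cumulative_prs,
    disease_raw_scores,
    hla_augmented_scores,
    load_hla_panels,
    load_variant_panels,
    normalize_score,
    plot_prs_distribution,
    save_hla_panels,
    save_variant_panels,
)
from mscomorb.synthetic_cohort import GenoSimConfig, generate_genotypes, make_genetic_subset, make_panels

from conftest import make_matrix


def panel_and_matrix(n_samples, n_variants, risk_pattern="alt", seed=0):
    """Matrix plus a panel over its variants; risk alleles mix REF and ALT."""
    rng = np.random.default_rng(seed)
    dosages = rng.integers(0, 3, size=(n_samples, n_variants)).astype(float)
    matrix = make_matrix(dosages)
    entries = []
    for j in range(n_variants):
        if risk_pattern == "alt":
            risk = "G"
        elif risk_pattern == "ref":
            risk = "A"
        else:
            risk = "G" if j % 2 == 0 else "A"
        entries.append((f"v{j}", risk))
    return matrix, VariantPanel(disease="d", entries=tuple(entries))


def test_all_reference_subject_scores_zero():
    matrix, panel = panel_and_matrix(3, 10, risk_pattern="alt")
    matrix.dosages[0] = 0.0
    assert disease_raw_scores(matrix, panel).iloc[0] == 0.0


def test_all_risk_subject_on_23_variant_panel_scores_46():
    """Maximum achievable score on a 23-variant panel is 2 x 23 = 46."""
    matrix, panel = panel_and_matrix(2, 23, risk_pattern="mixed")
    risk_dosage = np.array([2.0 if r == "G" else 0.0 for _, r in panel.entries])
    matrix.dosages[0] = risk_dosage
    raw = disease_raw_scores(matrix, panel)
    assert raw.iloc[0] == 46.0
    assert normalize_score(raw.iloc[0], panel.n_snps) == 1.0


def test_raw_scores_match_brute_force_oracle():
    matrix, panel = panel_and_matrix(50, 17, risk_pattern="mixed", seed=5)
    raw = disease_raw_scores(matrix, panel)
    meta = matrix.variants.set_index("variant_id")
    for i, sid in enumerate(matrix.samples["sample_id"]):
        total = 0
        for vid, risk in panel.entries:
            g = matrix.dosages[i, list(matrix.variants["variant_id"]).index(vid)]
            total += g if risk == meta.loc[vid, "alt"] else 2 - g
        assert raw.loc[sid] == pytest.approx(total)


def test_normalize_score_bounds_and_midpoint():
    assert normalize_score(0, 10) == 0.0
    assert normalize_score(20, 10) == 1.0
    assert normalize_score(201, 201) == 0.5
    with pytest.raises(ValueError):
        normalize_score(1, 0)


def test_cumulative_prs_order_invariant_and_bounded():
    rng = np.random.default_rng(3)
    norm = pd.DataFrame(rng.uniform(0, 1, size=(20, 9)), columns=[f"d{i}" for i in range(9)])
    total = cumulative_prs(norm)
    shuffled = cumulative_prs(norm[rng.permutation(norm.columns)])
    pd.testing.assert_series_equal(total, shuffled)
    assert ((total >= 0) & (total <= 9)).all()
    assert cumulative_prs(norm * 0).eq(0).all()
    assert cumulative_prs(norm * 0 + 1).eq(9).all()


def test_missing_variant_strict_errors_and_rescale_keeps_scale():
    matrix, panel = panel_and_matrix(5, 10, seed=2)
    matrix.dosages[2, 4] = np.nan
    with pytest.raises(ValueError, match="v4"):
        disease_raw_scores(matrix, panel, missing_rule="strict")
    raw = disease_raw_scores(matrix, panel, missing_rule="rescale")
    observed = np.nansum(matrix.dosages[2])
    assert raw.iloc[2] == pytest.approx(observed * 10 / 9)


def test_unmatched_risk_allele_rejected():
    matrix, _ = panel_and_matrix(3, 2)
    bad = VariantPanel(disease="d", entries=(("v0", "T"),))
    with pytest.raises(ValueError, match="risk allele"):
        disease_raw_scores(matrix, bad)


def test_adding_one_risk_allele_increments_cumulative_prs():
    cfg = GenoSimConfig(panel_sizes={"a": 6, "b": 11}, hla_panel_sizes={"a": 0, "b": 0}, seed=4)
    subs = make_genetic_subset(n=10, n_comorbid=2, seed=4)
    panels, _ = make_panels(cfg)
    matrix, _ = generate_genotypes(subs, panels, cfg)
    matrix.dosages[:] = np.round(matrix.dosages)  # integer dosages
    before = compute_profiles(matrix, panels)["prs_comorb"]
    vid, risk = panels["b"].entries[3]
    j = list(matrix.variants["variant_id"]).index(vid)
    direction = 1.0 if risk == "G" else -1.0
    i = int(np.argmax(direction * matrix.dosages[:, j] < (2 if direction > 0 else 0)))
    matrix.dosages[i, j] += direction
    after = compute_profiles(matrix, panels)["prs_comorb"]
    delta = after - before
    assert delta.iloc[i] == pytest.approx(1.0 / (2 * panels["b"].n_snps))
    assert (delta.drop(delta.index[i]) == 0).all()


def test_hla_augmentation_reduces_to_plain_prs_when_empty():
    cfg = GenoSimConfig(panel_sizes={"a": 5, "b": 7}, hla_panel_sizes={"a": 0, "b": 0}, seed=6)
    subs = make_genetic_subset(n=30, n_comorbid=5, seed=6)
    panels, hla_panels = make_panels(cfg)
    matrix, hla_counts = generate_genotypes(subs, panels, cfg, hla_panels)
    prof = compute_profiles(matrix, panels, hla_counts, hla_panels)
    pd.testing.assert_series_equal(
        prof["prs_comorb_hla"], prof["prs_comorb"], check_names=False
    )


def test_hla_augmented_scores_match_brute_force():
    cfg = GenoSimConfig(panel_sizes={"a": 4, "b": 6}, hla_panel_sizes={"a": 2, "b": 3}, seed=7)
    subs = make_genetic_subset(n=25, n_comorbid=6, seed=7)
    panels, hla_panels = make_panels(cfg)
    matrix, hla_counts = generate_genotypes(subs, panels, cfg, hla_panels)
    aug = hla_augmented_scores(matrix, hla_counts, panels, hla_panels)
    cols = list(matrix.variants["variant_id"])
    for d in panels:
        for i, sid in enumerate(matrix.samples["sample_id"]):
            g = np.round(matrix.dosages[i, [cols.index(v) for v, _ in panels[d].entries]])
            snp = sum(
                gg if risk == "G" else 2 - gg
                for gg, (_, risk) in zip(g, panels[d].entries)
            )
            hla = sum(hla_counts.loc[sid, a] for a in hla_panels[d].alleles)
            denom = 2 * (panels[d].n_snps + hla_panels[d].n_hla)
            assert aug.loc[sid, d] == pytest.approx((snp + hla) / denom)


def test_hla_counts_outside_range_rejected():
    cfg = GenoSimConfig(panel_sizes={"a": 4}, hla_panel_sizes={"a": 2}, seed=8)
    subs = make_genetic_subset(n=10, n_comorbid=3, seed=8)
    panels, hla_panels = make_panels(cfg)
    matrix, hla_counts = generate_genotypes(subs, panels, cfg, hla_panels)
    hla_counts.iloc[0, 0] = 3
    with pytest.raises(ValueError, match="0, 1, 2"):
        hla_augmented_scores(matrix, hla_counts, panels, hla_panels)


def _null_profiles(n=200, n_comorbid=40, seed=0):
    rng = np.random.default_rng(seed)
    comorbid = np.zeros(n, bool)
    comorbid[rng.choice(n, n_comorbid, replace=False)] = True
    return pd.DataFrame(
        {
            "prs_comorb_hla": rng.normal(2.5, 0.2, n),
            "comorbid": comorbid,
            "age_years": rng.integers(20, 80, n),
            "sex": rng.choice(["female", "male"], n),
            "pc1": rng.normal(size=n),
            "pc2": rng.normal(size=n),
            "pc3": rng.normal(size=n),
        },
        index=[f"s{i}" for i in range(n)],
    )


def test_compare_groups_null_coefficient_small():
    prof = _null_profiles(seed=10)
    res = compare_groups(prof)
    assert abs(res.coef) < 4 * res.se
    assert res.reduced is not None and "sex_female" not in res.reduced.covariate_coefs


def test_compare_groups_location_invariance():
    prof = _null_profiles(seed=11)
    res1 = compare_groups(prof)
    shifted = prof.assign(prs_comorb_hla=prof["prs_comorb_hla"] + 5.0)
    res2 = compare_groups(shifted)
    assert res2.coef == pytest.approx(res1.coef, abs=1e-10)
    assert res2.covariate_coefs["const"] == pytest.approx(res1.covariate_coefs["const"] + 5.0)


def test_compare_groups_recovers_planted_shift():
    prof = _null_profiles(n=637, n_comorbid=65, seed=12)
    delta = 0.4 * prof["prs_comorb_hla"].std()
    prof.loc[prof["comorbid"], "prs_comorb_hla"] += delta
    res = compare_groups(prof)
    assert res.coef == pytest.approx(delta, abs=3 * res.se)
    assert res.p < 0.05
    assert res.adjusted_means["comorbid"] - res.adjusted_means["non_comorbid"] == pytest.approx(res.coef)


def test_compare_groups_flags_collinearity_and_small_groups():
    prof = _null_profiles(seed=13)
    prof["pc2"] = prof["pc1"]
    assert compare_groups(prof).collinear
    tiny = _null_profiles(n=10, n_comorbid=1, seed=14)
    with pytest.raises(ValueError, match="at least 2"):
        compare_groups(tiny)


def test_plot_written_and_empty_group_rejected(tmp_path):
    prof = _null_profiles(seed=15)
    out = plot_prs_distribution(prof, tmp_path / "prs.png")
    assert out.exists() and out.stat().st_size > 0
    with pytest.raises(ValueError, match="non-empty"):
        plot_prs_distribution(prof.assign(comorbid=False), tmp_path / "bad.png")


def test_panel_tsv_round_trip(tmp_path):
    cfg = GenoSimConfig(panel_sizes={"a": 3, "b": 2}, hla_panel_sizes={"a": 1, "b": 2}, seed=16)
    panels, hla_panels = make_panels(cfg)
    save_variant_panels(panels, tmp_path / "p.tsv")
    save_hla_panels(hla_panels, tmp_path / "h.tsv")
    assert load_variant_panels(tmp_path / "p.tsv") == panels
    assert load_hla_panels(tmp_path / "h.tsv") == hla_panels


def test_duplicate_panel_entries_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        VariantPanel(disease="d", entries=(("v1", "A"), ("v1", "G")))
    with pytest.raises(ValueError, match="duplicate"):
        HlaPanel(disease="d", alleles=("x", "x"))
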