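"""Group-level permutation statistics, cluster correction, categorization."""

import numpy as np
import pandas as pd
import pytest
import xarray as xr

from infolearn import stats
from infolearn.dynamics import InfoSeries
from infolearn.stats import (
    bin_ii_by_selectivity,
    categorize_contacts,
    cluster_correct,
    condition_contrast,
    group_ttest_vs_perm_mean,
    subject_reproducibility,
)


def _series(values, null, target="RPE", measure="MI", rois=None):
    n_u, n_t = values.shape
    coords = {"unit": np.arange(n_u), "time": np.arange(n_t) / 256.0}
    da = xr.DataArray(values, dims=("unit", "time"), coords=coords)
    if rois is not None:
        da = da.assign_coords(roi=("unit", rois))
    nda = xr.DataArray(null, dims=("unit", "time", "perm"),
                       coords=coords | {"perm": np.arange(null.shape[-1])})
    return InfoSeries(values=da, measure=measure, target=target, null=nda)


def test_group_t_zero_when_values_equal_perm_mean(rng):
    null = rng.normal(size=(10, 40, 100))
    s = _series(null.mean(axis=2), null)
    t_obs, t_perm = group_ttest_vs_perm_mean(s)
    assert np.allclose(t_obs, 0.0)
    assert t_perm.shape == (100, 40)


def test_group_t_detects_injected_effect(rng):
    null = rng.normal(size=(20, 60, 200))
    values = null.mean(axis=2).copy()
    values[:, 20:35] += 3 * null.std()  # +3 null-SD uniform effect
    s = _series(values, null)
    t_obs, t_perm = group_ttest_vs_perm_mean(s)
    thr = np.percentile(t_perm, 95)
    assert (t_obs[20:35] > thr).all()
    # null t-distribution is centred at a null time point
    assert abs(t_perm[:, 50].mean()) < 0.3


def test_group_needs_two_units(rng):
    null = rng.normal(size=(1, 10, 20))
    s = _series(null.mean(2), null)
    with pytest.raises(ValueError):
        group_ttest_vs_perm_mean(s)
    s2 = _series(np.tile(null.mean(2), (3, 1)), np.tile(null, (3, 1, 1)))
    s2.null = None
    with pytest.raises(ValueError):
        group_ttest_vs_perm_mean(s2)


def test_cluster_correct_empty_when_subthreshold(rng):
    t_perm = rng.normal(size=(100, 50))
    t_obs = np.zeros(50)
    res = cluster_correct(t_obs, t_perm)
    assert res.clusters == ()


def test_cluster_recovers_effect_window(rng):
    t_perm = rng.normal(size=(200, 200))
    t_obs = rng.normal(size=200) * 0.5
    t_obs[60:137] += 6.0  # strong 300 ms effect at 256 Hz
    res = cluster_correct(t_obs, t_perm)
    sig = res.significant(0.05)
    assert len(sig) >= 1
    mask = res.mask(200)
    overlap = mask[60:137].mean()
    assert overlap >= 0.8


def test_cluster_p_monotone_in_mass(rng):
    t_perm = rng.normal(size=(300, 100))
    t_obs = np.zeros(100)
    t_obs[10:20] = 2.2
    t_obs[50:80] = 2.2
    res = cluster_correct(t_obs, t_perm)
    masses = [c.mass for c in res.clusters]
    ps = [c.p for c in res.clusters]
    assert ps[int(np.argmax(masses))] <= ps[int(np.argmin(masses))]


def test_type_one_error_calibration(rng):
    """Null group data: family-wise cluster error near the nominal 5%."""
    fp = 0
    runs = 150
    for _ in range(runs):
        null = rng.normal(size=(12, 64, 100))
        obs = rng.normal(size=(12, 64)) + null.mean(axis=2) * 0.0
        s = _series(obs, null)
        t_obs, t_perm = group_ttest_vs_perm_mean(s)
        res = cluster_correct(t_obs, t_perm)
        if res.significant(0.05):
            fp += 1
    assert 0.005 <= fp / runs <= 0.12


def _mi_cohort(rng, n_effect_rpe, n_effect_ppe, n_both, n_null, n_t=80,
               n_perm=120, amp=0.08):
    """Synthetic per-contact MI series with nulls and known selectivity."""
    n_u = n_effect_rpe + n_effect_ppe + n_both + n_null
    win = slice(30, 55)
    rois = ["aINS"] * n_u

    def build(idx_effect):
        null = rng.normal(scale=0.01, size=(n_u, n_t, n_perm))
        vals = rng.normal(scale=0.01, size=(n_u, n_t))
        for u in idx_effect:
            vals[u, win] += amp
        return vals, null

    rpe_idx = list(range(n_effect_rpe)) + list(
        range(n_effect_rpe + n_effect_ppe, n_effect_rpe + n_effect_ppe + n_both)
    )
    ppe_idx = list(range(n_effect_rpe, n_effect_rpe + n_effect_ppe)) + list(
        range(n_effect_rpe + n_effect_ppe, n_effect_rpe + n_effect_ppe + n_both)
    )
    v_r, n_r = build(rpe_idx)
    v_p, n_p = build(ppe_idx)
    return (_series(v_r, n_r, "RPE", rois=rois), _series(v_p, n_p, "PPE", rois=rois))


def test_categorize_contacts_recovers_proportions(rng):
    """10 RPE + 10 PPE + 5 Both + 25 null contacts: peak proportions match."""
    mi_rpe, mi_ppe = _mi_cohort(rng, 10, 10, 5, 25)
    labels = categorize_contacts(mi_rpe, mi_ppe)
    prop = labels.proportions.sel(roi="aINS")
    # proportions sum to one at every time point
    assert np.allclose(prop.sum("label").values, 1.0)
    peak = prop.isel(time=40)
    assert float(peak.sel(label="RPE")) == pytest.approx(0.2, abs=0.1)
    assert float(peak.sel(label="PPE")) == pytest.approx(0.2, abs=0.1)
    assert float(peak.sel(label="Both")) == pytest.approx(0.1, abs=0.1)
    assert float(peak.sel(label="Irrelevant")) == pytest.approx(0.5, abs=0.15)
    # contact-level labels
    assert (labels.contact_label.iloc[:10] == "RPE").mean() >= 0.8
    assert (labels.contact_label.iloc[20:25] == "Both").mean() >= 0.8


def test_categorize_all_null_cohort(rng):
    mi_rpe, mi_ppe = _mi_cohort(rng, 0, 0, 0, 40)
    labels = categorize_contacts(mi_rpe, mi_ppe)
    relevant = 1.0 - labels.proportions.sel(roi="aINS", label="Irrelevant").values
    assert relevant.max() <= 0.15  # near the nominal false-positive rate


def test_bin_ii_by_selectivity_significance():
    """Synergy only in PPE-RPE and Mixed pairs survives the FDR."""
    rng = np.random.default_rng(0)
    labels = pd.Series(
        {**{f"r{i}": "RPE" for i in range(8)},
         **{f"p{i}": "PPE" for i in range(8)},
         **{f"b{i}": "Both" for i in range(8)},
         **{f"x{i}": "Irrelevant" for i in range(4)}}
    )
    rows = []
    for i in range(8):
        rows.append({"contact1": f"p{i}", "contact2": f"r{i}",
                     "mean_ii": 0.05 + 0.01 * rng.normal()})  # synergistic
        rows.append({"contact1": f"b{i}", "contact2": f"r{i}",
                     "mean_ii": 0.05 + 0.01 * rng.normal()})  # synergistic
        rows.append({"contact1": f"r{i}", "contact2": f"r{(i+1) % 8}",
                     "mean_ii": -0.02 + 0.05 * rng.normal()})  # weakly redundant
        rows.append({"contact1": f"p{i}", "contact2": f"p{(i+1) % 8}",
                     "mean_ii": -0.02 + 0.05 * rng.normal()})
        rows.append({"contact1": f"x{i % 4}", "contact2": f"r{i}",
                     "mean_ii": 0.0})  # involves Irrelevant: dropped
    out = bin_ii_by_selectivity(pd.DataFrame(rows), labels)
    out = out.set_index("category")
    assert set(out.index) == {"RPE-RPE", "PPE-PPE", "PPE-RPE", "Mixed"}
    assert int(out["n_pairs"].sum()) == 32  # Irrelevant-involving pairs dropped
    assert out.loc["PPE-RPE", "p_fdr"] < 0.05
    assert out.loc["Mixed", "p_fdr"] < 0.05
    assert out.loc["RPE-RPE", "p_fdr"] > 0.05
    assert out.loc["PPE-PPE", "p_fdr"] > 0.05
    # label permutation kills the significance
    perm = pd.Series(rng.permutation(labels.values), index=labels.index)
    out_p = bin_ii_by_selectivity(pd.DataFrame(rows), perm)
    assert (out_p["p_fdr"] > 0.05).all() or len(out_p) == 0


def test_benjamini_hochberg_hand_example():
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
    assert np.allclose(adj, 0.04)


def test_condition_contrast_gated_effect(rng):
    n_u, n_t = 16, 100
    base = rng.normal(size=(n_u, n_t)) * 0.01
    a = base + rng.normal(size=(n_u, n_t)) * 0.01
    a[:, 40:70] += 0.05
    b = base
    coords = {"unit": np.arange(n_u), "time": np.arange(n_t) / 256.0}
    sa = InfoSeries(xr.DataArray(a, dims=("unit", "time"), coords=coords), "TE", "x")
    sb = InfoSeries(xr.DataArray(b, dims=("unit", "time"), coords=coords), "TE", "x")
    res = condition_contrast(sa, sb, n_perm=200, seed=0)
    assert len(res["a_gt_b"].significant(0.05)) >= 1
    assert len(res["b_gt_a"].significant(0.05)) == 0
    # identical series: no clusters anywhere
    res2 = condition_contrast(sa, sa, n_perm=100, seed=1)
    assert res2["a_gt_b"].clusters == () and res2["b_gt_a"].clusters == ()


def test_condition_contrast_null_calibration(rng):
    fp = 0
    runs = 100
    for r in range(runs):
        d = rng.normal(size=(12, 60)) * 0.01
        coords = {"unit": np.arange(12), "time": np.arange(60) / 256.0}
        sa = InfoSeries(xr.DataArray(d, dims=("unit", "time"), coords=coords), "TE", "x")
        sb = InfoSeries(xr.DataArray(np.zeros_like(d), dims=("unit", "time"),
                                     coords=coords), "TE", "x")
        res = condition_contrast(sa, sb, n_perm=100, seed=r)
        if res["a_gt_b"].significant(0.05):
            fp += 1
    assert 0.0 <= fp / runs <= 0.12


def test_subject_reproducibility():
    subjects = np.repeat(np.arange(8), 3)
    assert subject_reproducibility(np.ones(24, bool), subjects) == 1.0
    half = np.zeros(24, bool)
    half[subjects < 4] = True
    assert subject_reproducibility(half, subjects) == 0.5
    assert subject_reproducibility(np.zeros(24, bool), subjects) == 0.0
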