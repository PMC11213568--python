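"""Random-effects group inference with cluster-based permutation correction.

The same framework serves the local level (units = contacts, MI) and the
network level (units = pairs, II/TE).  At each time point a one-sample t-test
is computed across units of the observed information minus each unit's own
permutation mean; the identical statistic applied to every permutation slice
builds the null t-distribution.  The cluster-forming threshold is the 95th
percentile of the permutation t-values; contiguous supra-threshold runs form
temporal clusters whose mass (summed t) is compared against the distribution
of the largest per-permutation cluster masses, giving family-wise corrected
p-values.

The module also provides per-contact selectivity categorization
(RPE-specific / PPE-specific / Both / Irrelevant), binning of full-PE
interaction information by the local selectivity of the paired contacts with
one-sample t-tests and Benjamini-Hochberg FDR, paired condition contrasts
with sign-flip nulls, and inter-subject reproducibility proportions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .dynamics import InfoSeries

__all__ = [
    "Cluster",
    "ClusterResult",
    "SelectivityLabels",
    "group_ttest_vs_perm_mean",
    "group_cluster_test",
    "cluster_correct",
    "categorize_contacts",
    "bin_ii_by_selectivity",
    "condition_contrast",
    "subject_reproducibility",
]

LABELS = ("RPE", "PPE", "Both", "Irrelevant")


@dataclass(frozen=True)
class Cluster:
    """One contiguous supra-threshold temporal cluster."""

    start: int  # first time index
    stop: int  # one past the last time index
    mass: float
    p: float


@dataclass(frozen=True)
class ClusterResult:
    """Clusters found in a t time series with corrected p-values."""

    clusters: tuple[Cluster, ...]
    threshold: float
    n_perm: int
    times: np.ndarray | None = None

    def significant(self, alpha: float = 0.05) -> tuple[Cluster, ...]:
        return tuple(c for c in self.clusters if c.p < alpha)

    def mask(self, n_times: int, alpha: float = 0.05) -> np.ndarray:
        m = np.zeros(n_times, dtype=bool)
        for c in self.significant(alpha):
            m[c.start : c.stop] = True
        return m


@dataclass(frozen=True)
class SelectivityLabels:
    """Per contact x time selectivity labels and per-ROI proportions."""

    labels: xr.DataArray  # (unit, time) of strings from LABELS
    contact_label: pd.Series  # one label per contact (time-collapsed)
    proportions: xr.DataArray  # (roi, label, time), sums to 1 over label


def _onesample_t(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """t statistic of mean against 0; 0 where the SD degenerates."""
    n = x.shape[axis]
    m = x.mean(axis=axis)
    sd = x.std(axis=axis, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = m / (sd / np.sqrt(n))
    return np.where(sd > 0, t, 0.0)


def group_ttest_vs_perm_mean(series: InfoSeries) -> tuple[np.ndarray, np.ndarray]:
    """Observed and per-permutation group t time series.

    Returns ``(t_obs, t_perm)`` with shapes (time,) and (perm, time).  Units
    (contacts or pairs) are the random-effects replicates; each unit's
    permutation mean is its own null reference.
    """
    if series.null is None:
        raise ValueError("series carries no permutation null")
    vals = series.values.values  # (unit, time)
    if vals.shape[0] < 2:
        raise ValueError("group test needs >= 2 units")
    null = series.null.values  # (unit, time, perm)
    ref = null.mean(axis=2)
    t_obs = _onesample_t(vals - ref, axis=0)
    t_perm = _onesample_t(null - ref[:, :, None], axis=0).T  # (perm, time)
    return t_obs, t_perm


def group_cluster_test(
    series: InfoSeries,
    direction: int = 1,
    alpha: float = 0.05,
    percentile: float = 95.0,
) -> ClusterResult:
    """Group t-test against the permutation mean plus cluster correction.

    ``direction`` = +1 tests for information above chance (or net synergy for
    II); -1 tests the redundancy direction (information series below the
    permutation mean).
    """
    t_obs, t_perm = group_ttest_vs_perm_mean(series)
    return cluster_correct(
        direction * t_obs,
        direction * t_perm,
        alpha,
        percentile,
        times=series.values["time"].values,
    )


def _find_clusters(t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    above = np.nan_to_num(t, nan=-np.inf) > threshold
    out = []
    start = None
    for i, a in enumerate(above):
        if a and start is None:
            start = i
        elif not a and start is not None:
            out.append((start, i, float(t[start:i].sum())))
            start = None
    if start is not None:
        out.append((start, len(above), float(t[start:].sum())))
    return out


def cluster_correct(
    t_obs: np.ndarray,
    t_perm: np.ndarray,
    alpha: float = 0.05,
    percentile: float = 95.0,
    times: np.ndarray | None = None,
) -> ClusterResult:
    """Cluster-mass correction of a t time series against its permutation null.

    The cluster-forming threshold is the ``percentile`` of all permutation
    t-values; the null distribution of cluster mass is the largest cluster
    mass of each permutation; corrected p = proportion of permutations whose
    maximum mass reaches the observed mass (with the +1 guard so p > 0).
    """
    t_perm = np.asarray(t_perm)
    threshold = float(np.nanpercentile(t_perm, percentile))
    n_perm = t_perm.shape[0]
    max_null = np.zeros(n_perm)
    for p in range(n_perm):
        cl = _find_clusters(t_perm[p], threshold)
        if cl:
            max_null[p] = max(m for _, _, m in cl)
    clusters = []
    for start, stop, mass in _find_clusters(np.asarray(t_obs, dtype=float), threshold):
        pval = (1.0 + np.sum(max_null >= mass)) / (1.0 + n_perm)
        clusters.append(Cluster(start=start, stop=stop, mass=mass, p=float(pval)))
    return ClusterResult(
        clusters=tuple(clusters), threshold=threshold, n_perm=n_perm, times=times
    )


def _contact_cluster_mask(
    obs: np.ndarray, null: np.ndarray, alpha: float, percentile: float
) -> np.ndarray:
    """Significant-time mask for one contact from its own permutation null.

    The contact-level analog of the group rule: threshold at the
    ``percentile`` of the contact's null values (pooled over time and
    permutations), clusters of the observed time course above it, corrected
    against the distribution of each permutation's largest cluster mass.
    """
    threshold = float(np.nanpercentile(null, percentile))
    n_perm = null.shape[-1]
    max_null = np.zeros(n_perm)
    for p in range(n_perm):
        cl = _find_clusters(null[:, p], threshold)
        if cl:
            max_null[p] = max(m for _, _, m in cl)
    mask = np.zeros(obs.shape[0], dtype=bool)
    for start, stop, mass in _find_clusters(obs, threshold):
        pval = (1.0 + np.sum(max_null >= mass)) / (1.0 + n_perm)
        if pval < alpha:
            mask[start:stop] = True
    return mask


def categorize_contacts(
    mi_rpe: InfoSeries,
    mi_ppe: InfoSeries,
    alpha: float = 0.05,
    percentile: float = 95.0,
) -> SelectivityLabels:
    """Label each contact x time point by its PE selectivity.

    A contact is significant for a target wherever its MI time course forms a
    cluster surviving correction against its own permutation null.  Labels:
    significant for RPE only -> ``"RPE"``, PPE only -> ``"PPE"``, both ->
    ``"Both"``, neither -> ``"Irrelevant"``.  The time-collapsed contact
    label uses the same combination logic on "significant anywhere".
    ROI-wise label proportions sum to 1 at every time point.
    """
    if mi_rpe.null is None or mi_ppe.null is None:
        raise ValueError("both series need permutation nulls")
    units = mi_rpe.values["unit"].values
    if not np.array_equal(units, mi_ppe.values["unit"].values):
        raise ValueError("series must cover the same contacts")
    n_u, n_t = mi_rpe.values.shape
    sig = {}
    for name, series in (("RPE", mi_rpe), ("PPE", mi_ppe)):
        m = np.zeros((n_u, n_t), dtype=bool)
        for u in range(n_u):
            m[u] = _contact_cluster_mask(
                series.values.values[u], series.null.values[u], alpha, percentile
            )
        sig[name] = m
    lab = np.full((n_u, n_t), "Irrelevant", dtype=object)
    lab[sig["RPE"] & ~sig["PPE"]] = "RPE"
    lab[~sig["RPE"] & sig["PPE"]] = "PPE"
    lab[sig["RPE"] & sig["PPE"]] = "Both"
    labels = xr.DataArray(
        lab, dims=("unit", "time"),
        coords={"unit": units, "time": mi_rpe.values["time"].values},
    )
    any_r, any_p = sig["RPE"].any(axis=1), sig["PPE"].any(axis=1)
    contact_label = pd.Series(
        np.select(
            [any_r & any_p, any_r, any_p],
            ["Both", "RPE", "PPE"],
            default="Irrelevant",
        ),
        index=pd.Index(units, name="unit"),
        name="label",
    )
    rois = (
        mi_rpe.values["roi"].values
        if "roi" in mi_rpe.values.coords
        else np.array(["all"] * n_u)
    )
    uroi = np.unique(rois)
    props = np.zeros((len(uroi), len(LABELS), n_t))
    for i, r in enumerate(uroi):
        sel = lab[rois == r]
        for j, L in enumerate(LABELS):
            props[i, j] = (sel == L).mean(axis=0)
    proportions = xr.DataArray(
        props, dims=("roi", "label", "time"),
        coords={"roi": uroi, "label": list(LABELS),
                "time": mi_rpe.values["time"].values},
    )
    return SelectivityLabels(labels=labels, contact_label=contact_label,
                             proportions=proportions)


_PAIR_CATEGORIES = ("RPE-RPE", "PPE-PPE", "PPE-RPE", "Mixed")


def _pair_category(l1: str, l2: str) -> str | None:
    s = {l1, l2}
    if "Irrelevant" in s:
        return None
    if "Both" in s:
        return "Mixed"
    if s == {"RPE"}:
        return "RPE-RPE"
    if s == {"PPE"}:
        return "PPE-PPE"
    return "PPE-RPE"


def bin_ii_by_selectivity(
    ii_values: pd.DataFrame,
    contact_labels: pd.Series,
    window_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Bin full-PE II pairs by the local selectivity of their contacts.

    ``ii_values`` must carry columns ``contact1``, ``contact2`` and either a
    ``mean_ii`` column or time columns to be averaged over ``window_mask``.
    Categories: RPE-RPE, PPE-PPE, PPE-RPE and Mixed (a "Both" contact
    involved); pairs with an Irrelevant contact are dropped.  Each category
    present is tested against 0 with a one-sample t-test and the p-values are
    Benjamini-Hochberg corrected across present categories.

    Returns a DataFrame with category, n_pairs, mean, t, dof, p, p_fdr.
    """
    if "mean_ii" in ii_values.columns:
        means = ii_values["mean_ii"].to_numpy()
    else:
        tcols = [c for c in ii_values.columns if c not in ("contact1", "contact2")]
        vals = ii_values[tcols].to_numpy(dtype=float)
        if window_mask is not None:
            vals = vals[:, np.asarray(window_mask, dtype=bool)]
        means = vals.mean(axis=1)
    cats = [
        _pair_category(contact_labels.get(c1), contact_labels.get(c2))
        for c1, c2 in zip(ii_values["contact1"], ii_values["contact2"])
    ]
    rows = []
    for cat in _PAIR_CATEGORIES:
        x = means[[c == cat for c in cats]]
        if len(x) < 2:
            continue
        t, p = sps.ttest_1samp(x, 0.0)
        rows.append(
            {"category": cat, "n_pairs": len(x), "mean": float(np.mean(x)),
             "t": float(t), "dof": len(x) - 1, "p": float(p)}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_fdr"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def condition_contrast(
    series_a: InfoSeries,
    series_b: InfoSeries,
    n_perm: int = 1000,
    seed: int | None = None,
    alpha: float = 0.05,
    percentile: float = 95.0,
) -> dict[str, ClusterResult]:
    """Paired contrast of two information series over the same units.

    A paired t-test is computed per time point on a - b; the null randomly
    exchanges the condition labels within unit (sign flips of the paired
    differences).  Cluster correction is applied separately per direction;
    the result maps ``"a_gt_b"`` and ``"b_gt_a"`` to ClusterResults.
    """
    va, vb = series_a.values, series_b.values
    if not np.array_equal(va["unit"].values, vb["unit"].values):
        raise ValueError("the two series must cover the same units")
    d = np.nan_to_num(va.values - vb.values, nan=0.0)  # (unit, time)
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, d.shape[0]))
    t_obs = _onesample_t(d, axis=0)
    t_perm = np.stack(
        [_onesample_t(signs[p][:, None] * d, axis=0) for p in range(n_perm)]
    )
    times = va["time"].values
    return {
        "a_gt_b": cluster_correct(t_obs, t_perm, alpha, percentile, times=times),
        "b_gt_a": cluster_correct(-t_obs, -t_perm, alpha, percentile, times=times),
    }


def subject_reproducibility(
    significant: np.ndarray, subjects: np.ndarray
) -> float:
    """Fraction of subjects contributing at least one significant unit."""
    significant = np.asarray(significant, dtype=bool)
    subjects = np.asarray(subjects)
    uniq = np.unique(subjects)
    hit = sum(bool(significant[subjects == s].any()) for s in uniq)
    return hit / len(uniq)
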