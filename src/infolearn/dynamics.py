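"""Time-resolved, across-trials information measures on epoch arrays.

All measures share the same scheme: at every time sample, the across-trial
vector of gamma power (per contact) is copula-normalized and a Gaussian-model
information quantity is computed against the behavioral target (prediction
error) or against another contact's signal:

* ``mi_timecourse``          -- I(gamma; PE) per contact and time (bits);
* ``interaction_information``-- II(g1, g2; PE) = I(g1,g2;PE) - I(g1;PE)
  - I(g2;PE); negative values are redundancy-dominated, positive values
  synergy-dominated;
* ``transfer_entropy``       -- TE(X->Y) = I(X_{t-d}; Y_t | Y_{t-d}) averaged
  over a window of delays d (default 116-236 ms, one-sample steps at 256 Hz);
* ``te_delay_profile``       -- the same quantity on an explicit delay grid,
  with the argmax delay.

Permutation null distributions reproduce the estimator under the null by
shuffling the PE across trials (MI, II) or the source signal across trials
(TE), with the same estimator applied to every shuffle.

The "past" of source and target in the transfer entropy is the single sample
at lag d (no multi-sample embedding); temporal breadth comes from averaging
over the delay window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr
from scipy.special import ndtri
from scipy.stats import rankdata

from . import gcmi
from .gcmi import _mi_bias_nats  # net plug-in bias helpers (package-internal)

__all__ = [
    "DelayWindow",
    "InfoSeries",
    "mi_timecourse",
    "interaction_information",
    "transfer_entropy",
    "te_delay_profile",
    "build_permutation_null",
]

_LN2 = np.log(2.0)
_MIN_TRIALS = 20


@dataclass(frozen=True)
class DelayWindow:
    """Interval of delays (s) over which transfer entropy is averaged."""

    d1: float = 0.116
    d2: float = 0.236
    step: int = 1

    def __post_init__(self) -> None:
        if not 0 < self.d1 < self.d2:
            raise ValueError("need 0 < d1 < d2")
        if self.step < 1:
            raise ValueError("step must be >= 1 sample")

    def samples(self, sfreq: float) -> np.ndarray:
        d1 = int(np.ceil(self.d1 * sfreq))
        d2 = int(np.floor(self.d2 * sfreq))
        return np.arange(d1, d2 + 1, self.step)


@dataclass
class InfoSeries:
    """Per-unit information time courses (bits) with their permutation null.

    ``values`` is (unit, time); ``null`` is (unit, time, perm) or None.
    ``unit`` indexes contacts for MI and directed/undirected pairs for TE/II.
    """

    values: xr.DataArray
    measure: str
    target: str
    null: xr.DataArray | None = None
    seed: int | None = None

    @property
    def n_perm(self) -> int:
        return 0 if self.null is None else self.null.sizes["perm"]

    @property
    def time(self) -> np.ndarray:
        return self.values["time"].values


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------


def _copnorm_last(x: np.ndarray) -> np.ndarray:
    """Copula-normalize along the last (trial) axis."""
    n = x.shape[-1]
    r = rankdata(x, axis=-1, method="average")
    return ndtri(r / (n + 1.0))


def _select_trials(epochs: xr.DataArray, pe: pd.DataFrame, target: str):
    """Trial mask and PE target values for an analysis target."""
    if target == "RPE":
        mask = (pe["condition"] == "reward").to_numpy()
    elif target == "PPE":
        mask = (pe["condition"] == "punishment").to_numpy()
    elif target == "PE":
        mask = np.ones(len(pe), dtype=bool)
    else:
        raise ValueError(f"unknown target {target!r}")
    if epochs.sizes["trial"] != len(pe):
        raise ValueError("epoch trials do not match the PE table")
    n = int(mask.sum())
    if n < _MIN_TRIALS:
        raise ValueError(f"need >= {_MIN_TRIALS} trials for target {target}, got {n}")
    return mask, pe.loc[mask, "pe"].to_numpy()


def _perm_indices(rng: np.random.Generator, n: int, n_perm: int) -> np.ndarray:
    return np.stack([rng.permutation(n) for _ in range(n_perm)])


def _demean(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=-1, keepdims=True)


def _mi_curves(cx: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """I(x; y) bits for cx (..., n) against each row of ys (P, n).

    Exploits that every permutation of y has the same marginal variance, so
    only the cross-covariances depend on the permutation.  Returns
    (..., P).
    """
    n = cx.shape[-1]
    cxd, ysd = _demean(cx), _demean(ys)
    vx = np.sum(cxd * cxd, axis=-1) / (n - 1)
    vy = np.sum(ysd[0] * ysd[0]) / (n - 1)
    cxy = np.tensordot(cxd, ysd, axes=([-1], [-1])) / (n - 1)  # (..., P)
    det = vx[..., None] * vy - cxy**2
    if np.any(det <= 0):
        raise gcmi.DegenerateDataError("degenerate gamma/PE covariance")
    i_nats = 0.5 * (np.log(vx)[..., None] + np.log(vy) - np.log(det))
    return (i_nats - _mi_bias_nats((1, 1), n)) / _LN2


def _ii_curves(x1: np.ndarray, x2: np.ndarray, ys: np.ndarray) -> np.ndarray:
    """Interaction information (bits) for a pair against each row of ys.

    x1, x2: (T, n) normalized power; ys: (P, n) target rows (row 0 may be the
    observed ordering).  Returns (T, P).
    """
    n = x1.shape[-1]
    x1d, x2d, ysd = _demean(x1), _demean(x2), _demean(ys)
    v11 = np.sum(x1d * x1d, axis=-1) / (n - 1)
    v22 = np.sum(x2d * x2d, axis=-1) / (n - 1)
    c12 = np.sum(x1d * x2d, axis=-1) / (n - 1)
    vyy = np.sum(ysd[0] * ysd[0]) / (n - 1)
    c1y = x1d @ ysd.T / (n - 1)  # (T, P)
    c2y = x2d @ ysd.T / (n - 1)
    v11_, v22_, c12_ = v11[:, None], v22[:, None], c12[:, None]
    det2 = v11 * v22 - c12**2
    det3 = (
        v11_ * (v22_ * vyy - c2y**2)
        - c12_ * (c12_ * vyy - c2y * c1y)
        + c1y * (c12_ * c2y - v22_ * c1y)
    )
    for d in (det2, det3):
        if np.any(d <= 0):
            raise gcmi.DegenerateDataError("degenerate pair covariance")
    i_joint = 0.5 * (np.log(det2)[:, None] + np.log(vyy) - np.log(det3)) / _LN2
    i_joint -= _mi_bias_nats((2, 1), n) / _LN2
    i1 = 0.5 * (np.log(v11_) + np.log(vyy) - np.log(v11_ * vyy - c1y**2)) / _LN2
    i2 = 0.5 * (np.log(v22_) + np.log(vyy) - np.log(v22_ * vyy - c2y**2)) / _LN2
    bias1 = _mi_bias_nats((1, 1), n) / _LN2
    return i_joint - (i1 - bias1) - (i2 - bias1)


def _te_curve(x: np.ndarray, y: np.ndarray, delays: np.ndarray) -> np.ndarray:
    """Delay-averaged TE(X->Y) over time; x, y are (T, n) normalized power.

    Returns (T,) with NaN where t - max(delay) falls before the epoch start.
    """
    T = x.shape[0]
    out = np.full(T, np.nan)
    acc = np.zeros(T - delays.max())
    t0 = delays.max()
    for d in delays:
        xd = x[t0 - d : T - d]
        yd = y[t0 - d : T - d]
        yt = y[t0:]
        acc += gcmi.batch_cmi_1d(xd, yt, yd)
    out[t0:] = acc / len(delays)
    return out


# ---------------------------------------------------------------------------
# public measures
# ---------------------------------------------------------------------------


def mi_timecourse(
    epochs: xr.DataArray,
    pe: pd.DataFrame,
    target: str = "RPE",
    n_perm: int = 0,
    seed: int | None = None,
) -> InfoSeries:
    """Time course of I(gamma power; PE) per contact, in bits.

    Trials are restricted to the target's condition (all trials for the full
    signed PE).  When ``n_perm`` > 0 the PE values are shuffled across trials
    that many times and the same estimator is applied per shuffle.
    """
    mask, y = _select_trials(epochs, pe, target)
    n = len(y)
    cx = _copnorm_last(
        epochs.values[:, mask, :].transpose(0, 2, 1)
    )  # (contact, time, n)
    cy = _copnorm_last(y[None, :])  # (1, n)
    values = _mi_curves(cx, cy)[..., 0]
    null = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        ys = cy[0][_perm_indices(rng, n, n_perm)]
        null = _mi_curves(cx, ys)
    coords = {"contact": epochs["contact"].values, "time": epochs["time"].values}
    da = xr.DataArray(values, dims=("contact", "time"), coords=coords)
    for aux in ("subject", "roi", "role"):
        if aux in epochs.coords:
            da = da.assign_coords({aux: ("contact", epochs[aux].values)})
    null_da = None
    if null is not None:
        null_da = xr.DataArray(
            null, dims=("contact", "time", "perm"), coords=coords | {"perm": np.arange(n_perm)}
        )
    return InfoSeries(values=da.rename(contact="unit"), measure="MI", target=target,
                      null=None if null_da is None else null_da.rename(contact="unit"),
                      seed=seed)


def _pair_arrays(epochs: xr.DataArray, pair, mask):
    i, j = pair
    subj = epochs["subject"].values if "subject" in epochs.coords else None
    if subj is not None and subj[i] != subj[j]:
        raise ValueError("pairs must be formed within a subject")
    x1 = _copnorm_last(epochs.values[i][mask].T)  # (time, n)
    x2 = _copnorm_last(epochs.values[j][mask].T)
    return x1, x2


def interaction_information(
    epochs: xr.DataArray,
    pe: pd.DataFrame,
    pair: tuple[int, int],
    target: str = "PE",
    n_perm: int = 0,
    seed: int | None = None,
) -> InfoSeries:
    """Time course of II(g1, g2; PE) for one contact pair, in bits.

    Negative values indicate redundancy-dominated, positive values
    synergy-dominated encoding of the PE by the pair.  The permutation null
    shuffles the PE across trials.
    """
    mask, y = _select_trials(epochs, pe, target)
    n = len(y)
    x1, x2 = _pair_arrays(epochs, pair, mask)
    cy = _copnorm_last(y[None, :])
    values = _ii_curves(x1, x2, cy)[:, 0]
    null = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        ys = cy[0][_perm_indices(rng, n, n_perm)]
        null = _ii_curves(x1, x2, ys)
    times = epochs["time"].values
    da = xr.DataArray(values[None, :], dims=("unit", "time"),
                      coords={"unit": [f"{pair[0]}-{pair[1]}"], "time": times})
    null_da = None
    if null is not None:
        null_da = xr.DataArray(null[None, :, :], dims=("unit", "time", "perm"),
                               coords=da.coords | {"perm": np.arange(n_perm)})
    return InfoSeries(values=da, measure="II", target=target, null=null_da, seed=seed)


def transfer_entropy(
    epochs: xr.DataArray,
    pair: tuple[int, int],
    window: DelayWindow = DelayWindow(),
    trials: np.ndarray | None = None,
    n_perm: int = 0,
    seed: int | None = None,
) -> InfoSeries:
    """Delay-averaged transfer entropy from contact ``pair[0]`` to ``pair[1]``.

    At each target time t and delay d in ``window``,
    ``TE_d = I(X_{t-d}; Y_t | Y_{t-d})`` is estimated across trials with the
    Gaussian-copula CMI; the output is the mean over delays.  Time points
    whose largest delay reaches before the epoch start are NaN.  The
    permutation null shuffles the source signal across trials.
    """
    sfreq = float(epochs.attrs["sfreq"])
    delays = window.samples(sfreq)
    if delays.size == 0 or delays.max() >= epochs.sizes["time"]:
        raise ValueError("delay window outside the epoch")
    if trials is None:
        trials = np.ones(epochs.sizes["trial"], dtype=bool)
    if int(np.sum(trials)) < _MIN_TRIALS:
        raise ValueError(f"need >= {_MIN_TRIALS} trials")
    x, y = _pair_arrays(epochs, pair, trials)
    values = _te_curve(x, y, delays)
    null = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        n = x.shape[-1]
        idx = _perm_indices(rng, n, n_perm)
        null = np.stack([_te_curve(x[:, k], y, delays) for k in idx], axis=-1)
    times = epochs["time"].values
    name = f"{pair[0]}->{pair[1]}"
    da = xr.DataArray(values[None, :], dims=("unit", "time"),
                      coords={"unit": [name], "time": times})
    null_da = None
    if null is not None:
        null_da = xr.DataArray(null[None, :, :], dims=("unit", "time", "perm"),
                               coords=da.coords | {"perm": np.arange(n_perm)})
    return InfoSeries(values=da, measure="TE", target="power", null=null_da, seed=seed)


def te_delay_profile(
    epochs: xr.DataArray,
    pair: tuple[int, int],
    delays_s: np.ndarray | None = None,
    trials: np.ndarray | None = None,
) -> xr.DataArray:
    """Per-delay TE(X->Y) profile (mean over valid times) with argmax delay.

    ``delays_s`` defaults to 20-400 ms in one-sample steps.  The returned
    DataArray is indexed by delay (s) and stores the argmax delay in
    ``attrs['argmax_delay']``.
    """
    sfreq = float(epochs.attrs["sfreq"])
    if delays_s is None:
        d = np.arange(int(np.ceil(0.020 * sfreq)), int(0.400 * sfreq) + 1)
    else:
        d = np.unique(np.round(np.asarray(delays_s) * sfreq).astype(int))
        if (d < 1).any():
            raise ValueError("delays must be >= 1 sample")
    if trials is None:
        trials = np.ones(epochs.sizes["trial"], dtype=bool)
    x, y = _pair_arrays(epochs, pair, trials)
    T = x.shape[0]
    prof = np.empty(len(d))
    for k, dk in enumerate(d):
        xd, yt, yd = x[: T - dk], y[dk:], y[: T - dk]
        prof[k] = gcmi.batch_cmi_1d(xd, yt, yd).mean()
    out = xr.DataArray(prof, dims=("delay",), coords={"delay": d / sfreq})
    out.attrs["argmax_delay"] = float(d[np.argmax(prof)] / sfreq)
    return out


def concat_series(series: list[InfoSeries], units=None) -> InfoSeries:
    """Stack per-subject series of the same measure into one multi-unit series."""
    if not series:
        raise ValueError("no series to concatenate")
    measure, target = series[0].measure, series[0].target
    if any(s.measure != measure or s.target != target for s in series):
        raise ValueError("series mix measures or targets")
    vals = np.concatenate([s.values.values for s in series], axis=0)
    if units is None:
        units = [f"{k}:{u}" for k, s in enumerate(series) for u in s.values["unit"].values]
    da = xr.DataArray(vals, dims=("unit", "time"),
                      coords={"unit": units, "time": series[0].values["time"].values})
    null = None
    if all(s.null is not None for s in series):
        nv = np.concatenate([s.null.values for s in series], axis=0)
        null = xr.DataArray(nv, dims=("unit", "time", "perm"),
                            coords=da.coords | {"perm": np.arange(nv.shape[-1])})
    return InfoSeries(values=da, measure=measure, target=target, null=null,
                      seed=series[0].seed)


def build_permutation_null(
    measure: str,
    epochs: xr.DataArray,
    pe: pd.DataFrame | None = None,
    n_perm: int = 1000,
    seed: int | None = None,
    **kwargs,
) -> InfoSeries:
    """Estimate a measure together with its permutation null distribution.

    MI and II nulls shuffle the PE across trials; the TE null shuffles the
    source's trials.  Dispatches to the measure functions with ``n_perm``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if measure == "MI":
        return mi_timecourse(epochs, pe, n_perm=n_perm, seed=seed, **kwargs)
    if measure == "II":
        return interaction_information(epochs, pe, n_perm=n_perm, seed=seed, **kwargs)
    if measure == "TE":
        return transfer_entropy(epochs, n_perm=n_perm, seed=seed, **kwargs)
    raise ValueError(f"unknown measure {measure!r}")
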