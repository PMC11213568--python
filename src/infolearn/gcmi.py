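"""Gaussian-copula information estimators.

The estimators in this module are the numerical heart of the package.  Each
variable is first *copula-normalized*: its samples are replaced by the inverse
standard-normal CDF of their (average) ranks.  Mutual information is then
computed under a Gaussian model on the normalized scores, from log-determinants
of covariance blocks.  Because only the ranks of the data enter, the resulting
estimate is invariant under any strictly monotone transform of each variable
and is a lower bound on the true mutual information.

A parametric small-sample bias correction (the expected log-determinant of a
Wishart-distributed sample covariance, expressed through digamma functions) is
applied by default, so that estimates for independent variables are centred on
zero; bias-corrected values may therefore be slightly negative.

All public estimators report information in **bits**.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri, psi
from scipy.stats import rankdata

__all__ = [
    "DegenerateDataError",
    "InfoEstimate",
    "copula_normalize",
    "mi_gg",
    "cmi_ggg",
    "gcmi",
]

_LN2 = np.log(2.0)
_MIN_SAMPLES = 8


class DegenerateDataError(ValueError):
    """Raised when the data cannot support a Gaussian-copula estimate.

    Typical causes: a constant column (ranks are undefined up to ties), or a
    singular joint covariance (one variable duplicates another exactly).
    """


@dataclass(frozen=True)
class InfoEstimate:
    """An information estimate in bits with its estimation context."""

    value: float
    bias_corrected: bool
    n_samples: int
    dims: tuple[int, int, int]

    def __float__(self) -> float:  # pragma: no cover - convenience
        return float(self.value)


def _as_2d(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[:, None]
    if x.ndim != 2:
        raise ValueError(f"expected samples x dims array, got shape {x.shape}")
    return x


def copula_normalize(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Map each column of ``x`` to standard-normal scores of its ranks.

    Ranks (ties get the average rank) are scaled to ``r / (n + 1)`` and passed
    through the inverse normal CDF.  The output is a deterministic function of
    the within-column ordering only, hence exactly invariant under strictly
    increasing transforms.

    Parameters
    ----------
    x : array
        Data with samples along ``axis`` (default: first axis).
    axis : int
        Sample axis; every other axis indexes a separate variable.

    Raises
    ------
    DegenerateDataError
        If any column is constant.
    ValueError
        If fewer than 8 samples are provided.
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[axis]
    if n < _MIN_SAMPLES:
        raise ValueError(f"need at least {_MIN_SAMPLES} samples, got {n}")
    if (np.ptp(x, axis=axis) == 0).any():
        raise DegenerateDataError("constant column: copula ranks undefined")
    r = rankdata(x, axis=axis, method="average")
    return ndtri(r / (n + 1.0))


def _ent_bias_nats(d: int, n: int) -> float:
    """Bias of the plug-in Gaussian entropy for dimension d and n samples."""
    psiterms = psi((n - np.arange(1, d + 1)) / 2.0).sum() / 2.0
    dterm = (_LN2 - np.log(n - 1.0)) / 2.0
    return d * dterm + psiterms


def _logdet(cov: np.ndarray) -> float:
    """Log-determinant via Cholesky; raises on a non-PD covariance."""
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise DegenerateDataError(
            "singular joint covariance (duplicated or collinear variables)"
        ) from exc
    return 2.0 * np.log(np.diag(chol)).sum()


def _ent_nats(cov: np.ndarray, n: int, bias_correct: bool) -> float:
    d = cov.shape[0]
    h = 0.5 * _logdet(cov) + 0.5 * d * (np.log(2.0 * np.pi) + 1.0)
    if bias_correct:
        h -= _ent_bias_nats(d, n)
    return h


def mi_gg(x: np.ndarray, y: np.ndarray, bias_correct: bool = True) -> InfoEstimate:
    """Gaussian-model mutual information I(X;Y) in bits.

    ``x`` and ``y`` are (n, dx) / (n, dy) arrays of copula-normalized (or
    otherwise jointly Gaussian) scores.  The estimate is
    ``H(X) + H(Y) - H(X,Y)`` from sample covariances, with an analytic
    small-sample bias correction when ``bias_correct`` is set.
    """
    x, y = _as_2d(x), _as_2d(y)
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of samples")
    n = x.shape[0]
    xy = np.concatenate([x, y], axis=1)
    xy = xy - xy.mean(axis=0)
    c = xy.T @ xy / (n - 1)
    dx = x.shape[1]
    i_nats = (
        _ent_nats(c[:dx, :dx], n, bias_correct)
        + _ent_nats(c[dx:, dx:], n, bias_correct)
        - _ent_nats(c, n, bias_correct)
    )
    return InfoEstimate(
        value=float(i_nats / _LN2),
        bias_corrected=bias_correct,
        n_samples=n,
        dims=(dx, y.shape[1], 0),
    )


def cmi_ggg(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, bias_correct: bool = True
) -> InfoEstimate:
    """Gaussian-model conditional mutual information I(X;Y|Z) in bits.

    Computed as ``H(X,Z) + H(Y,Z) - H(X,Y,Z) - H(Z)`` on the joint sample
    covariance of the normalized scores.
    """
    x, y, z = _as_2d(x), _as_2d(y), _as_2d(z)
    if not (x.shape[0] == y.shape[0] == z.shape[0]):
        raise ValueError("x, y and z must have the same number of samples")
    n = x.shape[0]
    dx, dy, dz = x.shape[1], y.shape[1], z.shape[1]
    xyz = np.concatenate([x, y, z], axis=1)
    xyz = xyz - xyz.mean(axis=0)
    c = xyz.T @ xyz / (n - 1)
    ix = slice(0, dx)
    iy = slice(dx, dx + dy)
    iz = slice(dx + dy, dx + dy + dz)
    xz = np.r_[ix, iz]
    yz = np.r_[iy, iz]
    i_nats = (
        _ent_nats(c[np.ix_(xz, xz)], n, bias_correct)
        + _ent_nats(c[np.ix_(yz, yz)], n, bias_correct)
        - _ent_nats(c, n, bias_correct)
        - _ent_nats(c[iz, iz], n, bias_correct)
    )
    return InfoEstimate(
        value=float(i_nats / _LN2),
        bias_corrected=bias_correct,
        n_samples=n,
        dims=(dx, dy, dz),
    )


def gcmi(
    x: np.ndarray,
    y: np.ndarray,
    z: np.ndarray | None = None,
    bias_correct: bool = True,
) -> InfoEstimate:
    """Copula-normalize raw data then estimate MI (or CMI given ``z``)."""
    cx = copula_normalize(_as_2d(x))
    cy = copula_normalize(_as_2d(y))
    if z is None:
        return mi_gg(cx, cy, bias_correct=bias_correct)
    cz = copula_normalize(_as_2d(z))
    return cmi_ggg(cx, cy, cz, bias_correct=bias_correct)


# ---------------------------------------------------------------------------
# Vectorized kernels.
#
# The time-resolved measures evaluate thousands of small-dimensional Gaussian
# MI terms (one per time sample, permutation, delay...).  The helpers below
# operate on arrays whose *last* axis is the sample axis and broadcast over
# all leading axes, using closed-form 2x2 / 3x3 determinants instead of
# stacked Cholesky factorizations.  Inputs are expected to be already
# copula-normalized.  They are package-internal but stable enough for reuse.
# ---------------------------------------------------------------------------


def _mi_bias_nats(dims: tuple[int, ...], n: int) -> float:
    """Net bias (nats) of sum_i H(block_i) - H(joint) for given block dims."""
    d_tot = int(np.sum(dims))
    return sum(_ent_bias_nats(d, n) for d in dims) - _ent_bias_nats(d_tot, n)


def _check_pos(det: np.ndarray) -> np.ndarray:
    if np.any(det <= 0):
        raise DegenerateDataError("non-positive covariance determinant")
    return det


def _cov(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Sample covariance over the last axis with broadcasting."""
    n = a.shape[-1]
    a = a - a.mean(axis=-1, keepdims=True)
    b = b - b.mean(axis=-1, keepdims=True)
    return np.sum(a * b, axis=-1) / (n - 1)


def batch_mi_1d(x: np.ndarray, y: np.ndarray, bias_correct: bool = True) -> np.ndarray:
    """I(x;y) in bits for 1-D variables; broadcasts over leading axes."""
    n = x.shape[-1]
    vx, vy, cxy = _cov(x, x), _cov(y, y), _cov(x, y)
    det = _check_pos(vx * vy - cxy**2)
    i_nats = 0.5 * (np.log(vx) + np.log(vy) - np.log(det))
    if bias_correct:
        i_nats = i_nats - _mi_bias_nats((1, 1), n)
    return i_nats / _LN2


def batch_mi_2d_1d(
    x1: np.ndarray, x2: np.ndarray, y: np.ndarray, bias_correct: bool = True
) -> np.ndarray:
    """I([x1,x2]; y) in bits; broadcasts over leading axes."""
    n = x1.shape[-1]
    v11, v22, vyy = _cov(x1, x1), _cov(x2, x2), _cov(y, y)
    c12, c1y, c2y = _cov(x1, x2), _cov(x1, y), _cov(x2, y)
    det2 = _check_pos(v11 * v22 - c12**2)
    det3 = _check_pos(
        v11 * (v22 * vyy - c2y**2)
        - c12 * (c12 * vyy - c2y * c1y)
        + c1y * (c12 * c2y - v22 * c1y)
    )
    i_nats = 0.5 * (np.log(det2) + np.log(vyy) - np.log(det3))
    if bias_correct:
        i_nats = i_nats - _mi_bias_nats((2, 1), n)
    return i_nats / _LN2


def batch_cmi_1d(
    x: np.ndarray, y: np.ndarray, z: np.ndarray, bias_correct: bool = True
) -> np.ndarray:
    """I(x; y | z) in bits for 1-D variables; broadcasts over leading axes."""
    n = x.shape[-1]
    vxx, vyy, vzz = _cov(x, x), _cov(y, y), _cov(z, z)
    cxy, cxz, cyz = _cov(x, y), _cov(x, z), _cov(y, z)
    det_xz = _check_pos(vxx * vzz - cxz**2)
    det_yz = _check_pos(vyy * vzz - cyz**2)
    det_xyz = _check_pos(
        vxx * (vyy * vzz - cyz**2)
        - cxy * (cxy * vzz - cyz * cxz)
        + cxz * (cxy * cyz - vyy * cxz)
    )
    i_nats = 0.5 * (np.log(det_xz) + np.log(det_yz) - np.log(det_xyz) - np.log(vzz))
    if bias_correct:
        # H(xz) + H(yz) - H(xyz) - H(z)
        b = (
            _ent_bias_nats(2, n) * 2
            - _ent_bias_nats(3, n)
            - _ent_bias_nats(1, n)
        )
        i_nats = i_nats - b
    return i_nats / _LN2
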