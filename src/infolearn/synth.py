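"""Synthetic task, behavior and neural-epoch generators.

This module stands in for the patient recordings: it produces the
probabilistic learning task (4 cue pairs per session, 24 repetitions each,
reciprocal 0.75/0.25 contingencies, reward pairs paying +1/0 and punishment
pairs -1/0), Q-learning behavior through :mod:`infolearn.behavior`, and
outcome-locked gamma-power surrogates whose across-trial amplitude is coupled
to the prediction error with configurable structure:

``local``
    a single contact whose response amplitude tracks the PE;
``redundant_pair``
    two contacts driven by one shared PE-locked latent source, so their
    interaction information about the PE is negative (redundancy);
``synergistic_pair``
    contact 1 = PE signal + shared noise, contact 2 = the shared noise alone;
    conditioning on contact 2 denoises contact 1, so the pair is net
    synergistic about the PE;
``directed_pair``
    contact Y reproduces contact X at a fixed lag, giving a ground-truth
    direction and delay for transfer entropy.

Epochs are time-locked to outcome onset (t = 0), span -0.5 to +1.5 s at
256 Hz by default, and the PE-locked response is a Gaussian temporal kernel
at 0.5 s latency (width 0.15 s), matching the post-outcome gamma dynamics the
pipeline is designed to resolve.  Background activity is AR(1) noise scaled
to unit stationary variance — cheap, but autocorrelated enough that the
transfer-entropy conditioning on the target's past is meaningful.

Every generator is deterministic given its seed and reports its ground truth
in the returned objects.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import xarray as xr

from .behavior import QParams, compute_prediction_errors, simulate_agent

__all__ = [
    "TaskConfig",
    "CouplingSpec",
    "DEFAULT_AGENT",
    "default_times",
    "generate_task",
    "generate_behavior",
    "generate_epochs",
    "make_redundant_pair",
    "make_synergistic_pair",
    "make_directed_pair",
    "generate_raw_lfp",
    "build_summary_cohort",
    "build_null_cohort",
]

#: Generating agent used across the synthetic cohorts: moderately fast
#: learner, moderate exploration, small positive perseveration.
DEFAULT_AGENT = QParams(alpha=0.3, beta=0.2, theta=0.1)


@dataclass(frozen=True)
class TaskConfig:
    """Layout of the probabilistic learning task."""

    n_sessions: int = 1
    pairs_per_session: int = 4
    reps_per_pair: int = 24
    contingency: float = 0.75
    training_session: bool = False

    def __post_init__(self) -> None:
        if not 0.5 < self.contingency < 1.0:
            raise ValueError("contingency must be in (0.5, 1)")
        if self.reps_per_pair < 1:
            raise ValueError("reps_per_pair must be >= 1")
        if self.pairs_per_session % 2:
            raise ValueError("pairs_per_session must be even (half reward/punish)")


@dataclass(frozen=True)
class CouplingSpec:
    """Ground-truth coupling between PE and simulated gamma power.

    gain is in z-units of response amplitude per unit PE; latency/width/lag
    are in seconds relative to outcome onset.  ``shared_frac`` sets the
    PE-driven shared-source weight of redundant pairs, ``shared_noise_sd``
    the common-noise amplitude of synergistic pairs, and ``directed_gain`` /
    ``gate`` the strength and (optional) condition gating of directed pairs.
    """

    target: str = "RPE"  # {"RPE", "PPE", "both", "none"}
    mode: str = "local"  # {"local", "redundant_pair", "synergistic_pair", "directed_pair"}
    gain: float = 1.0
    latency: float = 0.5
    width: float = 0.15
    lag: float = 0.15
    ar_coef: float = 0.9
    noise_sd: float = 1.0
    shared_frac: float = 0.8
    shared_noise_sd: float = 1.0
    directed_gain: float = 0.8
    gate: str | None = None  # restrict directed coupling to one condition

    def __post_init__(self) -> None:
        if self.target not in ("RPE", "PPE", "both", "none"):
            raise ValueError(f"unknown target {self.target!r}")
        if self.mode not in (
            "local",
            "redundant_pair",
            "synergistic_pair",
            "directed_pair",
        ):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.gain < 0:
            raise ValueError("gain must be >= 0")
        if not 0.0 <= self.ar_coef < 1.0:
            raise ValueError("AR coefficient must be in [0, 1)")


def default_times(sfreq: float = 256.0, tmin: float = -0.5, tmax: float = 1.5) -> np.ndarray:
    """Outcome-locked time axis (s); t = 0 is outcome onset."""
    n = int(round((tmax - tmin) * sfreq)) + 1
    return tmin + np.arange(n) / sfreq


# ---------------------------------------------------------------------------
# Task and behavior
# ---------------------------------------------------------------------------


def generate_task(
    config: TaskConfig = TaskConfig(),
    seed: int | None = None,
    subject: int = 0,
    pair_offset: int = 0,
) -> pd.DataFrame:
    """Generate a task layout (no choices yet).

    Each session carries ``pairs_per_session`` cue pairs, half reward and
    half punishment, each repeated ``reps_per_pair`` times in a randomly
    intermingled order with left/right position counterbalanced.  A training
    session has 2 pairs x 8 repetitions (16 trials).  Outcomes for both cues
    of every trial are pre-drawn from the reciprocal contingencies
    (``contingency`` for the better cue, ``1 - contingency`` for the worse),
    so that simulated choices can be resolved deterministically.

    Pair ids are globally unique across sessions (offset by ``pair_offset``).
    """
    rng = np.random.default_rng(seed)
    if config.training_session:
        pairs_per_session, reps = 2, 8
    else:
        pairs_per_session, reps = config.pairs_per_session, config.reps_per_pair
    rows = []
    next_pair = pair_offset
    for sess in range(config.n_sessions):
        conditions = ["reward", "punishment"] * (pairs_per_session // 2)
        pair_ids = list(range(next_pair, next_pair + pairs_per_session))
        next_pair += pairs_per_session
        order = np.repeat(np.arange(pairs_per_session), reps)
        rng.shuffle(order)
        rep_count = np.zeros(pairs_per_session, dtype=int)
        # counterbalanced positions per pair
        positions = {}
        for k in range(pairs_per_session):
            pos = np.array(["L", "R"] * ((reps + 1) // 2))[:reps]
            rng.shuffle(pos)
            positions[k] = pos
        for t, k in enumerate(order):
            cond = conditions[k]
            c = config.contingency
            if cond == "reward":
                ob = 1.0 if rng.random() < c else 0.0
                ow = 1.0 if rng.random() < 1 - c else 0.0
            else:
                ob = 0.0 if rng.random() < c else -1.0
                ow = 0.0 if rng.random() < 1 - c else -1.0
            rows.append(
                {
                    "subject": subject,
                    "session": sess,
                    "trial": t,
                    "pair": pair_ids[k],
                    "condition": cond,
                    "rep": rep_count[k] + 1,
                    "better_pos": positions[k][rep_count[k]],
                    "outcome_better": ob,
                    "outcome_worse": ow,
                }
            )
            rep_count[k] += 1
    return pd.DataFrame(rows)


def generate_behavior(
    config: TaskConfig = TaskConfig(),
    params: QParams = DEFAULT_AGENT,
    seed: int | None = None,
    subject: int = 0,
    pair_offset: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Task + simulated agent + prediction errors in one call.

    Returns ``(trial_table, pe_table)``; the PE table is computed at the
    generating parameters.
    """
    ss = np.random.SeedSequence(seed)
    s_task, s_agent = (int(s.generate_state(1)[0] >> 1) for s in ss.spawn(2))
    layout = generate_task(config, seed=s_task, subject=subject, pair_offset=pair_offset)
    table = simulate_agent(layout, params, seed=s_agent)
    pe = compute_prediction_errors(table, params)
    return table, pe


# ---------------------------------------------------------------------------
# Epoch building blocks
# ---------------------------------------------------------------------------


def _ar1(rng: np.random.Generator, shape: tuple, coef: float, sd: float) -> np.ndarray:
    """AR(1) noise along the last axis, scaled to stationary SD ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - coef**2)
    x = np.empty(shape)
    e = rng.normal(scale=innov_sd, size=shape)
    x[..., 0] = rng.normal(scale=sd, size=shape[:-1])
    for t in range(1, shape[-1]):
        x[..., t] = coef * x[..., t - 1] + e[..., t]
    return x


def _kernel(times: np.ndarray, latency: float, width: float) -> np.ndarray:
    if not times[0] <= latency <= times[-1]:
        raise ValueError(f"latency {latency} s outside epoch window")
    return np.exp(-0.5 * ((times - latency) / width) ** 2)


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)


def _amplitudes(pe: pd.DataFrame, target: str) -> np.ndarray:
    """Per-trial coupling amplitude: the condition-appropriate PE, z-scored
    within the coupled condition; zero on uncoupled trials."""
    amp = np.zeros(len(pe))
    is_rew = (pe["condition"] == "reward").to_numpy()
    if target == "none":
        return amp
    if target in ("RPE", "both"):
        amp[is_rew] = _standardize(pe.loc[is_rew, "pe"].to_numpy())
    if target in ("PPE", "both"):
        amp[~is_rew] = _standardize(pe.loc[~is_rew, "pe"].to_numpy())
    return amp


def _wrap_epochs(
    data: np.ndarray,
    times: np.ndarray,
    sfreq: float,
    subjects=None,
    rois=None,
) -> xr.DataArray:
    n_c, n_tr, _ = data.shape
    coords = {
        "contact": np.arange(n_c),
        "trial": np.arange(n_tr),
        "time": times,
    }
    da = xr.DataArray(data, dims=("contact", "trial", "time"), coords=coords)
    da = da.assign_coords(
        subject=("contact", np.asarray(subjects if subjects is not None else [0] * n_c)),
        roi=("contact", np.asarray(rois if rois is not None else ["sim"] * n_c)),
    )
    da.attrs["sfreq"] = float(sfreq)
    return da


def generate_epochs(
    pe: pd.DataFrame,
    spec: CouplingSpec = CouplingSpec(),
    times: np.ndarray | None = None,
    sfreq: float = 256.0,
    n_contacts: int = 1,
    seed: int | None = None,
) -> xr.DataArray:
    """Outcome-locked gamma-power surrogate for ``n_contacts`` local contacts.

    Each contact's epoch is AR(1) background noise plus a Gaussian temporal
    kernel at ``spec.latency`` whose per-trial amplitude is
    ``gain * z(PE)`` for the contact's target (zero for ``target='none'``).
    Contacts share the coupling but have independent noise.
    """
    if times is None:
        times = default_times(sfreq)
    rng = np.random.default_rng(seed)
    amp = spec.gain * _amplitudes(pe, spec.target)
    k = _kernel(times, spec.latency, spec.width)
    noise = _ar1(rng, (n_contacts, len(pe), len(times)), spec.ar_coef, spec.noise_sd)
    data = noise + amp[None, :, None] * k[None, None, :]
    return _wrap_epochs(data, times, sfreq)


def make_redundant_pair(
    pe: pd.DataFrame,
    spec: CouplingSpec = CouplingSpec(mode="redundant_pair"),
    times: np.ndarray | None = None,
    sfreq: float = 256.0,
    seed: int | None = None,
) -> xr.DataArray:
    """Two contacts driven by one shared PE-locked source plus private noise.

    The per-trial amplitude of contact i is
    ``gain * (shared_frac * z(PE) + (1 - shared_frac) * e_i)`` with
    independent ``e_i``; at ``shared_frac = 0`` the contacts carry no PE
    information and the interaction information vanishes.
    """
    if times is None:
        times = default_times(sfreq)
    rng = np.random.default_rng(seed)
    z = _amplitudes(pe, spec.target)
    f = spec.shared_frac
    k = _kernel(times, spec.latency, spec.width)
    data = np.empty((2, len(pe), len(times)))
    for i in range(2):
        e = rng.normal(size=len(pe))
        amp = spec.gain * (f * z + (1.0 - f) * e)
        noise = _ar1(rng, (len(pe), len(times)), spec.ar_coef, spec.noise_sd)
        data[i] = noise + amp[:, None] * k[None, :]
    return _wrap_epochs(data, times, sfreq)


def make_synergistic_pair(
    pe: pd.DataFrame,
    spec: CouplingSpec = CouplingSpec(mode="synergistic_pair", noise_sd=0.5),
    times: np.ndarray | None = None,
    sfreq: float = 256.0,
    seed: int | None = None,
) -> xr.DataArray:
    """Synergistic pair: contact 1 = gain*z(PE) + N, contact 2 = N.

    ``N`` is trial-wise noise (SD ``shared_noise_sd``) common to both
    contacts.  Contact 2 alone carries no PE information, but conditioning on
    it removes N from contact 1, so the joint information exceeds the sum of
    the marginals and the interaction information at the response latency is
    positive.
    """
    if times is None:
        times = default_times(sfreq)
    rng = np.random.default_rng(seed)
    z = _amplitudes(pe, spec.target)
    shared = rng.normal(scale=spec.shared_noise_sd, size=len(pe))
    k = _kernel(times, spec.latency, spec.width)
    amps = [spec.gain * z + shared, shared]
    data = np.empty((2, len(pe), len(times)))
    for i, amp in enumerate(amps):
        noise = _ar1(rng, (len(pe), len(times)), spec.ar_coef, spec.noise_sd)
        data[i] = noise + amp[:, None] * k[None, :]
    return _wrap_epochs(data, times, sfreq)


def make_directed_pair(
    spec: CouplingSpec = CouplingSpec(mode="directed_pair"),
    n_trials: int = 200,
    times: np.ndarray | None = None,
    sfreq: float = 256.0,
    conditions: np.ndarray | None = None,
    seed: int | None = None,
) -> xr.DataArray:
    """Lagged directed pair: Y(t) = a * X(t - lag) + private noise.

    X is AR(1) noise; because an AR(1) source is Markov, the reverse-direction
    transfer entropy is zero by construction while the forward direction is
    positive, with a delay profile peaking at ``spec.lag``.  If ``spec.gate``
    names a condition, the coupling applies only on trials of that condition
    (``conditions`` must then be given per trial); contact 0 is the source.
    """
    if times is None:
        times = default_times(sfreq)
    lag_samp = int(round(spec.lag * sfreq))
    if lag_samp <= 0 or lag_samp >= len(times):
        raise ValueError(f"lag {spec.lag} s outside the epoch window")
    rng = np.random.default_rng(seed)
    x = _ar1(rng, (n_trials, len(times)), spec.ar_coef, spec.noise_sd)
    noise_y = _ar1(rng, (n_trials, len(times)), spec.ar_coef, spec.noise_sd)
    a = np.full(n_trials, spec.directed_gain)
    if spec.gate is not None:
        if conditions is None:
            raise ValueError("gated coupling requires per-trial conditions")
        a = np.where(np.asarray(conditions) == spec.gate, spec.directed_gain, 0.0)
    y = noise_y.copy()
    y[:, lag_samp:] += a[:, None] * x[:, :-lag_samp]
    return _wrap_epochs(np.stack([x, y]), times, sfreq)


def generate_raw_lfp(
    envelope: np.ndarray,
    sfreq: float = 1024.0,
    n_trials: int = 50,
    carrier_hz: float = 75.0,
    background_sd: float = 0.5,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Raw voltage traces: a gamma-band carrier amplitude-modulated by
    ``envelope`` plus 1/f background noise.

    Returns ``(traces, envelope)`` with traces shaped (trial, time); the
    carrier phase is randomized per trial.  Used to exercise the spectral
    stage against a known power envelope.
    """
    rng = np.random.default_rng(seed)
    envelope = np.asarray(envelope, dtype=float)
    n = envelope.size
    t = np.arange(n) / sfreq
    phases = rng.uniform(0, 2 * np.pi, size=n_trials)
    carrier = np.cos(2 * np.pi * carrier_hz * t[None, :] + phases[:, None])
    # 1/f background via spectral shaping of white noise
    white = rng.normal(size=(n_trials, n))
    freqs = np.fft.rfftfreq(n, 1 / sfreq)
    shaping = np.where(freqs > 0, 1.0 / np.sqrt(np.maximum(freqs, 1.0)), 0.0)
    pink = np.fft.irfft(np.fft.rfft(white, axis=-1) * shaping[None, :], n=n, axis=-1)
    pink = pink / pink.std(axis=-1, keepdims=True) * background_sd
    return envelope[None, :] * carrier + pink, envelope


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

#: Per-subject contact layout of the summary cohort; roles map onto the four
#: regions the analysis distinguishes.
_SUMMARY_ROLES = (
    ("vmPFC", "red_rpe"),
    ("lOFC", "red_rpe"),
    ("aINS", "red_ppe"),
    ("dlPFC", "red_ppe"),
    ("aINS", "dir_src"),
    ("dlPFC", "dir_dst"),
    ("dlPFC", "syn"),
    ("vmPFC", "syn"),
)


@dataclass(frozen=True)
class _CohortSubject:
    table: pd.DataFrame
    pe: pd.DataFrame
    epochs: xr.DataArray


def build_summary_cohort(
    n_subjects: int = 16,
    n_sessions: int = 2,
    agent: QParams = DEFAULT_AGENT,
    spec: CouplingSpec = CouplingSpec(),
    seed: int | None = None,
) -> list[_CohortSubject]:
    """Cohort reproducing the qualitative network summary of the analysis.

    Per subject, eight contacts: a redundant RPE-coupled vmPFC-lOFC pair, a
    redundant PPE-coupled aINS-dlPFC pair, a punishment-gated lagged
    aINS -> dlPFC directed pair, and a synergistic (full-PE) dlPFC-vmPFC
    pair.  Ground truth: negative II_RPE for the first pair, negative II_PPE
    for the second, TE_Pun > TE_Rew for the directed pair, positive full-PE
    II for the synergistic pair.
    """
    ss = np.random.SeedSequence(seed)
    subjects = []
    for s, sub_ss in enumerate(ss.spawn(n_subjects)):
        seeds = [int(x.generate_state(1)[0] >> 1) for x in sub_ss.spawn(5)]
        table, pe = generate_behavior(
            TaskConfig(n_sessions=n_sessions),
            agent,
            seed=seeds[0],
            subject=s,
            pair_offset=s * 100,
        )
        times = default_times()
        red_rpe = make_redundant_pair(
            pe, replace(spec, mode="redundant_pair", target="RPE"), seed=seeds[1]
        )
        red_ppe = make_redundant_pair(
            pe, replace(spec, mode="redundant_pair", target="PPE"), seed=seeds[2]
        )
        directed = make_directed_pair(
            replace(spec, mode="directed_pair", gate="punishment"),
            n_trials=len(pe),
            conditions=pe["condition"].to_numpy(),
            seed=seeds[3],
        )
        syn = make_synergistic_pair(
            pe,
            replace(spec, mode="synergistic_pair", target="both", noise_sd=0.5),
            seed=seeds[4],
        )
        # give the noise-only contact its own early local response so that the
        # selectivity categorization can label it; the early latency (150 ms,
        # narrow kernel) leaves the 500 ms synergy window untouched
        early = _kernel(times, 0.15, 0.08)
        syn.values[1] += (0.8 * _amplitudes(pe, "both"))[:, None] * early[None, :]
        data = np.concatenate(
            [red_rpe.values, red_ppe.values, directed.values, syn.values], axis=0
        )
        rois = [r for r, _ in _SUMMARY_ROLES]
        epochs = _wrap_epochs(
            data, times, 256.0, subjects=[s] * len(rois), rois=rois
        ).assign_coords(role=("contact", [role for _, role in _SUMMARY_ROLES]))
        subjects.append(_CohortSubject(table=table, pe=pe, epochs=epochs))
    return subjects


def build_null_cohort(
    n_contacts: int = 12,
    n_sessions: int = 1,
    agent: QParams = DEFAULT_AGENT,
    spec: CouplingSpec = CouplingSpec(target="none"),
    seed: int | None = None,
) -> _CohortSubject:
    """Contacts with no PE coupling, for type-I-error calibration."""
    ss = np.random.SeedSequence(seed)
    s_beh, s_ep = (int(x.generate_state(1)[0] >> 1) for x in ss.spawn(2))
    table, pe = generate_behavior(TaskConfig(n_sessions=n_sessions), agent, seed=s_beh)
    epochs = generate_epochs(pe, replace(spec, target="none"), n_contacts=n_contacts, seed=s_ep)
    return _CohortSubject(table=table, pe=pe, epochs=epochs)
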