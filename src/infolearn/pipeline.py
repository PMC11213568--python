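"""End-to-end orchestration: simulate -> fit -> analyze -> report.

A run is described by a :class:`RunConfig` (serializable to/from YAML or
JSON).  One master seed deterministically spawns a named seed per stage, so
re-running any stage with the same config reproduces its outputs exactly.
Every output file is listed in ``manifest.json`` with a SHA-256 checksum.

The demo cohort is the network-summary cohort of
:func:`infolearn.synth.build_summary_cohort`: per subject a redundant
RPE-coupled vmPFC-lOFC pair, a redundant PPE-coupled aINS-dlPFC pair, a
punishment-gated lagged aINS->dlPFC pair and a synergistic full-PE
dlPFC-vmPFC pair.  The analyze stage estimates the interaction-information
time courses (with PE-shuffle permutation nulls) for the three pair families
and the delay-averaged transfer entropy per condition for the directed pair;
the report stage runs the group cluster tests, the TE condition contrast and
the selectivity binning, and writes a markdown summary.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as ilio
from .behavior import QParams, compute_prediction_errors, fit_qlearning
from .dynamics import (
    DelayWindow,
    concat_series,
    interaction_information,
    mi_timecourse,
    transfer_entropy,
)
from .stats import (
    bin_ii_by_selectivity,
    categorize_contacts,
    condition_contrast,
    group_cluster_test,
)
from .synth import CouplingSpec, TaskConfig, build_summary_cohort

__all__ = ["RunConfig", "run", "STAGES"]

STAGES = ("simulate", "fit", "analyze", "report")


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run."""

    seed: int = 0
    n_subjects: int = 16
    n_sessions: int = 2
    n_perm: int = 200
    alpha: float = 0.05
    fit_starts: int = 2
    use_fitted_params: bool = True
    task: TaskConfig = field(default_factory=TaskConfig)
    coupling: CouplingSpec = field(default_factory=CouplingSpec)
    delay_window: DelayWindow = field(default_factory=DelayWindow)
    agent: QParams = field(default_factory=lambda: QParams(0.3, 0.2, 0.1))
    out_dir: str = "runs/demo"
    stages: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (
            ("task", TaskConfig),
            ("coupling", CouplingSpec),
            ("delay_window", DelayWindow),
            ("agent", QParams),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def stage_seed(self, stage: str) -> int:
        """Deterministic per-stage seed derived from the master seed."""
        ss = np.random.SeedSequence(self.seed).spawn(len(STAGES))
        return int(ss[STAGES.index(stage)].generate_state(1)[0] >> 1)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _require(path: Path) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"missing pipeline input: {path}")
    return path


def run(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": config.to_dict(),
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "outputs": {},
        "complete": False,
    }

    def record(name: str, path: Path):
        manifest["outputs"][name] = {"path": str(path), "sha256": _sha256(path)}

    try:
        if "simulate" in config.stages:
            _stage_simulate(config, out, record)
        if "fit" in config.stages:
            _stage_fit(config, out, record)
        if "analyze" in config.stages:
            _stage_analyze(config, out, record)
        if "report" in config.stages:
            _stage_report(config, out, record)
        manifest["complete"] = True
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def _stage_simulate(config: RunConfig, out: Path, record) -> None:
    cohort = build_summary_cohort(
        n_subjects=config.n_subjects,
        n_sessions=config.n_sessions,
        agent=config.agent,
        spec=config.coupling,
        seed=config.stage_seed("simulate"),
    )
    tables = pd.concat([s.table for s in cohort], ignore_index=True)
    p = out / "trials.csv"
    tables.to_csv(p, index=False)
    record("trials", p)
    for k, s in enumerate(cohort):
        p = out / f"epochs_sub{k:02d}.h5"
        ilio.save_epochs(p, s.epochs)
        record(f"epochs_sub{k:02d}", p)


def _stage_fit(config: RunConfig, out: Path, record) -> None:
    tables = pd.read_csv(_require(out / "trials.csv"))
    fits = {}
    pes = []
    seed = config.stage_seed("fit")
    for k, (subj, table) in enumerate(tables.groupby("subject")):
        res = fit_qlearning(table, n_starts=config.fit_starts, seed=seed + k)
        fits[int(subj)] = {
            "alpha": res.params.alpha,
            "beta": res.params.beta,
            "theta": res.params.theta,
            "nll": res.nll,
            "converged": list(res.converged),
        }
        params = res.params if config.use_fitted_params else config.agent
        pe = compute_prediction_errors(table, params)
        pes.append(pe)
    ilio.save_json(out / "fits.json", fits)
    record("fits", out / "fits.json")
    pe_all = pd.concat(pes, ignore_index=True)
    pe_all.to_csv(out / "pe.csv", index=False)
    record("pe", out / "pe.csv")


# contact indices of the summary-cohort roles (see synth._SUMMARY_ROLES);
# ii_cross pairs one RPE-selective with one PPE-selective contact across the
# two redundant subsystems
_PAIR_OF = {
    "ii_rpe": (0, 1),
    "ii_ppe": (2, 3),
    "ii_syn": (6, 7),
    "ii_cross": (0, 3),
}
_PAIR_TARGET = {"ii_rpe": "RPE", "ii_ppe": "PPE", "ii_syn": "PE", "ii_cross": "PE"}
_DIRECTED = (4, 5)


def _stage_analyze(config: RunConfig, out: Path, record) -> None:
    pe_all = pd.read_csv(_require(out / "pe.csv"))
    seed = config.stage_seed("analyze")
    families: dict[str, list] = {k: [] for k in _PAIR_OF}
    te_rew, te_pun = [], []
    mis = {"RPE": [], "PPE": []}
    for k in range(config.n_subjects):
        epochs = ilio.load_epochs(_require(out / f"epochs_sub{k:02d}.h5"))
        pe = pe_all[pe_all["subject"] == k].reset_index(drop=True)
        for fam, pair in _PAIR_OF.items():
            families[fam].append(
                interaction_information(
                    epochs, pe, pair, target=_PAIR_TARGET[fam],
                    n_perm=config.n_perm, seed=seed + 17 * k,
                )
            )
        rew = (pe["condition"] == "reward").to_numpy()
        te_rew.append(
            transfer_entropy(epochs, _DIRECTED, config.delay_window, trials=rew)
        )
        te_pun.append(
            transfer_entropy(epochs, _DIRECTED, config.delay_window, trials=~rew)
        )
        for target in mis:
            mis[target].append(
                mi_timecourse(epochs, pe, target, n_perm=config.n_perm,
                              seed=seed + 31 * k)
            )
    units = [f"s{k}" for k in range(config.n_subjects)]
    for fam, lst in families.items():
        series = concat_series(lst, units=units)
        ilio.save_info_series(out / f"{fam}.h5", series)
        record(fam, out / f"{fam}.h5")
    for name, lst in (("te_rew", te_rew), ("te_pun", te_pun)):
        series = concat_series(lst, units=units)
        ilio.save_info_series(out / f"{name}.h5", series)
        record(name, out / f"{name}.h5")
    for target, lst in mis.items():
        series = concat_series(lst)
        # keep per-contact coords for categorization
        subj = np.concatenate([[k] * s.values.sizes["unit"] for k, s in enumerate(lst)])
        roi = np.concatenate(
            [ilio.load_epochs(out / f"epochs_sub{k:02d}.h5")["roi"].values
             for k in range(config.n_subjects)]
        )
        series.values = series.values.assign_coords(
            subject=("unit", subj), roi=("unit", roi)
        )
        ilio.save_info_series(out / f"mi_{target.lower()}.h5", series)
        record(f"mi_{target.lower()}", out / f"mi_{target.lower()}.h5")


def _stage_report(config: RunConfig, out: Path, record) -> None:
    seed = config.stage_seed("report")
    summary: dict = {}
    lines = ["# Pipeline report", ""]
    # group cluster tests per II family (redundancy tested as direction -1)
    for fam, direction in (("ii_rpe", -1), ("ii_ppe", -1), ("ii_syn", +1)):
        series = ilio.load_info_series(_require(out / f"{fam}.h5"))
        res = group_cluster_test(series, direction=direction, alpha=config.alpha)
        summary[fam] = ilio.cluster_result_to_dict(res)
        kind = "redundant (II < 0)" if direction < 0 else "synergistic (II > 0)"
        sig = res.significant(config.alpha)
        lines.append(
            f"- **{fam}** ({kind}): {len(sig)} significant cluster(s)"
            + "".join(
                f"; {c.p:.3f} over {series.time[c.start]:.3f}-"
                f"{series.time[c.stop - 1]:.3f} s" for c in sig
            )
        )
    te_rew = ilio.load_info_series(_require(out / "te_rew.h5"))
    te_pun = ilio.load_info_series(_require(out / "te_pun.h5"))
    contrast = condition_contrast(
        te_pun, te_rew, n_perm=config.n_perm, seed=seed, alpha=config.alpha
    )
    summary["te_pun_gt_rew"] = ilio.cluster_result_to_dict(contrast["a_gt_b"])
    summary["te_rew_gt_pun"] = ilio.cluster_result_to_dict(contrast["b_gt_a"])
    n_sig = len(contrast["a_gt_b"].significant(config.alpha))
    lines.append(f"- **TE aINS->dlPFC**: {n_sig} cluster(s) with TE_Pun > TE_Rew; "
                 f"{len(contrast['b_gt_a'].significant(config.alpha))} reversed")
    # selectivity categorization and II binning on the synergistic pairs
    mi_rpe = ilio.load_info_series(_require(out / "mi_rpe.h5"))
    mi_ppe = ilio.load_info_series(_require(out / "mi_ppe.h5"))
    labels = categorize_contacts(mi_rpe, mi_ppe, alpha=config.alpha)
    rows = []
    units = mi_rpe.values["unit"].values
    per_subj = len(units) // config.n_subjects
    for fam in ("ii_syn", "ii_cross"):
        series = ilio.load_info_series(out / f"{fam}.h5")
        t = series.values["time"].values
        win = (t >= 0.25) & (t <= 0.75)
        i, j = _PAIR_OF[fam]
        for k in range(config.n_subjects):
            rows.append({
                "contact1": units[k * per_subj + i],
                "contact2": units[k * per_subj + j],
                "mean_ii": float(series.values.values[k, win].mean()),
            })
    cat = bin_ii_by_selectivity(pd.DataFrame(rows), labels.contact_label)
    cat.to_csv(out / "ii_categories.csv", index=False)
    record("ii_categories", out / "ii_categories.csv")
    lines.append("")
    lines.append("## II by selectivity category")
    lines.append(cat.to_string(index=False) if len(cat) else "(no category populated)")
    ilio.save_json(out / "clusters.json", summary)
    record("clusters", out / "clusters.json")
    (out / "report.md").write_text("\n".join(lines) + "\n")
    record("report", out / "report.md")
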