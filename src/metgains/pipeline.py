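"""End-to-end genetic-gain pipeline.

Stages, in order: single-trial REML fits -> repeatability filter ->
pooled k-means yield-environment classification (drop the high class) ->
per-series factor-analytic MET fits for each environment class and
across classes -> check-relative yields (GYC) -> top-decile HYL
selection -> gain regressions per class -> coancestry/PCA grouping of
the pooled HYLs.  Every intermediate table is written to the output
directory; the run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import env_class, gains, met_fa, pedigree, simulate, single_trial
from ._reml import FittingError
from .errors import ConfigurationError, ValidationError
from .simulate import PLOT_COLUMNS, SimConfig

log = logging.getLogger("metgains")

ACROSS = "Across"


@dataclass
class PipelineConfig:
    """All pipeline constants in one audited place."""

    sim: SimConfig | None = None
    plots_path: str | None = None
    pedigree_path: str | None = None
    repeatability_threshold: float = 0.05
    k_env: int = 3
    n_factors: int = 1
    hyl_fraction: float = 0.10
    n_groups: int = 4
    met_restarts: int = 1
    pedigree_founders: int = 16
    within_group_prob: float = 0.95
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        if self.sim is None and self.plots_path is None:
            raise ConfigurationError("either a SimConfig or plots_path is required")
        if not (0.0 <= self.repeatability_threshold <= 1.0):
            raise ConfigurationError("repeatability_threshold must be in [0, 1]")
        if not (0.0 < self.hyl_fraction <= 1.0):
            raise ConfigurationError("hyl_fraction must be in (0, 1]")
        if self.k_env < 2:
            raise ConfigurationError("k_env must be >= 2")
        if self.plots_path is not None and not Path(self.plots_path).exists():
            raise ConfigurationError(f"plots_path {self.plots_path!r} does not exist")
        if self.pedigree_path is not None and not Path(self.pedigree_path).exists():
            raise ConfigurationError(f"pedigree_path {self.pedigree_path!r} does not exist")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.sim is not None:
            d["sim"] = self.sim.to_dict()
        d.pop("outdir", None)  # where outputs land is not part of the analysis
        return d


@dataclass
class PipelineReport:
    """Machine-readable run summary (serializes losslessly to JSON)."""

    config: dict
    config_hash: str
    seed: int
    n_trials_in: int
    n_trials_retained: int
    n_trials_dropped: int
    class_counts: dict  # class -> {series -> count}; layout of a per-class table
    gains: dict  # class -> GainFit dict
    group_table: dict  # group -> {class -> n HYLs}; plus total
    n_hyl_lines: int
    stage_log: list = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineReport":
        return cls(**json.loads(text))


class StageError(RuntimeError):
    def __init__(self, stage: str, unit: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {unit!r}: {cause}")
        self.stage, self.unit, self.cause = stage, unit, cause


def _hash_config(d: dict) -> str:
    return hashlib.sha256(json.dumps(d, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and return the report."""
    config.validate()
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
    audit: list = []

    def stage(name: str, **consts):
        audit.append({"stage": name, **consts})
        log.info("stage %s %s", name, consts or "")

    # deterministic per-stage seed substreams
    ss = np.random.SeedSequence(config.seed)
    seeds = {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(
            ["simulate", "pedigree", "met", "kmeans", "grouping"], ss.spawn(5)
        )
    }

    # ---- data ----
    if config.sim is not None:
        sim = dataclasses.replace(config.sim, seed=seeds["simulate"])
        stage("simulate", seed=sim.seed)
        plots, truth = simulate.generate_met(sim)
        check_presence = {
            c: sorted(
                plots.loc[plots["genotype_id"] == c, "series"].unique().tolist()
            )
            for c in truth.checks
        }
        line_ids = sorted(
            truth.genotypes.loc[~truth.genotypes["is_check"], "genotype_id"]
        )
        ped_table, _ = simulate.generate_pedigree(
            config.pedigree_founders,
            len(line_ids),
            config.n_groups,
            seeds["pedigree"],
            line_ids=line_ids,
            within_group_prob=config.within_group_prob,
        )
    else:
        stage("load", plots=config.plots_path)
        plots = pd.read_csv(config.plots_path)
        violations = _validate_plot_frame(plots)
        if violations:
            raise ValidationError("; ".join(v["message"] for v in violations))
        checks = sorted(plots.loc[plots["is_check"].astype(bool), "genotype_id"].unique())
        check_presence = {
            c: sorted(plots.loc[plots["genotype_id"] == c, "series"].unique().tolist())
            for c in checks
        }
        ped_table = (
            pd.read_csv(config.pedigree_path, dtype=str, keep_default_na=False)
            if config.pedigree_path
            else None
        )
    if outdir:
        plots.to_csv(outdir / "plots.csv", index=False)
        if ped_table is not None:
            ped_table.to_csv(outdir / "pedigree.csv", index=False)

    # ---- single-trial fits + repeatability filter ----
    stage("single_trial", threshold=config.repeatability_threshold)
    try:
        summaries = single_trial.fit_all_trials(plots, adjusted_means=False)
    except FittingError as exc:
        raise StageError("single_trial", str(exc), exc) from exc
    retained = single_trial.filter_trials(summaries, config.repeatability_threshold)
    n_in, n_kept = len(summaries), len(retained)
    log.info("retained %d / %d trials", n_kept, n_in)
    if outdir:
        single_trial.summaries_frame(summaries).to_csv(outdir / "trial_summaries.csv", index=False)

    # ---- environment classification (pooled), drop the high class ----
    stage("env_class", k=config.k_env)
    try:
        assignments = env_class.classify_environments(retained, seed=seeds["kmeans"], k=config.k_env)
    except Exception as exc:
        raise StageError("env_class", "pooled retained trials", exc) from exc
    if outdir:
        env_class.assignments_frame(assignments).to_csv(outdir / "env_assignments.csv", index=False)
    label_of = {a.trial_id: a.class_label for a in assignments}
    analysis_classes = [c for c in ("LYE", "MYE") if any(v == c for v in label_of.values())]
    series_of = {s.trial_id: s.series for s in retained}
    class_counts: dict[str, dict[str, int]] = {}
    for a in assignments:
        class_counts.setdefault(a.class_label, {})
        key = str(series_of[a.trial_id])
        class_counts[a.class_label][key] = class_counts[a.class_label].get(key, 0) + 1

    # ---- per-series FA-MET fits, GYC ----
    stage("met_fa", n_factors=config.n_factors)
    plots_r = plots[plots["trial_id"].isin(label_of)]
    gyc_frames = []
    for series, sdf in plots_r.groupby("series", sort=True):
        units = {c: sdf[sdf["trial_id"].map(label_of) == c] for c in analysis_classes}
        units[ACROSS] = sdf[sdf["trial_id"].map(label_of).isin(analysis_classes)]
        for cls, udf in units.items():
            if udf.empty or udf["site_id"].nunique() < 1:
                continue
            try:
                met = met_fa.make_met(udf)
                k = min(config.n_factors, met.n_sites)
                fit = met_fa.fit_met(met, n_factors=k, seed=seeds["met"],
                                     n_restarts=config.met_restarts)
                btab = met_fa.blup_table(fit, met)
            except FittingError as exc:
                raise StageError("met_fa", f"series {series} class {cls}", exc) from exc
            series_checks = [c for c, pres in check_presence.items() if series in pres]
            try:
                gyc = gains.compute_gyc(btab, series_checks, int(series), cls)
            except Exception as exc:
                raise StageError("gyc", f"series {series} class {cls}", exc) from exc
            gyc_frames.append(gyc)
            if outdir:
                btab.to_csv(outdir / f"blups_s{series:02d}_{cls}.csv", index=False)
    gyc_all = pd.concat(gyc_frames, ignore_index=True)

    # ---- HYL selection + gain regressions ----
    stage("hyl", fraction=config.hyl_fraction)
    gyc_all = gains.select_hyl(gyc_all, config.hyl_fraction)
    if outdir:
        gyc_all.to_csv(outdir / "gyc.csv", index=False)
    gain_fits: dict[str, gains.GainFit] = {}
    for cls in analysis_classes + [ACROSS]:
        try:
            gain_fits[cls] = gains.gain_regression(gyc_all, cls)
        except Exception as exc:
            raise StageError("gains", cls, exc) from exc
    if outdir:
        with open(outdir / "gains.json", "w") as fh:
            json.dump({c: f.to_dict() for c, f in gain_fits.items()}, fh, indent=2, sort_keys=True)

    # ---- pedigree grouping of pooled HYLs ----
    hyl_ids = sorted(gyc_all.loc[gyc_all["is_hyl"], "genotype_id"].unique())
    group_table: dict = {}
    if ped_table is not None and len(hyl_ids) >= config.n_groups:
        stage("pedigree", n_groups=config.n_groups)
        try:
            ped = pedigree.Pedigree(ped_table)
            usable = [i for i in hyl_ids if i in ped]
            cmat = pedigree.cop_matrix(ped, usable)
            assignments_g = pedigree.group_lines(cmat, config.n_groups, seed=seeds["grouping"])
        except Exception as exc:
            raise StageError("pedigree", "HYL grouping", exc) from exc
        if outdir:
            cmat.to_frame().to_csv(outdir / "cop_matrix.csv")
            pedigree.groups_frame(assignments_g).to_csv(outdir / "groups.csv", index=False)
        group_of = {a.id: a.group for a in assignments_g}
        for grp in sorted(set(group_of.values())):
            members = {i for i, g_ in group_of.items() if g_ == grp}
            row = {
                cls: int(
                    gyc_all.loc[
                        (gyc_all["class"] == cls) & gyc_all["is_hyl"], "genotype_id"
                    ]
                    .isin(members)
                    .sum()
                )
                for cls in analysis_classes + [ACROSS]
            }
            row["total"] = len(members)
            group_table[str(grp)] = row

    report = PipelineReport(
        config=config.to_dict(),
        config_hash=_hash_config(config.to_dict()),
        seed=config.seed,
        n_trials_in=n_in,
        n_trials_retained=n_kept,
        n_trials_dropped=n_in - n_kept,
        class_counts=class_counts,
        gains={c: f.to_dict() for c, f in gain_fits.items()},
        group_table=group_table,
        n_hyl_lines=len(hyl_ids),
        stage_log=audit,
    )
    if outdir:
        (outdir / "report.json").write_text(report.to_json())
    return report


# ----------------------------------------------------------------------
# Input validation
# ----------------------------------------------------------------------

def _validate_plot_frame(plots: pd.DataFrame) -> list[dict]:
    violations = []
    for col in PLOT_COLUMNS:
        if col not in plots.columns:
            violations.append({"file": "plots", "message": f"missing column {col!r}"})
    if violations:
        return violations
    if not np.issubdtype(plots["yield_t_ha"].dtype, np.number):
        violations.append({"file": "plots", "message": "yield_t_ha is not numeric"})
    dup = plots.duplicated(subset=["trial_id", "genotype_id", "replicate"])
    if dup.any():
        first = plots.loc[dup.idxmax()]
        violations.append(
            {
                "file": "plots",
                "message": "duplicate (genotype, replicate) within trial "
                f"{first['trial_id']!r}",
            }
        )
    return violations


def validate_inputs(plots_path=None, pedigree_path=None) -> list[dict]:
    """Schema checks for input files; returns a violation list (empty = OK)."""
    violations: list[dict] = []
    if plots_path is not None:
        try:
            plots = pd.read_csv(plots_path)
        except OSError as exc:
            raise OSError(f"cannot read {plots_path}: {exc}") from exc
        violations.extend(_validate_plot_frame(plots))
    if pedigree_path is not None:
        try:
            ped = pd.read_csv(pedigree_path, dtype=str, keep_default_na=False)
        except OSError as exc:
            raise OSError(f"cannot read {pedigree_path}: {exc}") from exc
        for col in ("id", "parent1", "parent2"):
            if col not in ped.columns:
                violations.append({"file": "pedigree", "message": f"missing column {col!r}"})
        if not violations:
            ids = set(ped["id"])
            for col in ("parent1", "parent2"):
                for p in ped[col]:
                    if p and p not in ids:
                        violations.append(
                            {"file": "pedigree", "message": f"parent id {p!r} not in id column"}
                        )
    return violations
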