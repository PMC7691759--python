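"""Synthetic multi-environment-trial (MET) and pedigree generators.

The generator emulates an international semi-arid wheat nursery: an
annual series of ~50-entry alpha-lattice trials (2 replicates, 5
sub-blocks per replicate) grown at many sites per year, with a small set
of long-term drought-tolerant check cultivars repeated across years and
new elite lines whose true genetic merit drifts upward by a configurable
percentage of the check yield per year.  Sites belong to low-, medium-
or high-yielding environment classes with distinct mean yields, and
genotype-by-environment interaction follows a low-rank factor structure
(site loading times genotype score) plus site-specific noise.

Every dataset is emitted together with its generating truth
(:class:`GenTruth`), which downstream parameter-recovery tests consume;
the estimation code never sees the truth channel.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError

PLOT_COLUMNS = [
    "trial_id",
    "series",
    "site_id",
    "genotype_id",
    "is_check",
    "replicate",
    "sub_block",
    "yield_t_ha",
]

CLASS_NAMES = ("low", "medium", "high")


@dataclass
class SimConfig:
    """Configuration of the MET generator.

    Yields are in t/ha and variance components in (t/ha)^2.  The default
    scale — 12 annual series, 50 entries of which 3 are checks, 2
    replicates x 5 sub-blocks, 10 low- and 10 medium-yielding sites plus
    2 high-yielding sites per series, class mean yields 2.4 / 4.6 / 6.5
    t/ha and an injected merit trend of 1.8 % of the check yield per
    year — mirrors the trial structure the estimation pipeline targets.
    """

    n_series: int = 12
    entries_per_trial: int = 50
    n_checks: int = 3
    n_reps: int = 2
    n_subblocks: int = 5
    sites_per_class: tuple[int, int, int] = (10, 10, 2)
    class_mean_yield: tuple[float, float, float] = (2.4, 4.6, 6.5)
    trend_pct_per_year: float = 1.8
    sigma2_g: float = 0.0625
    sigma2_ge_factor: float = 0.04
    sigma2_ge_specific: float = 0.02
    sigma2_rep: float = 0.01
    sigma2_subblock: float = 0.01
    sigma2_e: float = 0.05
    sigma2_site: float = 0.09
    n_factors: int = 1
    seed: int = 0
    #: optional presence table: check id -> series indices it appears in
    check_presence: dict[str, list[int]] | None = None

    def validate(self) -> None:
        for name in (
            "sigma2_g",
            "sigma2_ge_factor",
            "sigma2_ge_specific",
            "sigma2_rep",
            "sigma2_subblock",
            "sigma2_e",
            "sigma2_site",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.entries_per_trial <= self.n_checks:
            raise ConfigurationError("entries_per_trial must exceed n_checks")
        if self.entries_per_trial % self.n_subblocks != 0:
            raise ConfigurationError(
                "entries_per_trial must be divisible by n_subblocks "
                f"({self.entries_per_trial} % {self.n_subblocks} != 0)"
            )
        if any(s < 0 for s in self.sites_per_class):
            raise ConfigurationError("sites_per_class entries must be >= 0")
        if self.sites_per_class[0] == 0 and self.sites_per_class[1] == 0:
            raise ConfigurationError(
                "at least one low- or medium-yielding site per series is required"
            )
        if self.n_series < 1 or self.n_reps < 1 or self.n_factors < 0:
            raise ConfigurationError("n_series, n_reps must be >= 1; n_factors >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sites_per_class"] = list(self.sites_per_class)
        d["class_mean_yield"] = list(self.class_mean_yield)
        return d


@dataclass
class GenTruth:
    """Generating truth emitted alongside a simulated dataset.

    ``genotypes`` has one row per genotype: id, first series, check flag,
    true merit (t/ha deviation from the base yield) and the true
    check-relative yield in percent.  ``sites`` has one row per site: id,
    series, true class label, site mean and factor loadings.  ``checks``
    lists check ids; ``trend_pct_per_year`` is the injected slope.
    """

    genotypes: pd.DataFrame
    sites: pd.DataFrame
    checks: list[str]
    trend_pct_per_year: float
    check_yield_ref: float


def _check_ids(n_checks: int) -> list[str]:
    return [f"CHK{c + 1}" for c in range(n_checks)]


def generate_met(config: SimConfig) -> tuple[pd.DataFrame, GenTruth]:
    """Simulate plot-level yields for every trial of every series.

    Returns the plot table (one row per plot, columns
    :data:`PLOT_COLUMNS`) and the :class:`GenTruth` channel.  The same
    config (including seed) always returns identical output.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    checks = _check_ids(config.n_checks)
    presence = config.check_presence or {c: list(range(config.n_series)) for c in checks}
    for c in presence:
        if c not in checks:
            raise ConfigurationError(f"presence table names unknown check {c!r}")

    # reference yield: mean of the two analysis classes' means; genotype
    # merit is expressed at this level and scales proportionally with the
    # class yield level, so percentage gains are comparable across classes
    ref = float(np.mean(config.class_mean_yield[:2]))
    check_merit = rng.normal(0.0, math.sqrt(config.sigma2_g), size=config.n_checks)
    mean_check_merit = float(np.mean(check_merit))
    check_yield_ref = ref + mean_check_merit
    if check_yield_ref <= 0:
        raise ConfigurationError("check reference yield must be positive")

    sd_g = math.sqrt(config.sigma2_g)
    sd_load = math.sqrt(config.sigma2_ge_factor)
    sd_spec = math.sqrt(config.sigma2_ge_specific)
    sd_rep = math.sqrt(config.sigma2_rep)
    sd_sb = math.sqrt(config.sigma2_subblock)
    sd_e = math.sqrt(config.sigma2_e)
    sd_site = math.sqrt(config.sigma2_site)

    merit: dict[str, float] = dict(zip(checks, check_merit))
    scores: dict[str, np.ndarray] = {
        c: rng.normal(size=config.n_factors) for c in checks
    }
    def true_gyc(m: float) -> float:
        return 100.0 * (m - mean_check_merit) / check_yield_ref

    geno_rows = [
        {
            "genotype_id": c,
            "first_series": 0,
            "is_check": True,
            "merit": merit[c],
            "true_gyc_pct": true_gyc(merit[c]),
        }
        for c in checks
    ]

    site_rows = []
    plot_frames = []
    n_new = config.entries_per_trial - config.n_checks

    for t in range(config.n_series):
        series_checks = [c for c in checks if t in presence.get(c, [])]
        new_ids = [f"L{t:02d}_{i:03d}" for i in range(n_new)]
        shift = config.trend_pct_per_year / 100.0 * t * check_yield_ref
        new_merit = rng.normal(shift, sd_g, size=n_new)
        for gid, m in zip(new_ids, new_merit):
            merit[gid] = float(m)
            scores[gid] = rng.normal(size=config.n_factors)
            geno_rows.append(
                {
                    "genotype_id": gid,
                    "first_series": t,
                    "is_check": False,
                    "merit": float(m),
                    "true_gyc_pct": true_gyc(m),
                }
            )
        entries = series_checks + new_ids
        g = len(entries)
        merit_vec = np.array([merit[e] for e in entries])
        score_mat = np.array([scores[e] for e in entries])  # g x k

        for cls_idx, cls in enumerate(CLASS_NAMES):
            # genotype effects scale with the class yield level, so the
            # injected percentage trend is the same in every class
            merit_scale = config.class_mean_yield[cls_idx] / ref
            for s in range(config.sites_per_class[cls_idx]):
                site_id = f"{t:02d}{cls[0].upper()}{s:02d}"
                site_mean = config.class_mean_yield[cls_idx] + rng.normal(0.0, sd_site)
                loadings = rng.normal(0.0, sd_load, size=config.n_factors)
                site_rows.append(
                    {
                        "site_id": site_id,
                        "series": t,
                        "true_class": cls,
                        "site_mean": site_mean,
                        **{f"loading_{q + 1}": loadings[q] for q in range(config.n_factors)},
                    }
                )
                ge = score_mat @ loadings + rng.normal(0.0, sd_spec, size=g)
                rep_eff = rng.normal(0.0, sd_rep, size=config.n_reps)
                plots = _layout_trial(
                    rng,
                    entries,
                    config.n_reps,
                    config.n_subblocks,
                    site_mean,
                    merit_scale * merit_vec,
                    ge,
                    rep_eff,
                    sd_sb,
                    sd_e,
                )
                plots["site_id"] = site_id
                plots["series"] = t
                plots["trial_id"] = f"T{site_id}"
                plot_frames.append(plots)

    plot_table = pd.concat(plot_frames, ignore_index=True)
    plot_table["is_check"] = plot_table["genotype_id"].isin(checks)
    plot_table = plot_table[PLOT_COLUMNS]
    truth = GenTruth(
        genotypes=pd.DataFrame(geno_rows),
        sites=pd.DataFrame(site_rows),
        checks=checks,
        trend_pct_per_year=config.trend_pct_per_year,
        check_yield_ref=check_yield_ref,
    )
    return plot_table, truth


def _layout_trial(rng, entries, n_reps, n_subblocks, site_mean, merit_vec, ge, rep_eff, sd_sb, sd_e):
    """One complete trial: every entry once per replicate, replicates
    partitioned into equal-size sub-blocks by a seeded random shuffle."""
    g = len(entries)
    per_block = max(g // n_subblocks, 1)
    entries_arr = np.asarray(entries, dtype=object)
    frames = []
    for j in range(n_reps):
        order = rng.permutation(g)
        sb_eff = rng.normal(0.0, sd_sb, size=n_subblocks)
        block = np.minimum(np.arange(g) // per_block, n_subblocks - 1)
        y = (
            site_mean
            + merit_vec[order]
            + ge[order]
            + rep_eff[j]
            + sb_eff[block]
            + rng.normal(0.0, sd_e, size=g)
        )
        frames.append(
            pd.DataFrame(
                {
                    "genotype_id": entries_arr[order],
                    "replicate": j + 1,
                    "sub_block": block + 1,
                    "yield_t_ha": y,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ----------------------------------------------------------------------
# Pedigree generator
# ----------------------------------------------------------------------

def generate_pedigree(
    n_founders: int,
    n_lines: int,
    n_groups: int,
    seed: int,
    line_ids: list[str] | None = None,
    within_group_prob: float = 0.95,
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a pedigree with ``n_groups`` ancestor groups.

    Founders (unknown parents) are split evenly among groups; each new
    line draws both parents from earlier members of its own group with
    probability ``within_group_prob`` per parent, otherwise from another
    group.  Parents are always strictly earlier than offspring, so the
    pedigree is acyclic by construction.

    Returns the pedigree table (columns id, parent1, parent2; empty
    string = unknown parent) and the truth group label per individual.
    """
    if n_founders < 2 * n_groups:
        raise ConfigurationError("need at least two founders per ancestor group")
    if line_ids is not None and len(line_ids) != n_lines:
        raise ConfigurationError("line_ids length must equal n_lines")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    founder_ids = [f"F{i + 1:03d}" for i in range(n_founders)]
    groups = {fid: i % n_groups for i, fid in enumerate(founder_ids)}
    pool: list[list[str]] = [[] for _ in range(n_groups)]
    for fid in founder_ids:
        pool[groups[fid]].append(fid)

    rows = [{"id": fid, "parent1": "", "parent2": ""} for fid in founder_ids]
    ids = line_ids if line_ids is not None else [f"L{i + 1:04d}" for i in range(n_lines)]
    for i, lid in enumerate(ids):
        grp = i % n_groups
        parents = []
        for _ in range(2):
            if rng.random() < within_group_prob or n_groups == 1:
                src = grp
            else:
                others = [x for x in range(n_groups) if x != grp]
                src = others[rng.integers(len(others))]
            parents.append(pool[src][rng.integers(len(pool[src]))])
        rows.append({"id": lid, "parent1": parents[0], "parent2": parents[1]})
        groups[lid] = grp
        pool[grp].append(lid)

    ped = pd.DataFrame(rows, columns=["id", "parent1", "parent2"])
    labels = pd.Series({r["id"]: groups[r["id"]] for r in rows}, name="group")
    return ped, labels


# ----------------------------------------------------------------------
# I/O helpers
# ----------------------------------------------------------------------

def write_dataset(outdir, plots: pd.DataFrame, truth: GenTruth, config: SimConfig) -> None:
    """Write plots, truth and config to ``outdir`` as CSV/JSON."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plots.to_csv(outdir / "plots.csv", index=False)
    truth.genotypes.to_csv(outdir / "truth_genotypes.csv", index=False)
    truth.sites.to_csv(outdir / "truth_sites.csv", index=False)
    with open(outdir / "sim_config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)
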