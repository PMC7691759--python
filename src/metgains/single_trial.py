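"""Single-site alpha-lattice trial analysis.

Each trial is fitted with the plot-level model

``y_ijk = mu + R_j + SB_k(R_j) + G_i + eps_ijk``

where replicates ``R_j`` are fixed, sub-blocks within replicates are
random with variance ``sigma2_sb`` and the residual has variance
``sigma2_e``.  Two companion REML fits are performed: genotypes fixed
(for generalized-least-squares adjusted entry means) and genotypes
random (for the genetic variance entering repeatability).  Entry-mean
repeatability is

``H2 = sigma2_g / (sigma2_g + sigma2_e / r)``

with ``r`` the number of replicates; trials below a repeatability
threshold (default 0.05, strict ``<``) are discarded from the
multi-environment stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._reml import FittingError, MixedModel, design_matrix, sum_to_zero

REPEATABILITY_BASIS = "entry-mean"  # recorded so outputs are auditable

SUMMARY_COLUMNS = [
    "trial_id",
    "mean_yield",
    "sigma2_g",
    "sigma2_sb",
    "sigma2_e",
    "repeatability",
    "retained",
]


@dataclass
class TrialSummary:
    """Fitted quantities for one trial."""

    trial_id: str
    series: int
    mean_yield: float
    sigma2_g: float
    sigma2_sb: float
    sigma2_e: float
    repeatability: float
    adjusted_entry_means: pd.Series
    retained: bool = True
    converged: bool = True
    repeatability_basis: str = REPEATABILITY_BASIS


def _codes(values: pd.Series) -> tuple[np.ndarray, list]:
    cat = pd.Categorical(values)
    return cat.codes.astype(int), list(cat.categories)


def fit_single_trial(plots: pd.DataFrame, adjusted_means: bool = True) -> TrialSummary:
    """Fit one trial's plot records and summarize it.

    ``plots`` must carry columns genotype_id, replicate, sub_block,
    yield_t_ha (plus trial_id/series used for bookkeeping) and contain
    at least two replicates with every genotype observed at least once.
    ``adjusted_means=False`` skips the genotypes-fixed companion fit and
    leaves ``adjusted_entry_means`` empty — the variance components and
    repeatability are unaffected (they come from the genotypes-random
    fit), so callers that only filter trials can save the extra solve.
    """
    trial_id = str(plots["trial_id"].iloc[0]) if "trial_id" in plots else "?"
    series = int(plots["series"].iloc[0]) if "series" in plots else -1
    y = plots["yield_t_ha"].to_numpy(dtype=float)

    g_codes, genotypes = _codes(plots["genotype_id"])
    r_codes, reps = _codes(plots["replicate"])
    if len(reps) < 2:
        raise FittingError(f"trial {trial_id}: needs >= 2 replicates, found {len(reps)}")
    counts = plots.groupby("replicate").size()
    if (counts == 0).any():  # pragma: no cover - categorical can't produce this
        raise FittingError(f"trial {trial_id}: empty replicate")
    # sub-blocks are nested in replicates: build joint levels
    sb_codes, _ = _codes(
        plots["replicate"].astype(str) + ":" + plots["sub_block"].astype(str)
    )
    n_g, n_r, n_sb = len(genotypes), len(reps), sb_codes.max() + 1

    Zg = design_matrix(g_codes, n_g)
    Zsb = design_matrix(sb_codes, n_sb)
    Xrep = sum_to_zero(r_codes, n_r)

    # (a) genotypes fixed: GLS adjusted entry means given REML sigma2_sb, sigma2_e
    fit_a_converged = True
    if adjusted_means:
        X_fixed = np.hstack([Zg, Xrep])
        try:
            fit_a = MixedModel(y, X_fixed, {"sb": Zsb}).fit()
        except FittingError as exc:
            raise FittingError(f"trial {trial_id}: {exc}") from exc
        adj_means = pd.Series(fit_a.beta[:n_g], index=genotypes, name="adjusted_mean")
        fit_a_converged = fit_a.converged
    else:
        adj_means = pd.Series(dtype=float, name="adjusted_mean")

    # (b) genotypes random: variance components for repeatability
    X_rand = np.hstack([np.ones((len(y), 1)), Xrep])
    fit_b = MixedModel(y, X_rand, {"g": Zg, "sb": Zsb}).fit()

    s2g = fit_b.variances["g"]
    s2sb = fit_b.variances["sb"]
    s2e = fit_b.sigma2_e
    denom = s2g + s2e / n_r
    repeatability = 0.0 if denom <= 1e-12 else s2g / denom
    converged = fit_a_converged and fit_b.converged
    return TrialSummary(
        trial_id=trial_id,
        series=series,
        mean_yield=float(np.mean(y)),
        sigma2_g=s2g,
        sigma2_sb=s2sb,
        sigma2_e=s2e,
        repeatability=min(max(repeatability, 0.0), 1.0),
        adjusted_entry_means=adj_means,
        retained=converged,
        converged=converged,
    )


def fit_all_trials(plots: pd.DataFrame, adjusted_means: bool = True) -> list[TrialSummary]:
    """Fit every trial in a pooled plot table, grouped by trial_id."""
    return [
        fit_single_trial(df, adjusted_means=adjusted_means)
        for _, df in plots.groupby("trial_id", sort=True)
    ]


def filter_trials(
    summaries: list[TrialSummary], threshold: float = 0.05
) -> list[TrialSummary]:
    """Keep trials with repeatability >= threshold and a converged fit.

    The boundary is strict on the discard side: a trial at exactly the
    threshold is retained.  The ``retained`` flag is updated in place.
    """
    kept = []
    for s in summaries:
        s.retained = bool(s.converged and s.repeatability >= threshold)
        if s.retained:
            kept.append(s)
    return kept


def summaries_frame(summaries: list[TrialSummary]) -> pd.DataFrame:
    """Trial-summary table in the documented CSV layout."""
    return pd.DataFrame(
        [
            {
                "trial_id": s.trial_id,
                "mean_yield": s.mean_yield,
                "sigma2_g": s.sigma2_g,
                "sigma2_sb": s.sigma2_sb,
                "sigma2_e": s.sigma2_e,
                "repeatability": s.repeatability,
                "retained": s.retained,
            }
            for s in summaries
        ],
        columns=SUMMARY_COLUMNS,
    )
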