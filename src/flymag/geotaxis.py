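"""Climbing statistics for the negative-geotaxis assays.

Works from tidy tracking tables (one row per detection).  The group assay
has no per-fly identity — ten flies share a tube and the tracker reports
anonymous centroids — so all statistics are identity-free: the number of
detections above a height line stands in for the number of flies that
climbed, and per-frame tube means stand in for individual positions.

Three inferential routes are provided for the sham-versus-exposed contrast:

* repeated-measures (mixed) ANOVA on per-trial climber ratios,
* a binomial mixed model on per-frame above-line counts with random
  intercepts for replicate and for frame nested in trial,
* a linear mixed model of per-frame mean height (``Ycm``) on
  Exposure x condition with random intercepts ``(1|id)`` and
  ``(1|trial/frame)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .result import TestResult
from .tracking import TrackTable

__all__ = [
    "ClimberCriterion",
    "climber_proportion",
    "proportion_timecourse",
    "mean_height_timecourse",
    "above_line_counts_table",
    "per_frame_tube_means",
    "test_exposure_ratio",
    "test_exposure_height",
]


@dataclass
class ClimberCriterion:
    """Binary climbing criterion: reach ``height_cm`` within ``time_s``.

    The classic criterion is 15 cm in 15 s, measured from the knockdown at
    each trial start; the time bound is inclusive by default.
    """

    height_cm: float = 15.0
    time_s: float = 15.0
    inclusive: bool = True

    def __post_init__(self) -> None:
        if self.height_cm <= 0 or self.time_s <= 0:
            raise ValueError("criterion height and time must be positive")


def _valid_with_trial_time(table: TrackTable) -> pd.DataFrame:
    """Valid rows plus time since the start of each trial."""
    df = table.valid_rows().copy()
    if df.empty:
        return df.assign(t_rel=pd.Series(dtype=float))
    trial_start = df.groupby("trial")["frame"].transform("min")
    df["t_rel"] = (df["frame"] - trial_start) / table.fps
    return df


def _above_line_counts(df: pd.DataFrame, crit: ClimberCriterion) -> pd.DataFrame:
    """Cumulative above-line proportion per (tube, trial, frame).

    Counts detections with height >= the criterion line in each frame and
    takes the running maximum within the trial: an identity-free reading of
    "how many flies have reached the line by now".
    """
    df = df.copy()
    df["above"] = (df["height_cm"] >= crit.height_cm).astype(int)
    counts = (df.groupby(["tube", "trial", "frame", "t_rel"])["above"]
                .sum().reset_index())
    counts = counts.sort_values(["tube", "trial", "frame"])
    counts["cum_above"] = counts.groupby(["tube", "trial"])["above"].cummax()
    return counts


def climber_proportion(table: TrackTable, crit: ClimberCriterion | None = None) -> pd.DataFrame:
    """Proportion of flies that reached the criterion line in time, per tube x trial.

    In group mode the proportion is the running maximum over frames at or
    before ``time_s`` of (detections above the line) / group size, capped at
    one.  Returns a frame with columns ``tube, trial, proportion``.
    """
    crit = crit or ClimberCriterion()
    if table.group_size <= 0:
        raise ValueError("group size must be positive")
    df = _valid_with_trial_time(table)
    if df.empty:
        return pd.DataFrame(columns=["tube", "trial", "proportion"])
    counts = _above_line_counts(df, crit)
    op = np.less_equal if crit.inclusive else np.less
    counts = counts[op(counts["t_rel"], crit.time_s)]
    out = (counts.groupby(["tube", "trial"])["cum_above"].max()
                 .div(table.group_size).clip(upper=1.0)
                 .rename("proportion").reset_index())
    return out


def proportion_timecourse(table: TrackTable, crit: ClimberCriterion | None = None) -> pd.DataFrame:
    """Cumulative proportion of flies past the criterion line over time.

    Per frame: per-tube running-maximum above-line proportion, averaged
    across tubes (replicates), with a Wilson score interval computed from
    the pooled counts.  Returns columns ``trial, t_rel, mean, ci_lo, ci_hi,
    n_tubes``.  Evaluated at ``time_s`` this curve reproduces
    :func:`climber_proportion` averaged over tubes.
    """
    crit = crit or ClimberCriterion()
    df = _valid_with_trial_time(table)
    if df.empty:
        return pd.DataFrame(columns=["trial", "t_rel", "mean", "ci_lo", "ci_hi", "n_tubes"])
    counts = _above_line_counts(df, crit)
    g = table.group_size
    counts["prop"] = counts["cum_above"].clip(upper=g) / g
    rows = []
    for (trial, t_rel), grp in counts.groupby(["trial", "t_rel"]):
        k = int(grp["cum_above"].clip(upper=g).sum())
        n = len(grp) * g
        lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
        rows.append((trial, t_rel, grp["prop"].mean(), lo, hi, len(grp)))
    return pd.DataFrame(rows, columns=["trial", "t_rel", "mean", "ci_lo", "ci_hi", "n_tubes"])


def mean_height_timecourse(table: TrackTable) -> pd.DataFrame:
    """Mean +/- s.d. of tube-average height per frame.

    The position of the (up to ten) flies in a tube is averaged per frame;
    the mean and standard deviation are then taken across tubes.  Frames in
    which a tube has no valid detection are missing for that tube, never
    zero.  Returns columns ``trial, t_rel, frame, mean, sd, n_tubes``.
    """
    df = _valid_with_trial_time(table)
    if df.empty:
        return pd.DataFrame(columns=["trial", "t_rel", "frame", "mean", "sd", "n_tubes"])
    per_tube = (df.groupby(["tube", "trial", "frame", "t_rel"])["height_cm"]
                  .mean().rename("tube_mean").reset_index())
    agg = (per_tube.groupby(["trial", "frame", "t_rel"])["tube_mean"]
                   .agg(["mean", "std", "size"]).reset_index()
                   .rename(columns={"std": "sd", "size": "n_tubes"}))
    return agg[["trial", "t_rel", "frame", "mean", "sd", "n_tubes"]]


def above_line_counts_table(table: TrackTable,
                            crit: ClimberCriterion | None = None) -> pd.DataFrame:
    """Per (tube, trial, frame) cumulative above-line counts for the GLMM.

    Returns columns ``tube, trial, frame, t_rel, n_above, n_total`` where
    ``n_above`` is the running maximum of detections past the criterion line
    (capped at the group size) and ``n_total`` the group size.
    """
    crit = crit or ClimberCriterion()
    df = _valid_with_trial_time(table)
    if df.empty:
        return pd.DataFrame(columns=["tube", "trial", "frame", "t_rel",
                                     "n_above", "n_total"])
    counts = _above_line_counts(df, crit)
    counts["n_above"] = counts["cum_above"].clip(upper=table.group_size)
    counts["n_total"] = table.group_size
    return counts[["tube", "trial", "frame", "t_rel", "n_above", "n_total"]]


def per_frame_tube_means(table: TrackTable) -> pd.DataFrame:
    """Per (tube, trial, frame) mean height of valid detections (``Ycm``)."""
    df = _valid_with_trial_time(table)
    return (df.groupby(["tube", "trial", "frame", "t_rel"])["height_cm"]
              .mean().rename("Ycm").reset_index())


# ---------------------------------------------------------------------------
# exposure tests
# ---------------------------------------------------------------------------

def test_exposure_ratio(data: pd.DataFrame, method: str = "rm_anova",
                        subsample: int = 5) -> TestResult:
    """Test for an exposure effect on the climber ratio.

    Parameters
    ----------
    data : DataFrame
        For ``rm_anova``: columns ``id, Exposure, trial, proportion`` — one
        climber ratio per biological replicate and trial.
        For ``binomial_glmm``: columns ``id, Exposure, trial, frame,
        n_above, n_total`` — per-frame counts of flies past the line.
    method : {"rm_anova", "binomial_glmm"}
        Mixed ANOVA with trial as the repeated measure, or a binomial
        mixed model with random intercepts ``(1|id) + (1|trial/frame)``
        (frames may be subsampled via ``subsample`` before fitting).
    """
    if method == "rm_anova":
        return _rm_anova_exposure(data)
    if method == "binomial_glmm":
        return _binomial_glmm_exposure(data, subsample=subsample)
    raise ValueError("method must be 'rm_anova' or 'binomial_glmm'")


test_exposure_ratio.__test__ = False  # not a pytest test, despite the name


def _rm_anova_exposure(data: pd.DataFrame) -> TestResult:
    import pingouin as pg

    need = {"id", "Exposure", "trial", "proportion"}
    if not need.issubset(data.columns):
        raise ValueError(f"rm_anova needs columns {sorted(need)}")
    if data["Exposure"].nunique() < 2:
        raise ValueError("need at least two Exposure levels")
    warns: list = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        aov = pg.mixed_anova(data=data, dv="proportion", within="trial",
                             subject="id", between="Exposure")
    row = aov[aov["Source"] == "Exposure"].iloc[0]
    pcol = "p_unc" if "p_unc" in aov.columns else "p-unc"
    means = data.groupby("Exposure")["proportion"].mean()
    est = float(means.iloc[-1] - means.iloc[0]) if len(means) == 2 else None
    return TestResult(
        method="repeated-measures ANOVA (climber ratio)",
        statistic_name="F", statistic=float(row["F"]),
        df=(float(row["DF1"]), float(row["DF2"])), pvalue=float(row[pcol]),
        estimate=est, warnings=warns,
        extra={"anova_table": aov},
    )


def _binomial_glmm_exposure(data: pd.DataFrame, subsample: int = 5) -> TestResult:
    from statsmodels.genmod.bayes_mixed_glm import BinomialBayesMixedGLM

    need = {"id", "Exposure", "trial", "frame", "n_above", "n_total"}
    if not need.issubset(data.columns):
        raise ValueError(f"binomial_glmm needs columns {sorted(need)}")
    df = data.copy()
    if subsample > 1:
        keep_frames = sorted(df["frame"].unique())[::subsample]
        df = df[df["frame"].isin(keep_frames)]
    df["tf"] = df["trial"].astype(str) + ":" + df["frame"].astype(str)
    # expand binomial counts to Bernoulli rows for the mixed-GLM fitter
    reps = df["n_total"].to_numpy()
    long = df.loc[df.index.repeat(reps)].reset_index(drop=True)
    hit = np.zeros(len(long), dtype=float)
    pos = 0
    for n_above, n_total in zip(df["n_above"], df["n_total"]):
        hit[pos:pos + int(n_above)] = 1.0
        pos += int(n_total)
    long["y"] = hit
    warns: list = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = BinomialBayesMixedGLM.from_formula(
            "y ~ Exposure", {"id": "0 + C(id)", "trial": "0 + C(trial)",
                             "tf": "0 + C(tf)"}, long)
        fit = model.fit_vb()
    names = list(fit.model.exog_names)
    idx = [i for i, nm in enumerate(names) if nm.startswith("Exposure")]
    if not idx:
        raise ValueError("Exposure term not found in model")
    i = idx[0]
    z = fit.fe_mean[i] / fit.fe_sd[i]
    p = 2 * stats.norm.sf(abs(z))
    # mean-field posteriors understate fixed-effect uncertainty when the
    # number of biological replicates is small; flag every result
    warns.append("variational_approximation")
    return TestResult(
        method="binomial GLMM (1|id)+(1|trial/frame), variational fit",
        statistic_name="z", statistic=float(z), df=(1.0,), pvalue=float(p),
        estimate=float(fit.fe_mean[i]),
        conf_int=(float(fit.fe_mean[i] - 1.96 * fit.fe_sd[i]),
                  float(fit.fe_mean[i] + 1.96 * fit.fe_sd[i])),
        warnings=warns,
    )


def test_exposure_height(data, design: pd.DataFrame | None = None,
                         subsample: int = 5) -> TestResult:
    """Linear mixed model of per-frame mean height on Exposure x condition.

    ``Ycm ~ Exposure * condition`` (the interaction is dropped when only one
    condition level is present) with random intercepts per replicate and per
    frame nested in trial — frame effects absorb the common climb curve.
    P-values use the between-replicate degrees of freedom
    ``n_ids - n_between_parameters``, appropriate for a between-tube factor.

    Parameters
    ----------
    data : TrackTable or DataFrame
        Either a track table (then ``design`` must map ``tube`` to ``id,
        Exposure`` and optionally ``condition``) or a ready long frame with
        columns ``id, Exposure, [condition,] trial, frame, Ycm``.
    subsample : int
        Keep every ``subsample``-th frame before fitting.
    """
    import statsmodels.formula.api as smf

    if isinstance(data, TrackTable):
        if design is None:
            raise ValueError("a design table is required with a TrackTable")
        ycm = per_frame_tube_means(data)
        df = ycm.merge(design, on="tube", validate="many_to_one")
    else:
        df = data.copy()
    need = {"id", "Exposure", "trial", "frame", "Ycm"}
    if not need.issubset(df.columns):
        raise ValueError(f"LME needs columns {sorted(need)}")
    if df["Exposure"].nunique() < 2:
        raise ValueError("need at least two Exposure levels")
    if subsample > 1:
        keep = sorted(df["frame"].unique())[::subsample]
        df = df[df["frame"].isin(keep)].copy()
    df = df.dropna(subset=["Ycm"])
    df["tf"] = df["trial"].astype(str) + ":" + df["frame"].astype(str)
    df["_one"] = 1

    has_cond = "condition" in df.columns and df["condition"].nunique() > 1
    if has_cond:
        fixed = "Ycm ~ C(Exposure, Sum) * C(condition, Sum)"
    else:
        fixed = "Ycm ~ C(Exposure)"
    vc = {"id": "0 + C(id)", "trial": "0 + C(trial)", "tf": "0 + C(tf)"}

    warns: list = []
    with warnings.catch_warnings(record=True) as wlist:
        warnings.simplefilter("always")
        model = smf.mixedlm(fixed, df, groups="_one", vc_formula=vc, re_formula="0")
        res = model.fit(reml=True, method="powell", maxiter=2000)
    if not res.converged:
        warns.append("non_convergence")
    if any("singular" in str(w.message).lower() for w in wlist):
        warns.append("singular_fit")

    n_ids = df["id"].nunique()
    exog_names = list(res.model.exog_names)
    n_between = len(exog_names)  # all fixed terms are between-replicate here
    ddf = max(n_ids - n_between, 1)

    terms = {}
    for factor in (["C(Exposure, Sum)", "C(condition, Sum)",
                    "C(Exposure, Sum):C(condition, Sum)"] if has_cond
                   else ["C(Exposure)"]):
        cols = [i for i, nm in enumerate(exog_names)
                if factor == _term_of(nm)]
        if not cols:
            continue
        beta = res.fe_params.iloc[cols].to_numpy()
        cov = res.cov_params().iloc[cols, cols].to_numpy()
        if np.allclose(beta, 0.0, atol=1e-10):
            chi2 = 0.0  # degenerate (constant-response) fits included
        else:
            chi2 = float(beta @ np.linalg.lstsq(cov, beta, rcond=None)[0])
        q = len(cols)
        fstat = chi2 / q
        pval = float(stats.f.sf(fstat, q, ddf))
        key = ("Exposure" if "Exposure" in factor and ":" not in factor
               else "condition" if "condition" in factor and ":" not in factor
               else "Exposure:condition")
        terms[key] = {"F": fstat, "df": (q, ddf), "p": pval}
    expo = terms["Exposure"]

    est = ci = None
    extra = {"terms": terms}
    if not has_cond:
        i = next(i for i, nm in enumerate(exog_names) if "Exposure" in nm)
        est = float(res.fe_params.iloc[i])
        se = float(res.bse_fe.iloc[i])
        tcrit = stats.t.ppf(0.975, ddf)
        ci = (est - tcrit * se, est + tcrit * se)
        extra["se_exposure"] = se

    return TestResult(
        method="LME Ycm ~ Exposure x condition + (1|id) + (1|trial/frame)",
        statistic_name="F", statistic=expo["F"], df=expo["df"], pvalue=expo["p"],
        estimate=est, conf_int=ci, warnings=warns, extra=extra,
    )


test_exposure_height.__test__ = False  # not a pytest test, despite the name


def _term_of(name: str) -> str:
    """Map a patsy column name like 'C(Exposure, Sum)[S.x]' to its term."""
    parts = name.split(":")
    return ":".join(p.split("[")[0] for p in parts)
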