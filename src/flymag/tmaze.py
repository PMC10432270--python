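"""T-maze choice statistics, effect sizes and the pseudoreplication study.

A T-maze run releases a set of ~100 flies that distribute between a
magnetic and a non-magnetic arm.  The set — not the fly — is the biological
replicate: flies sharing a run influence each other, so their choices are
correlated.  Treating each fly as independent (as the early reports did)
inflates significance; this module implements both the proportion-
appropriate group tests and, deliberately, the flawed per-fly analysis so
the inflation can be quantified, together with Cohen's h effect sizes and
the analytic power of the two-sample test of proportions.
"""

from __future__ import annotations

import math
import warnings

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .result import TestResult
from .synthetic import ChoiceSet, TMazeSimParams, simulate_tmaze_experiment

__all__ = [
    "ChoiceSet",
    "PowerSpec",
    "preference_index",
    "glm_group_test",
    "pseudoreplicated_test",
    "cohens_h",
    "power_two_proportions",
    "sample_size_for_power",
    "type1_error_study",
]


@dataclass
class PowerSpec:
    """Inputs of a two-sample proportion power calculation.

    Either give the two group proportions (``p1``, ``p2``) or Cohen's ``h``
    directly; ``n1``/``n2`` are replicates per group and ``alpha`` the
    two-sided significance level.
    """

    p1: float | None = None
    p2: float | None = None
    h: float | None = None
    n1: int = 10
    n2: int = 12
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.h is None:
            if self.p1 is None or self.p2 is None:
                raise ValueError("give either (p1, p2) or h")
            self.h = cohens_h(self.p1, self.p2)
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")


def preference_index(s: ChoiceSet) -> float:
    """PI = 2 * P_M - 1, where P_M is the proportion choosing the magnetic arm.

    0 means indifference, +1 all flies in the magnetic arm, -1 none.
    """
    return 2.0 * s.n_magnetic / s.n_total - 1.0


# ---------------------------------------------------------------------------
# group tests
# ---------------------------------------------------------------------------

def _to_arrays(sets: list):
    succ = np.array([s.n_magnetic for s in sets], dtype=float)
    tot = np.array([s.n_total for s in sets], dtype=float)
    grp = np.array([s.group for s in sets])
    levels = list(dict.fromkeys(grp))
    if len(levels) < 2:
        raise ValueError("need at least two groups")
    return succ, tot, grp, levels


def glm_group_test(sets: list, dispersion: str = "quasi") -> TestResult:
    """Set-level test of a group difference in choice proportions.

    Models per-set (magnetic, non-magnetic) counts on the group factor with
    a binomial GLM.  ``dispersion`` controls how within-set correlation is
    absorbed:

    - ``"binomial"`` — plain binomial likelihood-ratio chi-square;
    - ``"quasi"`` — quasi-binomial F-test with Pearson-estimated scale
      (the default: robust to overdispersed sets);
    - ``"beta_binomial"`` — beta-binomial maximum likelihood with a
      likelihood-ratio chi-square.
    """
    succ, tot, grp, levels = _to_arrays(sets)
    warns: list = []
    est_by_group = {}
    for lev in levels:
        m = grp == lev
        k, n = succ[m].sum(), tot[m].sum()
        lo, hi = proportion_confint(k, n, method="wilson")
        est_by_group[lev] = {"p": k / n, "ci": (lo, hi), "n_sets": int(m.sum())}
    p_hat = [est_by_group[lev]["p"] for lev in levels]
    estimate = p_hat[1] - p_hat[0] if len(levels) == 2 else None
    if any(p in (0.0, 1.0) for p in p_hat):
        warns.append("complete_separation")

    if dispersion == "beta_binomial":
        stat, df, pval = _betabin_lr_test(succ, tot, grp, levels)
        return TestResult(method="beta-binomial ML group test",
                          statistic_name="chi2", statistic=stat, df=df,
                          pvalue=pval, estimate=estimate, warnings=warns,
                          extra={"groups": est_by_group})

    endog = np.column_stack([succ, tot - succ])
    exog = pd.get_dummies(pd.Categorical(grp, categories=levels),
                          drop_first=True, dtype=float)
    exog = sm.add_constant(exog)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
        null = sm.GLM(endog, np.ones((len(succ), 1)),
                      family=sm.families.Binomial()).fit()
    dev_drop = null.deviance - fit.deviance
    q = len(levels) - 1
    if dispersion == "binomial":
        stat = float(dev_drop)
        pval = float(stats.chi2.sf(stat, q))
        return TestResult(method="binomial GLM likelihood-ratio test",
                          statistic_name="chi2", statistic=stat, df=(q,),
                          pvalue=pval, estimate=estimate, warnings=warns,
                          extra={"groups": est_by_group})
    if dispersion == "quasi":
        scale = float(fit.pearson_chi2 / fit.df_resid)
        if scale <= 0.0:  # degenerate: no residual variation at all
            fstat = 0.0 if dev_drop <= 1e-12 else float("inf")
        else:
            fstat = float(dev_drop / q / scale)
        pval = float(stats.f.sf(fstat, q, fit.df_resid))
        return TestResult(method="quasi-binomial GLM F-test",
                          statistic_name="F", statistic=fstat,
                          df=(q, float(fit.df_resid)), pvalue=pval,
                          estimate=estimate, warnings=warns,
                          extra={"groups": est_by_group, "scale": scale})
    raise ValueError("dispersion must be 'binomial', 'quasi' or 'beta_binomial'")


def _betabin_nll(params, succ, tot, grp_codes, n_groups):
    logit_p = params[:n_groups]
    rho = 1.0 / (1.0 + math.exp(-params[-1]))  # icc in (0, 1)
    rho = min(max(rho, 1e-9), 1 - 1e-9)
    s = (1.0 - rho) / rho
    p = 1.0 / (1.0 + np.exp(-logit_p[grp_codes]))
    a = np.clip(p * s, 1e-9, None)
    b = np.clip((1.0 - p) * s, 1e-9, None)
    return -stats.betabinom.logpmf(succ, tot, a, b).sum()


def _betabin_lr_test(succ, tot, grp, levels):
    codes = np.array([levels.index(g) for g in grp])
    k = len(levels)
    pbar = succ.sum() / tot.sum()
    x0_logit = math.log(pbar / (1 - pbar)) if 0 < pbar < 1 else 0.0

    def fit(n_groups, codes_):
        x0 = np.array([x0_logit] * n_groups + [-3.0])
        res = optimize.minimize(_betabin_nll, x0,
                                args=(succ, tot.astype(int), codes_, n_groups),
                                method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
        return res.fun

    nll_alt = fit(k, codes)
    nll_null = fit(1, np.zeros_like(codes))
    stat = max(2.0 * (nll_null - nll_alt), 0.0)
    q = k - 1
    return float(stat), (q,), float(stats.chi2.sf(stat, q))


def pseudoreplicated_test(sets: list, method: str = "per_fly_t") -> TestResult:
    """The flawed per-fly analysis, for comparison only.

    Treats every fly as an independent replicate: either a t-test across
    flies coded 0/1 (``per_fly_t``) or a pooled two-proportion z-test
    (``pooled``).  Ignoring the within-set correlation inflates
    significance; this exists to demonstrate that inflation, never for
    inference.
    """
    succ, tot, grp, levels = _to_arrays(sets)
    k = [(succ[grp == lev].sum(), tot[grp == lev].sum()) for lev in levels]
    estimate = k[1][0] / k[1][1] - k[0][0] / k[0][1] if len(levels) == 2 else None
    if method == "pooled":
        stat, pval = proportions_ztest([k[0][0], k[1][0]], [k[0][1], k[1][1]])
        return TestResult(method="pooled two-proportion z-test (for comparison only)",
                          statistic_name="z", statistic=float(stat), df=(1.0,),
                          pvalue=float(pval), estimate=estimate)
    if method == "per_fly_t":
        xs = []
        for (ki, ni) in k[:2]:
            xs.append(np.concatenate([np.ones(int(ki)), np.zeros(int(ni - ki))]))
        t, pval = stats.ttest_ind(xs[0], xs[1])
        return TestResult(method="per-fly t-test (for comparison only)",
                          statistic_name="t", statistic=float(t),
                          df=(float(len(xs[0]) + len(xs[1]) - 2),),
                          pvalue=float(pval), estimate=estimate)
    raise ValueError("method must be 'per_fly_t' or 'pooled'")


# ---------------------------------------------------------------------------
# effect size and power
# ---------------------------------------------------------------------------

def cohens_h(p1: float, p2: float) -> float:
    """Cohen's effect size for two proportions: 2 asin sqrt(p2) - 2 asin sqrt(p1)."""
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p2 <= 1.0):
        raise ValueError("proportions must be in [0, 1]")
    return 2.0 * math.asin(math.sqrt(p2)) - 2.0 * math.asin(math.sqrt(p1))


def power_two_proportions(spec: PowerSpec) -> float:
    """Two-sided power of the two-sample arcsine-transformed proportion test.

    Under the normal approximation the test statistic is non-central with
    ``lambda = |h| * sqrt(n1 n2 / (n1 + n2))``; the power at level alpha is
    ``Phi(lambda - z_{1-alpha/2}) + Phi(-lambda - z_{1-alpha/2})``.  With
    ``h = 0`` this reduces exactly to alpha.
    """
    lam = abs(spec.h) * math.sqrt(spec.n1 * spec.n2 / (spec.n1 + spec.n2))
    z = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    return float(stats.norm.cdf(lam - z) + stats.norm.cdf(-lam - z))


def sample_size_for_power(h: float, target_power: float = 0.8,
                          alpha: float = 0.05) -> int:
    """Smallest equal group size n with power >= target for effect size h.

    Seeds with the closed form ``(z_{1-alpha/2} + z_power)^2 / h^2`` and
    then searches the integers for the exact threshold.
    """
    if h == 0.0:
        raise ValueError("h = 0: target power is unattainable")
    if not alpha < target_power < 1.0:
        raise ValueError("target_power must be in (alpha, 1)")
    z_a = stats.norm.ppf(1.0 - alpha / 2.0)
    z_b = stats.norm.ppf(target_power)
    n = max(int(math.floor((z_a + z_b) ** 2 / h ** 2)), 1)

    def power_at(n_):
        return power_two_proportions(PowerSpec(h=h, n1=n_, n2=n_, alpha=alpha))

    while power_at(n) < target_power:
        n += 1
    while n > 1 and power_at(n - 1) >= target_power:
        n -= 1
    return n


# ---------------------------------------------------------------------------
# pseudoreplication type-I-error study
# ---------------------------------------------------------------------------

def type1_error_study(icc_grid=(0.0, 0.02, 0.05, 0.1), n_sets: int = 10,
                      flies_per_set: int = 100, n_reps: int = 500,
                      alpha: float = 0.05, seed: int = 0,
                      p_null: float = 0.5) -> pd.DataFrame:
    """Empirical type-I error of the set-level GLM versus the per-fly test.

    For each intraclass correlation, simulates ``n_reps`` pairs of null
    groups (identical choice probability ``p_null``), applies both the
    set-level quasi-binomial GLM and the pseudoreplicated per-fly t-test,
    and tabulates rejection rates at ``alpha``.  Deterministic given
    ``seed``.  Returns columns ``icc, test, rejection_rate, n_reps``.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100")
    ss = np.random.SeedSequence(seed)
    rows = []
    for icc in icc_grid:
        child = ss.spawn(1)[0]
        seeds = child.generate_state(2 * n_reps) % (2 ** 31)
        rej = {"per_set_glm": 0, "per_fly_t": 0}
        for r in range(n_reps):
            g1 = simulate_tmaze_experiment(TMazeSimParams(
                n_sets=n_sets, flies_per_set=flies_per_set, p_magnetic=p_null,
                icc=icc, seed=int(seeds[2 * r]), group="A"))
            g2 = simulate_tmaze_experiment(TMazeSimParams(
                n_sets=n_sets, flies_per_set=flies_per_set, p_magnetic=p_null,
                icc=icc, seed=int(seeds[2 * r + 1]), group="B"))
            sets = g1 + g2
            rej["per_set_glm"] += glm_group_test(sets).pvalue < alpha
            rej["per_fly_t"] += pseudoreplicated_test(sets).pvalue < alpha
        for test, k in rej.items():
            rows.append((icc, test, k / n_reps, n_reps))
    return pd.DataFrame(rows, columns=["icc", "test", "rejection_rate", "n_reps"])
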