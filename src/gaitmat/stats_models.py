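"""State-comparison statistics for gait parameter tables.

The central model is a linear mixed model with the factor of interest
(parkinsonian state, or subject for baseline comparisons) as a fixed
effect and session nested within that factor as a random intercept,
estimated by REML.  Least-square means are the model-based marginal
means of the factor levels; pairwise contrasts are adjusted with Tukey's
studentized-range procedure when the factor has more than two levels
(with two levels the adjustment reduces to the ordinary t test).

Variability shifts are assessed with Levene's homogeneity-of-variance
test (classic mean-centered form; median centering available), and
pairwise effect sizes with Cohen's d reconstructed from least-square
means and standard errors: ``s_i = se_i * sqrt(n_i)`` and the usual
pooled standard deviation for unequal sample sizes.  Effect sizes are
binned as small (< 0.35), medium (0.35-0.65, inclusive) and large
(> 0.65).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .errors import FittingError, UsageError

#: Effect-size category bounds on |d| (closed medium interval).
SMALL_MAX = 0.35
MEDIUM_MAX = 0.65


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with its category."""

    d: float
    category: str

    @staticmethod
    def categorize(d: float) -> str:
        a = abs(d)
        if a < SMALL_MAX:
            return "small"
        if a <= MEDIUM_MAX:
            return "medium"
        return "large"


@dataclass
class LevelEstimate:
    """Least-square mean of one factor level."""

    level: str
    mean: float
    se: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class Contrast:
    """One pairwise comparison between factor levels."""

    level_a: str
    level_b: str
    difference: float
    se: float
    t: float
    p_unadjusted: float
    p_tukey: float
    effect_size: EffectSize


@dataclass
class StateEffectEstimate:
    """Fitted factor-effect summary for one gait parameter."""

    parameter: str
    factor: str
    levels: list = field(default_factory=list)
    contrasts: list = field(default_factory=list)
    model_info: dict = field(default_factory=dict)

    def level(self, name: str) -> LevelEstimate:
        for lv in self.levels:
            if lv.level == name:
                return lv
        raise KeyError(name)

    def contrast(self, a: str, b: str) -> Contrast:
        for c in self.contrasts:
            if {c.level_a, c.level_b} == {a, b}:
                return c
        raise KeyError((a, b))

    def to_dict(self) -> dict:
        return {
            "parameter": self.parameter,
            "factor": self.factor,
            "levels": [vars(lv) for lv in self.levels],
            "contrasts": [
                {**{k: v for k, v in vars(c).items() if k != "effect_size"},
                 "effect_size_d": c.effect_size.d,
                 "effect_size_category": c.effect_size.category}
                for c in self.contrasts
            ],
            "model_info": self.model_info,
        }


def cohens_d_unequal(
    mean1: float, se1: float, n1: int, mean2: float, se2: float, n2: int
) -> EffectSize:
    """Cohen's d for unequal sample sizes from means and standard errors.

    Group standard deviations are reconstructed as ``s_i = se_i *
    sqrt(n_i)``; d is the mean difference over the pooled standard
    deviation ``s_p^2 = ((n1-1)s1^2 + (n2-1)s2^2) / (n1+n2-2)``.
    """
    if n1 < 2 or n2 < 2:
        raise UsageError("both groups need n >= 2")
    if se1 <= 0 or se2 <= 0:
        raise UsageError("standard errors must be > 0")
    s1 = se1 * np.sqrt(n1)
    s2 = se2 * np.sqrt(n2)
    s_pooled = np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2))
    d = float((mean1 - mean2) / s_pooled)
    return EffectSize(d=d, category=EffectSize.categorize(d))


def levene_hov(groups: list, center: str = "mean") -> tuple[float, float]:
    """Levene's homogeneity-of-variance test across groups.

    ``center='mean'`` is the classic form (absolute deviations from the
    group mean); ``'median'`` gives the Brown-Forsythe variant.  Groups
    of identical constants have zero spread everywhere and return a
    statistic of 0 with p = 1.
    """
    if center not in ("mean", "median"):
        raise UsageError("center must be 'mean' or 'median'")
    if len(groups) < 2:
        raise UsageError("need >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    for g in arrays:
        if len(g) < 2:
            raise UsageError("every group needs n >= 2")
        if len(g) < 3 and np.var(g) == 0:
            raise UsageError("zero-variance group with n < 3 is degenerate")
    devs = [
        np.abs(g - (np.mean(g) if center == "mean" else np.median(g))) for g in arrays
    ]
    if all(np.all(d == 0) for d in devs):
        return 0.0, 1.0
    stat, p = sps.levene(*arrays, center=center)
    return float(stat), float(p)


def _tukey_p(t_stat: float, k: int, df: int) -> float:
    """Tukey studentized-range p for a pairwise |t| with k level means."""
    q = abs(t_stat) * np.sqrt(2.0)
    return float(np.clip(sps.studentized_range.sf(q, k, df), 0.0, 1.0))


def _fit_factor_model(
    table: pd.DataFrame,
    parameter: str,
    factor_col: str,
    session_col: str,
) -> StateEffectEstimate:
    data = table[table["parameter"] == parameter]
    if data.empty:
        raise UsageError(f"no rows for parameter {parameter!r}")
    data = data[[factor_col, session_col, "value"]].dropna()
    levels = sorted(data[factor_col].unique())
    if len(levels) < 2:
        raise FittingError(f"factor {factor_col!r} needs >= 2 levels, got {levels}")
    for level in levels:
        sub = data[data[factor_col] == level]
        n_sessions = sub[session_col].nunique()
        if n_sessions < 2:
            raise FittingError(
                f"singular design: level {level!r} has {n_sessions} session(s); "
                "session-nested random effects need >= 2 sessions per level"
            )
        counts = sub.groupby(session_col)["value"].size()
        if (counts < 2).any():
            bad = counts[counts < 2].index[0]
            raise FittingError(
                f"session {bad!r} in level {level!r} has < 2 observations"
            )

    # cell-means coding: one column per level, no intercept
    exog = pd.get_dummies(data[factor_col]).astype(float)[levels]
    endog = data["value"].to_numpy(dtype=float)
    groups = data[session_col].to_numpy()

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(endog, exog.to_numpy(), groups=groups)
        result = None
        errors: list[str] = []
        for method in (None, "powell", "cg"):
            try:
                result = (
                    model.fit(reml=True)
                    if method is None
                    else model.fit(reml=True, method=method)
                )
            except Exception as exc:  # noqa: BLE001 - try the next optimizer
                errors.append(f"{method or 'default'}: {exc}")
                continue
            # a session variance estimated at (or squeezed onto) zero is a
            # boundary solution, not a failed fit
            boundary = float(np.squeeze(result.cov_re)) <= 1e-8 * max(result.scale, 1e-12)
            if result.converged or boundary:
                break
            errors.append(f"{method or 'default'}: not converged, params={result.params}")
            result = None
    if result is None:
        raise FittingError(
            "mixed model did not converge; attempts: " + "; ".join(errors)
        )

    k = len(levels)
    means = np.asarray(result.fe_params, dtype=float)
    cov = np.asarray(result.cov_params())[:k, :k]
    ses = np.sqrt(np.diag(cov))
    n_sessions_total = data[session_col].nunique()
    # comparisons of a between-session factor: session-level df when
    # available, else residual df
    df_between = n_sessions_total - k
    ddof = df_between if df_between >= 2 else max(len(data) - k, 2)
    z = sps.t.ppf(0.975, ddof)

    estimate = StateEffectEstimate(
        parameter=parameter,
        factor=factor_col,
        model_info={
            "n_obs": int(len(data)),
            "n_sessions": int(n_sessions_total),
            "df": int(ddof),
            "session_variance": float(np.squeeze(result.cov_re)),
            "residual_variance": float(result.scale),
            "reml": True,
        },
    )
    counts = data.groupby(factor_col)["value"].size()
    for i, level in enumerate(levels):
        estimate.levels.append(
            LevelEstimate(
                level=str(level),
                mean=float(means[i]),
                se=float(ses[i]),
                ci_low=float(means[i] - z * ses[i]),
                ci_high=float(means[i] + z * ses[i]),
                n=int(counts[level]),
            )
        )
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(means[i] - means[j])
            se_d = float(np.sqrt(cov[i, i] + cov[j, j] - 2 * cov[i, j]))
            t_stat = diff / se_d if se_d > 0 else np.inf
            p_un = float(2 * sps.t.sf(abs(t_stat), ddof))
            p_tk = _tukey_p(t_stat, k, ddof) if k > 2 else p_un
            effect = cohens_d_unequal(
                means[i], ses[i], int(counts[levels[i]]),
                means[j], ses[j], int(counts[levels[j]]),
            )
            estimate.contrasts.append(
                Contrast(
                    level_a=str(levels[i]),
                    level_b=str(levels[j]),
                    difference=diff,
                    se=se_d,
                    t=float(t_stat),
                    p_unadjusted=p_un,
                    p_tukey=max(p_tk, p_un),
                    effect_size=effect,
                )
            )
    return estimate


def fit_state_model(table: pd.DataFrame, parameter: str) -> StateEffectEstimate:
    """Mixed model: state fixed, session nested within state random.

    ``table`` is the long-format gait parameter table; observations are
    the rows of the requested parameter (stride-level for stride
    parameters, pass-level for cadence and gait speed).
    """
    return _fit_factor_model(table, parameter, "state", "session")


def fit_baseline_subject_model(table: pd.DataFrame, parameter: str) -> StateEffectEstimate:
    """Baseline across-subject comparison on naive-state data only:
    subject fixed, sessions nested within subject random."""
    naive = table[table["state"].str.lower().isin(["naive", "naïve"])]
    if naive.empty:
        raise UsageError("no naive-state rows in table")
    return _fit_factor_model(naive, parameter, "subject", "session")
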