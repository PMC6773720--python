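"""Mixed-model inference, likelihood-ratio comparisons, power analysis.

All models are linear mixed models with per-subject random intercepts,
fitted by maximum likelihood (not REML) so that likelihood-ratio tests
between nested fixed-effect structures are valid; p-values come from
the chi-square reference distribution.  Gravity enters as an unordered
categorical factor with 1 g as the reference level, so coefficients are
per-level contrasts against earth gravity.

The power analysis follows the design-planning logic of the study: a
two-condition within-subject comparison where trial-to-trial (within
subject) variability is six times the between-subject variability, with
power estimated by Monte-Carlo simulation of the full fit-and-test
pipeline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy.stats import chi2 as chi2_dist
from statsmodels.tools.sm_exceptions import ConvergenceWarning

GRAVITY_REFERENCE = 1.0

#: default variability scales (gain units): within-subject trial noise
#: is six times the between-subject intercept spread
SUBJECT_SD_DEFAULT = 0.025
SD_RATIO_DEFAULT = 6.0


class StatsError(ValueError):
    """Invalid model request."""


@dataclass
class LmmFit:
    """A fitted random-intercept linear mixed model (ML)."""

    formula: str
    fixed_effects: dict[str, tuple[float, float]]  # name -> (estimate, SE)
    random_intercept_var: float
    residual_var: float
    loglik: float
    n_obs: int
    n_groups: int
    n_fixed: int
    singular: bool = False
    converged: bool = True


@dataclass(frozen=True)
class LrtResult:
    """Likelihood-ratio comparison of nested ML fits."""

    chi2: float
    df: int
    p: float


def _gravity_formula_term(frame: pd.DataFrame, col: str = "gravity_mult") -> str:
    levels = sorted(frame[col].unique())
    if GRAVITY_REFERENCE in levels:
        return f"C({col}, Treatment(reference={GRAVITY_REFERENCE}))"
    return f"C({col})"


def fit_lmm(data: pd.DataFrame, response: str, fixed_terms: list[str],
            group: str) -> LmmFit:
    """ML fit of ``response ~ fixed_terms + (1 | group)``.

    ``fixed_terms`` are patsy-style terms; ``gravity_mult`` is
    automatically coded as a categorical with the 1 g reference.  An
    empty term list fits the intercept-only null model.
    """
    n_groups = data[group].nunique()
    if n_groups < 2:
        raise StatsError("need at least 2 groups for a mixed model")
    terms = []
    for term in fixed_terms:
        parts = []
        for factor in term.split(":"):
            factor = factor.strip()
            if factor == "gravity_mult":
                parts.append(_gravity_formula_term(data))
            elif factor in data.columns and (
                    data[factor].dtype == object
                    or str(data[factor].dtype) == "category"):
                if data[factor].nunique() < 2:
                    raise StatsError(f"fixed factor {factor!r} has one level")
                parts.append(f"C({factor})")
            else:
                parts.append(factor)
        if term != "1" and ":" not in term and term == "gravity_mult" \
                and data["gravity_mult"].nunique() < 2:
            raise StatsError("gravity factor has a single level")
        terms.append(":".join(parts))
    rhs = " + ".join(terms) if terms else "1"
    formula = f"{response} ~ {rhs}"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(formula, data, groups=data[group])
        fit = None
        err = None
        for method in ("bfgs", "powell", "nm"):  # deterministic cascade
            try:
                cand = model.fit(reml=False, method=method, maxiter=500)
            except np.linalg.LinAlgError as exc:
                err = exc
                continue
            if not np.isfinite(cand.llf):
                err = StatsError("non-finite log-likelihood")
                continue
            fit = cand
            if cand.converged:
                break
        if fit is None:
            raise StatsError(f"mixed-model fit failed: {err}")

    re_var = float(np.asarray(fit.cov_re)[0, 0])
    singular = re_var < 1e-10
    fe = {name: (float(fit.fe_params[name]), float(fit.bse_fe[name]))
          for name in fit.fe_params.index}
    return LmmFit(formula=formula, fixed_effects=fe,
                  random_intercept_var=max(re_var, 0.0),
                  residual_var=float(fit.scale), loglik=float(fit.llf),
                  n_obs=int(fit.nobs), n_groups=int(n_groups),
                  n_fixed=len(fe), singular=singular,
                  converged=bool(fit.converged))


def lrt(full: LmmFit, null: LmmFit) -> LrtResult:
    """Likelihood-ratio test of nested ML fits (chi-square reference)."""
    if full.n_obs != null.n_obs:
        raise StatsError("models fitted to different data")
    df = full.n_fixed - null.n_fixed
    if df < 0:
        raise StatsError("models are not nested (null has more parameters)")
    stat = max(2.0 * (full.loglik - null.loglik), 0.0)
    if df == 0:  # identical fixed structures: point-mass reference
        return LrtResult(chi2=stat, df=0, p=1.0 if stat < 1e-8 else 0.0)
    return LrtResult(chi2=stat, df=df, p=float(chi2_dist.sf(stat, df)))


@dataclass
class AnalysisReport:
    """Fit + comparison bundle for one pre-registered analysis."""

    block_type: str
    response: str
    full: LmmFit
    null: LmmFit
    lrt_vs_null: LrtResult
    coefficients: pd.DataFrame
    notes: dict = field(default_factory=dict)


def _coef_table(fit: LmmFit) -> pd.DataFrame:
    rows = [{"term": k, "estimate": v[0], "se": v[1]}
            for k, v in fit.fixed_effects.items()]
    return pd.DataFrame(rows)


def analyze_gain(data: pd.DataFrame, block_type: str,
                 response: str = "gain") -> AnalysisReport:
    """Pursuit-gain analysis: gain ~ gravity + (1|subject) vs null.

    The inversion block (1 g vs -1 g) and the graded blocks
    (0.7-1.3 g) are analysed separately; pass the block type to select.
    """
    sub = data.loc[data["block_type"] == block_type].copy()
    full = fit_lmm(sub, response, ["gravity_mult"], "subject")
    null = fit_lmm(sub, response, [], "subject")
    return AnalysisReport(block_type=block_type, response=response,
                          full=full, null=null, lrt_vs_null=lrt(full, null),
                          coefficients=_coef_table(full))


def analyze_timing(data: pd.DataFrame, block_type: str,
                   response: str = "corrected_error",
                   alpha: float = 0.05) -> AnalysisReport:
    """Timing-error analysis with model selection.

    Fits the pre-registered interaction model
    ``error ~ gravity * occlusion + (1|subject)`` and the gravity-only
    model; if the interaction does not improve the fit at ``alpha`` the
    simpler model is carried forward.  The selected model is then
    compared against the intercept-only null.
    """
    sub = data.loc[(data["block_type"] == block_type)
                   & ~data["excluded"]].copy()
    inter = fit_lmm(sub, response,
                    ["gravity_mult", "occ_category",
                     "gravity_mult:occ_category"], "subject")
    simple = fit_lmm(sub, response, ["gravity_mult"], "subject")
    sel_test = lrt(inter, simple)
    selected = inter if sel_test.p < alpha else simple
    null = fit_lmm(sub, response, [], "subject")
    report = AnalysisReport(block_type=block_type, response=response,
                            full=selected, null=null,
                            lrt_vs_null=lrt(selected, null),
                            coefficients=_coef_table(selected))
    report.notes["interaction_lrt"] = sel_test
    report.notes["selected"] = "interaction" if selected is inter else "gravity_only"
    return report


def _simulate_two_condition(rng: np.random.Generator, n_subjects: int,
                            n_trials: int, effect: float,
                            subject_sd: float, trial_sd: float,
                            baseline: float = 0.9) -> pd.DataFrame:
    subj = np.repeat(np.arange(n_subjects), 2 * n_trials)
    cond = np.tile(np.repeat([0.0, 1.0], n_trials), n_subjects)
    b = rng.normal(0.0, subject_sd, n_subjects)[subj]
    y = baseline + effect * cond + b + rng.normal(0.0, trial_sd, len(subj))
    return pd.DataFrame({"gain": y, "condition": cond.astype(int).astype(str),
                         "subject": subj})


def power_simulation(n_subjects: int, n_trials: int, effect: float,
                     sd_ratio: float = SD_RATIO_DEFAULT,
                     subject_sd: float = SUBJECT_SD_DEFAULT,
                     alpha: float = 0.05, n_sims: int = 200,
                     seed: int = 0) -> float:
    """Monte-Carlo power of the LMM + LRT pipeline for a gain difference.

    Each simulated cohort has ``n_subjects`` subjects contributing
    ``n_trials`` trials per condition, a between-condition gain
    difference ``effect``, Normal random intercepts (``subject_sd``)
    and trial noise ``sd_ratio * subject_sd``.  Returns the rejection
    fraction at ``alpha``.
    """
    if n_sims < 1:
        raise StatsError("n_sims must be positive")
    rng = np.random.default_rng(seed)
    trial_sd = sd_ratio * subject_sd
    hits = 0
    for _ in range(n_sims):
        df = _simulate_two_condition(rng, n_subjects, n_trials, effect,
                                     subject_sd, trial_sd)
        full = fit_lmm(df, "gain", ["condition"], "subject")
        null = fit_lmm(df, "gain", [], "subject")
        if lrt(full, null).p < alpha:
            hits += 1
    return hits / n_sims
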