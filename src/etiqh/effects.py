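"""Year, level and owner effects on facility scores via linear mixed models.

The estimation mirrors the survey design: facility-year scores are
regressed on categorical year, facility level and owner, with a random
intercept for council capturing within-council correlation. Reference
categories are year 2011, health center, and private-not-for-profit, so
coefficients read as percentage-point differences from those baselines.

Model selection starts from the full three-way factorial and prunes
interaction terms backwards by Wald tests — highest order first, within
an order the largest p-value first — until all remaining interactions
are significant; AIC (from ML fits) is tracked for every visited model.
A sensitivity check refits the fixed-effects-only model with
cluster-robust (council) standard errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .types import LEVELS, OWNERS

__all__ = [
    "EffectsResult",
    "build_model_frame",
    "fit_mixed",
    "prune_interactions",
    "robust_fixed_check",
]

REFERENCES = {"level": "health_center", "owner": "private_not_for_profit"}

MAIN_TERMS = ("year", "level", "owner")
INTERACTIONS_2 = ("year:level", "year:owner", "level:owner")
INTERACTION_3 = "year:level:owner"


@dataclass
class EffectsResult:
    """A fitted effects model: coefficients, uncertainty, and its history."""

    outcome: str
    formula: str
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    conf_int: pd.DataFrame
    re_variance: float
    aic: float
    converged: bool
    pruning_trace: list = field(default_factory=list)

    def summary_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "pvalue": self.pvalues,
                "ci_low": self.conf_int[0],
                "ci_high": self.conf_int[1],
            }
        )
        df["stars"] = pd.cut(
            df["pvalue"],
            [-1, 0.001, 0.01, 0.05, 1.1],
            labels=["***", "**", "*", ""],
        ).astype(str)
        return df


def build_model_frame(
    scorecards: pd.DataFrame, roster: pd.DataFrame, outcome: str = "overall"
) -> pd.DataFrame:
    """Join scorecards to the roster and fix categorical references.

    Categories are ordered with the reference first (year = earliest,
    level = health_center, owner = private-not-for-profit), which is the
    order the design matrices use.
    """
    if outcome not in scorecards.columns:
        raise ValueError(f"outcome {outcome!r} not in scorecards")
    df = scorecards.merge(roster, on="facility", how="inner")
    if df.empty:
        raise ValueError("no scorecards matched the roster")
    years = sorted(df["year"].unique())
    df["year"] = pd.Categorical(
        df["year"].astype(str), categories=[str(y) for y in years]
    )
    df["level"] = pd.Categorical(
        df["level"],
        categories=[REFERENCES["level"]]
        + [l for l in LEVELS if l != REFERENCES["level"] and l in set(df["level"])],
    )
    df["owner"] = pd.Categorical(
        df["owner"],
        categories=[REFERENCES["owner"]]
        + [o for o in OWNERS if o != REFERENCES["owner"] and o in set(df["owner"])],
    )
    return df.dropna(subset=[outcome])


def _fit(formula, frame, reml, facility_re=False):
    kwargs = {"groups": frame["council"]}
    if facility_re:
        kwargs["vc_formula"] = {"facility": "0 + C(facility)"}
    model = smf.mixedlm(formula, frame, **kwargs)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        # boundary (zero-variance) random-effect estimates are expected on
        # small or homogeneous data and are reported, not raised
        warnings.simplefilter("ignore", UserWarning)
        res = model.fit(reml=reml)
    return res


def fit_mixed(
    frame: pd.DataFrame,
    outcome: str = "overall",
    formula_rhs: str = "year + level + owner",
    reml: bool = True,
    facility_re: bool = False,
) -> EffectsResult:
    """Fit a linear mixed model with a council random intercept.

    ``facility_re`` adds a nested facility random intercept for data
    where facility-level deviations persist across years.
    """
    if frame["council"].nunique() < 2:
        raise ValueError("need at least 2 councils for a council random effect")
    formula = f"{outcome} ~ {formula_rhs}"
    res = _fit(formula, frame, reml, facility_re)
    if reml:  # AIC is only comparable across ML fits
        aic = float(_fit(formula, frame, reml=False, facility_re=facility_re).aic)
    else:
        aic = float(res.aic)
    fe = res.fe_params.index
    return EffectsResult(
        outcome=outcome,
        formula=formula,
        params=res.params[fe],
        bse=res.bse[fe],
        pvalues=res.pvalues[fe],
        conf_int=res.conf_int().loc[fe],
        re_variance=float(res.cov_re.iloc[0, 0]),
        aic=aic,
        converged=bool(res.converged),
    )


def _term_order(term: str) -> int:
    return term.count(":") + 1


def _wald_pvalues(res) -> dict[str, float]:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        table = res.wald_test_terms(scalar=True).table
    return dict(zip(table.index, table["pvalue"]))


def _estimable_terms(frame: pd.DataFrame, outcome: str, terms: list[str]) -> list[str]:
    """Largest estimable sub-model: add terms lowest-order first and keep a
    term only if its design columns are linearly independent of the
    design built so far (empty covariate cells make higher-order
    interaction columns collinear)."""
    import patsy

    kept: list[str] = []
    x = None
    rank = 0
    for term in sorted(terms, key=_term_order):
        trial = patsy.dmatrix(
            " + ".join(kept + [term]), frame, return_type="dataframe"
        ).to_numpy()
        trial_rank = np.linalg.matrix_rank(trial)
        if trial_rank == trial.shape[1]:
            kept.append(term)
            rank = trial_rank
        elif _term_order(term) == 1:
            kept.append(term)  # main effects always stay; collinearity there
            rank = trial_rank  # is a data defect surfaced by the fit itself
    return kept


def prune_interactions(
    frame: pd.DataFrame,
    outcome: str = "overall",
    alpha: float = 0.05,
    facility_re: bool = False,
) -> EffectsResult:
    """Backward-eliminate interaction terms by Wald tests.

    Starts from ``year*level*owner`` (reduced to the largest estimable
    model if cells are empty). At each step the candidate with the
    highest interaction order and, within that order, the largest Wald
    p-value is removed if p > alpha; main effects always stay. ML fits
    during selection make the recorded AICs comparable; the returned
    final model is refit by REML and carries the full pruning trace.
    """
    terms = list(MAIN_TERMS) + list(INTERACTIONS_2) + [INTERACTION_3]
    start = _estimable_terms(frame, outcome, terms)
    trace = []
    if start != terms:
        trace.append(
            {
                "action": "reduced_to_estimable",
                "removed": sorted(set(terms) - set(start)),
            }
        )
    terms = start

    while True:
        formula = f"{outcome} ~ {' + '.join(terms)}"
        try:
            res = _fit(formula, frame, reml=False, facility_re=facility_re)
            pvals = _wald_pvalues(res)
        except np.linalg.LinAlgError:
            inter = [t for t in terms if _term_order(t) > 1]
            if not inter:
                raise
            drop = max(inter, key=_term_order)
            terms.remove(drop)
            trace.append({"action": "removed_unfittable", "candidate": drop})
            continue
        inter = [t for t in terms if _term_order(t) > 1]
        if not inter:
            trace.append({"action": "fit", "formula": formula, "aic": float(res.aic)})
            break
        max_order = max(_term_order(t) for t in inter)
        # a lower-order interaction is only removable once nothing higher
        # contains it, so candidates are the current highest order
        candidates = [t for t in inter if _term_order(t) == max_order]
        worst = max(candidates, key=lambda t: pvals.get(t, 0.0))
        p = pvals.get(worst, np.nan)
        trace.append(
            {
                "action": "fit",
                "formula": formula,
                "aic": float(res.aic),
                "candidate": worst,
                "pvalue": float(p),
            }
        )
        if np.isnan(p) or p > alpha:
            terms.remove(worst)
            trace[-1]["action"] = "removed"
        else:
            break

    final = fit_mixed(
        frame,
        outcome,
        formula_rhs=" + ".join(terms),
        reml=True,
        facility_re=facility_re,
    )
    final.pruning_trace = trace
    return final


def robust_fixed_check(
    frame: pd.DataFrame,
    outcome: str = "overall",
    formula_rhs: str = "year + level + owner",
) -> pd.DataFrame:
    """Compare the mixed model against OLS with cluster-robust errors.

    Fits the same fixed effects by OLS with council-clustered (sandwich)
    standard errors and reports per-coefficient deltas against the mixed
    model — the sensitivity check for the random-effect specification.
    """
    mixed = fit_mixed(frame, outcome, formula_rhs=formula_rhs)
    ols = smf.ols(f"{outcome} ~ {formula_rhs}", frame).fit(
        cov_type="cluster", cov_kwds={"groups": frame["council"]}
    )
    idx = mixed.params.index
    out = pd.DataFrame(
        {
            "coef_mixed": mixed.params,
            "se_mixed": mixed.bse,
            "coef_fixed_robust": ols.params.reindex(idx),
            "se_fixed_robust": ols.bse.reindex(idx),
        }
    )
    out["coef_delta"] = out["coef_fixed_robust"] - out["coef_mixed"]
    out["delta_in_se"] = out["coef_delta"] / out["se_mixed"]
    return out
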