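"""Indicator, quality-dimension and overall facility scores, and rankings.

Scoring model
-------------
Each indicator at a facility-year may be answered one or more times with
yes/no/not-applicable (or graded values in [0, 1] for medicine
availability). The indicator's credit is its *fraction met*: the yes-share
of the non-NA answers (mean of graded values). Repeated answers therefore
earn fractional credit — answering an indicator more than once makes the
full score harder to obtain.

A quality-dimension (QD) score is the weight-weighted mean of indicator
fractions within that dimension, as a percentage of the maximal possible
points; QD3's four sub-sections pool into a single QD3 aggregate by
default. The overall facility score is the unweighted arithmetic mean of
the six QD scores, so every dimension contributes equally regardless of
how many indicators it contains. A QD with nothing applicable/assessed is
undefined and simply drops out of the overall mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import ensure_values
from .types import QDS, SECTION_TO_QD, SECTIONS

__all__ = [
    "ScoreCard",
    "Ranking",
    "RankAgreement",
    "fraction_met",
    "indicator_fractions",
    "qd_score",
    "score_facility",
    "score_all",
    "rank_facilities",
    "compare_rankings",
    "assessment_diagnostics",
]


@dataclass(frozen=True)
class ScoreCard:
    """Per-facility-year QD scores, overall score, and assessment diagnostics."""

    facility: str
    year: int
    qd_scores: Mapping[str, float]
    overall: float
    n_indicators_assessed: int
    avg_answers_per_indicator: float


@dataclass(frozen=True)
class Ranking:
    """An ordered ranking of facilities; rank 1 is the best score.

    Ties are broken by facility id (lexicographic), so ranks are always a
    permutation of 1..n and reruns are deterministic.
    """

    entries: tuple  # of (facility, rank, score)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.entries, columns=["facility", "rank", "score"])

    def rank_of(self) -> pd.Series:
        df = self.as_frame()
        return df.set_index("facility")["rank"]


@dataclass(frozen=True)
class RankAgreement:
    """Agreement between two rankings over the same facilities."""

    spearman_rho: float
    kendall_tau: float
    max_displacement: int
    displacement: Mapping[str, int] = field(default_factory=dict)


def fraction_met(answers: Sequence) -> float | None:
    """Credit earned by one indicator from its (possibly repeated) answers.

    Binary answers (``"yes"``/``"no"``/``"na"`` strings): yes / (yes + no).
    Graded answers (numbers in [0, 1], NA allowed as ``"na"``): mean of the
    graded values. Returns ``None`` when every answer is not-applicable —
    the indicator is excluded from scoring.

    Raises
    ------
    ValueError
        If the list is empty, mixes binary and graded answers, contains an
        unknown token, or a graded value falls outside [0, 1].
    """
    if len(answers) == 0:
        raise ValueError("empty answer list")
    binary: list[float] = []
    graded: list[float] = []
    for a in answers:
        if isinstance(a, str):
            s = a.strip().lower()
            if s == "yes":
                binary.append(1.0)
            elif s == "no":
                binary.append(0.0)
            elif s == "na":
                continue
            else:
                try:
                    graded.append(_check_graded(float(s)))
                except ValueError as e:
                    if "outside" in str(e):
                        raise
                    raise ValueError(f"unknown answer {a!r}") from None
        elif isinstance(a, (int, float, np.floating, np.integer)):
            if isinstance(a, float) and np.isnan(a):
                continue
            graded.append(_check_graded(float(a)))
        else:
            raise ValueError(f"unknown answer {a!r}")
    if binary and graded:
        raise ValueError("mixed binary and graded answers for one indicator")
    vals = binary or graded
    if not vals:
        return None
    return float(np.mean(vals))


def _check_graded(v: float) -> float:
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"graded answer {v} outside [0, 1]")
    return v


def indicator_fractions(
    responses: pd.DataFrame, catalog: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Per (facility, year, indicator) fraction met and answer count.

    Indicators whose answers are all NA are dropped (undefined). If a
    catalog is given, responses to indicators absent from it are dropped.
    Returns columns facility, year, indicator, fraction, n_answers (non-NA
    answers counted).
    """
    df = ensure_values(responses)
    if catalog is not None:
        df = df[df["indicator"].isin(set(catalog["id"]))]
    g = df.groupby(["facility", "year", "indicator"], sort=True)["value"]
    out = g.agg(fraction="mean", n_answers="count").reset_index()
    return out[out["fraction"].notna()].reset_index(drop=True)


def _section_scores(
    fractions: pd.DataFrame, catalog: pd.DataFrame, weighted: bool
) -> pd.DataFrame:
    """Weighted percentage score per (facility, year, section)."""
    m = fractions.merge(
        catalog[["id", "section", "weight"]],
        left_on="indicator",
        right_on="id",
        how="inner",
    )
    m["w"] = m["weight"].astype(float) if weighted else 1.0
    m["wf"] = m["w"] * m["fraction"]
    g = m.groupby(["facility", "year", "section"], sort=True)[["wf", "w"]].sum()
    g["score"] = 100.0 * g["wf"] / g["w"]
    return g.reset_index()[["facility", "year", "section", "score", "w"]]


def score_all(
    catalog: pd.DataFrame,
    responses: pd.DataFrame,
    weighted: bool = True,
    qd3: str = "pooled",
) -> pd.DataFrame:
    """Score every facility-year present in ``responses``.

    Parameters
    ----------
    weighted : bool
        Use the catalog's 1–5 importance weights; if False all indicators
        count equally.
    qd3 : {"pooled", "submean"}
        ``pooled`` aggregates all QD3A–QD3D indicators into one weighted
        QD3 score; ``submean`` scores each sub-section separately and
        averages the defined sub-scores.

    Returns
    -------
    DataFrame with columns facility, year, QD1..QD6, overall,
    n_indicators_assessed, avg_answers_per_indicator. Undefined QD scores
    are NaN; overall is the mean of the defined QDs.
    """
    if qd3 not in ("pooled", "submean"):
        raise ValueError(f"unknown qd3 mode {qd3!r}")
    fr = indicator_fractions(responses, catalog)
    if fr.empty:
        raise ValueError("no scoreable responses (empty assessment)")

    sec = _section_scores(fr, catalog, weighted)
    if qd3 == "pooled":
        sec["qd"] = sec["section"].map(SECTION_TO_QD)
        qd = (
            sec.assign(ws=sec["w"] * sec["score"])
            .groupby(["facility", "year", "qd"], sort=True)[["ws", "w"]]
            .sum()
        )
        qd["score"] = qd["ws"] / qd["w"]
        qd = qd.reset_index()
    else:
        sec["qd"] = sec["section"].map(SECTION_TO_QD)
        qd = (
            sec.groupby(["facility", "year", "qd"], sort=True)["score"]
            .mean()
            .reset_index()
        )
    wide = qd.pivot_table(
        index=["facility", "year"], columns="qd", values="score", dropna=False
    )
    wide = wide.reindex(columns=list(QDS))
    wide["overall"] = wide[list(QDS)].mean(axis=1, skipna=True)

    diag = fr.groupby(["facility", "year"])["n_answers"].agg(["size", "mean"])
    diag.columns = ["n_indicators_assessed", "avg_answers_per_indicator"]
    out = wide.join(diag).reset_index()
    out.columns.name = None
    return out


def qd_score(
    catalog: pd.DataFrame,
    responses: pd.DataFrame,
    facility: str,
    year: int,
    section_set: Iterable[str],
    weighted: bool = True,
) -> float:
    """Percentage score over the given sections for one facility-year.

    100 x sum(w_i f_i) / sum(w_i) over indicators with a defined fraction;
    w_i is the catalog weight when ``weighted`` else 1.

    Raises
    ------
    ValueError
        If no applicable indicator in the section set was assessed.
    """
    sections = set(section_set)
    unknown = sections - set(SECTIONS)
    if unknown:
        raise ValueError(f"unknown sections {sorted(unknown)}")
    df = ensure_values(responses)
    df = df[(df["facility"] == facility) & (df["year"] == year)]
    fr = indicator_fractions(df, catalog)
    m = fr.merge(
        catalog[catalog["section"].isin(sections)][["id", "weight"]],
        left_on="indicator",
        right_on="id",
        how="inner",
    )
    if m.empty:
        raise ValueError(
            f"no assessed indicator in sections {sorted(sections)} "
            f"for {facility}/{year}"
        )
    w = m["weight"].to_numpy(float) if weighted else np.ones(len(m))
    return float(100.0 * (w * m["fraction"].to_numpy()).sum() / w.sum())


def score_facility(
    catalog: pd.DataFrame,
    responses: pd.DataFrame,
    facility: str,
    year: int,
    weighted: bool = True,
    qd3: str = "pooled",
) -> ScoreCard:
    """Score one facility-year; see :func:`score_all` for the model."""
    df = ensure_values(responses)
    df = df[(df["facility"] == facility) & (df["year"] == year)]
    if df.empty:
        raise ValueError(f"no responses for {facility}/{year} (empty assessment)")
    card = score_all(catalog, df, weighted=weighted, qd3=qd3).iloc[0]
    return ScoreCard(
        facility=facility,
        year=year,
        qd_scores={q: float(card[q]) for q in QDS},
        overall=float(card["overall"]),
        n_indicators_assessed=int(card["n_indicators_assessed"]),
        avg_answers_per_indicator=float(card["avg_answers_per_indicator"]),
    )


def rank_facilities(
    scorecards: pd.DataFrame, score_col: str = "overall"
) -> Ranking:
    """Rank facilities by descending score; rank 1 is the best.

    All scorecards must belong to one year. Ties are broken by facility id
    so the output is deterministic.
    """
    df = scorecards
    if "year" in df.columns and df["year"].nunique() > 1:
        raise ValueError(
            f"scorecards span several years {sorted(df['year'].unique())}; rank one year at a time"
        )
    if len(df) == 0:
        raise ValueError("no scorecards to rank")
    ordered = df.sort_values(
        [score_col, "facility"], ascending=[False, True], kind="mergesort"
    )
    entries = tuple(
        (str(f), i + 1, float(s))
        for i, (f, s) in enumerate(zip(ordered["facility"], ordered[score_col]))
    )
    return Ranking(entries)


def compare_rankings(rank_a: Ranking, rank_b: Ranking) -> RankAgreement:
    """Agreement between two rankings of the same facilities.

    Reports Spearman's rho and Kendall's tau on the rank vectors, the
    maximal per-facility rank displacement, and every facility's
    displacement (rank in b minus rank in a).
    """
    a = rank_a.rank_of()
    b = rank_b.rank_of()
    if set(a.index) != set(b.index):
        raise ValueError("rankings cover different facility sets")
    b = b.reindex(a.index)
    rho = float(stats.spearmanr(a, b).statistic)
    tau = float(stats.kendalltau(a, b).statistic)
    disp = (b - a).astype(int)
    return RankAgreement(
        spearman_rho=rho,
        kendall_tau=tau,
        max_displacement=int(disp.abs().max()),
        displacement=disp.to_dict(),
    )


def assessment_diagnostics(
    responses: pd.DataFrame, facility: str, year: int
) -> tuple[int, float]:
    """(number of indicators assessed, average answers per indicator).

    An indicator counts as assessed when it has at least one non-NA
    answer; the average counts non-NA answers over assessed indicators.
    """
    df = ensure_values(responses)
    df = df[(df["facility"] == facility) & (df["year"] == year)]
    if df.empty:
        raise ValueError(f"no responses for {facility}/{year}")
    fr = indicator_fractions(df)
    return int(len(fr)), float(fr["n_answers"].mean()) if len(fr) else 0.0
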