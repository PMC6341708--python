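"""CSV dialects for catalogs, rosters, long-format responses and scorecards.

All tabular artifacts are plain CSV so that runs are diffable and
reproducible byte-for-byte. The response table is long format: one row per
recorded answer, so an indicator answered three times at one facility-year
contributes three rows.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import validate_catalog

ANSWER_STRINGS = {"yes": 1.0, "no": 0.0, "na": np.nan}


def read_catalog(path) -> pd.DataFrame:
    """Read an indicator catalog CSV (id,section,weight,itype,applicable_levels,response_kind)."""
    df = pd.read_csv(path, dtype={"id": str})
    return validate_catalog(df)


def write_catalog(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, index=False)


def read_roster(path) -> pd.DataFrame:
    """Read a facility roster CSV (facility,level,owner,council)."""
    df = pd.read_csv(path, dtype={"facility": str, "council": str})
    required = {"facility", "level", "owner", "council"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"roster missing columns {sorted(missing)}")
    return df


def write_roster(roster: pd.DataFrame, path) -> None:
    roster.to_csv(path, index=False)


def parse_answer(raw) -> float:
    """Parse one answer token: yes/no/na or a decimal in [0, 1].

    Returns the numeric credit (NaN for not-applicable).
    """
    s = str(raw).strip().lower()
    if s in ANSWER_STRINGS:
        return ANSWER_STRINGS[s]
    try:
        v = float(s)
    except ValueError:
        raise ValueError(f"unparseable answer {raw!r}") from None
    if not 0.0 <= v <= 1.0:
        raise ValueError(f"graded answer {v} outside [0, 1]")
    return v


def read_responses(path) -> pd.DataFrame:
    """Read a long-format responses CSV (facility,year,indicator,answer).

    Adds a numeric ``value`` column (yes=1, no=0, na=NaN, graded as-is)
    while keeping the raw ``answer`` strings.
    """
    df = pd.read_csv(path, dtype={"facility": str, "indicator": str, "answer": str})
    required = {"facility", "year", "indicator", "answer"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"responses missing columns {sorted(missing)}")
    df["year"] = df["year"].astype(int)
    df["value"] = df["answer"].map(parse_answer)
    return df


def write_responses(responses: pd.DataFrame, path) -> None:
    responses[["facility", "year", "indicator", "answer"]].to_csv(path, index=False)


def ensure_values(responses: pd.DataFrame) -> pd.DataFrame:
    """Return a copy of ``responses`` guaranteed to carry a numeric ``value`` column."""
    if "value" in responses.columns:
        return responses
    out = responses.copy()
    out["value"] = out["answer"].map(parse_answer)
    return out


def write_scorecards(scorecards: pd.DataFrame, path) -> None:
    """Write scorecards CSV (facility,year,qd1..qd6,overall,n_indicators,avg_answers)."""
    cols = [
        "facility", "year",
        "qd1", "qd2", "qd3", "qd4", "qd5", "qd6",
        "overall", "n_indicators", "avg_answers",
    ]
    out = scorecards.rename(
        columns={
            **{f"QD{i}": f"qd{i}" for i in range(1, 7)},
            "n_indicators_assessed": "n_indicators",
            "avg_answers_per_indicator": "avg_answers",
        }
    )
    out[cols].to_csv(path, index=False, float_format="%.10g")


def read_scorecards(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"facility": str})
    return df.rename(
        columns={
            **{f"qd{i}": f"QD{i}" for i in range(1, 7)},
            "n_indicators": "n_indicators_assessed",
            "avg_answers": "avg_answers_per_indicator",
        }
    )
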