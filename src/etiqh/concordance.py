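"""Factor-analysis concordance between empirical structure and designed sections.

The designed checklist groups indicators into nine sections. To test
whether that grouping matches the data's latent structure, fit a k=9
factor model to the facility-by-indicator score matrix, allocate each
indicator to the factor with its strongest (largest absolute) loading,
and compare the allocation with the designed sections via an optimal
one-to-one factor-section matching.

Allocation flags follow the conventional thresholds: an indicator is a
*weak* allocation when its best |loading| is below 0.4 (unlikely to be
relevant for predicting quality), and *cross-loaded* when any other
factor's |loading| comes within 0.2 of the best one (no clear association
with a single factor).

Extraction is principal-axis factoring (iterated communalities on the
correlation matrix) followed by varimax rotation; both standard, both
implemented here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .scoring import indicator_fractions
from .types import SECTIONS

__all__ = [
    "FactorAllocation",
    "indicator_score_matrix",
    "fit_factors",
    "allocate_indicators",
    "match_factors_to_sections",
    "concordance_table",
    "WEAK_LOADING",
    "CROSS_LOADING_BAND",
]

logger = logging.getLogger(__name__)

WEAK_LOADING = 0.4
CROSS_LOADING_BAND = 0.2


@dataclass(frozen=True)
class FactorAllocation:
    """One indicator's assigned factor and quality flags."""

    indicator: str
    factor: str
    loading: float
    weak: bool
    cross_loaded: bool


def indicator_score_matrix(
    responses: pd.DataFrame, catalog: pd.DataFrame, year: int
) -> pd.DataFrame:
    """Facility-by-indicator matrix of unweighted fractions met for one year.

    Not-applicable indicators leave missing cells. Indicators assessed at
    no facility are dropped (logged).
    """
    fr = indicator_fractions(responses[responses["year"] == year], catalog)
    if fr.empty:
        raise ValueError(f"no scoreable responses in year {year}")
    mat = fr.pivot(index="facility", columns="indicator", values="fraction")
    missing = [i for i in catalog["id"] if i not in mat.columns]
    if missing:
        logger.info(
            "dropping %d indicators assessed nowhere in %d: %s",
            len(missing), year, missing[:10],
        )
    order = [i for i in catalog["id"] if i in mat.columns]
    return mat[order]


def _varimax(loadings: np.ndarray, max_iter: int = 500, tol: float = 1e-10) -> np.ndarray:
    p, k = loadings.shape
    rot = np.eye(k)
    d = 0.0
    for _ in range(max_iter):
        lam = loadings @ rot
        u, s, vt = np.linalg.svd(
            loadings.T @ (lam**3 - lam @ np.diag((lam**2).sum(axis=0)) / p)
        )
        rot = u @ vt
        d_new = s.sum()
        if d_new < d * (1 + tol):
            break
        d = d_new
    return loadings @ rot


def fit_factors(
    matrix: pd.DataFrame,
    k: int = 9,
    method: str = "principal_axis",
    rotation: str = "varimax",
    min_rows: int = 10,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Extract ``k`` rotated factors from a facility-by-indicator matrix.

    Missing cells are imputed by column mean; constant columns are
    dropped (they carry no correlation information). Factors are ordered
    by explained variance (sum of squared loadings, descending) and each
    factor's sign is fixed so its largest-|loading| entry is positive.

    Returns an indicator-by-factor loading DataFrame (columns F1..Fk).
    """
    if method not in ("principal_axis",):
        raise ValueError(f"unknown extraction method {method!r}")
    if rotation not in ("varimax", "none"):
        raise ValueError(f"unknown rotation {rotation!r}")
    if len(matrix) < min_rows:
        raise ValueError(f"need at least {min_rows} facilities, got {len(matrix)}")

    x = matrix.copy()
    x = x.fillna(x.mean())
    sd = x.std(ddof=1)
    constant = sd[sd == 0].index.tolist() + sd[sd.isna()].index.tolist()
    if constant:
        logger.info("dropping %d constant indicators: %s", len(constant), constant[:10])
        x = x.drop(columns=constant)
    if k > min(len(x) - 1, x.shape[1]):
        raise ValueError(
            f"k={k} exceeds the rank supported by a {x.shape} matrix"
        )

    r = np.corrcoef(x.to_numpy(), rowvar=False)
    # initial communalities: squared multiple correlations where invertible
    try:
        rinv = np.linalg.inv(r)
        h2 = 1.0 - 1.0 / np.diag(rinv)
        if np.any(~np.isfinite(h2)) or np.any(h2 < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        off = r - np.diag(np.diag(r))
        h2 = np.max(np.abs(off), axis=1) ** 2
    h2 = np.clip(h2, 0.05, 0.998)

    lam = None
    for _ in range(max_iter):
        rr = r.copy()
        np.fill_diagonal(rr, h2)
        evals, evecs = np.linalg.eigh(rr)
        idx = np.argsort(evals)[::-1][:k]
        lam = evecs[:, idx] * np.sqrt(np.clip(evals[idx], 0.0, None))
        h2_new = np.clip((lam**2).sum(axis=1), 0.0, 0.998)
        if np.max(np.abs(h2_new - h2)) < tol:
            h2 = h2_new
            break
        h2 = h2_new

    if rotation == "varimax":
        lam = _varimax(lam)
    # descending explained variance, deterministic sign
    order = np.argsort((lam**2).sum(axis=0))[::-1]
    lam = lam[:, order]
    signs = np.sign(lam[np.abs(lam).argmax(axis=0), np.arange(k)])
    signs[signs == 0] = 1.0
    lam = lam * signs
    return pd.DataFrame(
        lam, index=x.columns, columns=[f"F{j + 1}" for j in range(k)]
    )


def allocate_indicators(
    loadings: pd.DataFrame,
    weak_threshold: float = WEAK_LOADING,
    cross_band: float = CROSS_LOADING_BAND,
) -> pd.DataFrame:
    """Allocate each indicator to its strongest factor and flag it.

    The assigned factor maximizes |loading| (ties broken toward the lower
    factor index, logged). ``weak`` flags best |loading| < 0.4;
    ``cross_loaded`` flags any other |loading| within 0.2 of the best.
    """
    if not np.isfinite(loadings.to_numpy()).all():
        raise ValueError("non-finite loadings")
    lam = loadings.to_numpy()
    ab = np.abs(lam)
    best = ab.argmax(axis=1)  # argmax takes the first (lowest index) on ties
    ties = (ab == ab[np.arange(len(ab)), best][:, None]).sum(axis=1) > 1
    for i in np.nonzero(ties)[0]:
        logger.warning(
            "loading tie for %s; assigned to %s",
            loadings.index[i], loadings.columns[best[i]],
        )
    best_abs = ab[np.arange(len(ab)), best]
    others = ab.copy()
    others[np.arange(len(ab)), best] = -np.inf
    cross = (others >= (best_abs - cross_band)[:, None]).any(axis=1)
    return pd.DataFrame(
        {
            "indicator": loadings.index,
            "factor": loadings.columns[best],
            "loading": lam[np.arange(len(lam)), best],
            "weak": best_abs < weak_threshold,
            "cross_loaded": cross,
        }
    ).reset_index(drop=True)


def match_factors_to_sections(
    allocations: pd.DataFrame, catalog: pd.DataFrame
) -> dict[str, str]:
    """Optimal one-to-one factor-to-section mapping.

    Builds the factor-by-section contingency table of allocated
    indicators and solves the assignment maximizing total agreement
    (Hungarian algorithm). Returns ``{factor: section}``.
    """
    merged = allocations.merge(
        catalog[["id", "section"]], left_on="indicator", right_on="id"
    )
    factors = list(allocations["factor"].cat.categories) if isinstance(
        allocations["factor"].dtype, pd.CategoricalDtype
    ) else sorted(allocations["factor"].unique(), key=lambda f: int(f.lstrip("F")))
    sections = [s for s in SECTIONS if (catalog["section"] == s).any()]
    table = (
        merged.groupby(["factor", "section"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(index=factors, columns=sections, fill_value=0)
    )
    if table.to_numpy().sum() == 0:
        raise ValueError("empty factor-section contingency table")
    # pad to square so the assignment is total even when counts differ
    n = max(len(factors), len(sections))
    cost = np.zeros((n, n))
    cost[: len(factors), : len(sections)] = -table.to_numpy(float)
    rows, cols = linear_sum_assignment(cost)
    mapping = {}
    for i, j in zip(rows, cols):
        if i < len(factors) and j < len(sections):
            mapping[factors[i]] = sections[j]
    return mapping


def concordance_table(
    allocations: pd.DataFrame,
    mapping: dict[str, str],
    catalog: pd.DataFrame,
) -> pd.DataFrame:
    """Per-section concordance between allocation and design.

    For each section: total indicators, how many were allocated to the
    section's matched factor, and — separately within the matched and
    unmatched groups — how many are cross-loaded or strongly loaded
    (|loading| >= 0.4). Percentages use the per-section total for the
    match rate, the matched count for the matched breakdown, and the
    unmatched count for the unmatched breakdown. A ``Total`` row sums the
    counts with the analogous overall denominators.
    """
    section_of_factor = dict(mapping)
    merged = allocations.merge(
        catalog[["id", "section"]], left_on="indicator", right_on="id"
    )
    merged["matched"] = (
        merged["factor"].map(section_of_factor) == merged["section"]
    )
    merged["strong"] = merged["loading"].abs() >= WEAK_LOADING

    rows = []
    sections = [s for s in SECTIONS if (catalog["section"] == s).any()]
    factor_of_section = {v: k for k, v in mapping.items()}
    for s in sections:
        g = merged[merged["section"] == s]
        m = g[g["matched"]]
        u = g[~g["matched"]]
        rows.append(
            {
                "section": s,
                "factor": factor_of_section.get(s, ""),
                "n_indicators": len(g),
                "n_matched": len(m),
                "n_unmatched": len(u),
                "n_matched_cross_loaded": int(m["cross_loaded"].sum()),
                "n_matched_strong": int(m["strong"].sum()),
                "n_unmatched_cross_loaded": int(u["cross_loaded"].sum()),
                "n_unmatched_strong": int(u["strong"].sum()),
            }
        )
    df = pd.DataFrame(rows)
    total = df.drop(columns=["section", "factor"]).sum()
    total["section"] = "Total"
    total["factor"] = ""
    df = pd.concat([df, total.to_frame().T], ignore_index=True)
    for col in df.columns:
        if col.startswith("n_"):
            df[col] = df[col].astype(int)

    def pct(num, den):
        return np.where(den > 0, 100.0 * num / np.maximum(den, 1), np.nan)

    df["pct_matched"] = pct(df["n_matched"], df["n_indicators"])
    df["pct_matched_cross_loaded"] = pct(df["n_matched_cross_loaded"], df["n_matched"])
    df["pct_matched_strong"] = pct(df["n_matched_strong"], df["n_matched"])
    df["pct_unmatched_cross_loaded"] = pct(
        df["n_unmatched_cross_loaded"], df["n_unmatched"]
    )
    df["pct_unmatched_strong"] = pct(df["n_unmatched_strong"], df["n_unmatched"])
    return df
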