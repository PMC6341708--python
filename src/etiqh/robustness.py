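"""Sensitivity of facility scores and ranks to indicator count and weights.

Two robustness probes for a composite checklist score:

* the *subset curve* — recompute unweighted overall scores from nested
  indicator subsets of growing size, and measure the mean absolute score
  and rank change relative to the largest (reference) set;
* *weight ablation* — score the same responses once with the 1–5
  importance weights and once unweighted, and compare means, per-facility
  score shifts, and rank shifts.

Differences are reported as absolute values: signed score/rank changes
cancel when averaged across facilities.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scoring import rank_facilities, score_all
from .types import SECTIONS

__all__ = [
    "SubsetCurvePoint",
    "WeightAblationReport",
    "nested_subsets",
    "subset_difference_curve",
    "fit_trend",
    "weight_ablation",
]


@dataclass(frozen=True)
class SubsetCurvePoint:
    subset_size: int
    mean_abs_score_diff: float
    mean_abs_rank_diff: float


@dataclass(frozen=True)
class WeightAblationReport:
    mean_overall_weighted: float
    mean_overall_unweighted: float
    mean_abs_score_diff: float
    mean_abs_rank_diff: float


def nested_subsets(
    catalog: pd.DataFrame, sizes: Sequence[int], seed: int = 0
) -> list[pd.DataFrame]:
    """Nested, section-stratified random indicator subsets.

    Each requested size yields a sub-catalog contained in every larger
    one. Selection is stratified: within each section the order is a
    seeded shuffle, and sections are filled proportionally to their size,
    with each section's first indicator guaranteed a slot among the first
    picks so no section empties.
    """
    sizes = list(sizes)
    if sizes != sorted(sizes):
        raise ValueError("sizes must be ascending")
    if sizes[-1] > len(catalog):
        raise ValueError(
            f"requested size {sizes[-1]} exceeds catalog size {len(catalog)}"
        )
    present = [s for s in SECTIONS if (catalog["section"] == s).any()]
    if sizes[0] < len(present):
        raise ValueError(
            f"smallest size {sizes[0]} cannot cover all {len(present)} sections"
        )
    rng = np.random.default_rng(seed)
    keys = pd.Series(index=catalog.index, dtype=float)
    firsts = []
    for s in present:
        idx = catalog.index[catalog["section"] == s].to_numpy()
        idx = rng.permutation(idx)
        # fractional position within the section -> proportional fill
        keys[idx] = (np.arange(len(idx)) + 0.5) / len(idx)
        firsts.append(idx[0])
    # pull each section's first pick to the very front (deterministic order)
    keys[firsts] = -1.0 + np.argsort(rng.permutation(len(firsts))) * 1e-6
    order = keys.sort_values(kind="mergesort").index
    return [catalog.loc[order[:n]].sort_index() for n in sizes]


def subset_difference_curve(
    responses: pd.DataFrame,
    subsets: Sequence[pd.DataFrame],
    reference_set: pd.DataFrame,
    weighted: bool = False,
) -> list[SubsetCurvePoint]:
    """Mean absolute score and rank change of each subset vs the reference.

    Scores are unweighted by default. All facility-years in
    ``responses`` must belong to one year (rank comparisons are
    within-year).
    """
    if any(len(s) > len(reference_set) for s in subsets):
        raise ValueError("reference_set must be the largest indicator set")
    ref_cards = score_all(reference_set, responses, weighted=weighted)
    if ref_cards.empty:
        raise ValueError("no facilities to compare")
    ref_rank = rank_facilities(ref_cards).rank_of()
    ref_score = ref_cards.set_index("facility")["overall"]

    points = []
    for sub in subsets:
        cards = score_all(sub, responses, weighted=weighted)
        score = cards.set_index("facility")["overall"].reindex(ref_score.index)
        rank = rank_facilities(cards).rank_of().reindex(ref_rank.index)
        points.append(
            SubsetCurvePoint(
                subset_size=len(sub),
                mean_abs_score_diff=float((score - ref_score).abs().mean()),
                mean_abs_rank_diff=float((rank - ref_rank).abs().mean()),
            )
        )
    return points


def fit_trend(
    curve: Sequence[SubsetCurvePoint], kind: str = "quadratic", y: str = "score"
) -> dict:
    """Least-squares trend through a subset curve.

    ``kind`` is ``"quadratic"`` (2nd-order polynomial, the shape the
    score curve follows) or ``"linear"`` (the rank curve). Returns
    coefficients in ascending order of degree plus R².
    """
    deg = {"quadratic": 2, "linear": 1}.get(kind)
    if deg is None:
        raise ValueError(f"unknown trend kind {kind!r}")
    if len(curve) < deg + 1:
        raise ValueError(f"{kind} trend needs at least {deg + 1} points")
    x = np.array([p.subset_size for p in curve], float)
    yv = np.array(
        [
            p.mean_abs_score_diff if y == "score" else p.mean_abs_rank_diff
            for p in curve
        ],
        float,
    )
    coeffs = np.polynomial.polynomial.polyfit(x, yv, deg)
    fitted = np.polynomial.polynomial.polyval(x, coeffs)
    ss_res = float(((yv - fitted) ** 2).sum())
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return {"kind": kind, "coefficients": coeffs.tolist(), "r_squared": r2}


def plot_subset_curve(curve: Sequence[SubsetCurvePoint], path) -> None:
    """Plot score and rank difference curves with their fitted trends."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.array([p.subset_size for p in curve], float)
    score = [p.mean_abs_score_diff for p in curve]
    rank = [p.mean_abs_rank_diff for p in curve]
    grid = np.linspace(x.min(), x.max(), 200)
    fit_s = fit_trend(curve, "quadratic", y="score")
    fit_r = fit_trend(curve, "linear", y="rank")

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    ax1.plot(x, score, "o", color="tab:blue")
    ax1.plot(grid, np.polynomial.polynomial.polyval(grid, fit_s["coefficients"]),
             "-", color="tab:blue", alpha=0.6)
    ax1.set_xlabel("indicators in subset")
    ax1.set_ylabel("mean |score difference| (pp)")
    ax2.plot(x, rank, "s", color="tab:orange")
    ax2.plot(grid, np.polynomial.polynomial.polyval(grid, fit_r["coefficients"]),
             "-", color="tab:orange", alpha=0.6)
    ax2.set_xlabel("indicators in subset")
    ax2.set_ylabel("mean |rank difference|")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def weight_ablation(
    catalog: pd.DataFrame, responses: pd.DataFrame
) -> WeightAblationReport:
    """Compare weighted vs unweighted scoring on identical responses."""
    wc = score_all(catalog, responses, weighted=True)
    uc = score_all(catalog, responses, weighted=False)
    ws = wc.set_index("facility")["overall"]
    us = uc.set_index("facility")["overall"].reindex(ws.index)
    wr = rank_facilities(wc).rank_of()
    ur = rank_facilities(uc).rank_of().reindex(wr.index)
    return WeightAblationReport(
        mean_overall_weighted=float(ws.mean()),
        mean_overall_unweighted=float(us.mean()),
        mean_abs_score_diff=float((ws - us).abs().mean()),
        mean_abs_rank_diff=float((wr - ur).abs().mean()),
    )
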