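"""Synthetic supportive-supervision data with known ground truth.

The generator emulates a multi-council roster of dispensaries, health
centers and hospitals under four owner categories, assessed yearly
2011–2014 with a nine-section checklist. Responses come from a latent
logistic model: for facility ``f``, year ``t``, indicator ``i`` in section
``s`` the per-answer success probability is

    p = invlogit( mu + year_t + level_f + owner_f + u_council(f)
                  + delta_{f,s} + slope * (w_i - mean w) - difficulty_i )

with council intercepts ``u ~ N(0, council_sd)``, facility-by-section
deviations ``delta ~ N(0, qd_sd)`` (these carry the factor structure that
a factor analysis can recover), indicator difficulties
``~ N(0, difficulty_sd)``, and a weight-compliance tilt ``slope`` that
makes heavily weighted indicators slightly more likely to be met.

Effect sizes are configured on the familiar percentage-point scale (the
scale on which facility scores are reported) and converted to logit
offsets by numerical calibration: each offset is solved so that the
*expected* overall score gap — marginalised over the difficulty, council
and section-deviation distributions — equals the requested gap. A naive
logit shift evaluated at the baseline alone would be attenuated by those
noise distributions and the generator would not honestly plant the effect
it claims.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .types import LEVELS, OWNERS, QDS, SECTIONS, SECTION_TO_QD, validate_catalog

__all__ = [
    "SyntheticConfig",
    "SyntheticTruth",
    "generate_catalog",
    "generate_roster",
    "simulate_responses",
    "calibrate_offsets",
    "planted_loadings",
    "sample_from_loadings",
]

#: Default indicators per section (the nine-section checklist layout).
DEFAULT_SECTION_SIZES = {
    "QD1": 41,
    "QD2": 17,
    "QD3A": 17,
    "QD3B": 19,
    "QD3C": 10,
    "QD3D": 12,
    "QD4": 16,
    "QD5": 21,
    "QD6": 6,
}

#: Sections whose indicators may be answered several times per visit
#: (clinical-observation and exit-interview sections).
MULTI_ANSWER_SECTIONS = ("QD3A", "QD3B", "QD3C", "QD3D", "QD6")

_ITYPE_PROBS = {
    # structure, process, outcome mix per section
    "QD1": (0.8, 0.2, 0.0),
    "QD2": (0.5, 0.5, 0.0),
    "QD3A": (0.0, 1.0, 0.0),
    "QD3B": (0.0, 1.0, 0.0),
    "QD3C": (0.0, 1.0, 0.0),
    "QD3D": (0.0, 1.0, 0.0),
    "QD4": (0.6, 0.4, 0.0),
    "QD5": (0.3, 0.7, 0.0),
    "QD6": (0.0, 0.2, 0.8),
}


@dataclass
class SyntheticConfig:
    """Study-design parameters for the generator.

    Effects are percentage points of overall score relative to the
    reference categories (year 2011, health center,
    private-not-for-profit); the defaults plant the magnitudes reported
    for the Tanzanian programme so that recovery tests exercise realistic
    signal sizes. Noise standard deviations are on the logit scale.
    """

    n_councils: int = 8
    facilities_per_council: int = 20
    level_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "dispensary": 0.70,
            "health_center": 0.22,
            "hospital": 0.08,
        }
    )
    owner_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "public": 0.60,
            "private_not_for_profit": 0.20,
            "private_for_profit": 0.15,
            "parastatal": 0.05,
        }
    )
    years: Sequence[int] = (2011, 2012, 2013, 2014)
    section_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SECTION_SIZES)
    )
    total_indicators: int | None = None  # scale sections proportionally

    baseline_score: float = 67.3  # mean overall score at reference levels, %
    year_effects: Mapping[int, float] = field(
        default_factory=lambda: {2012: 3.1, 2013: 6.5, 2014: 8.4}
    )
    level_effects: Mapping[str, float] = field(
        default_factory=lambda: {"hospital": 1.8, "dispensary": -7.7}
    )
    owner_effects: Mapping[str, float] = field(
        default_factory=lambda: {
            "private_for_profit": -5.5,
            "public": 1.8,
            "parastatal": -0.9,
        }
    )

    council_sd: float = 0.5
    qd_sd: float = 0.5
    difficulty_sd: float = 1.0
    weight_compliance_slope: float = 0.05

    graded_share_qd4: float = 0.5
    graded_levels: Sequence[float] = (0.0, 0.5, 1.0)
    inapplicable_dispensary_share: float = 0.2
    answers_multi_max: int = 3  # multi-answer sections draw 1..max uniformly
    dropout_rate: float = 0.0  # facility-years lost (unreachable facilities)
    seed: int = 0

    def resolved_section_sizes(self) -> dict[str, int]:
        sizes = dict(self.section_sizes)
        if self.total_indicators is None:
            return sizes
        total = sum(sizes.values())
        raw = {s: self.total_indicators * n / total for s, n in sizes.items()}
        out = {s: max(1, int(np.floor(v))) for s, v in raw.items()}
        # largest-remainder top-up to hit the target exactly
        rem = sorted(raw, key=lambda s: raw[s] - np.floor(raw[s]), reverse=True)
        i = 0
        while sum(out.values()) < self.total_indicators:
            out[rem[i % len(rem)]] += 1
            i += 1
        return out


@dataclass
class SyntheticTruth:
    """Everything needed to recompute each response probability exactly."""

    mu: float
    year_offsets: Mapping[int, float]  # logit scale
    level_offsets: Mapping[str, float]
    owner_offsets: Mapping[str, float]
    council_intercepts: Mapping[str, float]
    section_deviations: pd.DataFrame  # facility x section, logit
    difficulties: Mapping[str, float]  # indicator -> logit difficulty
    weight_compliance_slope: float
    config: SyntheticConfig

    def probability(
        self, facility_row: pd.Series, year: int, indicator_row: pd.Series
    ) -> float:
        """Success probability for one facility-year-indicator."""
        lp = (
            self.mu
            + self.year_offsets.get(year, 0.0)
            + self.level_offsets.get(facility_row["level"], 0.0)
            + self.owner_offsets.get(facility_row["owner"], 0.0)
            + self.council_intercepts[facility_row["council"]]
            + self.section_deviations.loc[
                facility_row["facility"], indicator_row["section"]
            ]
            + self.weight_compliance_slope * (indicator_row["weight"] - 3.0)
            - self.difficulties[indicator_row["id"]]
        )
        return float(expit(lp))

    def planted_effects_pp(self) -> dict[str, dict]:
        """The planted population-average effects, in percentage points.

        By construction of :func:`calibrate_offsets` these equal the
        configured gaps exactly (the calibration is solved so that the
        population-average expected-score contrast matches each one).
        """
        return {
            "year": dict(self.config.year_effects),
            "level": dict(self.config.level_effects),
            "owner": dict(self.config.owner_effects),
        }

    def expected_overall(
        self,
        catalog: pd.DataFrame,
        roster: pd.DataFrame,
        weighted: bool = True,
        force_year: int | None = None,
        force_level: str | None = None,
        force_owner: str | None = None,
    ) -> pd.DataFrame:
        """Exact expected overall score per facility-year (no sampling).

        ``force_level``/``force_owner``/``force_year`` counterfactually
        set that covariate for *every* facility (forcing a level also
        applies its indicator-applicability rules), which is how the
        realized population-average effects below are computed.

        Returns columns facility, year, expected_overall.
        """
        fac = roster.reset_index(drop=True)
        n_fac, n_ind = len(fac), len(catalog)
        sec_idx = catalog["section"].map(
            {s: i for i, s in enumerate(SECTIONS)}
        ).to_numpy()
        qd_idx = np.array(
            [QDS.index(SECTION_TO_QD[s]) for s in catalog["section"]]
        )
        w = catalog["weight"].to_numpy(float) if weighted else np.ones(n_ind)
        w_tilt = self.weight_compliance_slope * (
            catalog["weight"].to_numpy(float) - 3.0
        )
        diff = np.array([self.difficulties[i] for i in catalog["id"]])
        dev = self.section_deviations.loc[fac["facility"]].to_numpy()

        levels = fac["level"] if force_level is None else pd.Series(
            [force_level] * n_fac
        )
        owners = fac["owner"] if force_owner is None else pd.Series(
            [force_owner] * n_fac
        )
        fac_base = (
            np.array([self.level_offsets.get(l, 0.0) for l in levels])
            + np.array([self.owner_offsets.get(o, 0.0) for o in owners])
            + np.array([self.council_intercepts[c] for c in fac["council"]])
        )
        applicable = np.ones((n_fac, n_ind), dtype=bool)
        disp = (levels == "dispensary").to_numpy()
        needs_hc = ~catalog["applicable_levels"].str.contains("dispensary").to_numpy()
        applicable[np.ix_(disp, needs_hc)] = False

        years = (
            list(self.config.years) if force_year is None else [force_year]
        )
        rows = []
        for year in years:
            lp = (
                self.mu
                + self.year_offsets.get(year, 0.0)
                + fac_base[:, None]
                + dev[:, sec_idx]
                + w_tilt[None, :]
                - diff[None, :]
            )
            p = expit(lp)
            wm = np.where(applicable, w, 0.0)
            num = np.zeros((n_fac, 6))
            den = np.zeros((n_fac, 6))
            for q in range(6):
                cols = qd_idx == q
                num[:, q] = (wm[:, cols] * p[:, cols]).sum(axis=1)
                den[:, q] = wm[:, cols].sum(axis=1)
            with np.errstate(invalid="ignore"):
                qd_scores = np.where(den > 0, num / np.maximum(den, 1e-300), np.nan)
            overall = 100.0 * np.nanmean(qd_scores, axis=1)
            rows.append(
                pd.DataFrame(
                    {
                        "facility": fac["facility"],
                        "year": year,
                        "expected_overall": overall,
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def realized_effects_pp(
        self, catalog: pd.DataFrame, roster: pd.DataFrame, weighted: bool = True
    ) -> dict[str, dict]:
        """Population-average effects realized on this catalog and roster.

        For each covariate category, counterfactually switch every
        facility between the reference category and that category and
        average the exact expected-score change over facilities. These
        fluctuate around :meth:`planted_effects_pp` because councils,
        difficulties and section deviations are finite samples; they are
        the precise estimands a main-effects regression on this dataset
        targets.
        """

        def mean_of(**kw):
            return float(
                self.expected_overall(catalog, roster, weighted, **kw)[
                    "expected_overall"
                ].mean()
            )

        ref_year = min(self.config.years)
        out: dict[str, dict] = {"year": {}, "level": {}, "owner": {}}
        base = mean_of(force_year=ref_year)
        for t in self.config.year_effects:
            out["year"][t] = mean_of(force_year=t) - base
        base = mean_of(force_level="health_center")
        for l in self.config.level_effects:
            out["level"][l] = mean_of(force_level=l) - base
        base = mean_of(force_owner="private_not_for_profit")
        for o in self.config.owner_effects:
            out["owner"][o] = mean_of(force_owner=o) - base
        return out

    def to_json(self, path) -> None:
        payload = {
            "mu": self.mu,
            "year_offsets": {str(k): v for k, v in self.year_offsets.items()},
            "level_offsets": dict(self.level_offsets),
            "owner_offsets": dict(self.owner_offsets),
            "council_intercepts": dict(self.council_intercepts),
            "section_deviations": self.section_deviations.to_dict(),
            "difficulties": dict(self.difficulties),
            "weight_compliance_slope": self.weight_compliance_slope,
            "config": _config_dict(self.config),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["years"] = list(config.years)
    d["year_effects"] = {str(k): v for k, v in config.year_effects.items()}
    d["graded_levels"] = list(config.graded_levels)
    return d


# ---------------------------------------------------------------------------
# calibration: percentage-point gaps -> logit offsets


class _MarginalScore:
    """Expected fraction met as a function of a logit location offset.

    Marginalises the logistic response over the pooled normal noise
    (council + section deviation + difficulty) by Gauss-Hermite
    quadrature, and over the uniform 1..5 weight tilt exactly.
    """

    def __init__(self, config: SyntheticConfig, n_nodes: int = 80):
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
        s = np.sqrt(
            config.council_sd**2 + config.qd_sd**2 + config.difficulty_sd**2
        )
        w_tilt = config.weight_compliance_slope * (np.arange(1, 6) - 3.0)
        self._grid = (nodes[:, None] * s + w_tilt[None, :]).ravel()
        self._w = np.repeat(weights / (np.sqrt(2 * np.pi) * 5.0), 5)

    def __call__(self, mu) -> np.ndarray:
        mu = np.atleast_1d(np.asarray(mu, float))
        return expit(mu[:, None] + self._grid[None, :]) @ self._w


def calibrate_offsets(config: SyntheticConfig) -> tuple[float, dict, dict, dict]:
    """Solve the logit intercept and effect offsets from percentage gaps.

    The intercept ``mu`` is solved so the expected score at the reference
    categories (year 2011, health center, private-not-for-profit) equals
    ``baseline_score``. Because the response model is logistic, a fixed
    logit offset does not shift the expected score by the same amount at
    every covariate combination; each effect offset is therefore solved
    as a fixed point so that its *population-average* contrast — switch
    one covariate for every facility in the configured covariate mix,
    average the expected-score change — equals the requested
    percentage-point gap. That population-average contrast is exactly the
    estimand a main-effects linear regression targets, which makes
    "planted effect" well defined for parameter-recovery checks.

    Returns ``(mu, year_offsets, level_offsets, owner_offsets)``.
    """
    m = _MarginalScore(config)
    base = config.baseline_score / 100.0
    mu = float(brentq(lambda x: m(x)[0] - base, -15, 15))

    years = sorted(config.years)
    cells = []
    cell_w = []
    for t in years:
        for l in LEVELS:
            for o in OWNERS:
                cells.append((t, l, o))
                cell_w.append(
                    (1.0 / len(years))
                    * config.level_mix.get(l, 0.0)
                    * config.owner_mix.get(o, 0.0)
                )
    cell_w = np.array(cell_w)

    year_off = {t: 0.0 for t in config.year_effects}
    level_off = {l: 0.0 for l in config.level_effects}
    owner_off = {o: 0.0 for o in config.owner_effects}

    def cell_lp(exclude: str) -> np.ndarray:
        lp = np.full(len(cells), mu)
        for j, (t, l, o) in enumerate(cells):
            if exclude != "year":
                lp[j] += year_off.get(t, 0.0)
            if exclude != "level":
                lp[j] += level_off.get(l, 0.0)
            if exclude != "owner":
                lp[j] += owner_off.get(o, 0.0)
        return lp

    def solve_ape(lp_base: np.ndarray, gap_pp: float) -> float:
        ref_score = float(m(lp_base) @ cell_w)
        target = ref_score + gap_pp / 100.0
        if not 0.001 < target < 0.999:
            raise ValueError(
                f"gap {gap_pp} puts the expected score outside (0, 100)"
            )

        def f(delta):
            return float(m(lp_base + delta) @ cell_w) - target

        return float(brentq(f, -14, 14))

    for _ in range(25):
        prev = (dict(year_off), dict(level_off), dict(owner_off))
        lp = cell_lp("year")
        for t, g in config.year_effects.items():
            year_off[t] = solve_ape(lp, g)
        lp = cell_lp("level")
        for l, g in config.level_effects.items():
            level_off[l] = solve_ape(lp, g)
        lp = cell_lp("owner")
        for o, g in config.owner_effects.items():
            owner_off[o] = solve_ape(lp, g)
        delta = max(
            abs(d[k] - p[k])
            for d, p in zip((year_off, level_off, owner_off), prev)
            for k in d
        ) if (year_off or level_off or owner_off) else 0.0
        if delta < 1e-10:
            break

    return mu, year_off, level_off, owner_off


# ---------------------------------------------------------------------------
# catalog and roster


def generate_catalog(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate an indicator catalog with the configured section layout.

    Weights are uniform on 1..5; a configurable share of non-clinical
    indicators is marked inapplicable to dispensaries (mandate
    differences); a share of QD4 indicators uses the graded
    medicine-availability scale.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sizes = config.resolved_section_sizes()
    rows = []
    for section in SECTIONS:
        n = int(sizes.get(section, 0))
        probs = _ITYPE_PROBS[section]
        for k in range(n):
            weight = int(rng.integers(1, 6))
            itype = ("structure", "process", "outcome")[
                int(rng.choice(3, p=probs))
            ]
            graded = (
                section == "QD4" and rng.random() < config.graded_share_qd4
            )
            inapplicable = (
                rng.random() < config.inapplicable_dispensary_share
            )
            levels = (
                "health_center;hospital"
                if inapplicable
                else "dispensary;health_center;hospital"
            )
            rows.append(
                {
                    "id": f"{section}_{k + 1:03d}",
                    "section": section,
                    "weight": weight,
                    "itype": itype,
                    "applicable_levels": levels,
                    "response_kind": "graded" if graded else "binary",
                }
            )
    return validate_catalog(pd.DataFrame(rows))


def generate_roster(config: SyntheticConfig, seed: int | None = None) -> pd.DataFrame:
    """Generate the facility roster: council, level and owner per facility."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    lmix = np.array([config.level_mix.get(l, 0.0) for l in LEVELS])
    omix = np.array([config.owner_mix.get(o, 0.0) for o in OWNERS])
    if not (np.isclose(lmix.sum(), 1) and np.isclose(omix.sum(), 1)):
        raise ValueError("level_mix and owner_mix must each sum to 1")
    rows = []
    for c in range(config.n_councils):
        council = f"C{c + 1:02d}"
        for k in range(config.facilities_per_council):
            rows.append(
                {
                    "facility": f"{council}F{k + 1:03d}",
                    "level": LEVELS[int(rng.choice(3, p=lmix))],
                    "owner": OWNERS[int(rng.choice(4, p=omix))],
                    "council": council,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# responses


def simulate_responses(
    catalog: pd.DataFrame,
    roster: pd.DataFrame,
    config: SyntheticConfig,
    seed: int | None = None,
    difficulties: Mapping[str, float] | None = None,
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Draw a full long-format response table plus its generating truth.

    Binary indicators emit 1..k yes/no answers (independent Bernoulli at
    the facility-year-indicator probability); graded indicators emit
    values on the configured graded scale with that mean; indicators
    inapplicable at the facility's level emit a single ``na`` row.

    Passing ``difficulties`` (indicator id -> logit difficulty, e.g. from
    a previous run's truth) fixes the measurement instrument so that
    repeated simulations emulate fresh survey rounds with the same
    checklist rather than fresh checklists.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    mu, year_off, level_off, owner_off = calibrate_offsets(config)

    councils = sorted(roster["council"].unique())
    u = dict(
        zip(councils, rng.normal(0.0, config.council_sd, len(councils)))
    )
    fac = roster.reset_index(drop=True)
    n_fac, n_ind = len(fac), len(catalog)
    years = list(config.years)

    dev = pd.DataFrame(
        rng.normal(0.0, config.qd_sd, (n_fac, len(SECTIONS))),
        index=fac["facility"],
        columns=list(SECTIONS),
    )
    # Difficulties are decorrelated from weights section by section on the
    # success-probability scale (the sampled weight-difficulty covariance
    # at the baseline is projected out within each section), so the
    # weight-compliance tilt realized in any one catalog is the
    # configured slope rather than slope plus catalog sampling noise —
    # a handful of indicators per section otherwise carries a random
    # weight-success covariance of the same order as a realistic tilt.
    if difficulties is not None:
        missing = set(catalog["id"]) - set(difficulties)
        if missing:
            raise ValueError(f"difficulties missing for {sorted(missing)[:5]}")
        difficulty = {i: float(difficulties[i]) for i in catalog["id"]}
    else:
        d_raw = rng.normal(0.0, config.difficulty_sd, n_ind)
        # success rate marginal over facility-level noise, as in calibration
        noise_sd = float(np.sqrt(config.council_sd**2 + config.qd_sd**2))
        nodes, gh_w = np.polynomial.hermite_e.hermegauss(40)
        gh_w = gh_w / np.sqrt(2 * np.pi)
        x_grid = np.linspace(-14.0, 14.0, 2001)
        m_grid = expit(x_grid[:, None] + noise_sd * nodes[None, :]) @ gh_w
        pop_shift = (
            np.mean([year_off.get(t, 0.0) for t in config.years])
            + sum(config.level_mix.get(l, 0.0) * level_off.get(l, 0.0) for l in LEVELS)
            + sum(config.owner_mix.get(o, 0.0) * owner_off.get(o, 0.0) for o in OWNERS)
        )
        q = np.interp(mu + pop_shift - d_raw, x_grid, m_grid)
        w_arr = catalog["weight"].to_numpy(float)
        for s in SECTIONS:
            in_s = (catalog["section"] == s).to_numpy()
            if in_s.sum() < 2:
                continue
            w_c = w_arr[in_s] - w_arr[in_s].mean()
            if (w_c @ w_c) > 0:
                q_s = q[in_s]
                q[in_s] = np.clip(
                    q_s - (q_s @ w_c) / (w_c @ w_c) * w_c,
                    m_grid[0] + 1e-9,
                    m_grid[-1] - 1e-9,
                )
        d_raw = mu + pop_shift - np.interp(q, m_grid, x_grid)
        difficulty = dict(zip(catalog["id"], d_raw))

    sec_idx = catalog["section"].map({s: i for i, s in enumerate(SECTIONS)}).to_numpy()
    w_tilt = config.weight_compliance_slope * (
        catalog["weight"].to_numpy(float) - 3.0
    )
    diff_arr = np.array([difficulty[i] for i in catalog["id"]])
    graded_mask = (catalog["response_kind"] == "graded").to_numpy()
    applicable = np.ones((n_fac, n_ind), dtype=bool)
    disp = (fac["level"] == "dispensary").to_numpy()
    needs_hc = ~catalog["applicable_levels"].str.contains("dispensary").to_numpy()
    applicable[np.ix_(disp, needs_hc)] = False

    fac_base = (
        np.array([level_off.get(l, 0.0) for l in fac["level"]])
        + np.array([owner_off.get(o, 0.0) for o in fac["owner"]])
        + np.array([u[c] for c in fac["council"]])
    )

    multi = catalog["section"].isin(MULTI_ANSWER_SECTIONS).to_numpy()
    m_levels = len(config.graded_levels) - 1
    levels_arr = np.asarray(config.graded_levels, float)

    frames = []
    for year in years:
        lp = (
            mu
            + year_off.get(year, 0.0)
            + fac_base[:, None]
            + dev.to_numpy()[:, sec_idx]
            + w_tilt[None, :]
            - diff_arr[None, :]
        )
        p = expit(lp)

        counts = np.ones((n_fac, n_ind), dtype=np.int64)
        counts[:, multi] = rng.integers(
            1, config.answers_multi_max + 1, (n_fac, multi.sum())
        )
        counts[~applicable] = 1  # single na row

        keep = np.ones(n_fac, dtype=bool)
        if config.dropout_rate > 0:
            keep = rng.random(n_fac) >= config.dropout_rate

        f_idx, i_idx = np.nonzero(keep[:, None] & np.ones(n_ind, bool))
        c = counts[f_idx, i_idx]
        rf = np.repeat(f_idx, c)
        ri = np.repeat(i_idx, c)
        rp = p[rf, ri]
        app = applicable[rf, ri]
        gr = graded_mask[ri]

        answers = np.empty(len(rf), dtype=object)
        nb = ~gr & app
        answers[nb] = np.where(rng.random(nb.sum()) < rp[nb], "yes", "no")
        ng = gr & app
        if ng.any():
            draws = rng.binomial(m_levels, rp[ng])
            answers[ng] = [format(levels_arr[d], "g") for d in draws]
        answers[~app] = "na"

        frames.append(
            pd.DataFrame(
                {
                    "facility": fac["facility"].to_numpy()[rf],
                    "year": year,
                    "indicator": catalog["id"].to_numpy()[ri],
                    "answer": answers,
                }
            )
        )

    responses = pd.concat(frames, ignore_index=True)
    truth = SyntheticTruth(
        mu=mu,
        year_offsets=year_off,
        level_offsets=level_off,
        owner_offsets=owner_off,
        council_intercepts=u,
        section_deviations=dev,
        difficulties=difficulty,
        weight_compliance_slope=config.weight_compliance_slope,
        config=config,
    )
    return responses, truth


# ---------------------------------------------------------------------------
# planted factor structure (for concordance recovery tests)


def planted_loadings(
    block_sizes: Mapping[str, int],
    within: float = 0.8,
    noise: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """A block loading matrix: each block's indicators load ``within`` on
    its own factor and ``noise`` (random sign) elsewhere."""
    rng = np.random.default_rng(seed)
    blocks = list(block_sizes)
    p = sum(block_sizes.values())
    lam = rng.choice([-noise, noise], size=(p, len(blocks)))
    ids, row = [], 0
    for j, b in enumerate(blocks):
        for k in range(block_sizes[b]):
            lam[row, j] = within
            ids.append(f"{b}_{k + 1:03d}")
            row += 1
    return pd.DataFrame(lam, index=ids, columns=[f"F{j + 1}" for j in range(len(blocks))])


def sample_from_loadings(
    loadings: pd.DataFrame, n: int, seed: int = 0
) -> pd.DataFrame:
    """Sample ``n`` observations from the standard factor model
    ``x = Lambda f + e`` with unit-variance observed variables."""
    rng = np.random.default_rng(seed)
    lam = loadings.to_numpy()
    p, k = lam.shape
    resid_var = np.clip(1.0 - (lam**2).sum(axis=1), 0.01, None)
    f = rng.normal(size=(n, k))
    e = rng.normal(size=(n, p)) * np.sqrt(resid_var)
    x = f @ lam.T + e
    return pd.DataFrame(x, columns=loadings.index)
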