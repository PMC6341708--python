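"""One-config orchestration: simulate -> score -> rank -> robustness ->
concordance -> effects, with a content-hash manifest for reproducibility.

Every stochastic stage draws its seed deterministically from a single
master seed, so a whole run is reproducible from one number. Each stage
writes plain CSV/JSON artifacts; the manifest records every file with a
SHA-256 hash, which makes "two runs with the same config are identical"
a checkable property rather than a promise.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import concordance as conc
from . import effects as eff
from . import io as eio
from . import robustness as rob
from .scoring import rank_facilities, score_all
from .synthetic import (
    SyntheticConfig,
    generate_catalog,
    generate_roster,
    simulate_responses,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "score", "rank", "robustness", "concordance", "effects")


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``synthetic`` holds generator settings (dict of
    :class:`~etiqh.synthetic.SyntheticConfig` overrides) or the three
    input paths point at existing CSVs.
    """

    seed: int = 0
    outdir: str = "run"
    synthetic: dict = field(default_factory=dict)
    catalog_path: str | None = None
    roster_path: str | None = None
    responses_path: str | None = None
    stages: dict = field(
        default_factory=lambda: {s: True for s in STAGES}
    )
    weighted: bool = True
    analysis_year: int | None = None  # default: last year in the data
    subset_sizes: list = field(default_factory=list)  # default: auto grid
    n_factors: int = 9
    weak_loading: float = 0.4
    cross_loading: float = 0.2
    pruning_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), STAGES.index(stage)])
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def validate_inputs(
    catalog: pd.DataFrame, roster: pd.DataFrame, responses: pd.DataFrame
) -> list[dict]:
    """Cross-check the three input tables; returns a list of issues.

    Flags indicators absent from the catalog, facilities without a
    roster entry, answers outside the yes/no/na-or-[0,1] domain, and
    non-NA answers to indicators inapplicable at the facility's level.
    """
    issues: list[dict] = []
    known_ind = set(catalog["id"])
    known_fac = set(roster["facility"])

    for row, ind in responses["indicator"].items():
        if ind not in known_ind:
            issues.append(
                {"row": int(row), "kind": "unknown_indicator", "value": ind}
            )
    for row, f in responses["facility"].items():
        if f not in known_fac:
            issues.append(
                {"row": int(row), "kind": "unknown_facility", "value": f}
            )

    values = pd.Series(np.nan, index=responses.index)
    for row, a in responses["answer"].items():
        try:
            values[row] = eio.parse_answer(a)
        except ValueError:
            issues.append(
                {"row": int(row), "kind": "bad_answer", "value": str(a)}
            )

    applicable = catalog.set_index("id")["applicable_levels"].str.split(";").to_dict()
    level_of = roster.set_index("facility")["level"].to_dict()
    for row in responses.index:
        ind = responses.at[row, "indicator"]
        f = responses.at[row, "facility"]
        if ind not in applicable or f not in level_of:
            continue
        if level_of[f] not in applicable[ind] and not np.isnan(values[row]):
            issues.append(
                {
                    "row": int(row),
                    "kind": "inapplicable_level_answered",
                    "value": f"{f}({level_of[f]})/{ind}",
                }
            )
    return issues


def run_pipeline(config: RunConfig) -> dict:
    """Execute all enabled stages in dependency order; returns the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def emit(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["files"][name] = _sha256(path)

    # --- inputs
    if config.stages.get("simulate", True):
        seed = stage_seed(config.seed, "simulate")
        scfg = SyntheticConfig(**config.synthetic)
        catalog = generate_catalog(scfg, seed)
        roster = generate_roster(scfg, seed + 1)
        responses, truth = simulate_responses(catalog, roster, scfg, seed + 2)
        emit("catalog.csv", lambda p: eio.write_catalog(catalog, p))
        emit("roster.csv", lambda p: eio.write_roster(roster, p))
        emit("responses.csv", lambda p: eio.write_responses(responses, p))
        emit("truth.json", truth.to_json)
        manifest["stages"]["simulate"] = {
            "seed": seed,
            "n_indicators": len(catalog),
            "n_facilities": len(roster),
            "n_answers": len(responses),
        }
    else:
        if not (config.catalog_path and config.roster_path and config.responses_path):
            raise ValueError(
                "simulate disabled: catalog_path, roster_path and "
                "responses_path are required"
            )
        catalog = eio.read_catalog(config.catalog_path)
        roster = eio.read_roster(config.roster_path)
        responses = eio.read_responses(config.responses_path)
        manifest["stages"]["simulate"] = {"skipped": True}
    responses = eio.ensure_values(responses)
    year = config.analysis_year or int(responses["year"].max())
    year_responses = responses[responses["year"] == year]

    # --- scoring
    if config.stages.get("score", True):
        cards = score_all(catalog, responses, weighted=config.weighted)
        emit("scorecards.csv", lambda p: eio.write_scorecards(cards, p))
        manifest["stages"]["score"] = {"rows": len(cards), "weighted": config.weighted}
    else:
        cards = None
        manifest["stages"]["score"] = {"skipped": True}

    # --- ranking (analysis year)
    if config.stages.get("rank", True):
        if cards is None:
            raise ValueError("rank stage needs the score stage")
        ranking = rank_facilities(cards[cards["year"] == year])
        emit(
            f"ranking_{year}.csv",
            lambda p: ranking.as_frame().to_csv(p, index=False),
        )
        manifest["stages"]["rank"] = {"year": year, "n": len(ranking.entries)}
    else:
        manifest["stages"]["rank"] = {"skipped": True}

    # --- robustness
    if config.stages.get("robustness", True):
        seed = stage_seed(config.seed, "robustness")
        sizes = list(config.subset_sizes) or _default_sizes(len(catalog))
        subsets = rob.nested_subsets(catalog, sizes, seed)
        curve = rob.subset_difference_curve(year_responses, subsets, catalog)
        curve_df = pd.DataFrame([dataclasses.asdict(p) for p in curve])
        emit("subset_curve.csv", lambda p: curve_df.to_csv(p, index=False))
        trends = {
            "score": rob.fit_trend(curve, "quadratic", y="score"),
            "rank": rob.fit_trend(curve, "linear", y="rank"),
        }
        emit(
            "subset_trends.json",
            lambda p: Path(p).write_text(json.dumps(trends, indent=1)),
        )
        ablation = rob.weight_ablation(catalog, year_responses)
        emit(
            "weight_ablation.json",
            lambda p: Path(p).write_text(
                json.dumps(dataclasses.asdict(ablation), indent=1)
            ),
        )
        manifest["stages"]["robustness"] = {"seed": seed, "sizes": sizes, "year": year}
    else:
        manifest["stages"]["robustness"] = {"skipped": True}

    # --- concordance
    if config.stages.get("concordance", True):
        matrix = conc.indicator_score_matrix(responses, catalog, year)
        loadings = conc.fit_factors(matrix, k=config.n_factors)
        alloc = conc.allocate_indicators(
            loadings, config.weak_loading, config.cross_loading
        )
        mapping = conc.match_factors_to_sections(alloc, catalog)
        table = conc.concordance_table(alloc, mapping, catalog)
        emit("loadings.csv", lambda p: loadings.to_csv(p))
        emit("allocations.csv", lambda p: alloc.to_csv(p, index=False))
        emit(
            "factor_mapping.json",
            lambda p: Path(p).write_text(json.dumps(mapping, indent=1)),
        )
        emit("concordance_table.csv", lambda p: table.to_csv(p, index=False))
        manifest["stages"]["concordance"] = {
            "year": year,
            "k": config.n_factors,
            "matched": int(table.loc[table["section"] == "Total", "n_matched"].iloc[0]),
        }
    else:
        manifest["stages"]["concordance"] = {"skipped": True}

    # --- effects
    if config.stages.get("effects", True):
        if cards is None:
            raise ValueError("effects stage needs the score stage")
        outcomes = ["overall"] + [f"QD{i}" for i in range(1, 7)]
        frame = eff.build_model_frame(cards, roster, outcome="overall")
        columns = {}
        traces = {}
        for outcome in outcomes:
            res = eff.prune_interactions(
                frame.dropna(subset=[outcome]),
                outcome,
                alpha=config.pruning_alpha,
            )
            sf = res.summary_frame()
            columns[outcome] = sf["coef"].round(4).astype(str) + sf["stars"]
            traces[outcome] = res.pruning_trace
        table = pd.DataFrame(columns).fillna("")
        emit("effects_table.csv", lambda p: table.to_csv(p))
        emit(
            "pruning_trace.json",
            lambda p: Path(p).write_text(json.dumps(traces, indent=1)),
        )
        robust = eff.robust_fixed_check(frame)
        emit("robust_check.csv", lambda p: robust.to_csv(p))
        manifest["stages"]["effects"] = {"outcomes": outcomes}
    else:
        manifest["stages"]["effects"] = {"skipped": True}

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d files in %s", len(manifest["files"]), out)
    return manifest


def _default_sizes(n: int) -> list[int]:
    """An even grid of subset sizes from ~n/8 up to the full catalog."""
    lo = max(9, n // 8)
    return sorted(set(np.linspace(lo, n, 8, dtype=int).tolist()))
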