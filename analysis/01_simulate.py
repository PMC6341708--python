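"""Generate the synthetic supportive-supervision dataset used downstream.

Emulates an eight-council roster of 160 primary-care facilities
(dispensaries, health centers, hospitals; four owner categories)
assessed yearly 2011-2014 with a 159-indicator, nine-section checklist.
Effects planted on the percentage scale: +3.1/+6.5/+8.4 for 2012-2014,
-7.7 dispensary, +1.8 hospital, -5.5 private-for-profit, +1.8 public,
-0.9 parastatal, around a reference mean of 67.3.

Writes catalog/roster/responses CSVs and the generating truth to
results/data/.
"""

from pathlib import Path

from etiqh import io as eio
from etiqh.synthetic import (
    SyntheticConfig,
    generate_catalog,
    generate_roster,
    simulate_responses,
)

SEED = 20140101
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SyntheticConfig()
    catalog = generate_catalog(cfg, SEED)
    roster = generate_roster(cfg, SEED + 1)
    responses, truth = simulate_responses(catalog, roster, cfg, SEED + 2)

    eio.write_catalog(catalog, OUT / "catalog.csv")
    eio.write_roster(roster, OUT / "roster.csv")
    eio.write_responses(responses, OUT / "responses.csv")
    truth.to_json(OUT / "truth.json")

    print(f"catalog:   {len(catalog)} indicators in "
          f"{catalog['section'].nunique()} sections")
    print(f"roster:    {len(roster)} facilities in "
          f"{roster['council'].nunique()} councils")
    print(f"responses: {len(responses)} answers over years "
          f"{sorted(responses['year'].unique())}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
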