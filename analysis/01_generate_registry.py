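"""Generate the synthetic primary-care registry and activity survey.

Draws an entry cohort with the configured demographic structure, simulates
follow-up (four chronic conditions, death, annual depression and costs)
from the configured Weibull/logistic/two-part truth, and draws the
activity survey.  Writes CSVs under data/ and prints headline checks
against the configured truth.

Run:  python analysis/01_generate_registry.py [--n 200000] [--fast]
"""

import argparse
import json
from pathlib import Path

import numpy as np

from pacea.config import (
    build_activity_distribution,
    build_demographics,
    build_truth_models,
    load_default_config,
)
from pacea.registry import (
    age_standardize,
    generate_activity_survey,
    generate_cohort,
    simulate_event_histories,
)
from pacea.states import DISEASES

parser = argparse.ArgumentParser()
parser.add_argument("--n", type=int, default=200_000, help="registry cohort size")
parser.add_argument("--n-survey", type=int, default=30_000)
parser.add_argument("--horizon", type=float, default=5.0)
parser.add_argument("--seed", type=int, default=20140130)
parser.add_argument("--fast", action="store_true", help="10k-person fast profile")
parser.add_argument("--outdir", type=Path, default=Path("data"))
args = parser.parse_args()
n = 10_000 if args.fast else args.n

cfg = load_default_config()
demo = build_demographics(cfg)
truth = build_truth_models(cfg)

print(f"drawing cohort of {n} and simulating {args.horizon} years of follow-up ...")
cohort = generate_cohort(n, args.seed, demo)
registry = simulate_event_histories(cohort, truth, args.horizon, args.seed + 1)

args.outdir.mkdir(parents=True, exist_ok=True)
registry.to_csv(args.outdir / "registry_events.csv", args.outdir / "registry_person_years.csv")

ev = registry.events
print(f"  persons: {len(ev)}, person-years: {len(registry.person_years)}")
print(f"  deaths: {ev.event_death.sum()} "
      f"({1000 * ev.event_death.mean():.1f} per 1000 over follow-up)")
for d in DISEASES:
    print(f"  incident {d}: {ev[f'event_{d}'].sum()}")
dep_rate = registry.person_years.depressed.mean()
zero_cost = (registry.person_years.cost == 0).mean()
print(f"  annual depression prevalence: {100 * dep_rate:.1f}%  "
      f"zero-cost person-years: {100 * zero_cost:.1f}%")

dist = build_activity_distribution(cfg)
survey = generate_activity_survey(args.n_survey, args.seed + 2, dist)
survey.to_csv(args.outdir / "activity_survey.csv", index=False)
dist.to_csv(args.outdir / "activity_truth.csv")

# age-standardised inactivity, most vs least deprived men (equal band weights)
for q in (1, 5):
    sub = survey[(survey.female == 0) & (survey.quintile == q)]
    prev = sub.groupby("age_band").apply(
        lambda g: (g.activity == "inactive").mean(), include_groups=False
    )
    std = age_standardize(prev.to_numpy(), np.ones(len(prev)))
    print(f"  survey inactivity, men quintile {q}: {100 * std:.1f}% (age-standardised)")

with open(args.outdir / "generate_metadata.json", "w") as fh:
    json.dump({"seed": args.seed, "n": n, "n_survey": args.n_survey,
               "horizon": args.horizon}, fh, indent=1)
print(f"wrote registry + survey to {args.outdir}/")
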