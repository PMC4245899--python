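"""Fit the three input-model families to the synthetic registry.

Reads the registry written by 01_generate_registry.py, fits the Weibull
incidence/mortality models, the per-class depression logistics and the
two-part cost models, writes them to models/input_models.json and prints
the fitted deprivation gradients next to the configured truth.

Run:  python analysis/02_fit_input_models.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from pacea.cli import estimate_models
from pacea.config import build_truth_models, load_default_config

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=Path, default=Path("data"))
parser.add_argument("--outdir", type=Path, default=Path("models"))
args = parser.parse_args()

events = pd.read_csv(args.datadir / "registry_events.csv")
py = pd.read_csv(args.datadir / "registry_person_years.csv")
print(f"fitting input models to {len(events)} persons / {len(py)} person-years ...")

models = estimate_models(events, py)
args.outdir.mkdir(parents=True, exist_ok=True)
models.to_json(args.outdir / "input_models.json")

truth = build_truth_models(load_default_config())
print("\nmost-deprived (quintile 5) gradients, fitted vs truth:")
print(f"{'model':<22}{'fitted':>10}{'truth':>10}{'z':>9}")


def zval(diff, se):
    # fallback-model classes carry no gradient SE; report them as n/a
    return f"{diff / se:9.2f}" if se > 0 else "      n/a"


for d, m in models.incidence.items():
    t = truth.incidence[d]
    print(f"incidence {d:<12}{np.exp(m.beta[6]):>10.3f}{np.exp(t.beta[6]):>10.3f}"
          f"{zval(m.beta[6] - t.beta[6], m.se()[7])}")
for c, m in models.mortality.items():
    t = truth.mortality[c]
    print(f"mortality {c:<12}{np.exp(m.beta[6]):>10.3f}{np.exp(t.beta[6]):>10.3f}"
          f"{zval(m.beta[6] - t.beta[6], m.se()[7])}")
for c, m in models.depression.items():
    t = truth.depression[c]
    print(f"depression {c:<11}{np.exp(m.beta[6]):>10.3f}{np.exp(t.beta[6]):>10.3f}"
          f"{zval(m.beta[6] - t.beta[6], m.se()[6])}")
print(f"\nwrote {args.outdir}/input_models.json")
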