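"""Low-, mid- and high-level fusion of the three platforms for the final harvest.

Reproduces the data-fusion comparison at the last validation step: per class
pair, the three platform blocks are fused at the raw-variable level
(concatenation + autoscaling), the feature level (per-block PCA scores) and
the decision level (majority vote of the per-platform PLS-DA models).
"""

import argparse
from pathlib import Path

import pandas as pd

from honeyspec.synthetic import default_config, generate
from honeyspec.validation import FusionLevel, build_split_plan, run_yearly_validation

ROOT = Path(__file__).resolve().parents[1]
PAIRS = (("BA", "Cat"), ("BA", "Mis"), ("Cat", "Mis"))


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=2014)
    args = parser.parse_args()

    blocks, table = generate(default_config(args.seed)).averaged()
    plan = build_split_plan(table.years())[-1:]

    rows = {}
    widths = {}
    for level in ("low", "mid", "high"):
        for pair in PAIRS:
            step = run_yearly_validation(blocks, table, FusionLevel(level, pair),
                                         plan=plan).steps[-1]
            rows.setdefault(f"{level.upper()}-DF", {})[f"{pair[0]} vs {pair[1]}"] = step.ccr
            if "fused_width" in step.params:
                widths[level] = step.params["fused_width"]
    out = pd.DataFrame(rows).T

    tables = ROOT / "results" / "tables"
    tables.mkdir(parents=True, exist_ok=True)
    out.to_csv(tables / "fusion_ccr.csv")
    print(f"Data-fusion CCRs (%) for the {plan[0].test_year} prediction:")
    print(out.to_string())
    print(f"\nfused widths: low-level {widths.get('low')} channels, "
          f"mid-level {widths.get('mid')} scores")
    print("\nOn this synthetic study the three fusion levels score within a few "
          "points of one another; see docs/methods.md for why the raw-variable "
          "concatenation is not penalised here the way it is on real spectra.")


if __name__ == "__main__":
    main()
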