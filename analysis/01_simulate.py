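"""Generate the working survey-style dataset and its planted ground truth.

Writes the four canonical CSV tables plus ``truth.json`` under
``results/data/``.  The default scenario mirrors a national health-round
at reduced scale and additionally plants a realistic class gradient in
private charges (richer patients face higher prices), so the demo
analysis exhibits both utilization- and price-driven inequality.
"""

import argparse
import json
from pathlib import Path

import healthbia as hb

ROOT = Path(__file__).resolve().parents[1]

#: demo scenario: pro-private choice among the rich plus a private-price
#: gradient across classes (both switchable study conditions)
SCENARIO = dict(
    private_gradient=0.4,
    class_cost_multipliers=(0.8, 0.95, 1.1, 1.3),
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--households", type=int, default=8000,
                    help="households per state x sector cell")
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "data",
                    help="directory for the (bulky) generated CSV tables")
    args = ap.parse_args()

    cfg = hb.SimConfig(
        seed=args.seed, households_per_state_sector=args.households,
        **SCENARIO,
    )
    dataset, truth = hb.generate(cfg)
    report = hb.validate(dataset)
    assert report.ok, report.errors[:5]

    hb.write_dataset(dataset, args.out)
    (args.out / "truth.json").write_text(truth.to_json())
    (args.out / "sim_config.json").write_text(cfg.model_dump_json(indent=2))

    n_elderly = (dataset.individuals["age"] >= 60).sum()
    print(f"households        : {len(dataset.households):,}")
    print(f"individuals       : {len(dataset.individuals):,} "
          f"({100 * n_elderly / len(dataset.individuals):.1f}% elderly)")
    print(f"inpatient episodes: {len(dataset.inpatient):,}")
    print(f"outpatient spells : {len(dataset.outpatient):,}")
    print(f"validation        : {len(report.errors)} errors, "
          f"{len(report.warnings)} warnings")
    print(f"written to        : {args.out}")


if __name__ == "__main__":
    main()
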