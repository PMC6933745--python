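"""Form MPCE classes and select the elderly-NCD analysis population.

Reads the dataset written by 01_simulate.py, computes per-(state, sector)
weighted MPCE quartiles, assigns P/LM/UM/R labels, applies the
elderly (60+) and NCD filters (all-visits rule for outpatient spells) and
writes the cutpoint table and per-person class assignments.
"""

import argparse
from pathlib import Path

import healthbia as hb

ROOT = Path(__file__).resolve().parents[1]


def load_inputs(data_dir: Path) -> hb.SurveyDataset:
    return hb.load_survey({
        "households": data_dir / "households.csv",
        "individuals": data_dir / "individuals.csv",
        "inpatient": data_dir / "inpatient.csv",
        "outpatient": data_dir / "outpatient.csv",
    })


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "scratch" / "data")
    ap.add_argument("--scratch", type=Path, default=ROOT / "scratch")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    dataset = load_inputs(args.data)
    assert hb.validate(dataset).ok
    classification = hb.build_mpce_classification(dataset)
    amap = hb.default_ailment_map()
    ip, op = hb.select_elderly_ncd(dataset, classification, amap)

    hb.write_table(classification.cutpoints, args.out / "mpce_cutpoints.csv")
    # per-person assignments are bulky: keep them out of the results tree
    hb.write_table(
        classification.individuals, args.scratch / "class_assignments.csv"
    )

    print("MPCE quartile cutpoints per (state, sector):")
    print(classification.cutpoints.to_string(index=False))
    print(f"\nelderly NCD inpatient episodes : {len(ip):,}")
    print(f"elderly NCD outpatient spells  : {len(op):,} "
          f"(spells with any non-NCD visit excluded)")


if __name__ == "__main__":
    main()
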