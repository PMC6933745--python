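"""Utilization-share and mean-OOPE tables for elderly NCD care.

Produces the survey-weighted utilization panels (ailment-group mix, class
mix of NCD care, class mix of public NCD care) and the class-wise mean
out-of-pocket expenditure (medicine / medical / total) by sector and
facility type.
"""

import argparse
from pathlib import Path

import healthbia as hb

ROOT = Path(__file__).resolve().parents[1]


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=ROOT / "scratch" / "data")
    ap.add_argument("--out", type=Path, default=ROOT / "results")
    args = ap.parse_args()

    dataset = hb.load_survey({
        "households": args.data / "households.csv",
        "individuals": args.data / "individuals.csv",
        "inpatient": args.data / "inpatient.csv",
        "outpatient": args.data / "outpatient.csv",
    })
    classification = hb.build_mpce_classification(dataset)
    amap = hb.default_ailment_map()

    # utilization panels need *all* elderly episodes, not only NCD
    elderly = classification.individuals.query("age >= 60")
    keys = ["person_id", "household_id", "state", "sector", "mpce",
            "mpce_class"]
    ip_all = dataset.inpatient.merge(elderly[keys], on="person_id")
    op_all = dataset.outpatient.merge(elderly[keys], on="person_id")

    util = hb.utilization_share_table(ip_all, op_all, amap)
    hb.write_table(util, args.out / "table1_utilization.csv")

    ip, op = hb.select_elderly_ncd(dataset, classification, amap)
    oope = hb.mean_oope_table(ip, op)
    hb.write_table(oope, args.out / "table2_oope.csv")

    ncd = util.query(
        "panel == 'ailment_group' and group == 'NCD' and sector == 'combine'"
    ).set_index("service")["share_pct"]
    print("share of NCDs in elderly care utilization:")
    print(f"  inpatient {ncd['IP']:.1f}%   outpatient {ncd['OP']:.1f}%")
    wide = oope.query("component == 'total' and mpce_class == 'All' and "
                      "sector != 'combine'")
    print("\nmean total OOPE (INR) by sector and facility:")
    for _, r in wide.iterrows():
        print(f"  {r.service} {r.sector:5s} {r.facility:7s} "
              f"{r.mean_oope:>9,.0f}")
    print(f"\ntables written to {args.out}")


if __name__ == "__main__":
    main()
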