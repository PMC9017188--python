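"""Boost-channel loading: detection gain versus ion-sampling degradation.

Two paired experiments on one seed: (i) with and without the motif-centric
boost channel, counting identified low-stoichiometry pY sites (the
boosting mechanism); (ii) a boost-amount titration (5/25/125 units) at
limiting sample load (5 units), counting pY sites that pass the full
acceptance criteria — identification keeps rising with boost, but
quantifiability peaks and then collapses as the boost ratio and ion
sampling criteria remove over-boosted sites.
"""

import argparse
import json
from pathlib import Path

from motifboost.studies import boost_titration_study, boosting_detection_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/05_titration")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    paired = boosting_detection_study(seed=args.seed)
    detected = {str(b): len(s) for b, s in paired["detected_py"].items()}

    titration = boost_titration_study(seed=args.seed)
    titration.to_csv(outdir / "titration_counts.tsv", sep="\t", index=False)
    summary = {"detected_py_by_boost_amount": detected}
    (outdir / "boosting_summary.json").write_text(json.dumps(summary, indent=2) + "\n")

    print("identified pY sites, boost off vs on:", detected)
    print(titration.to_string(index=False))
    peak = titration.loc[titration["quantifiable_py"].idxmax(), "boost_amount"]
    print(
        f"Quantifiable pY counts peak at boost {peak:g} and fall at 125: "
        "with a fixed ion budget, over-boosting starves the sample channels "
        "and pushes sites past the boost-ratio limit."
    )


if __name__ == "__main__":
    main()
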