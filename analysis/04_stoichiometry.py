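"""Phosphorylation stoichiometry from endogenous/boost channel ratios.

Validates the estimator against ground truth (exact in the noiseless
oracle; small error under 20% CV noise), then reproduces the multi-kinase
stoichiometry comparison: cumulative distributions of estimated occupancy
for sites converted by different boost kinases, with the acidophilic >
Pro-directed > tyrosine ordering.
"""

import argparse
import json
from pathlib import Path

from motifboost.studies import multi_kinase_study, stoichiometry_recovery_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/04_stoichiometry")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    oracle = stoichiometry_recovery_study(seed=args.seed, noisy=False)
    noisy = stoichiometry_recovery_study(seed=args.seed, noisy=True)
    oracle["curve"].to_csv(outdir / "cumulative_curve_oracle.tsv", sep="\t", index=False)

    multi = multi_kinase_study(seed=args.seed)
    multi["stoichiometry"].to_csv(outdir / "stoichiometry_by_kinase.tsv", sep="\t", index=False)
    multi["overlap"].to_csv(outdir / "site_overlap.tsv", sep="\t", index=False)

    summary = {
        "oracle_max_abs_error": oracle["max_abs_error"],
        "noisy_median_abs_error": round(noisy["median_abs_error"], 4),
        "class_median_stoichiometry": {
            k: round(v, 4) for k, v in multi["class_median_stoichiometry"].items()
        },
    }
    (outdir / "stoichiometry_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    print(json.dumps(summary, indent=2))
    med = multi["class_median_stoichiometry"]
    print(
        "Median estimated occupancy by kinase class: "
        + ", ".join(f"{k}={v:.3f}" for k, v in sorted(med.items(), key=lambda kv: -kv[1]))
        + " — acidophilic substrates sit highest, tyrosine sites lowest."
    )


if __name__ == "__main__":
    main()
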