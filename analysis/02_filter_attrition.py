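"""Acceptance-criteria attrition and the signal/noise intensity notch.

Applies the quantification filters (boost ratio < 100, log2 total sample
intensity > 40, valid-channel rule, class-1 localization) to a standard
simulated run and reports per-criterion attrition and enrichment
specificity.  The notch between noise and signal appears in the log2
total sample intensity distribution of a heavily boosted, ion-starved
condition (high boost loading at limiting sample load): boosted
low-stoichiometry sites are identified through the boost channel while
their sample-channel reporters sit at the noise floor, producing the
bimodal distribution that motivates the >40 intensity threshold.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from motifboost.filters import (
    apply_acceptance_criteria,
    ck2_design,
    intensity_notch_threshold,
    titration_design,
)
from motifboost.motifs import load_models
from motifboost.simulate import AcquisitionParams, SimulationConfig, run_simulation
from motifboost.studies import specificity_and_attrition_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/02_filters")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    study = specificity_and_attrition_study(seed=args.seed)
    flagged = apply_acceptance_criteria(study["result"].table, ck2_design())

    # over-boosted pY condition: sample channels near the noise floor
    design = titration_design()
    amounts = {ch: (125.0 if design.roles[ch] == "boost" else 5.0) for ch in design.channels}
    cfg = SimulationConfig(
        n_sites=1500, planted={"EGFR": 300}, boost_kinase="EGFR",
        amounts=amounts, specificity=1.0,
    )
    boosted = run_simulation(design, load_models(), cfg, AcquisitionParams(seed=args.seed), seed=args.seed)
    boosted_flagged = apply_acceptance_criteria(boosted.table, design)
    log2_totals = boosted_flagged["log2_total_sample_intensity"].dropna().to_numpy()
    notch = intensity_notch_threshold(log2_totals)

    summary = {
        "attrition": study["attrition"],
        "enrichment_specificity": round(study["specificity"], 4),
        "median_log2_total_sample_intensity": round(study["median_log2_total"], 2),
        "boosted_condition_notch_log2": None if notch is None else round(notch, 2),
    }
    (outdir / "filter_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    np.savetxt(outdir / "log2_total_sample_intensity_boosted.tsv", log2_totals, fmt="%.4f")
    print(json.dumps(summary, indent=2))
    if notch is not None:
        print(
            f"The boosted condition's intensity distribution is bimodal with a "
            f"notch at log2 ~ {notch:.1f}: records below it are dominated by the "
            "reporter noise floor, supporting the >40 acceptance threshold on "
            "this intensity scale."
        )


if __name__ == "__main__":
    main()
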