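"""Direct-substrate (group B) recovery from the dual TMT ratio tests.

Simulates the CK2 inhibitor experiment with planted direct substrates and
classifies every quantified site from two Student t tests: inhibitor vs
control (direction) and motif-centric channel vs inhibitor (in vitro
response).  Scores sensitivity and precision of the group-B call against
the simulator's ground-truth substrate flags.
"""

import argparse
import json
from pathlib import Path

from motifboost.studies import ck2_substrate_study


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", default="results/03_substrates")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    study = ck2_substrate_study(seed=args.seed)
    study["classified"].to_csv(outdir / "classified_sites.tsv", sep="\t", index=False)
    metrics = {
        k: (round(v, 4) if isinstance(v, float) else v)
        for k, v in study.items()
        if k.startswith(("n_", "sensitivity", "precision", "median_"))
    }
    (outdir / "recovery_metrics.json").write_text(json.dumps(metrics, indent=2) + "\n")
    print(json.dumps(metrics, indent=2))
    print(
        f"Group B recovers the planted substrates with sensitivity "
        f"{study['sensitivity']:.2f} and precision {study['precision']:.2f}; "
        f"on substrates the inhibitor ratio is down (median "
        f"{study['median_log2_treatment_substrates']:.2f} log2) while the "
        f"motif-centric increase is larger "
        f"({study['median_log2_motif_substrates']:.2f} log2)."
    )


if __name__ == "__main__":
    main()
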