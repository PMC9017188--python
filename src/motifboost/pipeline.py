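"""End-to-end driver: simulate -> filter -> regulate -> stoichiometry -> motif.

Each stage writes its table under the output directory and records its
record counts in the manifest, so any stage can be re-run from the stored
intermediates with the corresponding CLI subcommand.  A stage failure
aborts with the stage name; intermediates written so far are preserved.
"""

from __future__ import annotations

import hashlib
import json
import logging
from importlib.metadata import version as pkg_version
from pathlib import Path

import pandas as pd

from . import motif_stats, regulation, tables
from .config import RunConfig
from .filters import apply_acceptance_criteria, attrition_counts, enrichment_specificity
from .motifs import load_models
from .simulate import run_simulation

log = logging.getLogger("motifboost")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def _config_hash(config: RunConfig) -> str:
    doc = config.to_dict()
    doc.pop("outdir", None)  # hash the science, not the paths
    payload = json.dumps(doc, sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> Path:
    """Run every stage; returns the output directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    design = config.build_design()
    models = load_models(config.models_path)
    counts: dict[str, int] = {}
    stage = "simulate"
    try:
        result = run_simulation(design, models, config.simulation, config.acquisition, config.seed)
        tables.write_fasta(result.proteins, outdir / "proteome.fasta")
        tables.write_truth_table(result.truth.to_frame(), outdir / "ground_truth.tsv")
        for inj, table in enumerate(result.tables):
            tables.write_site_table(table, outdir / f"sites_injection{inj + 1}.tsv")
        counts["simulated_sites"] = len(result.truth.sites)
        counts["identified_records"] = int(len(result.table))
        log.info("simulate: %d truth sites, %d identified", counts["simulated_sites"], counts["identified_records"])

        stage = "filter"
        flagged = apply_acceptance_criteria(result.table, design, config.criteria)
        tables.write_site_table(flagged, outdir / "filtered.tsv")
        attrition = attrition_counts(flagged)
        attrition["enrichment_specificity"] = round(enrichment_specificity(result.table), 4)
        with open(outdir / "attrition.json", "w") as fh:
            json.dump(attrition, fh, indent=2)
        counts["passing_records"] = attrition["pass_all"]
        log.info("filter: %s", attrition)
        accepted_keys = set(
            map(tuple, flagged.loc[flagged["pass_all"], ["protein_id", "position", "residue"]].to_numpy())
        )
        filtered_tables = [
            t[[tuple(k) in accepted_keys for k in t[["protein_id", "position", "residue"]].to_numpy()]]
            for t in result.tables
        ]

        ana = config.analysis
        control = ana.control or design.conditions[0]
        treated = ana.treated or (design.conditions[1] if len(design.conditions) > 1 else design.conditions[0])
        stage = "regulate"
        results = regulation.regulation_results(
            filtered_tables, design, control=control, treated=treated, equal_var=ana.equal_var
        )
        classified = regulation.classify_sites(
            results, alpha=ana.alpha, min_abs_log2_ratio=ana.min_abs_log2_ratio
        )
        classified.to_csv(outdir / "regulation.tsv", sep="\t", index=False)
        counts["tested_sites"] = len(classified)
        counts["group_A"] = int((classified["group"] == "A").sum())
        counts["group_B"] = int((classified["group"] == "B").sum())
        log.info("regulate: %d tested, %d group A, %d group B", counts["tested_sites"], counts["group_A"], counts["group_B"])

        stage = "stoichiometry"
        endo = ana.endo_condition or control
        est = regulation.estimate_stoichiometry(filtered_tables, design, endo)
        est.to_csv(outdir / f"stoichiometry_{endo}.tsv", sep="\t", index=False)
        curve = regulation.cumulative_stoichiometry_curve(est)
        curve.to_csv(outdir / f"stoichiometry_curve_{endo}.tsv", sep="\t", index=False)
        counts["stoichiometry_defined"] = int((~est["undefined"]).sum())

        stage = "motif"
        phospho = result.table[result.table["is_phosphopeptide"]]
        background = motif_stats.frequency_matrix(phospho["window"])
        motif_stats.write_matrix(background, outdir / "motif_freq_all.tsv")
        b_keys = set(
            map(tuple, classified.loc[classified["group"] == "B", ["protein_id", "position", "residue"]].to_numpy())
        )
        group_b = phospho[
            [tuple(k) in b_keys for k in phospho[["protein_id", "position", "residue"]].to_numpy()]
        ]
        if len(group_b):
            fg = motif_stats.frequency_matrix(group_b["window"])
            motif_stats.write_matrix(fg, outdir / "motif_freq_groupB.tsv")
            enr = motif_stats.enrichment_matrix(fg, background)
            motif_stats.write_matrix(enr, outdir / "motif_enrichment_groupB.tsv")
        counts["group_B_windows"] = int(len(group_b))
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        raise StageError(stage, exc) from exc

    manifest = {
        "package_version": pkg_version("motifboost"),
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "config": config.to_dict(),
        "record_counts": counts,
    }
    tables.write_manifest(manifest, outdir / "manifest.json")
    return outdir


def load_injection_tables(outdir: Path) -> list[pd.DataFrame]:
    paths = sorted(Path(outdir).glob("sites_injection*.tsv"))
    return [tables.read_site_table(p) for p in paths]
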