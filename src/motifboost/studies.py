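"""Reusable study drivers: the standard simulated experiments of the package.

Each function sets up one study design (CK2 inhibitor discrimination, boost
amount titration, boosting detection gain, stoichiometry recovery, motif
recovery) at its default conditions, runs the relevant pipeline stages, and
returns plain dictionaries / DataFrames.  The numbered analysis scripts and
the acceptance machinery are thin wrappers over these drivers.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .filters import (
    FilterCriteria,
    apply_acceptance_criteria,
    attrition_counts,
    ck2_design,
    enrichment_specificity,
    py_design,
    titration_design,
)
from .motifs import load_models, models_by_name, sample_window
from .regulation import (
    classify_sites,
    cumulative_stoichiometry_curve,
    estimate_stoichiometry,
    regulation_results,
)
from .simulate import (
    AcquisitionParams,
    SimulationConfig,
    TruthParams,
    run_simulation,
)

SITE_COLS = ["protein_id", "position", "residue"]


def _keys(frame: pd.DataFrame) -> set[tuple]:
    return set(map(tuple, frame[SITE_COLS].to_numpy()))


def ck2_substrate_study(
    seed: int,
    n_sites: int = 2000,
    n_planted: int = 200,
    inhibitor_effect: float = 0.5,
    n_injections: int = 2,
    alpha: float = 0.05,
    acq: AcquisitionParams | None = None,
) -> dict:
    """CK2 inhibitor discrimination: plant substrates, recover group B.

    Simulates the 6-plex design (DMSO / CK2 inhibitor in duplicate, two
    CK2 motif-centric boost channels) with planted CK2-consensus
    substrates whose stoichiometry drops by ``inhibitor_effect`` under
    treatment, then classifies sites from the two ratio tests and scores
    recovery against the simulator's direct-substrate flags.
    """
    design = ck2_design()
    models = load_models()
    cfg = SimulationConfig(
        n_sites=n_sites,
        planted={"CK2": n_planted},
        boost_kinase="CK2",
        n_injections=n_injections,
        truth=TruthParams(
            inhibited_kinase="CK2",
            treated_conditions=("CKi",),
            inhibitor_effect=inhibitor_effect,
        ),
    )
    acq = acq or AcquisitionParams.low_noise()
    result = run_simulation(design, models, cfg, acq, seed=seed)
    results = regulation_results(result.tables, design, control="DMSO", treated="CKi")
    classified = classify_sites(results, alpha=alpha)

    truth_frame = result.truth.to_frame()
    substrate_keys = _keys(
        truth_frame[truth_frame["direct_substrate_of"].str.contains("CK2")]
    )
    tested_keys = _keys(classified)
    pred_b = _keys(classified[classified["group"] == "B"])
    tp = len(pred_b & substrate_keys)
    substrates_tested = substrate_keys & tested_keys
    is_sub = [tuple(k) in substrate_keys for k in classified[SITE_COLS].to_numpy()]
    sub_rows = classified[is_sub]
    return {
        "result": result,
        "classified": classified,
        "truth_frame": truth_frame,
        "n_tested": len(classified),
        "n_substrates_tested": len(substrates_tested),
        "n_group_B": len(pred_b),
        "sensitivity": tp / len(substrates_tested) if substrates_tested else float("nan"),
        "precision": tp / len(pred_b) if pred_b else float("nan"),
        "median_log2_treatment_substrates": float(sub_rows["log2_ratio_treatment"].median()),
        "median_log2_motif_substrates": float(sub_rows["log2_ratio_motif"].median()),
    }


def stoichiometry_recovery_study(
    seed: int, n_sites: int = 1000, noisy: bool = False
) -> dict:
    """Channel-ratio stoichiometry estimation against ground truth.

    ``noisy=False``: oracle acquisition with assumed-complete in vitro
    conversion — the estimate must equal the true stoichiometry exactly.
    ``noisy=True``: 20% CV multiplicative noise, two replicate channel
    pairs, counting noise at a generous ion budget.
    """
    design = ck2_design()
    models = load_models()
    cfg = SimulationConfig(
        n_sites=n_sites, boost_kinase="CK2", assume_full_match=True, specificity=1.0
    )
    if noisy:
        acq = AcquisitionParams.low_noise(multiplicative_cv=0.2)
    else:
        acq = AcquisitionParams(oracle_mode=True, ms1_detection_threshold=0.0)
    result = run_simulation(design, models, cfg, acq, seed=seed)
    est = estimate_stoichiometry(result.tables, design, "DMSO")
    truth_frame = result.truth.to_frame()
    merged = est.merge(truth_frame[SITE_COLS + ["stoich_DMSO"]], on=SITE_COLS)
    defined = merged[~merged["undefined"]]
    err = (defined["stoichiometry"] - defined["stoich_DMSO"]).abs()
    return {
        "result": result,
        "estimates": est,
        "merged": merged,
        "n_defined": int(len(defined)),
        "max_abs_error": float(err.max()) if len(err) else float("nan"),
        "median_abs_error": float(err.median()) if len(err) else float("nan"),
        "curve": cumulative_stoichiometry_curve(est),
    }


def boosting_detection_study(
    seed: int, boost_amounts: Sequence[float] = (0.0, 25.0), oracle: bool = False,
    n_sites: int = 1500, n_planted: int = 300,
) -> dict:
    """Paired simulations differing only in boost loading.

    Same seed, same ground truth: only the boost channel amount changes,
    so detected-site sets are comparable one-to-one.  Returns, per boost
    amount, the identified records and the set of detected pY sites.
    """
    design = py_design()
    models = load_models()
    acq = AcquisitionParams(oracle_mode=oracle, seed=seed)
    detected: dict[float, set] = {}
    tables = {}
    for boost in boost_amounts:
        amounts = {ch: (boost if design.roles[ch] == "boost" else 25.0) for ch in design.channels}
        cfg = SimulationConfig(
            n_sites=n_sites,
            planted={"EGFR": n_planted},
            boost_kinase="EGFR",
            amounts=amounts,
            specificity=1.0,
        )
        result = run_simulation(design, models, cfg, acq, seed=seed)
        table = result.table
        py = table[table["residue"] == "Y"]
        detected[boost] = _keys(py)
        tables[boost] = table
    return {"detected_py": detected, "tables": tables}


def boost_titration_study(
    seed: int,
    boost_amounts: Sequence[float] = (5.0, 25.0, 125.0),
    sample_amount: float = 5.0,
    n_sites: int = 1500,
    n_planted: int = 300,
    criteria: FilterCriteria = FilterCriteria(),
) -> pd.DataFrame:
    """Boost-amount titration at fixed (limiting) sample loading.

    Reproduces the saturation/decline of quantifiable pY sites when the
    motif-centric loading outgrows the ion budget: identification keeps
    improving with boost, but the boost-ratio and sample-intensity
    criteria remove over-boosted sites.
    """
    design = titration_design()
    models = load_models()
    rows = []
    for boost in boost_amounts:
        amounts = {
            ch: (boost if design.roles[ch] == "boost" else sample_amount)
            for ch in design.channels
        }
        cfg = SimulationConfig(
            n_sites=n_sites,
            planted={"EGFR": n_planted},
            boost_kinase="EGFR",
            amounts=amounts,
            specificity=1.0,
        )
        result = run_simulation(design, models, cfg, AcquisitionParams(seed=seed), seed=seed)
        flagged = apply_acceptance_criteria(result.table, design, criteria)
        py = flagged[flagged["residue"] == "Y"]
        rows.append(
            {
                "boost_amount": boost,
                "sample_amount": sample_amount,
                "identified_total": len(flagged),
                "identified_py": len(py),
                "quantifiable_py": int(py["pass_all"].sum()),
                "quantifiable_total": int(flagged["pass_all"].sum()),
            }
        )
    return pd.DataFrame(rows)


def motif_recovery_study(seed: int, n_windows: int = 500) -> pd.DataFrame:
    """Frequency-matrix recovery of each shipped kinase's consensus.

    Samples windows from each model's planting distribution and correlates
    the observed per-position residue frequencies with the generator's
    probabilities over non-padding cells.
    """
    from .motif_stats import frequency_matrix

    models = load_models()
    rows = []
    for model in models:
        rng = substream(seed, "motif_recovery", model.name)
        windows = [sample_window(model, rng) for _ in range(n_windows)]
        fm = frequency_matrix(windows)
        probs = model.position_probabilities()
        obs, exp = [], []
        for pos in range(-model.width, model.width + 1):
            if pos == 0:
                continue
            obs.extend(fm.frequencies.loc[pos].to_numpy())
            exp.extend(probs[pos])
        r = float(np.corrcoef(obs, exp)[0, 1])
        rows.append({"kinase": model.name, "pearson_r": r})
    return pd.DataFrame(rows)


def multi_kinase_study(
    seed: int,
    kinases: Sequence[str] = ("CK2", "ERK2", "CDK1", "EGFR"),
    n_sites: int = 1500,
    n_planted: int = 100,
) -> dict:
    """Quantified-site overlap and stoichiometry across boost kinases.

    One simulated 6-plex per kinase on the same seed; reports quantifiable
    (acceptance-passing) motif-centric sites per kinase, pairwise overlap,
    and the per-class stoichiometry of the pooled estimates.
    """
    from .regulation import overlap_analysis

    design = ck2_design()
    models = load_models()
    by_name = models_by_name(models)
    site_sets: dict[str, set] = {}
    stoich_frames = []
    for kin in kinases:
        level = "protein" if by_name[kin].kinase_class == "basophilic" else "peptide"
        cfg = SimulationConfig(
            n_sites=n_sites,
            planted={kin: n_planted},
            boost_kinase=kin,
            reaction_level=level,
            specificity=1.0,
        )
        result = run_simulation(
            design, models, cfg, AcquisitionParams.low_noise(), seed=seed
        )
        flagged = apply_acceptance_criteria(result.table, design)
        passing = flagged[flagged["pass_all"]]
        # motif-centric = sites genuinely converted by the boost kinase
        truth_frame = result.truth.to_frame()
        boosted = truth_frame[truth_frame[f"back_{kin}"] > 0.5]
        site_sets[kin] = _keys(passing) & _keys(boosted)
        est = estimate_stoichiometry(result.tables, design, "DMSO")
        est = est[[tuple(k) in site_sets[kin] for k in est[SITE_COLS].to_numpy()]]
        merged = est.merge(
            truth_frame[SITE_COLS + ["kinase_class"]], on=SITE_COLS, how="left"
        )
        merged["boost_kinase"] = kin
        stoich_frames.append(merged)
    stoich = pd.concat(stoich_frames, ignore_index=True)
    class_median = (
        stoich[~stoich["undefined"]]
        .groupby("kinase_class")["stoichiometry"]
        .median()
        .to_dict()
    )
    return {
        "site_sets": site_sets,
        "overlap": overlap_analysis(site_sets),
        "stoichiometry": stoich,
        "class_median_stoichiometry": class_median,
    }


def notch_study(seed: int, n: int = 5000) -> dict:
    """Signal/noise notch detection on a bimodal log2-intensity mixture."""
    from .filters import intensity_notch_threshold

    rng = substream(seed, "notch")
    noise = rng.normal(35.0, 1.0, size=int(n * 0.4))
    signal = rng.normal(43.0, 1.5, size=n - len(noise))
    values = np.concatenate([noise, signal])
    return {
        "values": values,
        "threshold": intensity_notch_threshold(values),
    }


def specificity_and_attrition_study(seed: int, n_sites: int = 2000) -> dict:
    """Standard CK2 run: enrichment specificity and per-criterion attrition."""
    design = ck2_design()
    models = load_models()
    cfg = SimulationConfig(n_sites=n_sites, planted={"CK2": 200}, boost_kinase="CK2")
    result = run_simulation(design, models, cfg, AcquisitionParams(seed=seed), seed=seed)
    flagged = apply_acceptance_criteria(result.table, design)
    return {
        "result": result,
        "specificity": enrichment_specificity(result.table),
        "attrition": attrition_counts(flagged),
        "median_log2_total": float(flagged["log2_total_sample_intensity"].median()),
    }
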