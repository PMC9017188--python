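"""Synthetic-data generator: digestion, ground truth, acquisition."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from motifboost._rng import substream
from motifboost.filters import INTENSITY_PREFIX, ChannelDesign, ck2_design
from motifboost.simulate import (
    AcquisitionParams,
    GroundTruth,
    InvalidParameterError,
    ProteinEntry,
    SimulationConfig,
    SiteTruth,
    TruthParams,
    assign_ground_truth,
    channel_phospho_fractions,
    digest,
    enumerate_sites,
    generate_proteome,
    plant_motif_sites,
    run_simulation,
    select_phosphosites,
    simulate_kinase_reaction,
    simulate_tmt_experiment,
    uniform_ground_truth,
)

# ---------------------------------------------------------------------------
# proteome and digestion


def test_generate_proteome_seeded_determinism():
    a = generate_proteome(5, seed=7)
    b = generate_proteome(5, seed=7)
    assert [(p.id, p.sequence) for p in a] == [(p.id, p.sequence) for p in b]
    c = generate_proteome(5, seed=8)
    assert [p.sequence for p in a] != [p.sequence for p in c]


def test_generate_proteome_zero_kr_gives_single_peptide():
    comp = np.full(20, 1 / 20)
    comp[["K" == aa for aa in "ACDEFGHIKLMNPQRSTVWY"].index(True)] = 0.0
    comp["ACDEFGHIKLMNPQRSTVWY".index("R")] = 0.0
    comp = comp / comp.sum()
    for protein in generate_proteome(5, composition=comp, seed=1):
        assert len(digest(protein, max_missed=0)) == 1


def test_generate_proteome_uniform_composition_frequencies():
    proteins = generate_proteome(1000, length_mean=100, seed=2)
    joined = "".join(p.sequence for p in proteins)
    n = len(joined)
    se = np.sqrt((1 / 20) * (19 / 20) / n)
    for aa in "ACDEFGHIKLMNPQRSTVWY":
        assert abs(joined.count(aa) / n - 1 / 20) < 3 * se


def test_generate_proteome_rejects_bad_composition():
    comp = np.full(20, 1 / 20)
    comp[0] += 0.1
    with pytest.raises(InvalidParameterError):
        generate_proteome(3, composition=comp, seed=0)


@pytest.mark.parametrize(
    ("sequence", "max_missed", "expected"),
    [
        ("MKTAYIAKQR", 0, ["MK", "TAYIAK", "QR"]),
        ("AAAA", 2, ["AAAA"]),
        ("AKPA", 0, ["AKPA"]),  # KP suppression
    ],
)
def test_digest_cleavage_rule(sequence, max_missed, expected):
    peptides = digest(ProteinEntry("P1", sequence), max_missed=max_missed)
    assert [p.sequence for p in peptides if p.missed_cleavages == 0] == expected


def test_digest_missed_cleavage_products_and_coordinates():
    protein = ProteinEntry("P1", "MKTAYIAKQR")
    peptides = digest(protein, max_missed=2)
    assert {p.sequence for p in peptides if p.missed_cleavages == 1} == {"MKTAYIAK", "TAYIAKQR"}
    assert {p.sequence for p in peptides if p.missed_cleavages == 2} == {"MKTAYIAKQR"}
    for p in peptides:
        assert p.sequence == protein.sequence[p.start - 1 : p.end]


def test_digest_kp_suppression_can_be_disabled():
    peptides = digest(ProteinEntry("P1", "AKPA"), max_missed=0, suppress_kp=False)
    assert [p.sequence for p in peptides] == ["AK", "PA"]


# ---------------------------------------------------------------------------
# ground truth


def _sites_frame(windows, residues):
    return pd.DataFrame(
        {
            "protein_id": [f"P{i}" for i in range(len(windows))],
            "position": np.arange(1, len(windows) + 1) * 10,
            "residue": residues,
            "window": windows,
            "peptide_window": windows,
            "planted_by": "",
        }
    )


def test_ground_truth_class_mean_stoichiometry_ordering(models, model_map):
    """Acidophilic sites draw visibly higher stoichiometry than tyrosine sites."""
    rng = substream(5, "gt_order")
    from motifboost.motifs import sample_window

    n = 1500
    ck2_wins = [sample_window(model_map["CK2"], rng) for _ in range(n)]
    py_wins = [sample_window(model_map["EGFR"], rng) for _ in range(n)]
    sites = _sites_frame(
        ck2_wins + py_wins,
        [w[7] for w in ck2_wins] + ["Y"] * n,
    )
    truth = assign_ground_truth(sites, models, ["DMSO"], TruthParams(), seed=5)
    frame = truth.to_frame()
    acid = frame.loc[frame["kinase_class"] == "acidophilic", "stoich_DMSO"]
    tyr = frame.loc[frame["kinase_class"] == "tyrosine", "stoich_DMSO"]
    assert len(acid) > 1000 and len(tyr) > 1000
    assert acid.mean() > tyr.mean()
    assert frame[[c for c in frame.columns if c.startswith("stoich_")]].to_numpy().max() <= 1.0


def test_ground_truth_beta_prior_mean_matches_oracle(models):
    """A symmetric Beta(2,2) prior gives sample mean 0.5 within 3 SE."""
    n = 5000
    wins = ["_" * 7 + "S" + "_" * 7] * n
    sites = _sites_frame(wins, ["S"] * n)
    params = TruthParams(class_priors={k: (2.0, 2.0) for k in ("acidophilic", "basophilic", "pro_directed", "tyrosine")})
    truth = assign_ground_truth(sites, models, ["DMSO"], params, seed=9)
    vals = truth.to_frame()["stoich_DMSO"].to_numpy()
    se = np.sqrt(stats.beta(2, 2).var() / n)
    assert abs(vals.mean() - 0.5) < 3 * se


def test_null_inhibitor_effect_leaves_conditions_identical(models):
    wins = ["_" * 7 + "S" + "DDE____"] * 50
    sites = _sites_frame(wins, ["S"] * 50)
    params = TruthParams(inhibited_kinase="CK2", treated_conditions=("CKi",), inhibitor_effect=1.0)
    truth = assign_ground_truth(sites, models, ["DMSO", "CKi"], params, seed=3)
    for site in truth.sites:
        assert site.stoichiometry["DMSO"] == site.stoichiometry["CKi"]


def test_unknown_treated_condition_rejected(models):
    sites = _sites_frame(["_" * 7 + "S" + "_" * 7], ["S"])
    params = TruthParams(inhibited_kinase="CK2", treated_conditions=("nope",))
    with pytest.raises(InvalidParameterError):
        assign_ground_truth(sites, models, ["DMSO"], params, seed=0)


def test_direct_substrates_respect_acceptor_sets(models, model_map):
    from motifboost.motifs import sample_window

    rng = substream(11, "acc")
    wins = [sample_window(model_map["CK2"], rng) for _ in range(200)]
    sites = _sites_frame(wins, [w[7] for w in wins])
    truth = assign_ground_truth(sites, models, ["DMSO"], TruthParams(), seed=11)
    acceptors = {m.name: m.acceptor_residues for m in models}
    for site in truth.sites:
        for kin in site.direct_substrate_of:
            assert site.residue in acceptors[kin]


# ---------------------------------------------------------------------------
# kinase reaction


def _site(window, peptide_window=None, stoich=0.2, residue=None):
    return SiteTruth(
        protein_id="P1",
        position=10,
        residue=residue or window[7],
        window=window,
        peptide_window=peptide_window or window,
        kinase_class="none",
        best_kinase="",
        best_score=0.0,
        stoichiometry={"DMSO": stoich},
        direct_substrate_of=frozenset(),
        inhibitor_effect=1.0,
        planted_by="",
    )


def test_kinase_reaction_stated_formula(model_map):
    ck2 = model_map["CK2"]
    site = _site("A" * 7 + "S" + "A" * 7, stoich=0.2)
    assert simulate_kinase_reaction(site, ck2, 0.5, match_prob_override=0.8) == pytest.approx(0.32)
    site0 = _site("A" * 7 + "S" + "A" * 7, stoich=0.0)
    assert simulate_kinase_reaction(site0, ck2, 1.0, match_prob_override=1.0) == pytest.approx(1.0)


def test_kinase_reaction_wrong_acceptor_returns_zero(model_map):
    site = _site("A" * 7 + "Y" + "A" * 7, stoich=0.1)
    assert simulate_kinase_reaction(site, model_map["CK2"], 1.0) == 0.0


def test_kinase_reaction_peptide_level_truncates_basophilic(model_map):
    pka = model_map["PKA"]
    protein_win = "AAAA" + "RR" + "A" + "S" + "A" * 7
    peptide_win = "_" * 6 + "A" + "S" + "A" * 7
    site = _site(protein_win, peptide_window=peptide_win, stoich=0.1)
    protein_level = simulate_kinase_reaction(site, pka, 1.0, level="protein")
    peptide_level = simulate_kinase_reaction(site, pka, 1.0, level="peptide")
    assert protein_level > 0.8
    assert peptide_level < 0.01


def test_kinase_reaction_validates_inputs(model_map):
    site = _site("A" * 7 + "S" + "A" * 7)
    with pytest.raises(InvalidParameterError):
        simulate_kinase_reaction(site, model_map["CK2"], 1.5)
    with pytest.raises(InvalidParameterError):
        simulate_kinase_reaction(site, model_map["CK2"], 1.0, level="lysate")


# ---------------------------------------------------------------------------
# acquisition


def _uniform_truth(n, stoich, back):
    return uniform_ground_truth(n, stoichiometry=stoich, back_fraction=back)


def test_oracle_mode_reports_exact_abundances():
    design = ck2_design()
    truth = _uniform_truth(20, stoich=0.3, back=0.5)
    amounts = {ch: 25.0 for ch in design.channels}
    acq = AcquisitionParams(oracle_mode=True, ms1_detection_threshold=0.0, seed=4)
    (table,) = simulate_tmt_experiment(truth, design, amounts, acq, "CK2")
    frac = channel_phospho_fractions(truth, design, "CK2")
    for j, ch in enumerate(design.channels):
        expected = acq.intensity_scale * 25.0 * frac.iloc[:, j].to_numpy()
        np.testing.assert_allclose(table[INTENSITY_PREFIX + ch].to_numpy(), expected)


def test_channel_fractions_capped_at_one():
    truth = _uniform_truth(5, stoich=0.9, back=0.9)
    frac = channel_phospho_fractions(truth, ck2_design(), "CK2")
    assert frac.to_numpy().max() <= 1.0


def test_reporter_counts_match_poisson_multinomial_oracle():
    """Sample-channel counts follow Poisson(budget x channel share)."""
    design = ck2_design()
    n = 2000
    truth = _uniform_truth(n, stoich=0.05, back=0.95)
    # boost channels dominate: shares are identical across sites
    amounts = {ch: 25.0 for ch in design.channels}
    acq = AcquisitionParams(ms1_detection_threshold=0.0, id_probability_midpoint_log2=0.0, seed=6)
    (table,) = simulate_tmt_experiment(truth, design, amounts, acq, "CK2")
    frac = channel_phospho_fractions(truth, design, "CK2").iloc[0]
    share = frac["126"] / frac.sum()
    lam = acq.ion_budget * share
    counts = table["count_126"].to_numpy().astype(int)
    assert len(counts) == n
    # chi-square GOF against the Poisson oracle, tail-binned
    lo, hi = int(stats.poisson.ppf(0.001, lam)), int(stats.poisson.ppf(0.999, lam))
    edges = list(range(lo, hi + 1))
    observed = np.array([(counts == k).sum() for k in edges], dtype=float)
    observed = np.concatenate([[np.sum(counts < lo)], observed, [np.sum(counts > hi)]])
    pmf = stats.poisson.pmf(edges, lam)
    expected = np.concatenate([[stats.poisson.cdf(lo - 1, lam)], pmf, [stats.poisson.sf(hi, lam)]]) * n
    keep = expected > 5
    chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
    p = stats.chi2.sf(chi2, keep.sum() - 1)
    assert p > 0.01


def test_detection_threshold_and_boost_gate():
    """A site crosses the MS1 threshold only when the boost channel is loaded."""
    design = ck2_design()
    truth = _uniform_truth(1, stoich=0.01, back=0.95)
    acq = AcquisitionParams(oracle_mode=True, seed=1)
    no_boost = {ch: (0.0 if design.roles[ch] == "boost" else 25.0) for ch in design.channels}
    boosted = {ch: 25.0 for ch in design.channels}
    (t0,) = simulate_tmt_experiment(truth, design, no_boost, acq, "CK2")
    (t1,) = simulate_tmt_experiment(truth, design, boosted, acq, "CK2")
    assert len(t0) == 0 and len(t1) == 1


def test_simulate_tmt_rejects_bad_amounts():
    design = ck2_design()
    truth = _uniform_truth(2, stoich=0.1, back=0.5)
    acq = AcquisitionParams(seed=0)
    with pytest.raises(InvalidParameterError):
        simulate_tmt_experiment(truth, design, {ch: -1.0 for ch in design.channels}, acq, "CK2")
    with pytest.raises(InvalidParameterError):
        simulate_tmt_experiment(truth, design, {"126": 25.0}, acq, "CK2")


def test_counts_are_nonnegative_integers_and_localization_mix():
    design = ck2_design()
    truth = _uniform_truth(500, stoich=0.2, back=0.5)
    acq = AcquisitionParams(ms1_detection_threshold=0.0, id_probability_midpoint_log2=0.0, seed=2)
    (table,) = simulate_tmt_experiment(truth, design, {ch: 25.0 for ch in design.channels}, acq, "CK2")
    counts = table[[c for c in table.columns if c.startswith("count_")]].to_numpy()
    assert (counts >= 0).all() and np.allclose(counts, np.round(counts))
    frac_class1 = (table["localization_prob"] > 0.75).mean()
    assert 0.85 < frac_class1 < 0.95


# ---------------------------------------------------------------------------
# end-to-end generator properties


def test_run_simulation_seeded_determinism(models):
    design = ck2_design()
    cfg = SimulationConfig(n_sites=300, n_proteins=60, planted={"CK2": 30}, boost_kinase="CK2")
    acq = AcquisitionParams()
    a = run_simulation(design, models, cfg, acq, seed=42)
    b = run_simulation(design, models, cfg, acq, seed=42)
    pd.testing.assert_frame_equal(a.table, b.table)
    pd.testing.assert_frame_equal(a.truth.to_frame(), b.truth.to_frame())


def test_selected_phosphosite_residue_composition():
    """Site selection hits the 90:10:0.05 pS:pT:pY target within sampling error."""
    proteins = generate_proteome(400, length_mean=300, seed=13)
    candidates = enumerate_sites(proteins)
    n = 3000
    chosen = select_phosphosites(candidates, n, seed=13)
    counts = chosen["residue"].value_counts()
    probs = np.array([90.0, 10.0, 0.05]) / 100.05
    for aa, p in zip("STY", probs):
        se = np.sqrt(p * (1 - p) / n)
        assert abs(counts.get(aa, 0) / n - p) < 4 * se


def test_planted_sites_survive_selection_and_carry_flags(models):
    proteins = generate_proteome(100, seed=3)
    by_name = {m.name: m for m in models}
    proteins, planted = plant_motif_sites(proteins, by_name, {"PKA": 40}, seed=3)
    candidates = enumerate_sites(proteins, planted=planted)
    chosen = select_phosphosites(candidates, 300, seed=3)
    assert (chosen["planted_by"] == "PKA").sum() == 40
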