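# motifboost

Motif-centric isobaric (TMT) phosphoproteomics, as a tested, fully
simulated pipeline: boost-channel experiment simulation, acceptance-criteria
filtering, direct-substrate classification, phosphorylation-stoichiometry
estimation, and kinase-motif analysis.

## The problem

Low-stoichiometry phosphosites — above all phosphotyrosine, roughly 0.05% of
the phosphoproteome against 90% pS and 10% pT — sit below the detection limit
of ordinary TMT phosphoproteomics. The motif-centric boosting strategy loads
one or two channels of a TMT plex with peptides phosphorylated *in vitro* by a
chosen kinase ("back-phosphorylation" of the abundant unmodified counterparts).
Because isobarically labeled peptides co-elute as a single MS1 peak, the boost
channel lifts the precursor above the detection limit, and the sample channels
are then read out from MS3 reporter ions. The same design yields three
quantities per site:

- **Regulation**: a Student *t* test on log2 reporter intensities, treated vs
  control channels.
- **Direct-substrate status (group A/B)**: sites significantly *down* after
  kinase inhibition split by a second *t* test, motif-centric channel vs
  treated — a significant *increase* marks the site as a direct substrate of
  the assay kinase (group B).
- **Stoichiometry**: assuming complete *in vitro* conversion, the occupancy is
  the channel ratio endogenous / motif-centric, clipped to [0, 1].

Boosting has a cost: with a finite reporter ion budget *N* per MS3 scan
(AGC-like, default 5×10⁴), channel counts are multinomial with probabilities
proportional to true channel abundances, so an over-loaded boost channel
starves the sample channels. Sites are therefore only accepted when

1. the **boost ratio** (boost signal / mean sample signal) is **< 100**,
2. the **log2 total sample intensity** is **> 40** (the notch separating
   signal from the reporter noise floor on the calibrated intensity scale),
3. at least **2 valid reporter values** occur in one duplicate preparation, and
4. the site is **class 1** (localization probability > 0.75).

Everything runs on synthetic data: the package ships a seeded generator that
simulates the full experiment (random proteome, tryptic digestion,
kinase-class-dependent occupancy priors, *in vitro* back-phosphorylation with
position-weight-matrix kinase models, MS1 detection, ion-budget-limited
reporter sampling), so every stage is testable against ground truth without
any download.

## Layout

- `src/motifboost/` — the library: `simulate` (generator), `motifs`
  (kinase PWMs and window scoring), `filters` (designs and acceptance
  criteria), `regulation` (ratio tests, group A/B, stoichiometry),
  `motif_stats` (logo matrices), `tables`/`config`/`pipeline`/`cli`.
- `analysis/01..06_*.py` — numbered narrative analyses (full pipeline run,
  filter attrition and the intensity notch, substrate recovery,
  stoichiometry, boost titration, motif analysis); each writes its tables
  under `results/`.
- `motifboost` CLI — `simulate`, `filter`, `regulate`, `stoichiometry`,
  `motif`, `run` subcommands over the same library.

## Worked example

```bash
python analysis/03_substrate_classification.py --seed 1
```

prints (abridged):

```
  "n_tested": 2198,
  "n_substrates_tested": 413,
  "n_group_B": 424,
  "sensitivity": 1.0,
  "precision": 0.9741,
  "median_log2_treatment_substrates": -0.996,
  "median_log2_motif_substrates": 2.9549
Group B recovers the planted substrates with sensitivity 1.00 and precision 0.97;
on substrates the inhibitor ratio is down (median -1.00 log2) while the
motif-centric increase is larger (2.95 log2).
```

2,000 simulated phosphosites include 200 planted CK2-consensus substrates
whose occupancy halves under CK2 inhibition (hence the −1.0 median log2
inhibitor/control ratio); back-phosphorylation raises their motif-channel
signal far more (+2.95), and the dual-test classification recovers the
ground-truth substrate set with both sensitivity and precision above 0.95.

The boost titration (`analysis/05_boost_titration.py --seed 1`) shows the
central trade-off: at a limiting sample load of 5 units, quantifiable pY
sites go **0 → 46 → 1** as boost loading goes 5 → 25 → 125 units —
identification keeps rising with boost (0 → 212 → 287 identified pY), but
over-boosting pushes sites past the boost-ratio limit and starves the
sample-channel reporters.

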