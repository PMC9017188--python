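# Methods

This note documents the generative model behind the simulator, the analysis
procedures, the parameters that matter, and what the synthetic experiments do
and do not establish about real data.

## Kinase specificity model

Kinase sequence preference is a position-specific log2-odds matrix over a
15-mer window (half-width w = 7) centred on the phospho-acceptor, plus an
acceptor set ⊆ {S, T, Y}. A window's score is the sum of per-position
log-odds; unlisted residues and the padding symbol `_` (positions beyond a
sequence end) score 0, and a centre residue outside the acceptor set yields a
−∞ sentinel. The score maps to a *match probability* — the propensity of the
*in vitro* reaction to phosphorylate the site — through a logistic
`p = σ(slope · (score − midpoint))`.

The shipped models (CK2, PKA, ERK2, JNK1, p38α, CDK1, SRC, EGFR) encode
textbook consensi: CK2 acidic at +1..+3 (strongest +3), PKA basic at −3/−2,
the Pro-directed family Pro at +1 with per-kinase secondary positions, and
two distinct acidic-context pY models for SRC and EGFR. Magnitudes (+2
strong, +1 weak) and the logistic calibration (midpoint = half the maximal
score, slope = 4) are invented calibration, not fitted values; the slope is
deliberately steep so that consensus sites convert near-completely while
background windows stay near zero, reflecting the high specificity of an
overnight *in vitro* reaction at saturating ATP. Each Pro-directed model
carries secondary features beyond the shared Pro at +1 (ERK2: P−2; JNK1:
P+3, L+2; p38α: V−1, G−3; CDK1: K/R at +3 and +4) so that argmax
classification of consensus windows is well-posed; these combinations are
part of the same invented calibration and are trivially replaced via the
JSON model file. The published primary-sequence-preference scorer used in
the original motif analyses is not reproduced; this transparent PWM
log-odds stand-in supports the same qualitative conclusions and is
documented as such.

## Synthetic experiment generator

**Proteome and digestion.** Proteins are i.i.d. residue strings (default 300
proteins, Poisson-length mean 300, uniform composition, so K+R ≈ 10% and
tryptic peptides average ~10 residues). Digestion cleaves C-terminal to K/R,
suppressed before Pro (the common search-engine convention, switchable), and
emits products with 0–2 missed cleavages. The fully cleaved peptide containing
a site defines its *peptide-level* window: context outside the peptide appears
as padding, which is why basophilic motifs requiring K/R at −3/−2 score at
background on peptide substrates — protein-level reactions are required for
PKA-class kinases, and the simulator models both levels.

**Planted substrates.** Motif-centric target sites are planted by overwriting
non-overlapping windows with draws from a model's consensus distribution
(per-position softmax of `concentration × log-odds`, concentration 5; sharp
enough that ≥ 95% of draws classify back to their model and ≥ 99% of planted
CK2 windows qualify as direct substrates).

**Ground truth.** Endogenous phosphosites are selected from the S/T/Y
candidates to match the canonical pS:pT:pY = 90:10:0.05 ratio (planted sites
always kept). Kinase class is the best motif match; occupancy is drawn from
per-class Beta priors — Beta(2,8) acidophilic, Beta(1.5,12)
Pro-directed/basophilic, Beta(1,40) tyrosine — chosen to reproduce the
observed ordering acidophilic > Pro-directed > tyrosine with realistic
means (~0.20 / 0.11 / 0.024). A site is a *direct substrate* of a kinase when
its match probability reaches 0.5; direct substrates of the inhibited kinase
have occupancy multiplied by `inhibitor_effect` (default 0.5) in treated
conditions. Back-phosphorylation of a site is
`efficiency × match_probability × (1 − occupancy)`, evaluated on the protein-
or peptide-level window; the boost channel carries occupancy + back-fraction
(≤ 1 by construction).

**Acquisition.** True channel abundance is
`intensity_scale × loading × phospho fraction`. A site is detected when its
summed abundance exceeds the MS1 threshold, then identified with logistic
probability in log2 summed abundance. Reporter counts are Poisson per channel
with mean `ion_budget × channel share` — exactly the multinomial-with-
Poisson-total model, by Poisson thinning — rescaled to abundance units;
channels with zero counts are missing (0, the MaxQuant convention), non-zero
channels gain an additive lognormal noise floor and optional multiplicative
CV noise. Localization probabilities are drawn so 90% of sites are class 1.
An *oracle mode* reports exact abundances (no sampling, no floor), used by
parameter-recovery tests.

Calibration (defaults): `intensity_scale` 2⁴⁰ per unit loading × fraction,
MS1 threshold 2⁴³, identification midpoint 2⁴³·⁵ with slope 1.5, noise floor
LogNormal(log2 mean 35, sd 1.5), ion budget 5×10⁴, standard loading 25
units/channel. Jointly these put detected sites at log2 sample totals of
roughly 41–45 over a noise floor near 35 — so the acceptance threshold of 40
falls in the notch between the two populations — while leaving endogenous pY
sites below the detection limit unless boosted, and reproducing the
rise-then-collapse of quantifiable pY counts across boost loadings 5/25/125
at limiting sample load.

**Randomness.** One master seed; every draw comes from a named substream
(seed + CRC-32-hashed labels fed to `numpy.random.SeedSequence`). Per-site
identification and localization draws are keyed independently of channel
loadings, so paired simulations differing only in boost amount share them —
detected-set nesting under increasing boost is then exact, not statistical.

## Analysis procedures

- **Filtering**: the four criteria are evaluated independently as auditable
  flags; all inequalities are strict. The boost ratio generalizes to
  mean(boost channels) / mean(designated sample channels); a zero denominator
  is "undefined", which fails the criterion without being an error. Missing
  and zero intensities are equivalent. The notch finder fits a Gaussian KDE
  (Scott bandwidth), requires two modes carrying ≥ 5% of peak density, and
  returns the deepest interior minimum between the two largest modes, or none
  when the density is effectively unimodal (valley ≥ 95% of the smaller mode).
- **Regulation**: observations are log2 intensities pooled over duplicate
  channels × replicate injections. Tests are two-sided equal-variance Student
  *t* (Welch by flag); classification uses raw p < α = 0.05 with no
  fold-change cut-off by default, with Benjamini–Hochberg q-values reported
  alongside. Group B = down ∧ significant positive motif contrast; group A =
  down otherwise; {up, down, unchanged} partition the tested sites.
- **Stoichiometry**: median over replicate (endogenous, boost) channel-pair
  ratios, pooled across injections; values > 1 (incomplete conversion
  inflates the ratio — the estimator's known bias direction) are clipped and
  flagged, zero boost signal is "undefined". Cumulative curves use ascending
  sort with maximum-rank ties.

## What the simulation does and does not show

The generator reproduces the *statistical structure* the analysis relies on:
ion-budget competition between channels, detection driven by summed MS1
abundance, kinase-class occupancy differences, peptide-level truncation of
basophilic motifs, and a bimodal intensity distribution in over-boosted
conditions. It does **not** simulate spectra, chromatography, identification
FDR, co-isolation interference (assumed removed by SPS-MS3; no residual
compression term is modeled), TMT isotope impurities, or multiply
phosphorylated peptides (one site per record). Passing tests therefore
establish correctness and calibration of the *analysis* under the stated
generative assumptions — not instrument-level realism. Real-data effects such
as ratio compression, normalization across plexes, and PSM-to-site
aggregation are explicitly out of scope.

## Problem sizes and numerical choices

Standard studies use 300-protein proteomes, 1,500–2,000 sites, 200–300
planted substrates, and 1–2 replicate injections; each completes in seconds
and is fully determined by its seed. Degenerate inputs are contracts, not
crashes: empty tables give undefined (flagged) metrics, zero-variance *t*
tests return t = 0 / p = 1 when means coincide, windows at sequence edges are
padded, and classification ties break by model list order (documented).
Channel labels are strings throughout; protein coordinates are 1-based
inclusive.
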