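"""Seeded simulation of motif-centric boosting TMT phosphoproteomics.

The generator produces a complete synthetic experiment with the statistical
structure the downstream analysis assumes:

1. a random proteome (i.i.d. residues, configurable composition) into which
   kinase-consensus windows can be planted around chosen phospho-acceptors;
2. full tryptic digestion (cleave after K/R, KP suppression, configurable
   missed cleavages), which determines the peptide-level sequence context —
   the reason basophilic in vitro reactions must run at the protein level;
3. per-site ground truth: kinase class from the best motif match, true
   phosphorylation stoichiometry from kinase-class Beta priors (acidophilic
   highest, tyrosine lowest; site residues target the canonical pS:pT:pY
   ratio of 90:10:0.05), and an inhibitor effect applied to direct
   substrates of the inhibited kinase in treated conditions;
4. in vitro back-phosphorylation of the unphosphorylated fraction,
   ``efficiency x match_probability x (1 - stoichiometry)``, evaluated on
   the protein- or peptide-level window;
5. reporter-ion acquisition: true channel abundances proportional to
   loading amount x phospho fraction; MS1 detection by an abundance
   threshold; identification by a logistic in log2 summed abundance;
   reporter counts Poisson-sampled against a finite ion budget (AGC-like,
   default 5x10^4 ions) and rescaled to abundance units, plus a lognormal
   noise floor.  An oracle mode reports exact abundances for
   parameter-recovery tests.

All randomness flows from one master seed through named substreams
(:mod:`motifboost._rng`), so paired simulations that differ only in, say,
boost loading share the per-site identification and localization draws that
must coincide for detected-set nesting to be exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from .filters import COUNT_PREFIX, INTENSITY_PREFIX, ChannelDesign
from .motifs import (
    AMINO_ACIDS,
    KinaseMotifModel,
    assign_kinase_class,
    extract_window,
    match_probability,
    motif_score,
    sample_window,
)

ACCEPTOR_RESIDUES = ("S", "T", "Y")


class InvalidParameterError(ValueError):
    pass


# ---------------------------------------------------------------------------
# proteome and digestion


@dataclass(frozen=True)
class ProteinEntry:
    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise InvalidParameterError("empty protein sequence")
        bad = set(self.sequence) - set(AMINO_ACIDS)
        if bad:
            raise InvalidParameterError(f"non-canonical residues: {sorted(bad)}")


@dataclass(frozen=True)
class PeptideEntry:
    """Tryptic peptide with 1-based inclusive protein coordinates."""

    protein_id: str
    start: int
    end: int
    sequence: str
    missed_cleavages: int


def generate_proteome(
    n_proteins: int,
    length_mean: float = 300.0,
    composition: Sequence[float] | None = None,
    seed: int = 0,
) -> list[ProteinEntry]:
    """Random proteome with i.i.d. residues.

    ``composition`` is a frequency vector over the 20 residues in
    alphabetical one-letter order (default uniform); its K/R content sets
    the tryptic peptide length distribution.  Deterministic for fixed seed.
    """
    if n_proteins < 1:
        raise InvalidParameterError("n_proteins must be >= 1")
    if composition is None:
        comp = np.full(20, 1 / 20)
    else:
        comp = np.asarray(composition, dtype=float)
        if comp.shape != (20,):
            raise InvalidParameterError("composition must have 20 entries")
        if abs(comp.sum() - 1.0) > 1e-6:
            raise InvalidParameterError("composition must sum to 1")
        comp = comp / comp.sum()
    rng = substream(seed, "proteome")
    width = len(str(n_proteins))
    proteins = []
    for i in range(n_proteins):
        length = max(30, int(rng.poisson(length_mean)))
        seq = "".join(np.asarray(list(AMINO_ACIDS))[rng.choice(20, size=length, p=comp)])
        proteins.append(ProteinEntry(id=f"SYN{i + 1:0{width}d}", sequence=seq))
    return proteins


def digest(
    protein: ProteinEntry, max_missed: int = 2, suppress_kp: bool = True
) -> list[PeptideEntry]:
    """Full tryptic digestion: cleave C-terminal to K/R.

    Cleavage is suppressed when the following residue is Pro (common search
    engine convention; ``suppress_kp=False`` disables it).  Emits every
    product with 0..``max_missed`` missed cleavages.
    """
    if max_missed < 0:
        raise InvalidParameterError("max_missed must be >= 0")
    seq = protein.sequence
    cuts = [0]
    for i, aa in enumerate(seq):
        if aa in "KR" and i + 1 < len(seq) and not (suppress_kp and seq[i + 1] == "P"):
            cuts.append(i + 1)
    cuts.append(len(seq))
    segments = [(cuts[j], cuts[j + 1]) for j in range(len(cuts) - 1)]
    peptides = []
    for j in range(len(segments)):
        for mc in range(max_missed + 1):
            if j + mc >= len(segments):
                break
            start = segments[j][0]
            end = segments[j + mc][1]
            peptides.append(
                PeptideEntry(
                    protein_id=protein.id,
                    start=start + 1,
                    end=end,
                    sequence=seq[start:end],
                    missed_cleavages=mc,
                )
            )
    return peptides


# ---------------------------------------------------------------------------
# site enumeration and motif planting


def plant_motif_sites(
    proteins: list[ProteinEntry],
    models: Mapping[str, KinaseMotifModel],
    n_per_kinase: Mapping[str, int],
    seed: int,
    concentration: float = 5.0,
) -> tuple[list[ProteinEntry], dict[tuple[str, int], str]]:
    """Overwrite windows in the proteome with kinase-consensus draws.

    For each kinase, ``n_per_kinase[name]`` non-overlapping windows are
    written at random interior positions; the centre residue is drawn from
    the kinase's acceptor set.  Returns the modified proteome and a map
    (protein_id, position) -> kinase name of the planted sites.
    """
    seqs = {p.id: list(p.sequence) for p in proteins}
    ids = [p.id for p in proteins]
    used: dict[str, set[int]] = {pid: set() for pid in ids}
    planted: dict[tuple[str, int], str] = {}
    for name in sorted(n_per_kinase):
        model = models[name]
        rng = substream(seed, "plant", name)
        w = model.width
        placed = 0
        attempts = 0
        while placed < n_per_kinase[name]:
            attempts += 1
            if attempts > 200 * n_per_kinase[name]:
                raise InvalidParameterError(f"cannot place {n_per_kinase[name]} sites for {name}")
            pid = ids[rng.integers(len(ids))]
            seq = seqs[pid]
            if len(seq) < 2 * w + 3:
                continue
            pos = int(rng.integers(w + 1, len(seq) - w + 1))  # 1-based centre
            span = range(pos - w, pos + w + 1)
            if any((s in used[pid]) for s in span):
                continue
            window = sample_window(model, rng, concentration=concentration)
            for off, aa in zip(range(-w, w + 1), window):
                seqs[pid][pos - 1 + off] = aa
            used[pid].update(span)
            planted[(pid, pos)] = name
            placed += 1
    new_proteins = [ProteinEntry(id=pid, sequence="".join(seqs[pid])) for pid in ids]
    return new_proteins, planted


def enumerate_sites(
    proteins: list[ProteinEntry],
    w: int = 7,
    planted: Mapping[tuple[str, int], str] | None = None,
) -> pd.DataFrame:
    """All S/T/Y positions with protein-level and peptide-level windows.

    The peptide-level window is extracted from the fully cleaved (0 missed
    cleavages) tryptic peptide containing the site, so context outside the
    peptide appears as padding.
    """
    planted = planted or {}
    rows = []
    for protein in proteins:
        peptides = [p for p in digest(protein, max_missed=0)]
        bounds = {}
        for pep in peptides:
            for pos in range(pep.start, pep.end + 1):
                bounds[pos] = pep
        for pos, aa in enumerate(protein.sequence, start=1):
            if aa not in ACCEPTOR_RESIDUES:
                continue
            pep = bounds[pos]
            rows.append(
                {
                    "protein_id": protein.id,
                    "position": pos,
                    "residue": aa,
                    "window": extract_window(protein.sequence, pos, w).residues,
                    "peptide_window": extract_window(
                        pep.sequence, pos - pep.start + 1, w
                    ).residues,
                    "planted_by": planted.get((protein.id, pos), ""),
                }
            )
    return pd.DataFrame(rows)


def select_phosphosites(
    candidates: pd.DataFrame,
    n_sites: int,
    residue_ratio: Sequence[float] = (90.0, 10.0, 0.05),
    seed: int = 0,
) -> pd.DataFrame:
    """Choose endogenous phosphosites targeting the pS:pT:pY ratio.

    Planted sites are always kept (they are the motif-centric targets);
    the remainder is drawn per residue with multinomial counts matching
    ``residue_ratio`` (default the canonical 90:10:0.05).
    """
    ratio = np.asarray(residue_ratio, dtype=float)
    if ratio.shape != (3,) or (ratio < 0).any() or ratio.sum() == 0:
        raise InvalidParameterError("residue_ratio must be 3 non-negative weights")
    rng = substream(seed, "select_sites")
    keep = candidates[candidates["planted_by"] != ""]
    pool = candidates[candidates["planted_by"] == ""]
    n_free = max(0, n_sites - len(keep))
    counts = rng.multinomial(n_free, ratio / ratio.sum())
    parts = [keep]
    for aa, n_aa in zip(ACCEPTOR_RESIDUES, counts):
        sub = pool[pool["residue"] == aa]
        take = min(int(n_aa), len(sub))
        if take:
            parts.append(sub.iloc[np.sort(rng.choice(len(sub), size=take, replace=False))])
    out = pd.concat(parts, ignore_index=True)
    return out.sort_values(["protein_id", "position"], ignore_index=True)


# ---------------------------------------------------------------------------
# ground truth


@dataclass
class TruthParams:
    """Priors and perturbation structure of the simulated ground truth.

    Per-class Beta stoichiometry priors default to Beta(2,8) acidophilic,
    Beta(1.5,12) Pro-directed/basophilic and Beta(1,40) tyrosine,
    reproducing the observed ordering acidophilic > Pro-directed >
    tyrosine; unassigned sites use the prior of their residue type
    (tyrosine prior for Y, Pro-directed prior otherwise).
    """

    class_priors: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "acidophilic": (2.0, 8.0),
            "basophilic": (1.5, 12.0),
            "pro_directed": (1.5, 12.0),
            "tyrosine": (1.0, 40.0),
        }
    )
    inhibited_kinase: str | None = None
    treated_conditions: tuple[str, ...] = ()
    inhibitor_effect: float = 0.5
    direct_substrate_min_match: float = 0.5
    class_score_floor: float = 0.0

    def prior_for(self, kinase_class: str, residue: str) -> tuple[float, float]:
        if kinase_class in self.class_priors:
            return self.class_priors[kinase_class]
        return self.class_priors["tyrosine" if residue == "Y" else "pro_directed"]


@dataclass
class SiteTruth:
    protein_id: str
    position: int
    residue: str
    window: str
    peptide_window: str
    kinase_class: str
    best_kinase: str
    best_score: float
    stoichiometry: dict[str, float]
    direct_substrate_of: frozenset[str]
    inhibitor_effect: float
    planted_by: str
    back_phospho: dict[str, float] = field(default_factory=dict)

    @property
    def site_key(self) -> tuple[str, int, str]:
        return (self.protein_id, self.position, self.residue)


@dataclass
class GroundTruth:
    conditions: tuple[str, ...]
    sites: list[SiteTruth]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.sites:
            row = {
                "protein_id": s.protein_id,
                "position": s.position,
                "residue": s.residue,
                "window": s.window,
                "peptide_window": s.peptide_window,
                "kinase_class": s.kinase_class,
                "best_kinase": s.best_kinase,
                "best_score": s.best_score,
                "direct_substrate_of": ";".join(sorted(s.direct_substrate_of)),
                "inhibitor_effect": s.inhibitor_effect,
                "planted_by": s.planted_by,
            }
            for cond in self.conditions:
                row[f"stoich_{cond}"] = s.stoichiometry[cond]
            for kin, frac in s.back_phospho.items():
                row[f"back_{kin}"] = frac
            rows.append(row)
        return pd.DataFrame(rows)


def assign_ground_truth(
    sites: pd.DataFrame,
    kinase_models: Sequence[KinaseMotifModel],
    conditions: Sequence[str],
    params: TruthParams,
    seed: int,
) -> GroundTruth:
    """Draw per-site true stoichiometry and substrate structure.

    Kinase class comes from the best motif match on the protein-level
    window; base stoichiometry is Beta-distributed by class; direct
    substrates are sites whose match probability for a kinase reaches
    ``direct_substrate_min_match``.  Direct substrates of the inhibited
    kinase have their stoichiometry multiplied by ``inhibitor_effect`` in
    every treated condition.  Deterministic for fixed seed.
    """
    unknown = set(params.treated_conditions) - set(conditions)
    if unknown:
        raise InvalidParameterError(f"unknown treated condition(s): {sorted(unknown)}")
    bad = set(sites["residue"]) - set(ACCEPTOR_RESIDUES)
    if bad:
        raise InvalidParameterError(f"non-acceptor residues in sites: {sorted(bad)}")
    rng = substream(seed, "ground_truth")
    by_name = {m.name: m for m in kinase_models}
    out: list[SiteTruth] = []
    for row in sites.itertuples(index=False):
        assignment = assign_kinase_class(
            row.window, kinase_models, score_floor=params.class_score_floor
        )
        if assignment is None:
            kinase_class, best_kinase, best_score = "none", "", float("nan")
        else:
            best_kinase, best_score = assignment
            kinase_class = by_name[best_kinase].kinase_class
        direct = frozenset(
            m.name
            for m in kinase_models
            if match_probability(motif_score(row.window, m), m)
            >= params.direct_substrate_min_match
        )
        a, b = params.prior_for(kinase_class, row.residue)
        base = float(rng.beta(a, b))
        stoich = {}
        inhibited = (
            params.inhibited_kinase is not None and params.inhibited_kinase in direct
        )
        for cond in conditions:
            s = base
            if inhibited and cond in params.treated_conditions:
                s = base * params.inhibitor_effect
            stoich[cond] = s
        out.append(
            SiteTruth(
                protein_id=row.protein_id,
                position=row.position,
                residue=row.residue,
                window=row.window,
                peptide_window=row.peptide_window,
                kinase_class=kinase_class,
                best_kinase=best_kinase,
                best_score=best_score,
                stoichiometry=stoich,
                direct_substrate_of=direct,
                inhibitor_effect=params.inhibitor_effect if inhibited else 1.0,
                planted_by=row.planted_by,
            )
        )
    return GroundTruth(conditions=tuple(conditions), sites=out)


def uniform_ground_truth(
    n: int,
    stoichiometry: float,
    back_fraction: float,
    kinase: str = "CK2",
    conditions: Sequence[str] = ("DMSO", "CKi"),
) -> GroundTruth:
    """n identical sites with fixed occupancy and back-phosphorylation.

    A degenerate truth object for acquisition oracles: with every site
    sharing one channel-probability vector, reporter counts across sites
    are i.i.d. draws from the sampling model.
    """
    window = "A" * 7 + "S" + "A" * 7
    sites = [
        SiteTruth(
            protein_id=f"P{i:05d}",
            position=11,
            residue="S",
            window=window,
            peptide_window=window,
            kinase_class="acidophilic",
            best_kinase=kinase,
            best_score=4.0,
            stoichiometry={c: stoichiometry for c in conditions},
            direct_substrate_of=frozenset({kinase}),
            inhibitor_effect=1.0,
            planted_by=kinase,
            back_phospho={kinase: back_fraction},
        )
        for i in range(n)
    ]
    return GroundTruth(conditions=tuple(conditions), sites=sites)


# ---------------------------------------------------------------------------
# in vitro kinase reaction


def simulate_kinase_reaction(
    site: SiteTruth,
    kinase: KinaseMotifModel,
    efficiency: float,
    level: str = "peptide",
    source_condition: str | None = None,
    match_prob_override: float | None = None,
) -> float:
    """Back-phosphorylated fraction of one site in the motif-centric sample.

    ``efficiency x match_probability(score) x (1 - true stoichiometry)``,
    where the score is taken on the peptide-level window when
    ``level='peptide'`` — so a basophilic site whose required N-terminal
    K/R lies outside its tryptic peptide scores at background — and the
    stoichiometry is that of the condition the motif-centric sample was
    made from (default: first condition).
    """
    if not 0.0 <= efficiency <= 1.0:
        raise InvalidParameterError("efficiency must be in [0, 1]")
    if level not in ("protein", "peptide"):
        raise InvalidParameterError(f"level must be protein or peptide, got {level!r}")
    cond = source_condition or next(iter(site.stoichiometry))
    s = site.stoichiometry[cond]
    if match_prob_override is not None:
        m = match_prob_override
    else:
        window = site.peptide_window if level == "peptide" else site.window
        m = match_probability(motif_score(window, kinase), kinase)
    return efficiency * m * (1.0 - s)


def run_kinase_reactions(
    truth: GroundTruth,
    kinase: KinaseMotifModel,
    efficiency: float = 1.0,
    level: str = "peptide",
    source_condition: str | None = None,
    match_prob_override: float | None = None,
) -> None:
    """Fill ``back_phospho[kinase.name]`` for every site in the truth."""
    for site in truth.sites:
        site.back_phospho[kinase.name] = simulate_kinase_reaction(
            site, kinase, efficiency, level, source_condition, match_prob_override
        )


# ---------------------------------------------------------------------------
# acquisition


@dataclass(frozen=True)
class AcquisitionParams:
    """Instrument model of the reporter-ion read-out.

    ``ion_budget`` is the expected number of reporter ions per MS3 scan
    (AGC-like; default 5x10^4).  ``intensity_scale`` converts one unit of
    loading amount x phospho fraction into reporter abundance units; the
    default (2^40) calibrates typical detected sites at standard loading
    (25 units/channel) to a log2 summed sample intensity of roughly 41-45
    with a lognormal noise floor around 2^35, which makes the default
    acceptance threshold of 40 meaningful.  ``oracle_mode`` bypasses all
    sampling noise: reported intensities equal the true channel abundances
    exactly.
    """

    ms1_detection_threshold: float = 2.0**43
    id_probability_slope: float = 1.5
    id_probability_midpoint_log2: float = 43.5
    ion_budget: float = 5.0e4
    noise_floor_log2_mean: float = 35.0
    noise_floor_log2_sd: float = 1.5
    intensity_scale: float = 2.0**40
    multiplicative_cv: float = 0.0
    class1_fraction: float = 0.9
    oracle_mode: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ion_budget <= 0:
            raise InvalidParameterError("ion_budget must be > 0")
        if self.ms1_detection_threshold < 0:
            raise InvalidParameterError("ms1_detection_threshold must be >= 0")

    @classmethod
    def low_noise(cls, seed: int = 0, **overrides) -> "AcquisitionParams":
        """Everything detected and identified; mild multiplicative noise only."""
        kwargs = dict(
            ms1_detection_threshold=0.0,
            id_probability_midpoint_log2=0.0,
            ion_budget=1.0e7,
            noise_floor_log2_mean=25.0,
            noise_floor_log2_sd=0.5,
            multiplicative_cv=0.15,
            seed=seed,
        )
        kwargs.update(overrides)
        return cls(**kwargs)


def _logistic(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def channel_phospho_fractions(
    truth: GroundTruth, design: ChannelDesign, boost_kinase: str
) -> pd.DataFrame:
    """True phospho fraction of every site in every channel.

    Sample channels carry the endogenous stoichiometry of their condition;
    boost channels carry the motif-centric sample: source-condition
    stoichiometry plus the back-phosphorylated fraction (capped at 1).
    """
    rows = []
    for site in truth.sites:
        back = site.back_phospho.get(boost_kinase)
        if back is None:
            raise InvalidParameterError(
                f"no kinase reaction recorded for {boost_kinase!r}; "
                "call run_kinase_reactions first"
            )
        source = truth.conditions[0]
        row = {}
        for ch in design.channels:
            if design.roles[ch] == "boost":
                row[ch] = min(1.0, site.stoichiometry[source] + back)
            else:
                cond = design.roles[ch].split(":", 1)[1]
                row[ch] = site.stoichiometry[cond]
        rows.append(row)
    return pd.DataFrame(rows, columns=list(design.channels))


def simulate_tmt_experiment(
    truth: GroundTruth,
    design: ChannelDesign,
    per_channel_amounts: Mapping[str, float],
    acq: AcquisitionParams,
    boost_kinase: str,
    n_injections: int = 1,
    n_contaminants: int = 0,
) -> list[pd.DataFrame]:
    """Acquire one table of SiteQuantRecords per replicate injection.

    Detection and localization draws are per-site properties shared across
    injections (and across paired simulations with the same seed and
    sites); reporter sampling and noise are drawn fresh per injection.
    ``n_contaminants`` adds non-phosphopeptide background records (flagged
    ``is_phosphopeptide=False``) for enrichment-specificity accounting.
    """
    missing = set(design.channels) ^ set(per_channel_amounts)
    if missing:
        raise InvalidParameterError(f"amounts/design channel mismatch: {sorted(missing)}")
    amounts = np.array([float(per_channel_amounts[ch]) for ch in design.channels])
    if (amounts < 0).any():
        raise InvalidParameterError("loading amounts must be non-negative")

    fractions = channel_phospho_fractions(truth, design, boost_kinase).to_numpy()
    meta = pd.DataFrame(
        {
            "protein_id": [s.protein_id for s in truth.sites],
            "position": [s.position for s in truth.sites],
            "residue": [s.residue for s in truth.sites],
            "window": [s.window for s in truth.sites],
            "is_phosphopeptide": True,
        }
    )

    if n_contaminants:
        crng = substream(acq.seed, "contaminants")
        levels = crng.beta(2.0, 8.0, size=n_contaminants)
        cfrac = np.tile(levels[:, None], (1, len(design.channels)))
        fractions = np.vstack([fractions, cfrac])
        cmeta = pd.DataFrame(
            {
                "protein_id": [f"CONTAM{i + 1:05d}" for i in range(n_contaminants)],
                "position": 0,
                "residue": "-",
                "window": "",
                "is_phosphopeptide": False,
            }
        )
        meta = pd.concat([meta, cmeta], ignore_index=True)

    n = len(meta)
    abundance = acq.intensity_scale * fractions * amounts[None, :]
    total = abundance.sum(axis=1)

    detected = total > acq.ms1_detection_threshold
    with np.errstate(divide="ignore"):
        log2_total = np.where(total > 0, np.log2(np.maximum(total, 1e-300)), -np.inf)
    p_id = _logistic(
        acq.id_probability_slope * (log2_total - acq.id_probability_midpoint_log2)
    )
    if acq.oracle_mode:
        identified = detected
    else:
        u_id = substream(acq.seed, "identify").uniform(size=n)
        identified = detected & (u_id < p_id)

    loc_rng = substream(acq.seed, "localization")
    is_class1 = loc_rng.uniform(size=n) < acq.class1_fraction
    loc = np.where(
        is_class1,
        loc_rng.uniform(0.7501, 1.0, size=n),
        loc_rng.uniform(0.0, 0.75, size=n),
    )
    loc = np.where(meta["is_phosphopeptide"].to_numpy(), loc, 0.0)

    tables = []
    for inj in range(n_injections):
        if acq.oracle_mode:
            intensities = abundance.copy()
            counts = np.full_like(abundance, np.nan)
        else:
            rng = substream(acq.seed, "reporter", str(inj))
            probs = np.divide(
                abundance, total[:, None], out=np.zeros_like(abundance), where=total[:, None] > 0
            )
            # Poisson-total multinomial == independent Poissons per channel
            counts = rng.poisson(acq.ion_budget * probs).astype(float)
            unit = total / acq.ion_budget
            intensities = counts * unit[:, None]
            floor = 2.0 ** rng.normal(
                acq.noise_floor_log2_mean, acq.noise_floor_log2_sd, size=abundance.shape
            )
            intensities = np.where(counts > 0, intensities + floor, 0.0)
            if acq.multiplicative_cv > 0:
                sigma = np.sqrt(np.log1p(acq.multiplicative_cv**2))
                noise = rng.lognormal(-0.5 * sigma**2, sigma, size=abundance.shape)
                intensities = intensities * noise
        table = meta.copy()
        table["localization_prob"] = loc
        for j, ch in enumerate(design.channels):
            table[INTENSITY_PREFIX + ch] = intensities[:, j]
        for j, ch in enumerate(design.channels):
            table[COUNT_PREFIX + ch] = counts[:, j]
        tables.append(table[identified].reset_index(drop=True))
    return tables


# ---------------------------------------------------------------------------
# end-to-end simulation driver


@dataclass
class SimulationConfig:
    """Study conditions of one synthetic motif-centric experiment."""

    n_proteins: int = 300
    length_mean: float = 300.0
    composition: tuple[float, ...] | None = None
    n_sites: int = 2000
    planted: dict[str, int] = field(default_factory=dict)
    boost_kinase: str = "CK2"
    efficiency: float = 1.0
    reaction_level: str = "peptide"
    amounts: dict[str, float] | None = None
    n_injections: int = 1
    residue_ratio: tuple[float, float, float] = (90.0, 10.0, 0.05)
    specificity: float = 0.91
    consensus_concentration: float = 5.0
    assume_full_match: bool = False
    truth: TruthParams = field(default_factory=TruthParams)


@dataclass
class SimulationResult:
    proteins: list[ProteinEntry]
    truth: GroundTruth
    design: ChannelDesign
    tables: list[pd.DataFrame]
    config: SimulationConfig
    acq: AcquisitionParams

    @property
    def table(self) -> pd.DataFrame:
        return self.tables[0]


def run_simulation(
    design: ChannelDesign,
    models: Sequence[KinaseMotifModel],
    config: SimulationConfig,
    acq: AcquisitionParams,
    seed: int,
) -> SimulationResult:
    """Generate proteome -> plant motifs -> truth -> reaction -> acquisition."""
    by_name = {m.name: m for m in models}
    if config.boost_kinase not in by_name:
        raise InvalidParameterError(f"unknown boost kinase {config.boost_kinase!r}")
    proteins = generate_proteome(
        config.n_proteins, config.length_mean, config.composition, seed=seed
    )
    planted_map: dict[tuple[str, int], str] = {}
    if config.planted:
        proteins, planted_map = plant_motif_sites(
            proteins,
            by_name,
            config.planted,
            seed=seed,
            concentration=config.consensus_concentration,
        )
    candidates = enumerate_sites(proteins, w=by_name[config.boost_kinase].width, planted=planted_map)
    sites = select_phosphosites(candidates, config.n_sites, config.residue_ratio, seed=seed)
    truth = assign_ground_truth(sites, models, design.conditions, config.truth, seed=seed)
    run_kinase_reactions(
        truth,
        by_name[config.boost_kinase],
        efficiency=config.efficiency,
        level=config.reaction_level,
        match_prob_override=1.0 if config.assume_full_match else None,
    )
    amounts = config.amounts or {ch: 25.0 for ch in design.channels}
    acq = replace(acq, seed=acq.seed if acq.seed else seed)
    n_contam = int(round(config.n_sites * (1.0 - config.specificity) / config.specificity))
    tables = simulate_tmt_experiment(
        truth,
        design,
        amounts,
        acq,
        boost_kinase=config.boost_kinase,
        n_injections=config.n_injections,
        n_contaminants=n_contam,
    )
    return SimulationResult(
        proteins=proteins, truth=truth, design=design, tables=tables, config=config, acq=acq
    )
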