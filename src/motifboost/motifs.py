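"""Kinase sequence-specificity models and phosphosite window scoring.

Kinase specificity is represented as a position-specific log2-odds matrix
over a fixed window centred on the phospho-acceptor residue (default
half-width 7, i.e. a 15-mer), plus the set of residues the kinase can
phosphorylate.  A window's score is the sum of per-position log-odds; the
score is converted to a back-phosphorylation propensity through a logistic
calibration (``match_probability``).

The shipped default models (CK2, PKA, ERK2, JNK1, p38a, CDK1, SRC, EGFR)
encode textbook consensus preferences — acidic residues C-terminal for CK2,
basic residues at -3/-2 for PKA, Pro at +1 for the Pro-directed family,
acidic-context pY for SRC/EGFR — with documented, invented magnitudes.
They are deliberately transparent position-weight models, not a fitted
primary-sequence-preference scorer; users may load their own matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PAD = "_"
ACCEPTORS = frozenset("STY")
NEG_INF = float("-inf")

_AA_SET = frozenset(AMINO_ACIDS)
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class InvalidSiteError(ValueError):
    """Raised when a putative phosphosite is not a phospho-acceptor residue."""


@dataclass(frozen=True)
class SequenceWindow:
    """Fixed-width amino-acid context around a phospho-acceptor.

    ``residues`` has odd length ``2w + 1`` over the 20 canonical residues plus
    the padding symbol ``_`` (positions beyond the sequence ends); the centre
    residue must be S, T or Y.
    """

    residues: str

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n % 2 != 1:
            raise ValueError(f"window length must be odd, got {n}")
        bad = set(self.residues) - _AA_SET - {PAD}
        if bad:
            raise ValueError(f"invalid symbols in window: {sorted(bad)}")
        if self.center_residue not in ACCEPTORS:
            raise InvalidSiteError(
                f"center residue {self.center_residue!r} is not S/T/Y"
            )
        core = self.residues.strip(PAD)
        if PAD in core:
            raise ValueError("padding must form maximal runs at the window ends")

    @property
    def half_width(self) -> int:
        return len(self.residues) // 2

    @property
    def center_residue(self) -> str:
        return self.residues[len(self.residues) // 2]

    def residue_at(self, offset: int) -> str:
        """Residue at signed offset from the centre (0 = acceptor)."""
        return self.residues[self.half_width + offset]


@dataclass(frozen=True)
class KinaseMotifModel:
    """Position-specific log2-odds model of one kinase's site preference.

    ``logodds`` maps signed position offsets (never 0) to per-residue log2
    odds versus background; residues and positions not listed score 0.
    ``match_midpoint``/``match_slope`` calibrate the logistic that maps a
    score to a match probability used as back-phosphorylation propensity.
    """

    name: str
    kinase_class: str
    acceptor_residues: frozenset[str]
    width: int = 7
    logodds: dict[int, dict[str, float]] = field(default_factory=dict)
    match_midpoint: float = 2.0
    match_slope: float = 4.0

    def __post_init__(self) -> None:
        if not self.acceptor_residues <= ACCEPTORS:
            raise ValueError(f"acceptors must be within S/T/Y: {self.acceptor_residues}")
        if 0 in self.logodds:
            raise ValueError("position 0 (the acceptor) cannot carry log-odds")
        for pos, row in self.logodds.items():
            if abs(pos) > self.width:
                raise ValueError(f"position {pos} outside width {self.width}")
            bad = set(row) - _AA_SET
            if bad:
                raise ValueError(f"invalid residues at position {pos}: {sorted(bad)}")

    @property
    def max_score(self) -> float:
        """Best attainable score: sum of per-position row maxima (>= 0)."""
        return sum(max(max(row.values()), 0.0) for row in self.logodds.values())

    def position_probabilities(self, concentration: float = 5.0) -> dict[int, np.ndarray]:
        """Per-position residue sampling distribution of the model's consensus.

        Softmax of ``concentration * logodds`` over the 20 residues (uniform
        background); positions without a row are uniform.  Used by the
        simulator to plant substrate windows.
        """
        out: dict[int, np.ndarray] = {}
        for pos in range(-self.width, self.width + 1):
            if pos == 0:
                continue
            weights = np.ones(20)
            for aa, lo in self.logodds.get(pos, {}).items():
                weights[_AA_INDEX[aa]] = 2.0 ** (concentration * lo)
            out[pos] = weights / weights.sum()
        return out


def extract_window(sequence: str, position: int, w: int = 7) -> SequenceWindow:
    """Extract the ``2w + 1`` window centred on a 1-based S/T/Y position.

    Positions beyond the sequence ends are padded with ``_``; the same call
    on a tryptic peptide therefore shows the peptide-level context (residues
    outside the peptide appear as padding).
    """
    if not 1 <= position <= len(sequence):
        raise IndexError(f"position {position} outside sequence of length {len(sequence)}")
    center = sequence[position - 1]
    if center not in ACCEPTORS:
        raise InvalidSiteError(f"residue {center!r} at position {position} is not S/T/Y")
    lo = position - 1 - w
    hi = position + w
    left_pad = max(0, -lo)
    right_pad = max(0, hi - len(sequence))
    residues = PAD * left_pad + sequence[max(lo, 0) : min(hi, len(sequence))] + PAD * right_pad
    return SequenceWindow(residues)


def motif_score(window: SequenceWindow | str, model: KinaseMotifModel) -> float:
    """Sum of per-position log2 odds; ``-inf`` when the acceptor is not accepted.

    Padding and unlisted residues contribute 0, so a window of pure padding
    scores exactly 0 (uninformative).
    """
    if isinstance(window, str):
        window = SequenceWindow(window)
    if window.half_width != model.width:
        raise ValueError(
            f"window half-width {window.half_width} != model width {model.width}"
        )
    if window.center_residue not in model.acceptor_residues:
        return NEG_INF
    score = 0.0
    for pos, row in model.logodds.items():
        score += row.get(window.residue_at(pos), 0.0)
    return score


def match_probability(score: float, model: KinaseMotifModel) -> float:
    """Logistic map from log-odds score to [0, 1] match probability."""
    if score == NEG_INF:
        return 0.0
    x = (score - model.match_midpoint) * model.match_slope
    # stable logistic
    if x >= 0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return float(e / (1.0 + e))


def assign_kinase_class(
    window: SequenceWindow | str,
    models: Sequence[KinaseMotifModel],
    score_floor: float = 0.0,
) -> tuple[str, float] | None:
    """Best-scoring model whose acceptors include the centre residue.

    Returns ``(model name, score)`` for the argmax among models scoring
    strictly above ``score_floor``; ties go to the earlier model in the
    list.  Returns ``None`` when no model qualifies.
    """
    if not models:
        raise ValueError("at least one model required")
    if isinstance(window, str):
        window = SequenceWindow(window)
    best: tuple[str, float] | None = None
    for model in models:
        s = motif_score(window, model)
        if s == NEG_INF or s <= score_floor:
            continue
        if best is None or s > best[1]:
            best = (model.name, s)
    return best


def sample_window(
    model: KinaseMotifModel,
    rng: np.random.Generator,
    concentration: float = 5.0,
    center_residue: str | None = None,
) -> str:
    """Draw a window string from the model's consensus distribution."""
    probs = model.position_probabilities(concentration)
    if center_residue is None:
        center_residue = str(rng.choice(sorted(model.acceptor_residues)))
    chars = []
    for pos in range(-model.width, model.width + 1):
        if pos == 0:
            chars.append(center_residue)
        else:
            chars.append(AMINO_ACIDS[rng.choice(20, p=probs[pos])])
    return "".join(chars)


def _parse_model(entry: dict, width: int) -> KinaseMotifModel:
    logodds = {
        int(pos): {aa: float(v) for aa, v in row.items()}
        for pos, row in entry.get("logodds", {}).items()
    }
    return KinaseMotifModel(
        name=entry["name"],
        kinase_class=entry["kinase_class"],
        acceptor_residues=frozenset(entry["acceptor_residues"]),
        width=int(entry.get("width", width)),
        logodds=logodds,
        match_midpoint=float(entry.get("match_midpoint", 2.0)),
        match_slope=float(entry.get("match_slope", 4.0)),
    )


def load_models(path: str | None = None) -> list[KinaseMotifModel]:
    """Load motif models from JSON; the shipped defaults when ``path`` is None."""
    if path is None:
        text = resources.files("motifboost.data").joinpath("kinase_models.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    width = int(doc.get("width", 7))
    return [_parse_model(entry, width) for entry in doc["models"]]


def models_by_name(models: Iterable[KinaseMotifModel]) -> dict[str, KinaseMotifModel]:
    return {m.name: m for m in models}
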