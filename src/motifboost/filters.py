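"""Acceptance criteria and summary metrics for boosted TMT site tables.

In a motif-centric boosting experiment one or two TMT channels carry an
abundant in-vitro-phosphorylated ("motif-centric") sample whose role is to
raise MS1 precursor signal.  Because reporter-ion sampling is ion-budget
limited, an over-loaded boost channel starves the sample channels, so sites
are only accepted for quantification when

(a) the boost ratio (boost-channel signal over mean sample-channel signal)
    is defined and strictly below a maximum (default 100),
(b) the log2 total sample-channel intensity is strictly above a noise
    threshold (default 40, matching the notch between the noise floor and
    the signal population on the calibrated intensity scale),
(c) enough sample channels carry non-zero signal (default: at least 2 valid
    values within at least one duplicate preparation), and
(d) the site is class 1 (localization probability > 0.75) when requested.

All criteria are evaluated independently and kept as auditable per-record
flags alongside the overall verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

SiteKey = tuple[str, int, str]  # (protein_id, 1-based position, residue)

INTENSITY_PREFIX = "intensity_"
COUNT_PREFIX = "count_"


class SchemaError(ValueError):
    """Raised when a table does not match the channel design or dialect."""


@dataclass(frozen=True)
class ChannelDesign:
    """Maps TMT channel labels to roles and duplicate structure.

    ``roles`` assigns each channel either ``"sample:<condition>"`` or
    ``"boost"``.  ``duplicate_sets`` partitions the sample channels into
    replicate preparations; with one boost channel per preparation, the
    i-th boost channel is paired with the i-th duplicate set (used for
    stoichiometry replicate pairs).  ``boost_ratio_samples`` optionally
    designates the sample channels used in the boost-ratio denominator
    (e.g. 127 and 129 in the 6-plex pY design, where the ratio is the
    131 signal over the average of 127 and 129); default all sample
    channels.
    """

    channels: tuple[str, ...]
    roles: Mapping[str, str]
    duplicate_sets: tuple[tuple[str, ...], ...]
    boost_ratio_samples: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if set(self.roles) != set(self.channels):
            raise ValueError("roles must cover exactly the design channels")
        for ch, role in self.roles.items():
            if role != "boost" and not role.startswith("sample:"):
                raise ValueError(f"bad role {role!r} for channel {ch}")
        if len(self.boost_channels) < 1 or len(self.sample_channels) < 2:
            raise ValueError("need >=1 boost and >=2 sample channels")
        flat = [ch for ds in self.duplicate_sets for ch in ds]
        if sorted(flat) != sorted(self.sample_channels):
            raise ValueError("duplicate_sets must partition the sample channels")
        if self.boost_ratio_samples is not None:
            if not set(self.boost_ratio_samples) <= set(self.sample_channels):
                raise ValueError("boost_ratio_samples must be sample channels")

    @property
    def sample_channels(self) -> tuple[str, ...]:
        return tuple(ch for ch in self.channels if self.roles[ch] != "boost")

    @property
    def boost_channels(self) -> tuple[str, ...]:
        return tuple(ch for ch in self.channels if self.roles[ch] == "boost")

    @property
    def conditions(self) -> tuple[str, ...]:
        seen: list[str] = []
        for ch in self.sample_channels:
            cond = self.roles[ch].split(":", 1)[1]
            if cond not in seen:
                seen.append(cond)
        return tuple(seen)

    def condition_channels(self, condition: str) -> tuple[str, ...]:
        out = tuple(
            ch for ch in self.sample_channels
            if self.roles[ch].split(":", 1)[1] == condition
        )
        if not out:
            raise ValueError(f"unknown condition {condition!r}")
        return out

    def ratio_denominator_channels(self) -> tuple[str, ...]:
        return self.boost_ratio_samples or self.sample_channels

    def replicate_pairs(self, endo_condition: str) -> list[tuple[str, str]]:
        """(endogenous channel, boost channel) pairs across duplicate preps."""
        endo = set(self.condition_channels(endo_condition))
        boosts = self.boost_channels
        pairs = []
        for i, dset in enumerate(self.duplicate_sets):
            b = boosts[i % len(boosts)]
            pairs.extend((ch, b) for ch in dset if ch in endo)
        return pairs


def ck2_design() -> ChannelDesign:
    """6-plex CK2 design: DMSO 126/129, CK2-inhibitor 127/130, boost 128/131."""
    return ChannelDesign(
        channels=("126", "127", "128", "129", "130", "131"),
        roles={
            "126": "sample:DMSO", "127": "sample:CKi", "128": "boost",
            "129": "sample:DMSO", "130": "sample:CKi", "131": "boost",
        },
        duplicate_sets=(("126", "127"), ("129", "130")),
    )


def py_design() -> ChannelDesign:
    """6-plex pY design: EGF 126/128, EGF+afatinib 127/129, spare 130, boost 131.

    The boost ratio is defined as the 131 signal over the average of the
    127 and 129 signals.
    """
    return ChannelDesign(
        channels=("126", "127", "128", "129", "130", "131"),
        roles={
            "126": "sample:EGF", "127": "sample:EGF_afatinib",
            "128": "sample:EGF", "129": "sample:EGF_afatinib",
            "130": "sample:EGF", "131": "boost",
        },
        duplicate_sets=(("126", "127"), ("128", "129"), ("130",)),
        boost_ratio_samples=("127", "129"),
    )


def titration_design() -> ChannelDesign:
    """Boost-titration design: four untreated sample channels, one boost."""
    return ChannelDesign(
        channels=("126", "127", "129", "130", "131"),
        roles={
            "126": "sample:endo", "127": "sample:endo",
            "129": "sample:endo", "130": "sample:endo", "131": "boost",
        },
        duplicate_sets=(("126", "127"), ("129", "130")),
    )


@dataclass(frozen=True)
class SiteQuantRecord:
    """One phosphosite row: per-channel reporter intensities plus metadata.

    Intensity 0 (or an absent channel) encodes a missing value, following
    the MaxQuant reporter-intensity convention.
    """

    site_key: SiteKey
    window: str
    localization_probability: float
    intensities: Mapping[str, float]
    is_phosphopeptide: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.localization_probability <= 1.0:
            raise ValueError("localization probability outside [0, 1]")
        if any(v < 0 for v in self.intensities.values()):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class FilterCriteria:
    """Thresholds of the acceptance criteria (all strict inequalities)."""

    boost_ratio_max: float = 100.0
    log2_total_sample_intensity_min: float = 40.0
    min_valid_channels: int = 2
    require_valid_in_one_duplicate_set: bool = True
    class1_min_localization: float = 0.75
    require_class1: bool = True

    def __post_init__(self) -> None:
        if min(
            self.boost_ratio_max,
            self.log2_total_sample_intensity_min,
            self.min_valid_channels,
            self.class1_min_localization,
        ) <= 0:
            raise ValueError("all thresholds must be positive")


# ---------------------------------------------------------------------------
# table helpers

def intensity_columns(design: ChannelDesign) -> list[str]:
    return [INTENSITY_PREFIX + ch for ch in design.channels]


def records_to_frame(records: Iterable[SiteQuantRecord], design: ChannelDesign) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "protein_id": r.site_key[0],
            "position": r.site_key[1],
            "residue": r.site_key[2],
            "window": r.window,
            "localization_prob": r.localization_probability,
            "is_phosphopeptide": r.is_phosphopeptide,
        }
        for ch in design.channels:
            row[INTENSITY_PREFIX + ch] = float(r.intensities.get(ch, 0.0))
        rows.append(row)
    return pd.DataFrame(rows)


def _check_frame(frame: pd.DataFrame, design: ChannelDesign) -> None:
    missing = [c for c in intensity_columns(design) if c not in frame.columns]
    if missing:
        raise SchemaError(f"table lacks intensity columns for design channels: {missing}")


# ---------------------------------------------------------------------------
# operations

def boost_ratio(record: SiteQuantRecord, design: ChannelDesign) -> float | None:
    """Mean boost-channel intensity over mean designated sample intensity.

    Returns None (undefined, not an error) when the denominator is 0.
    """
    boost = np.mean([record.intensities.get(ch, 0.0) for ch in design.boost_channels])
    denom = np.mean(
        [record.intensities.get(ch, 0.0) for ch in design.ratio_denominator_channels()]
    )
    if denom == 0:
        return None
    return float(boost / denom)


def boost_ratio_column(frame: pd.DataFrame, design: ChannelDesign) -> pd.Series:
    """Vectorized boost ratio; NaN where undefined (zero denominator)."""
    _check_frame(frame, design)
    boost = frame[[INTENSITY_PREFIX + ch for ch in design.boost_channels]].mean(axis=1)
    denom = frame[
        [INTENSITY_PREFIX + ch for ch in design.ratio_denominator_channels()]
    ].mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = boost / denom
    return ratio.where(denom > 0, np.nan).rename("boost_ratio")


def count_valid_channels(
    record: SiteQuantRecord | Mapping[str, float], channel_group: Sequence[str]
) -> int:
    """Number of channels in the group with a present, strictly positive value."""
    intens = record.intensities if isinstance(record, SiteQuantRecord) else record
    return sum(1 for ch in channel_group if intens.get(ch, 0.0) > 0)


def apply_acceptance_criteria(
    frame: pd.DataFrame, design: ChannelDesign, criteria: FilterCriteria = FilterCriteria()
) -> pd.DataFrame:
    """Annotate a site table with per-criterion pass flags and the verdict.

    Adds columns ``boost_ratio``, ``log2_total_sample_intensity``,
    ``pass_boost_ratio``, ``pass_intensity``, ``pass_valid_channels``,
    ``pass_localization`` and ``pass_all``; the input is not modified.
    """
    _check_frame(frame, design)
    out = frame.copy()
    ratio = boost_ratio_column(frame, design)
    out["boost_ratio"] = ratio
    pass_ratio = ratio.notna() & (ratio < criteria.boost_ratio_max)

    sample_cols = [INTENSITY_PREFIX + ch for ch in design.sample_channels]
    total = frame[sample_cols].sum(axis=1)
    with np.errstate(divide="ignore"):
        log2_total = np.log2(total.where(total > 0, np.nan))
    out["log2_total_sample_intensity"] = log2_total
    pass_intensity = (total > 0) & (
        log2_total > criteria.log2_total_sample_intensity_min
    )

    valid = frame[sample_cols].to_numpy() > 0
    col_of = {ch: i for i, ch in enumerate(design.sample_channels)}
    if criteria.require_valid_in_one_duplicate_set:
        per_set = [
            valid[:, [col_of[ch] for ch in dset]].sum(axis=1) >= criteria.min_valid_channels
            for dset in design.duplicate_sets
        ]
        pass_valid = np.logical_or.reduce(per_set)
    else:
        pass_valid = valid.sum(axis=1) >= criteria.min_valid_channels

    if criteria.require_class1:
        pass_loc = frame["localization_prob"] > criteria.class1_min_localization
    else:
        pass_loc = pd.Series(True, index=frame.index)

    out["pass_boost_ratio"] = pass_ratio.to_numpy()
    out["pass_intensity"] = pass_intensity.fillna(False).to_numpy()
    out["pass_valid_channels"] = pass_valid
    out["pass_localization"] = pass_loc.to_numpy()
    out["pass_all"] = (
        out["pass_boost_ratio"]
        & out["pass_intensity"]
        & out["pass_valid_channels"]
        & out["pass_localization"]
    )
    return out


def attrition_counts(flagged: pd.DataFrame) -> dict[str, int]:
    """Per-criterion failure counts and the overall pass count."""
    return {
        "input": int(len(flagged)),
        "fail_boost_ratio": int((~flagged["pass_boost_ratio"]).sum()),
        "fail_intensity": int((~flagged["pass_intensity"]).sum()),
        "fail_valid_channels": int((~flagged["pass_valid_channels"]).sum()),
        "fail_localization": int((~flagged["pass_localization"]).sum()),
        "pass_all": int(flagged["pass_all"].sum()),
    }


def enrichment_specificity(frame: pd.DataFrame) -> float:
    """Fraction of records flagged as phosphopeptides; NaN for an empty table."""
    if len(frame) == 0:
        return float("nan")
    return float(frame["is_phosphopeptide"].mean())


def intensity_notch_threshold(
    log2_intensities: Sequence[float], grid_size: int = 512
) -> float | None:
    """Locate the notch separating noise from signal in a log2-intensity sample.

    Fits a Gaussian KDE (Scott bandwidth), finds the two largest density
    modes and returns the deepest interior minimum between them; None when
    the smoothed density is unimodal.
    """
    x = np.asarray(log2_intensities, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3 or np.ptp(x) == 0:
        return None
    kde = gaussian_kde(x)
    grid = np.linspace(x.min() - 1.0, x.max() + 1.0, grid_size)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.flatnonzero(interior) + 1
    # discard spurious tail ripples: a mode must carry real density
    peaks = peaks[dens[peaks] >= 0.05 * dens.max()]
    if len(peaks) < 2:
        return None
    top_two = peaks[np.argsort(dens[peaks])[-2:]]
    lo, hi = int(top_two.min()), int(top_two.max())
    if hi - lo < 2:
        return None
    valley = lo + 1 + int(np.argmin(dens[lo + 1 : hi]))
    if dens[valley] > 0.95 * min(dens[lo], dens[hi]):
        return None  # no real notch between the modes
    return float(grid[valley])
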