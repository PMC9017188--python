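"""Inhibitor-response classification and phosphorylation stoichiometry.

Two TMT ratio contrasts drive the direct-substrate logic: treated vs
control sample channels (does the inhibitor reduce the site?) and the
motif-centric boost channel vs treated (does the in vitro kinase reaction
raise it?).  Sites significantly down after inhibition split into group A
(no significant motif-channel increase) and group B (significant increase
= inferred direct substrates of the assay kinase).

Stoichiometry is the endogenous-channel signal over the motif-centric
channel signal, assuming complete in vitro conversion of the
unphosphorylated fraction: if the back-phosphorylation drives the site to
100% occupancy in the boost channel, the endogenous/boost intensity ratio
is the fraction phosphorylated in vivo.  Incomplete conversion inflates
the estimate, which is why estimates are clipped (and flagged) at 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .filters import INTENSITY_PREFIX, ChannelDesign

SITE_COLS = ["protein_id", "position", "residue"]


def log2_transform_normalize(
    frame: pd.DataFrame, design: ChannelDesign, method: str = "none"
) -> pd.DataFrame:
    """Log2-transform intensity columns; optionally median-centre per channel.

    Zero/missing intensities become NaN.  ``method='none'`` (default)
    applies no normalization beyond the log transform.
    """
    if method not in ("none", "median_center"):
        raise ValueError(f"unknown normalization method {method!r}")
    out = frame.copy()
    for ch in design.channels:
        col = INTENSITY_PREFIX + ch
        vals = out[col].to_numpy(dtype=float)
        with np.errstate(divide="ignore"):
            logged = np.where(vals > 0, np.log2(np.maximum(vals, 1e-300)), np.nan)
        if method == "median_center":
            logged = logged - np.nanmedian(logged)
        out[col] = logged
    return out


def ratio_test(
    group1: Sequence[float], group2: Sequence[float], equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sided two-sample t test on log2 values.

    Returns ``(mean log2 ratio, t, p)`` with ratio = mean(group1) -
    mean(group2).  Degenerate inputs (both groups constant) give t=0, p=1
    when the means coincide and t=inf, p=0 otherwise; fewer than 2
    observations in either group gives NaNs.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    g1, g2 = g1[np.isfinite(g1)], g2[np.isfinite(g2)]
    if len(g1) < 2 or len(g2) < 2:
        return (float("nan"), float("nan"), float("nan"))
    diff = float(g1.mean() - g2.mean())
    if g1.var(ddof=1) == 0 and g2.var(ddof=1) == 0:
        if diff == 0:
            return (diff, 0.0, 1.0)
        return (diff, float("inf") if diff > 0 else float("-inf"), 0.0)
    t, p = stats.ttest_ind(g1, g2, equal_var=equal_var)
    return (diff, float(t), float(p))


def _site_observations(
    tables: Iterable[pd.DataFrame], channels: Sequence[str]
) -> pd.DataFrame:
    """Long table of log2 intensities per site x channel x injection."""
    frames = []
    for inj, table in enumerate(tables):
        cols = [INTENSITY_PREFIX + ch for ch in channels]
        sub = table[SITE_COLS + cols].melt(
            id_vars=SITE_COLS, value_vars=cols, var_name="channel", value_name="intensity"
        )
        sub["channel"] = sub["channel"].str.removeprefix(INTENSITY_PREFIX)
        sub["injection"] = inj
        frames.append(sub)
    long = pd.concat(frames, ignore_index=True)
    long = long[long["intensity"] > 0].copy()
    long["log2_intensity"] = np.log2(long["intensity"])
    return long


def regulation_results(
    tables: Sequence[pd.DataFrame],
    design: ChannelDesign,
    control: str,
    treated: str,
    equal_var: bool = True,
    min_obs: int = 2,
) -> pd.DataFrame:
    """Per-site treatment and motif-channel contrasts.

    Observations are log2 intensities pooled over duplicate channels and
    replicate injections.  ``log2_ratio_treatment`` is treated vs control;
    ``log2_ratio_motif`` is the motif-centric boost channels vs treated.
    Sites with fewer than ``min_obs`` observations in a group get an
    undefined (NaN) result for that contrast.
    """
    groups = {
        "control": design.condition_channels(control),
        "treated": design.condition_channels(treated),
        "motif": design.boost_channels,
    }
    long = _site_observations(tables, design.channels)
    role = {}
    for name, chans in groups.items():
        for ch in chans:
            role[ch] = name
    long["group"] = long["channel"].map(role)
    long = long.dropna(subset=["group"])

    rows = []
    for key, sub in long.groupby(SITE_COLS, sort=True):
        obs = {
            name: sub.loc[sub["group"] == name, "log2_intensity"].to_numpy()
            for name in groups
        }
        r_t, t_t, p_t = ratio_test(obs["treated"], obs["control"], equal_var)
        r_m, t_m, p_m = ratio_test(obs["motif"], obs["treated"], equal_var)
        rows.append(
            {
                "protein_id": key[0],
                "position": key[1],
                "residue": key[2],
                "n_control": len(obs["control"]),
                "n_treated": len(obs["treated"]),
                "n_motif": len(obs["motif"]),
                "log2_ratio_treatment": r_t,
                "t_treatment": t_t,
                "p_treatment": p_t,
                "log2_ratio_motif": r_m,
                "t_motif": t_m,
                "p_motif": p_m,
            }
        )
    return pd.DataFrame(rows)


def classify_sites(
    results: pd.DataFrame,
    alpha: float = 0.05,
    min_abs_log2_ratio: float = 0.0,
    add_qvalues: bool = True,
) -> pd.DataFrame:
    """Assign direction (up/down/unchanged) and group (A/B/none).

    Down: p_treatment < alpha and log2 treatment ratio < -min_abs_log2_ratio
    (up symmetric).  Group B: down sites whose motif-channel contrast is
    significantly positive (inferred direct substrates); group A: the
    remaining down sites.  Benjamini-Hochberg q-values are reported
    alongside but do not enter the default classification (raw p < alpha,
    matching standard Perseus-style practice).
    """
    out = results.copy()
    p_t = out["p_treatment"].to_numpy()
    r_t = out["log2_ratio_treatment"].to_numpy()
    sig_t = np.nan_to_num(p_t, nan=1.0) < alpha
    down = sig_t & (r_t < -min_abs_log2_ratio)
    up = sig_t & (r_t > min_abs_log2_ratio)
    out["direction"] = np.select([down, up], ["down", "up"], default="unchanged")

    p_m = out["p_motif"].to_numpy()
    r_m = out["log2_ratio_motif"].to_numpy()
    motif_up = (np.nan_to_num(p_m, nan=1.0) < alpha) & (r_m > 0)
    out["group"] = np.select(
        [down & motif_up, down & ~motif_up], ["B", "A"], default="none"
    )
    if add_qvalues:
        for col in ("p_treatment", "p_motif"):
            q = np.full(len(out), np.nan)
            ok = np.isfinite(out[col].to_numpy())
            if ok.any():
                q[ok] = multipletests(out[col].to_numpy()[ok], method="fdr_bh")[1]
            out[col.replace("p_", "q_")] = q
    return out


# ---------------------------------------------------------------------------
# stoichiometry


@dataclass(frozen=True)
class StoichiometryEstimate:
    site_key: tuple[str, int, str]
    condition: str
    stoichiometry: float
    n_used: int
    clipped: bool
    undefined: bool


def stoichiometry_for_record(
    intensities: Mapping[str, float], design: ChannelDesign, endo_condition: str
) -> tuple[float, int, bool, bool]:
    """(value, n pairs used, clipped, undefined) for one record's channel map.

    Value is the median over replicate (endogenous, boost) channel pairs
    of endogenous/boost intensity; pairs with missing boost signal are
    skipped, and a record with no usable pair is undefined.
    """
    ratios = []
    for endo_ch, boost_ch in design.replicate_pairs(endo_condition):
        e = float(intensities.get(endo_ch, 0.0))
        b = float(intensities.get(boost_ch, 0.0))
        if b > 0 and e > 0:
            ratios.append(e / b)
    if not ratios:
        return (float("nan"), 0, False, True)
    value = float(np.median(ratios))
    clipped = value > 1.0
    return (min(value, 1.0), len(ratios), clipped, False)


def estimate_stoichiometry(
    tables: Sequence[pd.DataFrame] | pd.DataFrame,
    design: ChannelDesign,
    endo_condition: str,
) -> pd.DataFrame:
    """Per-site stoichiometry in one condition, pooled across injections.

    The median is taken over all (replicate pair x injection) ratios; the
    ``clipped`` flag marks estimates above 1 (incomplete in vitro
    conversion inflates the ratio), ``undefined`` marks sites with no
    usable boost signal.
    """
    if isinstance(tables, pd.DataFrame):
        tables = [tables]
    pairs = design.replicate_pairs(endo_condition)
    per_site: dict[tuple, list[float]] = {}
    seen: dict[tuple, None] = {}
    for table in tables:
        for row in table.itertuples(index=False):
            key = (row.protein_id, row.position, row.residue)
            seen.setdefault(key, None)
            for endo_ch, boost_ch in pairs:
                e = getattr(row, f"{INTENSITY_PREFIX}{endo_ch}", 0.0)
                b = getattr(row, f"{INTENSITY_PREFIX}{boost_ch}", 0.0)
                if b > 0 and e > 0:
                    per_site.setdefault(key, []).append(e / b)
    rows = []
    for key in seen:
        ratios = per_site.get(key, [])
        if ratios:
            value = float(np.median(ratios))
            rows.append(
                {
                    "protein_id": key[0],
                    "position": key[1],
                    "residue": key[2],
                    "condition": endo_condition,
                    "stoichiometry": min(value, 1.0),
                    "n_used": len(ratios),
                    "clipped": value > 1.0,
                    "undefined": False,
                }
            )
        else:
            rows.append(
                {
                    "protein_id": key[0],
                    "position": key[1],
                    "residue": key[2],
                    "condition": endo_condition,
                    "stoichiometry": float("nan"),
                    "n_used": 0,
                    "clipped": False,
                    "undefined": True,
                }
            )
    return pd.DataFrame(rows).sort_values(SITE_COLS, ignore_index=True)


def cumulative_stoichiometry_curve(estimates: pd.DataFrame | Sequence[float]) -> pd.DataFrame:
    """Ascending stoichiometry vs cumulative fraction percent.

    Ties share the higher rank, so equal values collapse to a single step.
    """
    if isinstance(estimates, pd.DataFrame):
        values = estimates.loc[~estimates["undefined"], "stoichiometry"].to_numpy()
    else:
        values = np.asarray(list(estimates), dtype=float)
    values = values[np.isfinite(values)]
    if values.size == 0:
        return pd.DataFrame(columns=["stoichiometry", "cumulative_percent"])
    s = pd.Series(np.sort(values))
    ranks = s.rank(method="max")
    frame = pd.DataFrame(
        {"stoichiometry": s, "cumulative_percent": ranks / len(s) * 100.0}
    )
    return frame.drop_duplicates(subset="stoichiometry", keep="last", ignore_index=True)


def overlap_analysis(site_sets: Mapping[str, set]) -> pd.DataFrame:
    """Exact pairwise intersections plus per-set and union/total counts."""
    rows = [
        {"sets": name, "count": len(s)} for name, s in site_sets.items()
    ]
    for a, b in combinations(site_sets, 2):
        rows.append({"sets": f"{a}&{b}", "count": len(site_sets[a] & site_sets[b])})
    all_sets = list(site_sets.values())
    if all_sets:
        union = set().union(*all_sets)
        inter = set(all_sets[0]).intersection(*all_sets[1:]) if len(all_sets) > 1 else set(all_sets[0])
        rows.append({"sets": "union", "count": len(union)})
        rows.append({"sets": "intersection", "count": len(inter)})
    return pd.DataFrame(rows)
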