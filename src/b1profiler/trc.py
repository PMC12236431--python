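"""Dissolved thiamine-related compound (TRC) depth-profile statistics.

Ingests long-format concentration tables of dissolved B1 and its congeners
(HMP, HET, cHET, AmMP) with technical replicates, attaches CTD context
(dissolved oxygen), labels oxygen-minimum-zone (OMZ) depths, and computes
replicate summaries, OMZ fold changes, and local concentration maxima.

Operational OMZ definition: dissolved oxygen <= 30 µmol kg⁻¹, with a core at
<= 10 µmol kg⁻¹ (both inclusive). Concentrations are normalized to pM on
ingest; fM inputs are accepted via a units column.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .ecology import assign_depth_layer
from .errors import ConfigurationError, ConsistencyError, ParseError

COMPOUNDS = ("B1", "HMP", "HET", "cHET", "AmMP")
CAMPAIGNS = ("autumn2018", "spring2019")

OMZ_DO_MAX = 30.0       # µmol kg⁻¹, inclusive
OMZ_CORE_DO_MAX = 10.0  # µmol kg⁻¹, inclusive

_UNIT_TO_PM = {"pM": 1.0, "fM": 1e-3, "nM": 1e3}

PROFILE_KEY = ["station", "campaign", "compound", "depth_m"]


def read_trc_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format TRC table and normalize concentrations to pM.

    Expected columns: station, campaign, depth_m, compound, replicate_id,
    concentration, and optionally units (default pM).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"station", "campaign", "depth_m", "compound", "replicate_id",
                "concentration"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"TRC table missing columns {sorted(missing)}", path=str(path))
    if "units" not in df.columns:
        df["units"] = "pM"
    bad_units = sorted(set(df["units"]) - set(_UNIT_TO_PM))
    if bad_units:
        raise ParseError(f"unknown concentration units {bad_units}", path=str(path))
    bad_compounds = sorted(set(df["compound"]) - set(COMPOUNDS))
    if bad_compounds:
        raise ParseError(f"unknown compounds {bad_compounds}", path=str(path))
    df["concentration"] = df["concentration"].astype(float) * df["units"].map(_UNIT_TO_PM)
    df = df.drop(columns=["units"])
    if (df["concentration"] < 0).any():
        raise ParseError("negative concentrations", path=str(path))
    return df


def read_ctd_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"station", "campaign", "depth_m", "dissolved_oxygen"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"CTD table missing columns {sorted(missing)}", path=str(path))
    if (df["dissolved_oxygen"] < 0).any():
        raise ParseError("negative dissolved oxygen", path=str(path))
    return df


def replicate_stats(measurements: pd.DataFrame) -> pd.DataFrame:
    """Per-(station, campaign, compound, depth) replicate mean, sd, and n.

    The sd uses the n-1 denominator and is 0 for single replicates.
    Input is a long table with one row per replicate (``concentration`` in pM).
    """
    if measurements.empty:
        raise ConsistencyError("empty measurement table")
    if (measurements["concentration"] < 0).any():
        raise ConsistencyError("negative concentrations")

    def _agg(x: pd.Series) -> pd.Series:
        return pd.Series({
            "mean_pm": x.mean(),
            "sd_pm": x.std(ddof=1) if len(x) > 1 else 0.0,
            "n": len(x),
        })

    out = (
        measurements.groupby(PROFILE_KEY)["concentration"]
        .apply(_agg).unstack().reset_index()
    )
    out["n"] = out["n"].astype(int)
    return out.sort_values(PROFILE_KEY).reset_index(drop=True)


def assign_oxygen_layers(
    profile: pd.DataFrame,
    ctd: pd.DataFrame,
    depth_tolerance_m: float = 5.0,
) -> pd.DataFrame:
    """Attach depth-layer labels and OMZ flags to profile rows.

    Each (station, campaign, depth) is matched to the nearest CTD depth for
    the same station/campaign within ``depth_tolerance_m``; the OMZ flag is
    DO <= 30 µmol kg⁻¹ and the core flag DO <= 10 µmol kg⁻¹ (inclusive).
    """
    out = profile.copy()
    do_vals: list[float] = []
    unmatched: list[tuple] = []
    for row in out.itertuples(index=False):
        sub = ctd[(ctd["station"] == row.station) & (ctd["campaign"] == row.campaign)]
        if sub.empty:
            unmatched.append((row.station, row.campaign, row.depth_m))
            do_vals.append(np.nan)
            continue
        gaps = (sub["depth_m"] - row.depth_m).abs()
        if gaps.min() > depth_tolerance_m:
            unmatched.append((row.station, row.campaign, row.depth_m))
            do_vals.append(np.nan)
            continue
        do_vals.append(float(sub.loc[gaps.idxmin(), "dissolved_oxygen"]))
    if unmatched:
        raise ConsistencyError(
            f"no CTD context within {depth_tolerance_m} m for depths: {unmatched}"
        )
    out["dissolved_oxygen"] = do_vals
    out["layer"] = out["depth_m"].map(assign_depth_layer)
    out["omz"] = out["dissolved_oxygen"] <= OMZ_DO_MAX
    out["omz_core"] = out["dissolved_oxygen"] <= OMZ_CORE_DO_MAX
    return out


@dataclass(frozen=True)
class FoldChange:
    """An OMZ/reference concentration ratio plus how it was computed."""

    value: float
    rule: str
    reference_mean_pm: float
    target_summary_pm: float
    reference_depths: tuple[float, ...]
    target_depths: tuple[float, ...]


def _select(profile: pd.DataFrame, compound: str,
            station: str | None, campaign: str | None) -> pd.DataFrame:
    sub = profile[profile["compound"] == compound]
    if station is not None:
        sub = sub[sub["station"] == station]
    if campaign is not None:
        sub = sub[sub["campaign"] == campaign]
    return sub


def fold_change(
    profile: pd.DataFrame,
    compound: str,
    station: str | None = None,
    campaign: str | None = None,
    reference_window_m: tuple[float, float] = (0.0, 100.0),
    rule: str = "mean",
) -> FoldChange:
    """Concentration fold change from a near-surface reference to the OMZ.

    Reference: mean of per-depth means over the reference depth window
    (default upper 100 m). Target: depths flagged ``omz`` within the
    mesopelagic layer, summarized by ``rule`` ("mean" or "max").
    Requires a profile that has passed :func:`assign_oxygen_layers`.
    """
    if rule not in {"mean", "max"}:
        raise ConfigurationError(f"unknown fold-change rule {rule!r}")
    if "omz" not in profile.columns:
        raise ConsistencyError("profile lacks OMZ flags; run assign_oxygen_layers first")
    sub = _select(profile, compound, station, campaign)
    lo, hi = reference_window_m
    ref = sub[(sub["depth_m"] >= lo) & (sub["depth_m"] <= hi)]
    target = sub[sub["omz"] & (sub["layer"] == "mesopelagic")]
    if ref.empty:
        raise ConsistencyError(f"no depths in reference window {reference_window_m}")
    if target.empty:
        raise ConsistencyError("no OMZ-flagged mesopelagic depths in profile")
    ref_mean = float(ref["mean_pm"].mean())
    if ref_mean == 0:
        raise ConsistencyError("reference window mean is zero; fold change undefined")
    summary = float(target["mean_pm"].mean() if rule == "mean" else target["mean_pm"].max())
    return FoldChange(
        value=summary / ref_mean,
        rule=rule,
        reference_mean_pm=ref_mean,
        target_summary_pm=summary,
        reference_depths=tuple(sorted(ref["depth_m"])),
        target_depths=tuple(sorted(target["depth_m"])),
    )


def find_local_maxima(
    profile: pd.DataFrame,
    compound: str,
    station: str | None = None,
    campaign: str | None = None,
) -> list[float]:
    """Depths whose mean concentration strictly exceeds both neighbours.

    Endpoints qualify when they exceed their single neighbour. Results are
    sorted by mean concentration, largest first. Needs >= 3 sampled depths.
    """
    sub = _select(profile, compound, station, campaign).sort_values("depth_m")
    depths = sub["depth_m"].to_numpy(dtype=float)
    means = sub["mean_pm"].to_numpy(dtype=float)
    if len(depths) < 3:
        raise ConsistencyError(
            f"need >= 3 depths for local maxima, got {len(depths)}"
        )
    maxima = []
    for i in range(len(depths)):
        left_ok = i == 0 or means[i] > means[i - 1]
        right_ok = i == len(depths) - 1 or means[i] > means[i + 1]
        if left_ok and right_ok:
            maxima.append((means[i], depths[i]))
    maxima.sort(key=lambda t: (-t[0], t[1]))
    return [d for _, d in maxima]
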