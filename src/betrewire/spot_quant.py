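"""Quantification of SPOT peptide-array binding intensities.

Peptides synthesized on cellulose membranes are probed with a recombinant
bromodomain or ET domain; each spot's chemiluminescence intensity is
expressed as percent of the brightest hexa-His control spot on the same
array. Binding calls use nested intensity tiers

    moderate     >= 50 % of control maximum
    strong       >= 75 %
    very strong  >= 85 %

and, when the two bromodomains of a BET protein (BD1/BD2) are profiled in
parallel, a peptide is called domain-preferring when it binds one domain
strongly (>= 75 %) with >= 2-fold lower intensity toward the other.
Alanine-scanning arrays (each position of a peptide mutated to A in turn)
yield per-position retained binding relative to wild type (100 % = no
change, 0 % = total loss) and a derived per-residue contribution score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError

TIER_NONE = "none"
TIER_MODERATE = "moderate"
TIER_STRONG = "strong"
TIER_VERY_STRONG = "very_strong"
TIERS = (TIER_NONE, TIER_MODERATE, TIER_STRONG, TIER_VERY_STRONG)

#: Tier thresholds in percent of control maximum; >= semantics, nested.
TIER_THRESHOLDS = {TIER_MODERATE: 50.0, TIER_STRONG: 75.0, TIER_VERY_STRONG: 85.0}

PREF_BOTH = "both"
PREF_BD1 = "BD1_only"
PREF_BD2 = "BD2_only"
PREF_NONE = "none"

STRONG_CUT = 75.0
FOLD_GAP = 2.0


def merge_layout_intensity(layout: pd.DataFrame, intensity: pd.DataFrame) -> pd.DataFrame:
    """Join a layout table with an intensity grid on (array_id, row, col)."""
    merged = layout.merge(intensity, on=["array_id", "row", "col"], how="left", validate="1:1")
    if merged["raw"].isna().any():
        missing = merged.loc[merged["raw"].isna(), ["array_id", "row", "col"]].iloc[0].tolist()
        raise ValidationError(f"no intensity for spot {missing}")
    return merged


def normalize_array(spots: pd.DataFrame, cap: bool = False) -> pd.DataFrame:
    """Per-array normalization to the maximum control-spot intensity.

    Adds a ``normalized`` column: 100 * raw / max(raw over control spots of
    the same array). Scale-invariant under raw-intensity rescaling. Values
    above 100 (test spot brighter than the controls) are kept unless *cap*.
    """
    out = spots.copy()
    out["normalized"] = np.nan
    for array_id, sub in spots.groupby("array_id"):
        controls = sub.loc[sub["is_control"], "raw"]
        if controls.empty:
            raise ValidationError(f"array {array_id!r} has no control spots")
        ctrl_max = controls.max()
        if ctrl_max <= 0:
            raise ValidationError(f"array {array_id!r}: all control spots are zero")
        out.loc[sub.index, "normalized"] = 100.0 * sub["raw"] / ctrl_max
    if cap:
        out["normalized"] = out["normalized"].clip(upper=100.0)
    return out


def call_binding(normalized: float, thresholds: Mapping[str, float] = TIER_THRESHOLDS) -> str:
    """Highest binding tier reached by a normalized intensity (>= semantics)."""
    if normalized < 0:
        raise ContractError("normalized intensity must be >= 0")
    tier = TIER_NONE
    for name in (TIER_MODERATE, TIER_STRONG, TIER_VERY_STRONG):
        if normalized >= thresholds[name]:
            tier = name
    return tier


def tier_at_least(tier: str, floor: str) -> bool:
    """Nested-tier comparison: does *tier* reach at least *floor*?"""
    return TIERS.index(tier) >= TIERS.index(floor)


def domain_preference(
    norm_bd1: float,
    norm_bd2: float,
    strong_cut: float = STRONG_CUT,
    fold_gap: float = FOLD_GAP,
    both_min: float = 50.0,
) -> str:
    """Two-domain preference call for one peptide.

    BD1_only iff BD1 >= strong_cut and BD1 >= fold_gap * BD2 (symmetrically
    for BD2_only); otherwise ``both`` when both domains reach *both_min*
    (default the moderate tier; set 75 for the stricter reading); ``none``
    otherwise. Boundaries use >=.
    """
    if norm_bd1 < 0 or norm_bd2 < 0:
        raise ContractError("normalized intensities must be >= 0")
    if norm_bd1 >= strong_cut and norm_bd1 >= fold_gap * norm_bd2:
        return PREF_BD1
    if norm_bd2 >= strong_cut and norm_bd2 >= fold_gap * norm_bd1:
        return PREF_BD2
    if norm_bd1 >= both_min and norm_bd2 >= both_min:
        return PREF_BOTH
    return PREF_NONE


@dataclass
class BindingCall:
    """Tier and (optionally) two-domain preference for one peptide."""

    peptide: str
    tier: str
    norm_bd1: float | None = None
    norm_bd2: float | None = None
    preference: str | None = None


def call_peptides(
    norm_bd1: Mapping[str, float],
    norm_bd2: Mapping[str, float] | None = None,
    **pref_kwargs,
) -> list[BindingCall]:
    """Per-peptide tier (on the stronger domain) and preference calls."""
    calls = []
    for peptide, b1 in norm_bd1.items():
        if norm_bd2 is None:
            calls.append(BindingCall(peptide, call_binding(b1), norm_bd1=b1))
        else:
            b2 = norm_bd2.get(peptide, 0.0)
            calls.append(
                BindingCall(peptide, call_binding(max(b1, b2)), b1, b2,
                            domain_preference(b1, b2, **pref_kwargs))
            )
    return calls


def summarize_fractions(calls: Sequence[BindingCall], universe_size: int | None = None) -> pd.DataFrame:
    """Percent of the peptide universe in each tier and preference category.

    Returns a table with columns category, count, percent (full precision)
    and percent_1dp (rounded for report). Tier rows are cumulative
    ("moderate" means moderate-or-better); preference rows partition the
    universe together with the implicit remainder.
    """
    n = universe_size if universe_size is not None else len(calls)
    if n < len(calls):
        raise ContractError("universe_size smaller than the number of calls")
    rows = []
    for floor in (TIER_MODERATE, TIER_STRONG, TIER_VERY_STRONG):
        count = sum(tier_at_least(c.tier, floor) for c in calls)
        rows.append((f"tier>={floor}", count))
    have_pref = [c for c in calls if c.preference is not None]
    for pref in (PREF_BOTH, PREF_BD1, PREF_BD2, PREF_NONE):
        rows.append((f"pref={pref}", sum(c.preference == pref for c in have_pref)))
    df = pd.DataFrame(rows, columns=["category", "count"])
    df["percent"] = 100.0 * df["count"] / n if n else 0.0
    df["percent_1dp"] = df["percent"].round(1)
    return df


@dataclass
class AlaScanProfile:
    """Per-position alanine-scan quantification of one peptide."""

    wt_peptide: str
    retained: np.ndarray  # percent of WT intensity per mutated position
    contribution: np.ndarray  # binding-loss share, sums to 100 when any loss

    def ranking(self) -> list[int]:
        """Positions (1-based within the scanned range) by contribution, descending."""
        order = np.argsort(-self.contribution, kind="stable")
        return [int(i) + 1 for i in order]


def ala_scan(
    wt_intensity: float,
    mutant_intensities: Sequence[float],
    wt_peptide: str = "",
) -> AlaScanProfile:
    """Retained binding and per-residue contribution from an alanine scan.

    retained(i) = 100 * mutant(i) / wt; contribution(i) = max(0, 100 -
    retained(i)), normalized to sum 100 across positions when any position
    shows a loss. The contribution formula is this package's definition of
    "relative residue contribution"; it is monotone in binding loss.
    """
    if wt_intensity <= 0:
        raise ValidationError("wild-type intensity must be > 0")
    mut = np.asarray(mutant_intensities, dtype=float)
    if (mut < 0).any():
        raise ValidationError("mutant intensities must be >= 0")
    retained = 100.0 * mut / wt_intensity
    loss = np.clip(100.0 - retained, 0.0, None)
    total = loss.sum()
    contribution = 100.0 * loss / total if total > 0 else np.zeros_like(loss)
    return AlaScanProfile(wt_peptide, retained, contribution)
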