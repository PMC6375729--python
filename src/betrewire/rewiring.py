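"""Classification of drug-induced interactome rewiring from spectral counts.

Each bait-prey pair is compared between a reference and a treated time point
of a BET-inhibitor (JQ1) time course. Replicate spectral counts are summed
(not averaged), a pseudocount keeps the log2 fold change (LFC) finite, and
pairs are called:

    decreased   LFC <= -T
    sustained   -T < LFC < +T
    increased   LFC >= +T

with threshold T = 2 by default. Pairs whose counts drop to exactly zero
after treatment form the "below-detection" set, the candidate pool for
acetyl-lysine-dependent interactions. The classified universe is the union
of pairs passing the SAINT FDR cut (default 0.01, i.e. FDR <= 1%) at either
of the two compared time points; 0-vs-0 pairs are excluded. Rows without an
FDR value are treated as passing (pre-filtered tables).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ContractError

DECREASED = "decreased"
SUSTAINED = "sustained"
INCREASED = "increased"
CATEGORIES = (DECREASED, SUSTAINED, INCREASED)

DEFAULT_THRESHOLD = 2.0
DEFAULT_PSEUDOCOUNT = 1.0
DEFAULT_FDR_CUT = 0.01


@dataclass
class RewiringSummary:
    """Per-bait and global category totals for one rewiring comparison."""

    per_bait: pd.DataFrame  # index bait, columns decreased/sustained/increased
    totals: dict[str, int]
    n_pairs: int  # classified bait-prey pairs
    n_triples: int  # bait-prey-timepoint observations passing FDR (alt. convention)
    threshold: float
    pseudocount: float
    calls: pd.DataFrame = field(repr=False, default=None)


def sum_replicates(table: pd.DataFrame, bait: str, prey: str, timepoint: int) -> int:
    """Summed spectral count over replicates for one key; 0 when absent."""
    mask = (
        (table["bait"] == bait)
        & (table["prey"] == prey)
        & (table["timepoint"] == timepoint)
    )
    return int(table.loc[mask, "spectral_count"].sum())


def lfc(count_ref: float, count_treated: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((count_treated + p) / (count_ref + p)); antisymmetric in its arguments."""
    if count_ref < 0 or count_treated < 0:
        raise ContractError("spectral counts must be non-negative")
    if pseudocount <= 0:
        raise ContractError("pseudocount must be > 0")
    return math.log2((count_treated + pseudocount) / (count_ref + pseudocount))


def classify(
    count_ref: float,
    count_treated: float,
    threshold: float = DEFAULT_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> tuple[str, bool]:
    """Category and below-detection flag for one count pair.

    below_detection is True when a prey seen at reference (count > 0) has no
    spectral counts at all after treatment.
    """
    if threshold <= 0:
        raise ContractError("threshold must be > 0")
    value = lfc(count_ref, count_treated, pseudocount)
    if value <= -threshold:
        category = DECREASED
    elif value >= threshold:
        category = INCREASED
    else:
        category = SUSTAINED
    below = count_ref > 0 and count_treated == 0
    return category, below


def _passing(table: pd.DataFrame, fdr_cut: float | None) -> pd.DataFrame:
    if fdr_cut is None:
        return table
    return table[table["fdr"].isna() | (table["fdr"] <= fdr_cut)]


def _summed(table: pd.DataFrame, timepoint: int) -> pd.Series:
    sub = table[table["timepoint"] == timepoint]
    return sub.groupby(["bait", "prey"])["spectral_count"].sum()


def classify_table(
    table: pd.DataFrame,
    reference_timepoint: int,
    treated_timepoint: int,
    fdr_cut: float | None = DEFAULT_FDR_CUT,
    threshold: float = DEFAULT_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Classify every bait-prey pair of the table between two time points.

    Returns one row per classified pair with columns bait, prey, count_ref,
    count_treated, lfc, category, below_detection.
    """
    timepoints = set(table["timepoint"].unique())
    for tp in (reference_timepoint, treated_timepoint):
        if tp not in timepoints:
            raise ConfigurationError(f"time point {tp} not present in table")
    passing = _passing(table, fdr_cut)
    pass_ref = set(
        passing[passing["timepoint"] == reference_timepoint]
        .groupby(["bait", "prey"]).groups
    )
    pass_treat = set(
        passing[passing["timepoint"] == treated_timepoint]
        .groupby(["bait", "prey"]).groups
    )
    universe = sorted(pass_ref | pass_treat)
    ref_counts = _summed(table, reference_timepoint)
    treat_counts = _summed(table, treated_timepoint)
    rows = []
    for bait, prey in universe:
        c0 = int(ref_counts.get((bait, prey), 0))
        c1 = int(treat_counts.get((bait, prey), 0))
        if c0 == 0 and c1 == 0:
            continue  # never observed at either compared time point
        value = lfc(c0, c1, pseudocount)
        category, below = classify(c0, c1, threshold, pseudocount)
        rows.append((bait, prey, c0, c1, value, category, below))
    return pd.DataFrame(
        rows,
        columns=["bait", "prey", "count_ref", "count_treated", "lfc", "category", "below_detection"],
    )


def rewiring_summary(
    table: pd.DataFrame,
    reference_timepoint: int,
    treated_timepoint: int,
    fdr_cut: float | None = DEFAULT_FDR_CUT,
    threshold: float = DEFAULT_THRESHOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> RewiringSummary:
    """Category totals per bait and globally (conservation invariant holds)."""
    calls = classify_table(
        table, reference_timepoint, treated_timepoint, fdr_cut, threshold, pseudocount
    )
    if calls.empty:
        per_bait = pd.DataFrame(columns=list(CATEGORIES))
    else:
        per_bait = (
            calls.pivot_table(index="bait", columns="category", values="prey",
                              aggfunc="count", fill_value=0)
            .reindex(columns=list(CATEGORIES), fill_value=0)
        )
    totals = {cat: int((calls["category"] == cat).sum()) for cat in CATEGORIES}
    passing = _passing(table, fdr_cut)
    n_triples = int(
        passing[passing["spectral_count"] > 0]
        .groupby(["bait", "prey", "timepoint"]).ngroups
    )
    return RewiringSummary(
        per_bait=per_bait,
        totals=totals,
        n_pairs=len(calls),
        n_triples=n_triples,
        threshold=threshold,
        pseudocount=pseudocount,
        calls=calls,
    )


def below_detection_set(
    table: pd.DataFrame,
    bait: str,
    reference_timepoint: int,
    treated_timepoint: int,
    fdr_cut: float | None = DEFAULT_FDR_CUT,
) -> set[str]:
    """Preys of one bait passing FDR at reference, with counts dropping to 0.

    These are the candidates for acetylation-dependent binding: present in the
    untreated purification, absent (no spectral counts at all) after treatment.
    """
    if bait not in set(table["bait"].unique()):
        warnings.warn(f"unknown bait {bait!r}; returning empty set", stacklevel=2)
        return set()
    sub = table[table["bait"] == bait]
    passing = _passing(sub, fdr_cut)
    ref_pass = set(
        passing[passing["timepoint"] == reference_timepoint]["prey"].unique()
    )
    ref_counts = sub[sub["timepoint"] == reference_timepoint].groupby("prey")["spectral_count"].sum()
    treat_counts = sub[sub["timepoint"] == treated_timepoint].groupby("prey")["spectral_count"].sum()
    out = set()
    for prey in ref_pass:
        if ref_counts.get(prey, 0) > 0 and treat_counts.get(prey, 0) == 0:
            out.add(prey)
    return out


@dataclass
class BaitOverlap:
    """Prey sharing structure across baits at one time point."""

    prey_to_baits: dict[str, set[str]]
    shared_by_all: set[str]
    single_bait: set[str]
    n_baits: int


def bait_overlap(
    table: pd.DataFrame,
    fdr_cut: float | None = DEFAULT_FDR_CUT,
    timepoint: int = 0,
) -> BaitOverlap:
    """Which preys are seen with every bait, and which with exactly one."""
    sub = table[table["timepoint"] == timepoint]
    passing = _passing(sub, fdr_cut)
    counts = passing.groupby(["bait", "prey"])["spectral_count"].sum()
    observed = counts[counts > 0]
    prey_to_baits: dict[str, set[str]] = {}
    for bait, prey in observed.index:
        prey_to_baits.setdefault(prey, set()).add(bait)
    baits = set(sub["bait"].unique())
    shared = {p for p, bs in prey_to_baits.items() if bs == baits}
    single = {p for p, bs in prey_to_baits.items() if len(bs) == 1}
    return BaitOverlap(prey_to_baits, shared, single, len(baits))


@dataclass
class GroupRollup:
    """Per-group, per-bait summed counts and fractional contributions."""

    counts: pd.DataFrame  # index group, columns baits
    fractions: pd.DataFrame  # rows sum to 1 where the group total > 0
    n_unmapped_preys: int


def group_rollup(
    table: pd.DataFrame,
    group_map: Mapping[str, str],
    timepoint: int | None = None,
    fdr_cut: float | None = DEFAULT_FDR_CUT,
) -> GroupRollup:
    """Roll prey counts up to functional groups; fractions across baits.

    The relative spectral-count contribution of each bait to a group is the
    bait's summed counts over the group's preys divided by the group total.
    """
    if not group_map:
        raise ConfigurationError("group_map is empty")
    sub = table if timepoint is None else table[table["timepoint"] == timepoint]
    passing = _passing(sub, fdr_cut)
    mapped = passing[passing["prey"].isin(group_map)]
    n_unmapped = passing.loc[~passing["prey"].isin(group_map), "prey"].nunique()
    work = mapped.copy()
    work["group"] = work["prey"].map(dict(group_map))
    counts = work.pivot_table(
        index="group", columns="bait", values="spectral_count", aggfunc="sum", fill_value=0
    )
    row_totals = counts.sum(axis=1)
    fractions = counts.div(row_totals.replace(0, np.nan), axis=0)
    return GroupRollup(counts=counts, fractions=fractions, n_unmapped_preys=int(n_unmapped))
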