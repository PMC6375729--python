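"""Positional amino-acid composition and relative enrichment around Kac sites.

For a set of proteins (typically the below-detection preys of one bait after
BET-inhibitor treatment), 15-mer windows are extracted around every annotated
acetyl-lysine, and for each offset -7..+7 (0 = the central Kac, excluded) the
percentage of each amino acid is computed. The "positional enrichment" is
that percentage normalized by the residue's overall frequency, by default the
pooled frequency over all non-center, non-gap window positions of the same
set ("in each set"); whole-proteome or user-supplied backgrounds are options.

Gap-padded positions at sequence termini reduce the per-offset denominator
rather than counting as a 21st symbol, so per-offset percentages always sum
to 100 over the 20 residues.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, ValidationError
from .motif_scan import GAP
from .tables_io import ProteinSeq, PtmSite, STANDARD_AA, proteome_index

RESIDUES = tuple(STANDARD_AA)


@dataclass(frozen=True)
class KacWindow:
    """A gap-padded window of odd width centered on one acetyl-lysine."""

    accession: str
    position: int  # 1-based position of the central K
    window: str

    @property
    def halfwidth(self) -> int:
        return len(self.window) // 2


@dataclass
class EnrichmentMatrix:
    """Positional composition (percent) and relative enrichment (ratio).

    Both tables are residues x offsets; offsets run -halfwidth..+halfwidth
    excluding 0. ``occupancy`` counts non-gap windows per offset. ``ratio``
    is percent / (100 * background) and is NaN until computed.
    """

    percent: pd.DataFrame
    occupancy: pd.Series
    n_windows: int
    ratio: pd.DataFrame | None = None
    background: pd.Series | None = None
    background_mode: str | None = None
    counts: pd.DataFrame = field(default=None, repr=False)

    @property
    def offsets(self) -> list[int]:
        return list(self.percent.columns)


def build_windows(
    ptm_sites: Iterable[PtmSite],
    proteome: Sequence[ProteinSeq],
    halfwidth: int = 7,
    accessions: Iterable[str] | None = None,
) -> list[KacWindow]:
    """One centered window per acetyl-K site; termini are gap-padded.

    Sites whose residue is not K, or whose accession is missing from the
    proteome, are excluded with a warning. *accessions* optionally restricts
    the site set to a protein subset (e.g. a below-detection set).
    """
    if halfwidth < 1:
        raise ContractError("halfwidth must be >= 1")
    index = proteome_index(proteome)
    keep = set(accessions) if accessions is not None else None
    windows = []
    for site in ptm_sites:
        if "acetyl" not in site.modification.lower():
            continue
        if keep is not None and site.accession not in keep:
            continue
        if site.residue != "K":
            warnings.warn(f"site {site.accession}:{site.position} is {site.residue}, not K; excluded",
                          stacklevel=2)
            continue
        seq_rec = index.get(site.accession)
        if seq_rec is None:
            warnings.warn(f"site accession {site.accession} absent from proteome; excluded",
                          stacklevel=2)
            continue
        seq = seq_rec.sequence
        p0 = site.position - 1
        left = seq[max(0, p0 - halfwidth):p0]
        right = seq[p0 + 1:p0 + 1 + halfwidth]
        window = (GAP * (halfwidth - len(left)) + left + seq[p0]
                  + right + GAP * (halfwidth - len(right)))
        windows.append(KacWindow(site.accession, site.position, window))
    return windows


def composition_matrix(windows: Sequence[KacWindow]) -> EnrichmentMatrix:
    """Percent of windows carrying each residue at each offset from the Kac."""
    if not windows:
        raise ValidationError("no windows to analyze")
    halfwidth = windows[0].halfwidth
    if any(w.halfwidth != halfwidth for w in windows):
        raise ValidationError("windows have mixed widths")
    offsets = [o for o in range(-halfwidth, halfwidth + 1) if o != 0]
    counts = pd.DataFrame(0, index=list(RESIDUES), columns=offsets, dtype=int)
    occupancy = pd.Series(0, index=offsets, dtype=int)
    for w in windows:
        for o in offsets:
            ch = w.window[o + halfwidth]
            if ch == GAP:
                continue
            occupancy[o] += 1
            if ch in counts.index:
                counts.loc[ch, o] += 1
    denom = occupancy.replace(0, np.nan)
    percent = 100.0 * counts.div(denom, axis=1)
    return EnrichmentMatrix(percent=percent, occupancy=occupancy,
                            n_windows=len(windows), counts=counts)


def _pooled_background(matrix: EnrichmentMatrix) -> pd.Series:
    total = matrix.counts.to_numpy().sum()
    if total == 0:
        raise ValidationError("no non-gap residues to pool for the background")
    return matrix.counts.sum(axis=1) / total


def proteome_background(proteome: Sequence[ProteinSeq]) -> pd.Series:
    """Whole-proteome residue frequencies over the 20 standard letters."""
    counts = pd.Series(0, index=list(RESIDUES), dtype=float)
    for seq in proteome:
        for ch in seq.sequence:
            if ch in counts.index:
                counts[ch] += 1
    return counts / counts.sum()


def enrichment_ratio(
    matrix: EnrichmentMatrix,
    background_mode: str = "pooled",
    background: Mapping[str, float] | pd.Series | None = None,
    proteome: Sequence[ProteinSeq] | None = None,
) -> EnrichmentMatrix:
    """Fill in ratio = percent / (100 * background) pointwise.

    background_mode is one of ``pooled`` (non-center, non-gap window residues
    of this set; the default), ``proteome`` (requires *proteome*), or ``file``
    (requires *background*). Residues absent from the background but observed
    at some offset get a +inf sentinel with a warning.
    """
    if background_mode == "pooled":
        bg = _pooled_background(matrix)
    elif background_mode == "proteome":
        if proteome is None:
            raise ContractError("background_mode='proteome' needs a proteome")
        bg = proteome_background(proteome)
    elif background_mode == "file":
        if background is None:
            raise ContractError("background_mode='file' needs a background table")
        bg = pd.Series(background, dtype=float).reindex(list(RESIDUES)).fillna(0.0)
        bg = bg / bg.sum()
    else:
        raise ContractError(f"unknown background_mode {background_mode!r}")
    ratio = matrix.percent.div(100.0 * bg.replace(0, np.nan), axis=0)
    zero_bg = bg.index[bg == 0]
    for r in zero_bg:
        observed = matrix.percent.loc[r] > 0
        if observed.any():
            warnings.warn(f"residue {r} observed but absent from background; ratio set to +inf",
                          stacklevel=2)
            ratio.loc[r, observed[observed].index] = np.inf
    matrix.ratio = ratio
    matrix.background = bg
    matrix.background_mode = background_mode
    return matrix


def top_enriched(matrix: EnrichmentMatrix, offset: int, k: int = 5) -> list[tuple[str, float]]:
    """Residues ranked by enrichment ratio at one offset, ties alphabetical."""
    if matrix.ratio is None:
        raise ContractError("compute enrichment_ratio first")
    if offset not in matrix.ratio.columns:
        raise ContractError(f"offset {offset} outside the matrix range")
    col = matrix.ratio[offset].fillna(0.0)
    ranked = sorted(col.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
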