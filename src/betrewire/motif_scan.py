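"""Di-lysine and ET-domain short-linear-motif (SLiM) scanning.

Bromodomains of the BET family read acetyl-lysine (Kac) marks; a single BET
bromodomain can accommodate two Kac separated by a short linker (Kac-XX-Kac),
or a Kac followed by a bulky tyrosine (Kac-Y). The extra-terminal (ET) domain
instead binds unmodified basic/hydrophobic SLiMs. This module enumerates the
corresponding sequence motifs over a proteome:

* ``scan_k_linker_k`` - all K-X{n}-K occurrences for a linker-length range;
* ``is_histone_like`` - membership of a 2-residue linker in the 13 linkers
  observed in the four core histones;
* ``scan_ky`` / ``scan_kyxk`` - K-Y and K-YX-K di-lysine/tyrosine motifs;
* ``scan_et_slim`` - positional-alphabet SLiM patterns built from the
  hydrophobic class Phi = {M, L, V, I} (optionally + F) and the basic class
  [+] = {K, R}.

Overlapping matches are always reported: the unit of counting is the site
occurrence, not a maximal matching, so a lysine may serve as the second
anchor of one motif and the first anchor of the next.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .errors import ContractError, ValidationError
from .tables_io import PtmSite, ProteinSeq, STANDARD_AA

#: 2-residue K-XX-K linkers found in the four core histones.
HISTONE_LIKE_LINKERS = frozenset(
    ["GG", "GS", "DG", "AA", "AP", "AV", "AQ", "AR", "SA", "VL", "LN", "TA", "TP"]
)

GAP = "-"
FLANK_WIDTH = 5

PHI = frozenset("MLVI")
PHI_WITH_PHE = frozenset("MLVIF")
BASIC = frozenset("KR")
ANY_RESIDUE = frozenset(STANDARD_AA)

UNMODIFIED = "unmodified"
FIRST_K_AC = "first_K_ac"
SECOND_K_AC = "second_K_ac"
DI_AC = "di_ac"
K_AC = "K_ac"


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; all positions are 1-based."""

    accession: str
    anchor1: int
    anchor2: int | None
    linker: str
    motif_class: str
    window: str
    flank_n: str
    flank_c: str
    truncated: bool = False
    acetyl_state: str | None = None


@dataclass(frozen=True)
class MotifPattern:
    """A positional-alphabet SLiM pattern (one allowed-residue set per position)."""

    name: str
    positions: tuple[frozenset, ...]
    notes: str = ""

    def __post_init__(self):
        if not self.positions:
            raise ContractError("pattern needs at least one position")
        for s in self.positions:
            if not s or not set(s) <= set(STANDARD_AA):
                raise ContractError("positional sets must be non-empty subsets of the 20 letters")

    def __len__(self) -> int:
        return len(self.positions)


def et_patterns(include_phe: bool = False) -> dict[str, MotifPattern]:
    """The ET-domain SLiM pattern library.

    Phi defaults to {M, L, V, I}; *include_phe* adds F (the second-round scan
    that recovered e.g. the RPS26 KFVIK motif). [+] is always {K, R}.
    """
    phi = PHI_WITH_PHE if include_phe else PHI
    phib = phi | BASIC
    return {
        "ET_minimal": MotifPattern("ET_minimal", (BASIC, phi, phib),
                                   "minimal combination of BRD9 and WHSC1 motifs"),
        "ET_BRD9like": MotifPattern("ET_BRD9like", (phib, phi, phi, phib, phi),
                                    "BRD9-like (Phi/[+])PhiPhi(Phi/[+])Phi"),
        "ET_WHSC1like": MotifPattern("ET_WHSC1like", (phi, BASIC, phi, BASIC),
                                     "WHSC1/L1-like Phi[+]Phi[+]"),
        "CM1": MotifPattern("CM1", (BASIC, ANY_RESIDUE, BASIC), "[+]x[+]"),
        "CM2": MotifPattern("CM2", (BASIC, frozenset("H")),
                            "[+](H); literal His reading, interpretation uncertain"),
        "CM3": MotifPattern("CM3", (BASIC,), "[+]"),
    }


def _flanks(seq: str, start0: int, end0: int) -> tuple[str, str, bool]:
    """Up to FLANK_WIDTH residues either side of seq[start0:end0], gap-padded."""
    left = seq[max(0, start0 - FLANK_WIDTH):start0]
    right = seq[end0:end0 + FLANK_WIDTH]
    truncated = len(left) < FLANK_WIDTH or len(right) < FLANK_WIDTH
    return GAP * (FLANK_WIDTH - len(left)) + left, right + GAP * (FLANK_WIDTH - len(right)), truncated


def _make_hit(seq: str, accession: str, start0: int, end0: int, anchor1: int,
              anchor2: int | None, linker: str, motif_class: str) -> MotifHit:
    flank_n, flank_c, truncated = _flanks(seq, start0, end0)
    core = seq[start0:end0]
    return MotifHit(
        accession=accession, anchor1=anchor1, anchor2=anchor2, linker=linker,
        motif_class=motif_class, window=flank_n + core + flank_c,
        flank_n=flank_n, flank_c=flank_c, truncated=truncated,
    )


def _coerce(seq: str | ProteinSeq, accession: str) -> tuple[str, str]:
    if isinstance(seq, ProteinSeq):
        return seq.sequence, seq.accession
    return seq, accession


def scan_k_linker_k(
    seq: str | ProteinSeq,
    linker_min: int = 2,
    linker_max: int = 2,
    accession: str = "",
    strict: bool = True,
) -> list[MotifHit]:
    """All K-X{n}-K occurrences with linker_min <= n <= linker_max.

    Every anchor index pair is reported, so overlapping motifs (shared
    anchors) all appear. Linkers containing a letter outside the 20-letter
    alphabet raise under *strict*, or skip the hit with a warning otherwise.
    """
    if not (0 <= linker_min <= linker_max <= 6):
        raise ContractError("linker range must satisfy 0 <= min <= max <= 6")
    seq, accession = _coerce(seq, accession)
    hits = []
    k_positions = [i for i, ch in enumerate(seq) if ch == "K"]
    for i in k_positions:
        for j in k_positions:
            gap = j - i - 1
            if gap < linker_min:
                continue
            if gap > linker_max:
                break
            linker = seq[i + 1:j]
            bad = set(linker) - set(STANDARD_AA)
            if bad:
                msg = f"{accession}: linker at K{i + 1} contains non-standard letter {sorted(bad)}"
                if strict:
                    raise ValidationError(msg)
                warnings.warn(msg, stacklevel=2)
                continue
            motif_class = "KXXK" if gap == 2 else "K_long_linker"
            hits.append(_make_hit(seq, accession, i, j + 1, i + 1, j + 1, linker, motif_class))
    return hits


def is_histone_like(linker: str) -> bool:
    """Is a 2-residue K-XX-K linker one of the 13 core-histone linkers?"""
    if len(linker) != 2:
        raise ContractError("histone-like test is defined for 2-residue linkers")
    return linker in HISTONE_LIKE_LINKERS


def enumerate_linker_space(alphabet: str | Iterable[str] = STANDARD_AA) -> int:
    """Number of distinct XX linker combinations over an alphabet (|A|^2)."""
    letters = set(alphabet)
    if not letters:
        raise ContractError("alphabet must be non-empty")
    return len(letters) ** 2


def scan_kgxk(seq: str | ProteinSeq, accession: str = "") -> list[MotifHit]:
    """K-GX-K motifs: the glycine-first subset of the K-XX-K space."""
    hits = scan_k_linker_k(seq, 2, 2, accession)
    return [replace(h, motif_class="KGXK") for h in hits if h.linker[0] == "G"]


def scan_ky(seq: str | ProteinSeq, accession: str = "") -> list[MotifHit]:
    """K-Y motifs: a lysine immediately followed by tyrosine."""
    seq, accession = _coerce(seq, accession)
    hits = []
    for i in range(len(seq) - 1):
        if seq[i] == "K" and seq[i + 1] == "Y":
            hits.append(_make_hit(seq, accession, i, i + 2, i + 1, None, "", "KY"))
    return hits


def scan_kyxk(seq: str | ProteinSeq, accession: str = "") -> list[MotifHit]:
    """K-YX-K motifs: K, tyrosine at +1, any residue, K at +3."""
    seq, accession = _coerce(seq, accession)
    hits = []
    for i in range(len(seq) - 3):
        if seq[i] == "K" and seq[i + 1] == "Y" and seq[i + 3] == "K":
            hits.append(
                _make_hit(seq, accession, i, i + 4, i + 1, i + 4, seq[i + 1:i + 3], "KYXK")
            )
    return hits


def scan_et_slim(seq: str | ProteinSeq, pattern: MotifPattern, accession: str = "") -> list[MotifHit]:
    """All (overlapping) matches of a positional-alphabet SLiM pattern.

    Flanks are captured for display but never constrain matching.
    """
    seq, accession = _coerce(seq, accession)
    width = len(pattern)
    hits = []
    for start in range(len(seq) - width + 1):
        if all(seq[start + k] in allowed for k, allowed in enumerate(pattern.positions)):
            hits.append(
                _make_hit(seq, accession, start, start + width, start + 1, None, "", pattern.name)
            )
    return hits


def acetyl_positions(sites: Iterable[PtmSite]) -> set[tuple[str, int]]:
    """(accession, position) pairs of acetyl-lysine sites in a PTM table."""
    out = set()
    for s in sites:
        if s.residue == "K" and "acetyl" in s.modification.lower():
            out.add((s.accession, s.position))
    return out


def overlay_kac(hits: Sequence[MotifHit], ptm_sites: Iterable[PtmSite]) -> list[MotifHit]:
    """Annotate each hit with the acetylation state of its anchor lysines.

    Two-anchor motifs become one of {unmodified, first_K_ac, second_K_ac,
    di_ac}; single-anchor K-Y motifs one of {unmodified, K_ac}.
    """
    kac = acetyl_positions(ptm_sites)
    out = []
    for h in hits:
        a1 = (h.accession, h.anchor1) in kac
        if h.anchor2 is None:
            state = K_AC if a1 else UNMODIFIED
        else:
            a2 = (h.accession, h.anchor2) in kac
            state = (DI_AC if a2 else FIRST_K_AC) if a1 else (SECOND_K_AC if a2 else UNMODIFIED)
        out.append(replace(h, acetyl_state=state))
    return out


@dataclass(frozen=True)
class UniqueWindow:
    """One deduplicated peptide window with its source hits."""

    window: str
    multiplicity: int
    sources: tuple[tuple[str, int], ...]  # (accession, anchor1) per source hit


def unique_windows(hits: Sequence[MotifHit], width: int = 15) -> list[UniqueWindow]:
    """Collapse hits whose extracted windows are identical strings.

    Deduplication is at the window-sequence level, so e.g. identical peptides
    arising from splice variants count once (with multiplicity recorded).
    """
    if width % 2 == 0:
        raise ContractError("window width must be odd")
    groups: dict[str, list[MotifHit]] = {}
    for h in hits:
        groups.setdefault(h.window, []).append(h)
    return [
        UniqueWindow(w, len(hs), tuple((h.accession, h.anchor1) for h in hs))
        for w, hs in groups.items()
    ]


def scan_proteome(
    proteome: Iterable[ProteinSeq],
    scanner,
    **kwargs,
) -> list[MotifHit]:
    """Apply one scan function across a whole proteome."""
    hits: list[MotifHit] = []
    for seq in proteome:
        hits.extend(scanner(seq, **kwargs))
    return hits
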