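"""Readers and writers for every external table and sequence format the
pipeline touches.

Canonical table dialect is TSV with a mandatory header (SAINT/ProHits exports
are tab-delimited); comma-separated variants are accepted via ``sep=","``.
All residue positions are 1-based and inclusive, matching PTM-database
convention ("K5ac" means lysine at position 5).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ValidationError

#: The 20 standard amino-acid letters.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
#: Default alphabet: the 20 standard letters plus the ambiguity code X.
DEFAULT_ALPHABET = frozenset(STANDARD_AA + "X")
#: Extra letters tolerated under the permissive flag (Sec/Pyl/ambiguity codes).
PERMISSIVE_EXTRA = frozenset("BZJUO*")

INTERACTION_COLUMNS = ("bait", "prey", "timepoint", "replicate", "spectral_count", "fdr")
REQUIRED_INTERACTION_COLUMNS = ("bait", "prey", "timepoint", "replicate", "spectral_count")
PTM_COLUMNS = ("accession", "position", "residue", "modification")


@dataclass(frozen=True)
class ProteinSeq:
    """One protein sequence with a UniProt-style accession."""

    accession: str
    description: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PtmSite:
    """One post-translational modification site (1-based position)."""

    accession: str
    position: int
    residue: str
    modification: str


class PtmProblem(NamedTuple):
    """A PTM-site row that failed cross-checking against the proteome."""

    site: PtmSite
    reason: str


@dataclass
class PtmReadResult:
    """Accepted sites plus explicit problem records (never silently dropped)."""

    sites: list[PtmSite]
    problems: list[PtmProblem] = field(default_factory=list)


def _read_table(path: str | Path, sep: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        # '#' lines are provenance headers written by the CLI
        return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False, comment="#")
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file has no header line")


def read_interaction_table(
    path: str | Path,
    sep: str = "\t",
    column_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a SAINT-style interaction table into a validated DataFrame.

    Parameters
    ----------
    path
        TSV file with at least the columns ``bait, prey, timepoint, replicate,
        spectral_count`` (``fdr`` optional). Deposited supplementary sheets with
        different headers are adapted with *column_map*.
    column_map
        Mapping from file column names to canonical names, e.g.
        ``{"Bait": "bait", "PreyGene": "prey"}``. Unknown columns are retained
        untouched as opaque annotations.

    Returns
    -------
    DataFrame in file row order with canonical dtypes: ``spectral_count`` is a
    non-negative integer, ``fdr`` a float in [0, 1] (NaN when absent),
    ``timepoint`` an integer number of minutes.
    """
    df = _read_table(path, sep)
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in REQUIRED_INTERACTION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    if df.empty:
        out = df.copy()
        if "fdr" not in out.columns:
            out["fdr"] = pd.Series(dtype=float)
        out = out.astype({"timepoint": int, "spectral_count": int, "fdr": float},
                         errors="ignore")
        return out

    out = df.copy()
    try:
        out["timepoint"] = out["timepoint"].astype(int)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-integer timepoint ({exc})")
    try:
        out["spectral_count"] = out["spectral_count"].astype(int)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-integer spectral_count ({exc})")
    bad = out.index[out["spectral_count"] < 0]
    if len(bad):
        # +2: 1-based data rows below the header line
        raise ValidationError(
            f"{path}: negative spectral_count in row {bad[0] + 2}"
        )
    if "fdr" in out.columns:
        fdr = out["fdr"].replace("", "nan").astype(float)
        bad_fdr = fdr.dropna()
        if ((bad_fdr < 0) | (bad_fdr > 1)).any():
            row = (bad_fdr[(bad_fdr < 0) | (bad_fdr > 1)]).index[0] + 2
            raise ValidationError(f"{path}: fdr outside [0, 1] in row {row}")
        out["fdr"] = fdr
    else:
        out["fdr"] = float("nan")
    key = ["bait", "prey", "timepoint", "replicate"]
    dup = out.duplicated(subset=key)
    if dup.any():
        first = out.loc[dup, key].iloc[0].tolist()
        raise ValidationError(
            f"{path}: duplicate (bait, prey, timepoint, replicate) key {first}"
        )
    return out


def write_interaction_table(df: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    df.to_csv(path, sep=sep, index=False)


def _parse_fasta_header(record_id: str) -> str:
    """UniProt-style ``db|ACC|NAME`` headers yield ACC; otherwise the id token."""
    parts = record_id.split("|")
    if len(parts) >= 3 and parts[1]:
        return parts[1]
    return record_id


def read_fasta(path: str | Path, permissive: bool = False) -> list[ProteinSeq]:
    """Read protein sequences from FASTA.

    Sequence bodies may span multiple lines. Letters outside the 20 standard
    amino acids plus X raise :class:`ValidationError` unless *permissive*.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    allowed = DEFAULT_ALPHABET | (PERMISSIVE_EXTRA if permissive else frozenset())
    seqs: list[ProteinSeq] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = _parse_fasta_header(record.id)
        sequence = str(record.seq).upper()
        if not sequence:
            raise ValidationError(f"{path}: empty sequence for {accession}")
        bad = set(sequence) - allowed
        if bad:
            raise ValidationError(
                f"{path}: sequence {accession} contains letters outside the "
                f"amino-acid alphabet: {sorted(bad)}"
            )
        if accession in seen:
            raise ValidationError(f"{path}: duplicate accession {accession}")
        seen.add(accession)
        seqs.append(ProteinSeq(accession, record.description, sequence))
    return seqs


def write_fasta(seqs: Iterable[ProteinSeq], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(s.sequence), id=s.accession, description="")
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def proteome_index(seqs: Iterable[ProteinSeq]) -> dict[str, ProteinSeq]:
    return {s.accession: s for s in seqs}


def read_ptm_table(
    path: str | Path,
    proteome: Sequence[ProteinSeq] | None = None,
    sep: str = "\t",
) -> PtmReadResult:
    """Read a PhosphoSitePlus-like PTM-site table.

    When *proteome* is supplied every site is cross-checked: out-of-range
    positions and residue mismatches are reported in ``problems`` rather than
    silently dropped.
    """
    df = _read_table(path, sep)
    for col in PTM_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    index = proteome_index(proteome) if proteome is not None else None
    result = PtmReadResult(sites=[])
    for _, row in df.iterrows():
        try:
            pos = int(row["position"])
        except ValueError:
            raise ValidationError(f"{path}: non-integer position {row['position']!r}")
        site = PtmSite(row["accession"], pos, row["residue"], row["modification"])
        if pos < 1:
            result.problems.append(PtmProblem(site, "position < 1"))
            continue
        if index is not None and site.accession in index:
            seq = index[site.accession].sequence
            if pos > len(seq):
                result.problems.append(
                    PtmProblem(site, f"position {pos} beyond sequence length {len(seq)}")
                )
                continue
            if seq[pos - 1] != site.residue:
                result.problems.append(
                    PtmProblem(site, f"sequence has {seq[pos - 1]} at {pos}, site says {site.residue}")
                )
                continue
        result.sites.append(site)
    return result


def write_ptm_table(sites: Iterable[PtmSite], path: str | Path, sep: str = "\t") -> None:
    pd.DataFrame([dataclasses.asdict(s) for s in sites], columns=list(PTM_COLUMNS)).to_csv(
        path, sep=sep, index=False
    )


def write_matrix(matrix: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a named 2-D table as TSV, row labels in column 1.

    Integer matrices round-trip bit-exactly; floats to ~12 significant digits.
    """
    if matrix.index.has_duplicates or matrix.columns.has_duplicates:
        raise ValidationError("matrix row/column names must be unique")
    matrix.to_csv(path, sep=sep, index=True, index_label="name", float_format="%.12g")


def read_matrix(path: str | Path, sep: str = "\t") -> pd.DataFrame:
    df = _read_table(path, sep)
    if "name" not in df.columns:
        raise FormatError(f"{path}: matrix file lacks the 'name' label column")
    df = df.set_index("name")
    df.index.name = "name"
    return df.apply(pd.to_numeric)


def read_spot_layout(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a SPOT-array layout CSV: array_id, row, col, peptide, is_control."""
    df = _read_table(path, sep)
    for col in ("array_id", "row", "col", "peptide", "is_control"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df = df.astype({"row": int, "col": int})
    df["is_control"] = df["is_control"].map(
        lambda v: str(v).strip().lower() in {"1", "true", "yes"}
    )
    return df


def read_spot_intensity(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a SPOT-array intensity CSV: array_id, row, col, raw."""
    df = _read_table(path, sep)
    for col in ("array_id", "row", "col", "raw"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column '{col}'")
    df = df.astype({"row": int, "col": int, "raw": float})
    if (df["raw"] < 0).any():
        raise ValidationError(f"{path}: negative raw intensity")
    return df
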