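"""Synthetic generators for every pipeline input, with recorded ground truth.

The generators emulate the structure of the study's deposited data — SAINT-
scored AP-MS spectral-count tables (4 baits, hundreds of preys, a 0/10/60/240
minute inhibitor time course, 2 replicates), UniProt-style proteomes with
planted motif occurrences, PhosphoSitePlus-like acetyl-K site tables, and
SPOT-array layout/intensity grids — so that every downstream operation can be
tested against known truth without any download.

Spectral counts are negative-binomial (over-dispersion is standard for
spectral counting; dispersion alpha defaults to 0.2, variance m + alpha*m^2).
SPOT intensities carry multiplicative log-normal noise (densitometry noise is
multiplicative). Motif planting re-scans the finished proteome so accidental
background matches are part of recorded truth. Identical seed and parameters
reproduce outputs bit-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError
from . import motif_scan
from .motif_scan import GAP, et_patterns
from .rewiring import CATEGORIES, DECREASED, INCREASED, SUSTAINED
from .tables_io import ProteinSeq, PtmSite, STANDARD_AA


@dataclass
class SimulationTruth:
    """Planted ground truth plus every parameter needed to regenerate it."""

    seed: int
    params: dict
    data: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"seed": self.seed, "params": self.params, "data": self.data},
            indent=2, sort_keys=True, default=str,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        obj = json.loads(text)
        return cls(seed=obj["seed"], params=obj["params"], data=obj["data"])


def _nb_counts(rng: np.random.Generator, mean: float, dispersion: float, size: int) -> np.ndarray:
    """Negative-binomial draws with variance mean + dispersion * mean^2."""
    if mean <= 0:
        return np.zeros(size, dtype=int)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


DEFAULT_CLASS_PROBS = {DECREASED: 0.4, SUSTAINED: 0.35, INCREASED: 0.25}
DEFAULT_PLANTED_LFC = {DECREASED: -4.0, SUSTAINED: 0.0, INCREASED: 4.0}


def simulate_interactions(
    n_baits: int = 4,
    n_preys: int = 250,
    timepoints: Sequence[int] = (0, 10, 60, 240),
    n_replicates: int = 2,
    class_probs: Mapping[str, float] = None,
    base_mean: float = 50.0,
    dispersion: float = 0.2,
    planted_lfc_by_class: Mapping[str, float] = None,
    below_detection_fraction: float = 0.25,
    fdr_pass_fraction: float = 1.0,
    presence_prob: float = 1.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, SimulationTruth]:
    """A SAINT-style interaction table with planted per-pair rewiring classes.

    Reference (t=0) counts are negative binomial around *base_mean*; treated
    means are scaled by 2**planted_lfc. A *below_detection_fraction* of the
    decreased pairs is forced to exactly zero counts at all treated time
    points (the below-detection truth). FDR values are drawn so that a
    *fdr_pass_fraction* of pairs passes 0.01 at every time point. Each
    bait-prey pair exists at all with probability *presence_prob*, planting a
    bait-sharing overlap structure (absent pairs produce no table rows).
    """
    class_probs = dict(class_probs or DEFAULT_CLASS_PROBS)
    planted = dict(planted_lfc_by_class or DEFAULT_PLANTED_LFC)
    probs = np.array([class_probs.get(c, 0.0) for c in CATEGORIES])
    if not np.isclose(probs.sum(), 1.0):
        raise ContractError("class_probs must sum to 1")
    if base_mean <= 0 or dispersion <= 0:
        raise ContractError("base_mean and dispersion must be > 0")
    rng = np.random.default_rng(seed)
    baits = [f"BAIT{i + 1}" for i in range(n_baits)]
    preys = [f"PREY{i + 1:04d}" for i in range(n_preys)]
    rows = []
    truth_rows = []
    for bait in baits:
        for prey in preys:
            if presence_prob < 1.0 and rng.random() >= presence_prob:
                truth_rows.append(
                    {"bait": bait, "prey": prey, "present": False, "category": None,
                     "planted_lfc": None, "below_detection": False,
                     "below_detection_realized": {}, "ref_count": 0, "fdr_pass": False}
                )
                continue
            category = CATEGORIES[rng.choice(len(CATEGORIES), p=probs)]
            planted_lfc = planted[category]
            below = category == DECREASED and rng.random() < below_detection_fraction
            passes = rng.random() < fdr_pass_fraction
            counts_by_tp = {}
            for tp in timepoints:
                mean = base_mean if tp == timepoints[0] else base_mean * 2.0 ** planted_lfc
                if below and tp != timepoints[0]:
                    counts = np.zeros(n_replicates, dtype=int)
                else:
                    counts = _nb_counts(rng, mean, dispersion, n_replicates)
                counts_by_tp[tp] = counts
                fdr = rng.uniform(0.0, 0.009) if passes else rng.uniform(0.02, 0.3)
                for r in range(n_replicates):
                    rows.append((bait, prey, tp, f"rep{r + 1}", int(counts[r]), fdr))
            # realized zero-outs (forced ones plus chance all-zero draws) are
            # the ground truth for below-detection recovery, recorded per
            # treated time point
            ref_total = int(counts_by_tp[timepoints[0]].sum())
            realized = {
                str(tp): ref_total > 0 and int(counts_by_tp[tp].sum()) == 0
                for tp in timepoints[1:]
            }
            truth_rows.append(
                {"bait": bait, "prey": prey, "present": True, "category": category,
                 "planted_lfc": planted_lfc, "below_detection": below,
                 "below_detection_realized": realized, "ref_count": ref_total,
                 "fdr_pass": passes}
            )
    table = pd.DataFrame(
        rows, columns=["bait", "prey", "timepoint", "replicate", "spectral_count", "fdr"]
    )
    truth = SimulationTruth(
        seed=seed,
        params={
            "n_baits": n_baits, "n_preys": n_preys, "timepoints": list(timepoints),
            "n_replicates": n_replicates, "class_probs": class_probs,
            "base_mean": base_mean, "dispersion": dispersion,
            "planted_lfc_by_class": planted,
            "below_detection_fraction": below_detection_fraction,
            "fdr_pass_fraction": fdr_pass_fraction,
            "presence_prob": presence_prob,
        },
        data={"interactions": truth_rows},
    )
    return table, truth


def _random_sequence(rng: np.random.Generator, length: int, letters: str,
                     freqs: np.ndarray) -> list[str]:
    return list(rng.choice(list(letters), size=length, p=freqs))


def _motif_instance(rng: np.random.Generator, motif_class: str) -> str:
    """A random sequence realizing one motif class."""
    letters = list(STANDARD_AA)
    if motif_class == "KXXK":
        return "K" + "".join(rng.choice(letters, size=2)) + "K"
    if motif_class == "KGXK":
        return "KG" + str(rng.choice(letters)) + "K"
    if motif_class == "KYXK":
        return "KY" + str(rng.choice(letters)) + "K"
    if motif_class == "KY":
        return "KY"
    patterns = et_patterns(include_phe=False)
    if motif_class in patterns:
        return "".join(str(rng.choice(sorted(s))) for s in patterns[motif_class].positions)
    raise ContractError(f"unknown motif class {motif_class!r}")


_SCANNERS = {
    "KXXK": lambda seq: motif_scan.scan_k_linker_k(seq, 2, 2),
    "KGXK": motif_scan.scan_kgxk,
    "KYXK": motif_scan.scan_kyxk,
    "KY": motif_scan.scan_ky,
}


def _rescan(proteome: Sequence[ProteinSeq], motif_class: str) -> list:
    if motif_class in _SCANNERS:
        return motif_scan.scan_proteome(proteome, _SCANNERS[motif_class])
    pattern = et_patterns()[motif_class]
    return motif_scan.scan_proteome(proteome, motif_scan.scan_et_slim, pattern=pattern)


def simulate_proteome(
    n_proteins: int = 50,
    length_range: tuple[int, int] = (200, 600),
    background_freqs: Mapping[str, float] | None = None,
    planted_motifs: Sequence[tuple[str, int]] = (),
    seed: int = 0,
) -> tuple[list[ProteinSeq], SimulationTruth]:
    """A random proteome with motif instances planted at recorded positions.

    Background residues are i.i.d. from *background_freqs* (uniform over the
    20 letters by default). After planting, every planted class is re-scanned
    and the full hit list recorded as truth, so accidental background matches
    are ground truth too rather than a source of flaky comparisons.
    """
    rng = np.random.default_rng(seed)
    letters = STANDARD_AA
    if background_freqs is None:
        freqs = np.full(len(letters), 1.0 / len(letters))
    else:
        freqs = np.array([background_freqs.get(ch, 0.0) for ch in letters], dtype=float)
        freqs = freqs / freqs.sum()
    lengths = rng.integers(length_range[0], length_range[1] + 1, size=n_proteins)
    seqs = [_random_sequence(rng, int(L), letters, freqs) for L in lengths]
    used: list[list[tuple[int, int]]] = [[] for _ in range(n_proteins)]
    planted_records = []
    for motif_class, count in planted_motifs:
        for _ in range(count):
            inst = _motif_instance(rng, motif_class)
            placed = False
            for _attempt in range(200):
                p = int(rng.integers(0, n_proteins))
                L = len(seqs[p])
                if L < len(inst) + 2:
                    continue
                start = int(rng.integers(1, L - len(inst) - 1))
                span = (start - 1, start + len(inst) + 1)  # 1-residue margin
                if any(not (span[1] <= a or span[0] >= b) for a, b in used[p]):
                    continue
                seqs[p][start:start + len(inst)] = list(inst)
                used[p].append(span)
                planted_records.append(
                    {"accession": f"SYN{p + 1:04d}", "motif_class": motif_class,
                     "start": start + 1, "instance": inst}
                )
                placed = True
                break
            if not placed:
                raise ContractError(
                    f"could not place a {motif_class} instance; proteome too crowded"
                )
    proteome = [
        ProteinSeq(f"SYN{i + 1:04d}", f"synthetic protein {i + 1}", "".join(s))
        for i, s in enumerate(seqs)
    ]
    rescans = {
        cls: [
            {"accession": h.accession, "anchor1": h.anchor1, "anchor2": h.anchor2,
             "linker": h.linker}
            for h in _rescan(proteome, cls)
        ]
        for cls in {c for c, _ in planted_motifs}
    }
    truth = SimulationTruth(
        seed=seed,
        params={"n_proteins": n_proteins, "length_range": list(length_range),
                "planted_motifs": [list(pm) for pm in planted_motifs]},
        data={"planted": planted_records, "rescans": rescans},
    )
    return proteome, truth


def kxxk_census_sequence(separator: str = "GSP") -> str:
    """All 400 K-XX-K linker combinations concatenated with K-free separators.

    The separator must be lysine-free and at least 3 residues long so that no
    cross-unit K-XX-K arises; scanning the result with linker range 2-2 then
    yields exactly 400 hits, 13 of them with histone-like linkers.
    """
    if "K" in separator or len(separator) < 3:
        raise ContractError("separator must be lysine-free and >= 3 residues")
    units = ["K" + a + b + "K" for a in STANDARD_AA for b in STANDARD_AA]
    return separator + separator.join(units) + separator


@dataclass(frozen=True)
class PositionalBias:
    """Up-weighting of acetylation when *residue* occupies *offset*."""

    offset: int
    residue: str
    multiplier: float


def simulate_ptm_sites(
    proteome: Sequence[ProteinSeq],
    acetyl_fraction_of_K: float = 0.15,
    bias: PositionalBias | None = None,
    seed: int = 0,
) -> tuple[list[PtmSite], SimulationTruth]:
    """Acetylate each lysine independently, optionally biased by context.

    With a bias, lysines whose *offset* neighbour is *residue* are acetylated
    at ``multiplier`` times the base probability (capped at 1). Note that the
    positional-enrichment ratio this induces in the resulting window set is
    smaller than the multiplier (the conditional frequency saturates); to
    plant an exact enrichment ratio use :func:`simulate_acetylome`.
    """
    if not 0.0 <= acetyl_fraction_of_K <= 1.0:
        raise ContractError("acetyl fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    sites = []
    for rec in proteome:
        seq = rec.sequence
        for i, ch in enumerate(seq):
            if ch != "K":
                continue
            p = acetyl_fraction_of_K
            if bias is not None:
                j = i + bias.offset
                if 0 <= j < len(seq) and seq[j] == bias.residue:
                    p = min(1.0, p * bias.multiplier)
            if rng.random() < p:
                sites.append(PtmSite(rec.accession, i + 1, "K", "acetyl-K"))
    truth = SimulationTruth(
        seed=seed,
        params={"acetyl_fraction_of_K": acetyl_fraction_of_K,
                "bias": None if bias is None else vars(bias)},
        data={"n_sites": len(sites)},
    )
    return sites, truth


def simulate_acetylome(
    n_sites: int = 10_000,
    bias: PositionalBias | None = None,
    protein_length: int = 400,
    sites_per_protein: int = 10,
    background_freqs: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[list[ProteinSeq], list[PtmSite], SimulationTruth]:
    """Co-generate a proteome and acetyl-K sites with an exact planted signal.

    Site positions are chosen first (well separated, away from termini), the
    central residue is set to K, and — when a bias is given — the residue at
    ``bias.offset`` of each site is drawn so that its conditional frequency is
    exactly ``multiplier`` times its background frequency, all other residues
    rescaled proportionally. Against the generating background frequencies
    (recorded in the returned truth), the positional-enrichment ratio at that
    offset is therefore the multiplier, up to sampling error.
    """
    rng = np.random.default_rng(seed)
    letters = STANDARD_AA
    if background_freqs is None:
        freqs = np.full(len(letters), 1.0 / len(letters))
    else:
        freqs = np.array([background_freqs.get(ch, 0.0) for ch in letters], dtype=float)
        freqs = freqs / freqs.sum()
    if bias is not None:
        q = freqs[letters.index(bias.residue)]
        target = bias.multiplier * q
        if target > 1.0:
            raise ContractError("multiplier * background frequency exceeds 1")
        biased = freqs * (1.0 - target) / (1.0 - q)
        biased[letters.index(bias.residue)] = target
    n_proteins = int(np.ceil(n_sites / sites_per_protein))
    spacing = protein_length // (sites_per_protein + 1)
    if spacing < 18:
        raise ContractError("protein_length too small for the requested site density")
    proteome = []
    sites = []
    remaining = n_sites
    for i in range(n_proteins):
        seq = _random_sequence(rng, protein_length, letters, freqs)
        take = min(sites_per_protein, remaining)
        remaining -= take
        for s in range(take):
            pos0 = spacing * (s + 1)  # 0-based, >= 18 from both termini and neighbours
            seq[pos0] = "K"
            if bias is not None:
                seq[pos0 + bias.offset] = str(rng.choice(list(letters), p=biased))
            sites.append(PtmSite(f"ACE{i + 1:05d}", pos0 + 1, "K", "acetyl-K"))
        proteome.append(ProteinSeq(f"ACE{i + 1:05d}", f"synthetic acetylome {i + 1}", "".join(seq)))
    truth = SimulationTruth(
        seed=seed,
        params={"n_sites": n_sites, "protein_length": protein_length,
                "sites_per_protein": sites_per_protein,
                "bias": None if bias is None else vars(bias)},
        data={"background": {ch: float(f) for ch, f in zip(letters, freqs)}},
    )
    return proteome, sites, truth


def shuffle_within_windows(windows, seed: int = 0):
    """Permute each window's non-center, non-gap residues (null model).

    Destroys positional signal while preserving per-window composition, so
    every enrichment ratio tends to 1.
    """
    rng = np.random.default_rng(seed)
    out = []
    for w in windows:
        chars = list(w.window)
        center = len(chars) // 2
        idx = [i for i, c in enumerate(chars) if i != center and c != GAP]
        values = [chars[i] for i in idx]
        rng.shuffle(values)
        for i, v in zip(idx, values):
            chars[i] = v
        out.append(type(w)(w.accession, w.position, "".join(chars)))
    return out


def simulate_spot_arrays(
    peptides: Sequence[str],
    true_binding: Mapping[str, float],
    noise_cv: float = 0.05,
    n_controls: int = 4,
    control_scale: float = 1000.0,
    grid_width: int = 20,
    array_id: str = "A1",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, SimulationTruth]:
    """A SPOT-array layout + raw-intensity grid with known binding strengths.

    raw = control_scale * strength/100 * lognormal(mean 1, cv); hexa-His
    control spots sit at strength 100. With noise_cv = 0 normalization
    recovers the planted strengths exactly.
    """
    if noise_cv < 0:
        raise ContractError("noise_cv must be >= 0")
    if any(true_binding.get(p, 0.0) < 0 for p in peptides):
        raise ContractError("binding strengths must be >= 0")
    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(noise_cv ** 2)))
        noise = lambda: float(rng.lognormal(-sigma ** 2 / 2.0, sigma))  # mean 1
    else:
        noise = lambda: 1.0
    layout_rows, intensity_rows = [], []
    entries = [("HHHHHH", True)] * n_controls + [(p, False) for p in peptides]
    for k, (pep, is_ctrl) in enumerate(entries):
        r, c = divmod(k, grid_width)
        strength = 100.0 if is_ctrl else float(true_binding.get(pep, 0.0))
        raw = control_scale * strength / 100.0 * noise()
        layout_rows.append((array_id, r + 1, c + 1, pep, is_ctrl))
        intensity_rows.append((array_id, r + 1, c + 1, raw))
    layout = pd.DataFrame(layout_rows, columns=["array_id", "row", "col", "peptide", "is_control"])
    intensity = pd.DataFrame(intensity_rows, columns=["array_id", "row", "col", "raw"])
    truth = SimulationTruth(
        seed=seed,
        params={"noise_cv": noise_cv, "n_controls": n_controls,
                "control_scale": control_scale, "array_id": array_id},
        data={"true_binding": {p: float(true_binding.get(p, 0.0)) for p in peptides}},
    )
    return layout, intensity, truth
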