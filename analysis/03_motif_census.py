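#!/usr/bin/env python
"""Census di-lysine and ET-domain motifs on the simulated proteome.

Counts the analytic K-XX-K linker space (400 combinations, 13 histone-like),
scans the simulated proteome for K-XX-K / K-Y / K-YX-K motifs, overlays the
acetyl-K annotation to split hits into unmodified / mono- / di-acetylated
classes, deduplicates peptide windows, and verifies the worked ET-domain
SLiMs (BRD9 LKLVLKV, WHSC1 IKLKI).
"""

from collections import Counter
from pathlib import Path

import pandas as pd

from betrewire import motif_scan, tables_io
from betrewire.motif_scan import et_patterns
from betrewire.synthetic import kxxk_census_sequence

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "data"
OUT = ROOT / "motifs"


def hits_frame(hits):
    return pd.DataFrame(
        [{"accession": h.accession, "anchor1": h.anchor1, "anchor2": h.anchor2,
          "linker": h.linker, "class": h.motif_class, "acetyl_state": h.acetyl_state,
          "window": h.window} for h in hits])


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    print(f"K-XX-K linker space: {motif_scan.enumerate_linker_space()} combinations, "
          f"{len(motif_scan.HISTONE_LIKE_LINKERS)} histone-like")
    census = motif_scan.scan_k_linker_k(kxxk_census_sequence(), 2, 2)
    histone_like = sum(motif_scan.is_histone_like(h.linker) for h in census)
    print(f"census sequence: {len(census)} hits, {histone_like} histone-like")

    proteome = tables_io.read_fasta(DATA / "proteome.fasta")
    sites = tables_io.read_ptm_table(DATA / "kac_sites.tsv", proteome).sites

    all_hits = []
    for name, scanner in [("K-XX-K", lambda s: motif_scan.scan_k_linker_k(s, 2, 2)),
                          ("K-Y", motif_scan.scan_ky),
                          ("K-YX-K", motif_scan.scan_kyxk)]:
        hits = motif_scan.overlay_kac(
            motif_scan.scan_proteome(proteome, scanner), sites)
        states = Counter(h.acetyl_state for h in hits)
        unique = motif_scan.unique_windows(hits)
        print(f"{name}: {len(hits)} hits ({dict(states)}), "
              f"{len(unique)} unique windows")
        all_hits.extend(hits)
    hits_frame(all_hits).to_csv(OUT / "di_lysine_hits.tsv", sep="\t", index=False)

    et_hits = []
    for pname, pattern in et_patterns().items():
        hits = motif_scan.scan_proteome(proteome, motif_scan.scan_et_slim, pattern=pattern)
        print(f"{pname}: {len(hits)} proteome hits")
        et_hits.extend(hits)
    hits_frame(et_hits).to_csv(OUT / "et_slim_hits.tsv", sep="\t", index=False)

    for slim, pname in [("LKLVLKV", "ET_minimal"), ("LKLVLKV", "ET_BRD9like"),
                        ("IKLKI", "ET_WHSC1like")]:
        hits = motif_scan.scan_et_slim(slim, et_patterns()[pname])
        print(f"{slim} vs {pname}: {len(hits)} match(es) at {[h.anchor1 for h in hits]}")


if __name__ == "__main__":
    main()
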