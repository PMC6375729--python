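#!/usr/bin/env python
"""Generate every pipeline input with recorded ground truth.

Emulates the study's data layout: a SAINT-scored AP-MS spectral-count table
(4 BET-like baits, 250 preys, 0/10/60/240 min inhibitor time course, 2
replicates), a synthetic proteome with planted di-lysine and ET-domain
motifs, an acetyl-K site table, and SPOT-array layout/intensity grids.
Outputs land under results/data/ together with JSON truth files.
"""

from pathlib import Path

import numpy as np

from betrewire import synthetic, tables_io

SEED = 20240917
OUT = Path(__file__).resolve().parent.parent / "results" / "data"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # presence_prob < 1 plants a bait-sharing structure (not every prey is
    # recovered with every bait, as in real AP-MS maps)
    table, truth = synthetic.simulate_interactions(
        n_baits=4, n_preys=250, below_detection_fraction=0.25,
        presence_prob=0.6, seed=SEED)
    tables_io.write_interaction_table(table, OUT / "interactions.tsv")
    truth.to_json(OUT / "interactions.truth.json")
    print(f"interaction table: {len(table)} rows, "
          f"{table.groupby(['bait', 'prey']).ngroups} bait-prey pairs")

    proteome, ptruth = synthetic.simulate_proteome(
        n_proteins=80,
        planted_motifs=[("KXXK", 40), ("KY", 30), ("KYXK", 15),
                        ("ET_BRD9like", 8), ("ET_WHSC1like", 8)],
        seed=SEED)
    tables_io.write_fasta(proteome, OUT / "proteome.fasta")
    ptruth.to_json(OUT / "proteome.truth.json")
    print(f"proteome: {len(proteome)} proteins, "
          f"{sum(len(s) for s in proteome)} residues, "
          f"{len(ptruth.data['planted'])} planted motifs")

    sites, struth = synthetic.simulate_ptm_sites(proteome, 0.2, seed=SEED)
    tables_io.write_ptm_table(sites, OUT / "kac_sites.tsv")
    struth.to_json(OUT / "kac_sites.truth.json")
    print(f"acetyl-K sites: {len(sites)}")

    rng = np.random.default_rng(SEED)
    peptides = [f"PEP{i:03d}" for i in range(300)]
    strengths_bd1 = {p: float(rng.uniform(0, 120)) for p in peptides}
    # BD2 binds the same peptides systematically weaker, as on the real arrays
    strengths_bd2 = {p: s * float(rng.uniform(0.3, 1.0)) for p, s in strengths_bd1.items()}
    for domain, strengths in (("BD1", strengths_bd1), ("BD2", strengths_bd2)):
        layout, intensity, sptruth = synthetic.simulate_spot_arrays(
            peptides, strengths, noise_cv=0.05, array_id=domain, seed=SEED)
        layout.to_csv(OUT / f"spot_layout_{domain}.csv", index=False)
        intensity.to_csv(OUT / f"spot_intensity_{domain}.csv", index=False)
        sptruth.to_json(OUT / f"spot_{domain}.truth.json")
    print(f"SPOT arrays: {len(peptides)} peptides x 2 domains")


if __name__ == "__main__":
    main()
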