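#!/usr/bin/env python
"""Generate the synthetic study datasets every later stage consumes.

The field collections behind the original study are not public, so the
analysis runs on coalescent data simulated at the study's scale:

* a focal-virus alignment (87 sequences, 929 sites) from a recent sweep
  (exponential growth, doubling time 1.5 years) with ADAR hyper-mutation
  tracts injected on top, plus the injection truth table;
* a structured two-deme alignment (2 x 20 sequences) for K_ST;
* transmission crosses at maternal/paternal rates 0.9 / 0.5;
* a prevalence survey over eight populations.

Writes FASTA/TSV under results/data/.
"""

import argparse
from pathlib import Path

import numpy as np

from sigmapop.core_io import write_fasta_alignment
from sigmapop.synthetic_data import (
    SimulationConfig,
    inject_adar_tracts,
    simulate_coalescent,
    simulate_crosses,
    simulate_prevalence,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=ROOT / "results" / "data")
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    seeds = [int(s) for s in
             np.random.SeedSequence(args.seed).generate_state(8) % (2**31)]

    growth = float(np.log(2) / 1.5)  # doubling time 1.5 years
    cfg = SimulationConfig(n=87, L=929, theta=40.0, model="exponential",
                           growth_rate=growth, seed=seeds[0])
    ds = simulate_coalescent(cfg)
    edited, truth = inject_adar_tracts(ds.alignment, n_events=4,
                                       tract_mean=6.0, seed=seeds[1])
    write_fasta_alignment(edited, args.outdir / "focal_virus.fasta")
    with open(args.outdir / "focal_virus.adar_truth.tsv", "w") as fh:
        fh.write("seq_id\tcolumn\tsense\n")
        for sid, col, sense in truth:
            fh.write(f"{sid}\t{col}\t{sense}\n")
    print(f"focal virus: n={cfg.n}, L={cfg.L}, true TMRCA "
          f"{ds.tmrca_years:.1f} y, {len(truth)} injected ADAR edits")

    cfg_split = SimulationConfig(n=40, L=929, theta=12.0, model="split",
                                 deme_sizes=(20, 20), split_time=2.0,
                                 seed=seeds[2])
    ds_split = simulate_coalescent(cfg_split)
    write_fasta_alignment(ds_split.alignment, args.outdir / "structured.fasta")
    with open(args.outdir / "structured.metadata.tsv", "w") as fh:
        fh.write("sample_id\tpopulation\n")
        for sid, pop in zip(ds_split.alignment.ids, ds_split.population_labels):
            fh.write(f"{sid}\t{pop}\n")
    print(f"structured pair: split time {cfg_split.split_time} coalescent units")

    crosses = simulate_crosses(20, 18, 8, maternal_rate=0.9, paternal_rate=0.5,
                               offspring_per_cross=(4, 8), seed=seeds[3])
    with open(args.outdir / "crosses.tsv", "w") as fh:
        fh.write("cross_id\tmother_status\tfather_status\toffspring_sex\toffspring_status\n")
        for cr in crosses:
            for sex, infected in cr.offspring:
                fh.write(f"{cr.cross_id}\t{int(cr.mother_infected)}\t"
                         f"{int(cr.father_infected)}\t{sex}\t{int(infected)}\n")
    print(f"crosses: {len(crosses)} (20 maternal, 18 paternal, 8 control)")

    prev = simulate_prevalence(
        {f"pop{i}": (p, 66) for i, p in
         enumerate((0.15, 0.25, 0.35, 0.40, 0.45, 0.50, 0.55, 0.40))},
        seed=seeds[4])
    with open(args.outdir / "prevalence.tsv", "w") as fh:
        fh.write("population\tn_tested\tn_infected\n")
        for pop, (tested, infected) in prev.counts.items():
            fh.write(f"{pop}\t{tested}\t{infected}\n")
    print("prevalence: 8 populations, 66 tested each")


if __name__ == "__main__":
    main()
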