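#!/usr/bin/env python
"""Simulate the full fractionation study and write its tables.

Generates the default 8-fraction, 3-replicate, two-condition experiment
(3,000 transcripts with ground-truth localization proportions, spike-ins,
background RNA content differences, and a 600-protein PSM table with planted
contaminants and outliers) and writes everything under scratch/synthetic/.
"""

from pathlib import Path

from subloc import SimulationConfig, simulate_experiment, write_dataset

# full raw tables are bulky and regenerable: they go to scratch/
OUTDIR = Path(__file__).resolve().parent.parent / "scratch" / "synthetic"
SEED = 1


def main() -> None:
    config = SimulationConfig(seed=SEED)
    dataset = simulate_experiment(config)
    write_dataset(dataset, OUTDIR)
    config.to_yaml(OUTDIR / "config.yaml")

    n_psm = len(dataset.psm_table)
    print(f"simulated {config.n_transcripts} transcripts x "
          f"{config.fraction_count} fractions x {config.replicates} "
          f"replicates x {len(config.conditions)} conditions")
    print(f"simulated {n_psm} PSMs over {config.n_proteins} proteins "
          f"({len(dataset.psm_truth['contaminant_proteins'])} contaminant "
          f"proteins, {len(dataset.psm_truth['outlier_psms'])} outlier PSMs "
          "planted)")
    print(f"tables written to {OUTDIR}")


if __name__ == "__main__":
    main()
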