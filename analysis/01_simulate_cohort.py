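"""Simulate the default study-structured phantom cohort.

Builds the template-space brain phantom and draws the default cohort:
three molecular groups of 50/64/45 lesions with log-normal volumes
(medians 48.4/73.4/45.9 ml) and niche-proximity bias — periventricular
seeding for the oligodendroglioma group, weak and strong SGZ attraction
for the IDH-mutant and IDH-wild-type astrocytoma groups. Writes the cohort
layout (masks, cohort.csv, truth.csv, phantom volumes, config.yaml) under
results/cohort/.

Run:  python analysis/01_simulate_cohort.py [--seed 1]
"""

import argparse
from pathlib import Path

import nichedist as nd


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results/cohort"))
    args = parser.parse_args()

    phantom = nd.make_phantom()
    config = nd.CohortConfig(seed=args.seed)
    records, _, truth = nd.generate_cohort(config, phantom, outdir=args.outdir)

    print(f"phantom: brain {phantom.brain.foreground_count} voxels "
          f"({phantom.brain.foreground_count * phantom.brain.voxel_volume_mm3 / 1000:.0f} ml), "
          f"SVZ band {len(phantom.svz.elements)} voxels, "
          f"SGZ points at {phantom.sgz.elements.round(1).tolist()}")
    print(f"cohort: {len(records)} lesions "
          f"({records.groupby('group').size().to_dict()})")
    clipped = int(truth["clipped"].sum())
    print(f"{clipped} lesions clipped at the brain boundary (flagged in truth.csv)")
    print(f"written to {args.outdir}/")


if __name__ == "__main__":
    main()
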