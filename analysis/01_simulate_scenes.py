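#!/usr/bin/env python
"""Simulate the demo scenes used by the downstream analysis drivers.

Writes, under results/demo/: the pillar-movie truth table, the cell
track table with per-cell true speeds, and control/treated omics
tables with planted changes.  Image stacks are regenerated on the fly
by the later drivers (the generators are deterministic), so no bulky
raster files need to be kept.
"""

import json
from pathlib import Path

import numpy as np

from cellmech import simgen

OUT = Path("results/demo")
SEED = 20260929


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    # pillar movie: central cell, 10 deflected pillars, slow stage drift
    mask = simgen.disk_mask((192, 192), (96, 96), 40)
    spec = simgen.PillarSceneSpec(
        image_shape=(192, 192), pixel_size=0.2, n_frames=20,
        drift_per_frame=(0.05, 0.0), photon_level=500.0, read_noise_sd=2.0,
        cell_mask=mask, seed=SEED,
    )
    spec = simgen.add_random_deflections(spec, 10, (0.1, 0.4))
    scene = simgen.simulate_pillar_sequence(spec)
    scene.truth.round(6).to_csv(OUT / "pillar_truth.csv", index=False)
    n_defl = int((np.hypot(scene.truth.defl_x_um, scene.truth.defl_y_um) > 0)
                 .groupby(scene.truth.pillar_id).any().sum())
    print(f"pillar movie: {len(scene.rest)} pillars, {spec.n_frames} frames, "
          f"{n_defl} deflected, {int(scene.rest.is_reference.sum())} reference")

    # migration tracks: control vs treated speeds (slower after treatment)
    for offset, (label, speed) in enumerate((("control", 0.6), ("treated", 0.35))):
        tracks, truth = simgen.simulate_tracks(simgen.TrackSpec(
            n_cells=20, speed_mean=speed, speed_sd=0.1, seed=SEED + offset,
        ))
        tracks.round(6).to_csv(OUT / f"tracks_{label}.csv", index=False)
        truth.round(6).to_csv(OUT / f"tracks_{label}_truth.csv", index=False)
        print(f"tracks ({label}): {truth.speed_um_per_min.mean():.3f} um/min mean true speed")

    # omics tables with planted hits
    genes, mets = simgen.simulate_omics_table(
        n_genes=500, n_metabolites=40,
        planted_gene_fc={**{i: 5.0 for i in range(6)}, **{i: 0.2 for i in range(6, 10)}},
        planted_metabolite_change={**{i: 0.35 for i in range(4)},
                                   **{i: -0.3 for i in range(4, 7)}},
        noise_sd=0.05, seed=SEED,
    )
    genes.round(6).to_csv(OUT / "genes.csv", index=False)
    mets.round(6).to_csv(OUT / "metabolites.csv", index=False)
    print(f"omics: {genes.truth_flag.sum()} planted gene hits, "
          f"{mets.truth_flag.sum()} planted metabolite hits")

    (OUT / "scene_meta.json").write_text(json.dumps({"seed": SEED}, indent=2))


if __name__ == "__main__":
    main()
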