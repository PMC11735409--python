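#!/usr/bin/env python
"""Generate the synthetic study scenes used by the downstream analyses.

Produces one micropattern (disc) colony and one elongated (capsule)
organoid scene with imperfect 2D detections, and writes their intensity
stacks, per-plane label masks and ground-truth tables under results/01/.
"""

import numpy as np
import pandas as pd

from axialquant import NoiseSpec, SceneSpec, emit_detections, generate_scene
from axialquant.io import write_plane_masks, write_stack, write_table

from _common import RESULTS, SEED

OUT = RESULTS / "01"

NOISE = NoiseSpec(miss_prob=0.02, split_prob=0.05, merge_prob=0.02, jitter_px=1)


def main() -> None:
    for name, spec in {
        "disc": SceneSpec.micropattern(diameter=200.0, n_nuclei=150, rng_seed=SEED),
        "capsule": SceneSpec.notoroid(length=500.0, width=160.0, n_nuclei=220, rng_seed=SEED + 1),
    }.items():
        stack, truth = generate_scene(spec)
        masks = emit_detections(truth, NOISE, np.random.default_rng(SEED + 2))
        d = OUT / name
        d.mkdir(parents=True, exist_ok=True)
        nz, ny, nx = truth.shape
        write_stack(d / "intensity.tif", stack)
        write_plane_masks(d / "plane_masks", masks, (ny, nx), nz)
        rows = [
            {"nucleus_id": n.nucleus_id, "x_um": n.center[0], "y_um": n.center[1],
             "z_um": n.center[2], "zone": n.zone}
            for n in truth.nuclei
        ]
        write_table(d / "ground_truth.csv", pd.DataFrame(rows),
                    {"stage": "simulate", "seed": SEED, "channels": ",".join(truth.channel_names)})
        prov = pd.DataFrame(
            [{"plane": k[0], "label": k[1], "nucleus_id": v, "merged": k in truth.merged_masks}
             for k, v in sorted(truth.mask_to_nucleus.items())]
        )
        write_table(d / "mask_provenance.csv", prov, {"stage": "simulate", "seed": SEED})
        print(f"{name}: {len(truth.nuclei)} nuclei -> {len(masks)} plane masks "
              f"(events {truth.events})")


if __name__ == "__main__":
    main()
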