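"""Size-exclusion contrast: 40 kDa vs 70 kDa dextran leakage on one phantom.

Simulates a dual-channel acquisition (permeable 40 kDa channel, size-excluded
70 kDa channel, clearance and noise on), measures the O/I time course of both
channels with the fixed 5-min mask, and compares the leakage deltas against a
noise floor from matched zero-permeability control simulations.

Writes results/permeability_contrast.csv (per-timepoint traces) and prints
the two deltas with the control floor.
"""

import dataclasses
import sys
from pathlib import Path

import numpy as np
import pandas as pd

from vasomet import permeability as pm
from vasomet import phantom, segmentation

ROOT = Path(__file__).resolve().parents[1]
SEED = 11


def main() -> None:
    spec = phantom.PhantomSpec(frame_shape=(160, 160), n_layers=5, seed=SEED)
    graph = phantom.build_network(spec, n_segments=4, branch_prob=0.4,
                                  radius_range=(3.0, 7.0))
    stack, truth = phantom.simulate_timeseries(graph, spec)
    mask = segmentation.VesselMask(truth.true_mask_2d, spec.pixel_size_um,
                                   {"method": "truth"})
    frames = []
    deltas = {}
    for ch in stack.channel_labels:
        trace = pm.oi_timeseries(stack, mask, ch)
        frames.append(trace.as_frame())
        deltas[ch] = pm.leakage_delta(trace).value
    null_deltas = []
    for ns in range(3):
        null_spec = dataclasses.replace(
            spec, seed=SEED + 1000 + ns,
            tracer_channels=(("FITC40", 40.0, 0.0), ("TRITC70", 70.0, 0.0)))
        null_stack, _ = phantom.simulate_timeseries(graph, null_spec)
        for ch in ("FITC40", "TRITC70"):
            null_deltas.append(pm.leakage_delta(
                pm.oi_timeseries(null_stack, mask, ch)).value)
    floor = float(np.sqrt(np.mean(np.square(null_deltas))))

    out = pd.concat(frames)
    (ROOT / "results").mkdir(exist_ok=True)
    out.to_csv(ROOT / "results" / "permeability_contrast.csv", index=False)
    print(out.pivot(index="timepoint_min", columns="channel",
                    values="oi_ratio").round(4).to_string())
    print(f"\nleakage delta 40 kDa: {deltas['FITC40']:.4f}")
    print(f"leakage delta 70 kDa: {deltas['TRITC70']:.4f}")
    print(f"noise floor (matched zero-permeability controls): {floor:.4f}")
    print(f"40 kDa delta / floor: {deltas['FITC40'] / floor:.1f}x; "
          f"70 kDa delta / floor: {deltas['TRITC70'] / floor:.1f}x")


if __name__ == "__main__":
    sys.exit(main())
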