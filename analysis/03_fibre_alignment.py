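#!/usr/bin/env python
"""Fibre-orientation estimation and the aligned-fraction statistic.

Checks modal-orientation accuracy on stripe fields, then renders fibre
fields of increasing orientation concentration (von Mises kappa) and shows
the fraction of fibres within 10 degrees of the mode rising with alignment —
the statistic used to compare fibroblast-derived matrices.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from ecmquant import synthgen
from ecmquant.fibres import (
    aligned_fraction,
    mode_orientation,
    orientation_histogram,
    structure_tensor_orientation,
)

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    res_dir = ROOT / "results"
    res_dir.mkdir(exist_ok=True)

    rows = []
    for theta0 in (0.0, 30.0, 60.0, 89.0):
        img = synthgen.make_stripe_image(theta0)
        mode = mode_orientation(orientation_histogram(structure_tensor_orientation(img)))
        rows.append(dict(true_angle=theta0, measured_mode=mode,
                         circ_error=abs((mode - theta0 + 90) % 180 - 90)))
    acc = pd.DataFrame(rows)
    acc.to_csv(res_dir / "orientation_accuracy.csv", index=False)
    print("stripe-field orientation accuracy:")
    print(acc.to_string(index=False))

    rows = []
    for kappa in (0.0, 1.0, 4.0, 16.0):
        spec = synthgen.FibreFieldSpec(
            mean_angle_deg=20.0, concentration_kappa=kappa, seed=seed
        )
        img, angles = synthgen.make_fibre_image(spec)
        dist = orientation_histogram(structure_tensor_orientation(img))
        rows.append(
            dict(kappa=kappa, mode_deg=mode_orientation(dist),
                 aligned_fraction=aligned_fraction(dist),
                 drawn_angle_sd=float(np.std(angles)))
        )
    series = pd.DataFrame(rows)
    series.to_csv(res_dir / "fibre_alignment_series.csv", index=False)
    print("\naligned fraction vs orientation concentration:")
    print(series.round(4).to_string(index=False))
    print(f"aligned fraction strictly increasing: "
          f"{series.aligned_fraction.is_monotonic_increasing}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
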