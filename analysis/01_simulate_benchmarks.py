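#!/usr/bin/env python
"""Generate one synthetic benchmark of each assay and record its ground truth.

Images (binary TIFFs) go to scratch/benchmarks/; the machine-readable ground
truth and a summary table go to results/.
"""

import argparse
from pathlib import Path

import pandas as pd

from ecmquant import io, synthgen

ROOT = Path(__file__).resolve().parents[1]


def main(seed: int) -> None:
    img_dir = ROOT / "scratch" / "benchmarks"
    res_dir = ROOT / "results"
    img_dir.mkdir(parents=True, exist_ok=True)
    res_dir.mkdir(exist_ok=True)
    rows = []

    spec = synthgen.SpheroidSpec(seed=seed)
    stack, truth = synthgen.make_spheroid_image(spec)
    io.write_image(img_dir / "spheroid.tif", stack, stack=True)
    synthgen.write_ground_truth_json(truth, res_dir / "spheroid_truth.json")
    rows.append(
        dict(assay="spheroid", n_objects=spec.halo_cell_count + spec.single_cell_count,
             key_truth=f"invasive_area_pct={truth.invasive_area_pct:.2f}")
    )

    fspec = synthgen.FibreFieldSpec(concentration_kappa=4.0, mean_angle_deg=30.0, seed=seed)
    fimg, angles = synthgen.make_fibre_image(fspec)
    io.write_image(img_dir / "fibres.tif", fimg)
    io.write_json(res_dir / "fibre_truth.json", dict(angles_deg=[float(a) for a in angles]))
    rows.append(dict(assay="fibres", n_objects=fspec.fibre_count,
                     key_truth=f"mean_angle={fspec.mean_angle_deg}, kappa={fspec.concentration_kappa}"))

    dspec = synthgen.DegradationFieldSpec(cell_count=120, seed=seed)
    imgs, dtruth = synthgen.make_degradation_image(dspec)
    for name in ("dq", "cytoplasm", "nuclei"):
        io.write_image(img_dir / f"degradation_{name}.tif", getattr(imgs, name))
    synthgen.write_ground_truth_json(dtruth, res_dir / "degradation_truth.json")
    rows.append(dict(assay="degradation", n_objects=dspec.cell_count,
                     key_truth=f"class counts={[dtruth.labels.count(c) for c in (1, 2, 3)]}"))

    sspec = synthgen.SurvivalSimSpec(seed=seed)
    ds, struth = synthgen.make_expression_dataset(sspec)
    # the full matrix is bulky; it lives with the other regenerable artefacts
    ds.values.to_csv(img_dir / "expression.tsv", sep="\t")
    ds.survival.rename_axis("sample_id").to_csv(res_dir / "survival.tsv", sep="\t")
    rows.append(dict(assay="expression", n_objects=sspec.n_samples,
                     key_truth=f"hazard_ratio={sspec.hazard_ratio_high_vs_low}"))

    df = pd.DataFrame(rows)
    df.to_csv(res_dir / "benchmark_manifest.csv", index=False)
    print(df.to_string(index=False))
    print(f"\nimages in {img_dir}, tables in {res_dir}")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    main(ap.parse_args().seed)
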