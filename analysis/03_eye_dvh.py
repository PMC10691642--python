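"""Eye-phantom dose-volume analysis: cDVH curves and D-metrics.

Runs the two clinical situations on the synthetic eye phantom:

* medial tumor + standard 16 mm COMS plaque (uniform and non-uniform
  loading) — shows that non-uniform loading matched at the planning points
  reproduces the uniform cDVHs, and that TG-43 overestimates every
  structure metric relative to the full MC;
* juxtapapillary tumor + notched 20 mm plaque (non-uniform) — shows the
  optic-nerve sparing by the modulay notch wall that the TG-43 water
  formalism cannot see.

Writes results/eye_dvh/: per-structure cDVH CSVs (structure, engine,
dose_Gy, volume_fraction) and a metrics CSV (structure, engine, D1, D20,
D95).

Run:  python analysis/03_eye_dvh.py [--histories N] [--seed S]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from plaquedose.dvh import compute_cdvh, dose_metric
from plaquedose.pipeline import eye_study
from plaquedose.tg43 import load_default_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "eye_dvh"


def write_curves(tag: str, study: dict) -> None:
    exclude = study["phantom"].structures.get("notch_cut")
    with (OUT / f"cdvh_{tag}.csv").open("w") as fh:
        fh.write("structure,engine,dose_gy,volume_fraction\n")
        for engine, key in (("tg43", "tg43_grid"), ("mc", "mc_grid")):
            if key not in study:
                continue
            for name, mask in study["structures"].items():
                m = mask & ~exclude if exclude is not None else mask
                curve = compute_cdvh(study[key], m, structure=name)
                for d, v in zip(curve.bin_edges_gy, curve.volume_fraction):
                    fh.write(f"{name},{engine},{d:.1f},{v:.5f}\n")


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--histories", type=int, default=3_000_000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)
    dataset = load_default_dataset()

    metrics_rows = []

    def collect(tag, study):
        write_curves(tag, study)
        for engine, key in (("tg43", "tg43_metrics"), ("mc", "mc_metrics")):
            if key not in study:
                continue
            for name, mx in study[key].items():
                metrics_rows.append((tag, name, engine, mx[1.0], mx[20.0],
                                     mx[95.0]))

    # the MC-to-TG43 calibration factor scales with the total implanted
    # strength, so each loading computes its own
    s16u = eye_study("coms16_uniform", args.histories, args.seed, dataset)
    s16n = eye_study("coms16_nonuniform", args.histories, args.seed + 1,
                     dataset)
    collect("coms16_uniform", s16u)
    collect("coms16_nonuniform", s16n)
    # uniform vs non-uniform overlay (TG-43 curves, tumor)
    worst = 0.0
    for name, mask in s16u["structures"].items():
        cu = compute_cdvh(s16u["tg43_grid"], mask, structure=name)
        cn = compute_cdvh(s16n["tg43_grid"], mask, structure=name)
        n = min(len(cu.volume_fraction), len(cn.volume_fraction))
        worst = max(worst, float(np.max(np.abs(
            cu.volume_fraction[:n] - cn.volume_fraction[:n]))))
    print(f"16 mm uniform vs non-uniform cDVH: max volume difference "
          f"{100 * worst:.1f}% (curves essentially overlay)")

    sn = eye_study("notched20_nonuniform", args.histories, args.seed + 2,
                   dataset)
    collect("notched20_nonuniform", sn)
    print("notched case: tumor D95 TG-43 "
          f"{sn['tg43_metrics']['tumor'][95.0]:.1f} Gy vs MC "
          f"{sn['mc_metrics']['tumor'][95.0]:.1f} Gy; optic nerve D95 "
          f"TG-43 {sn['tg43_metrics']['optic_nerve'][95.0]:.1f} Gy vs MC "
          f"{sn['mc_metrics']['optic_nerve'][95.0]:.2f} Gy "
          "(notch wall shields the nerve)")

    with (OUT / "metrics.csv").open("w") as fh:
        fh.write("case,structure,engine,D1_gy,D20_gy,D95_gy\n")
        for row in metrics_rows:
            fh.write(f"{row[0]},{row[1]},{row[2]},{row[3]:.2f},"
                     f"{row[4]:.2f},{row[5]:.2f}\n")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
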