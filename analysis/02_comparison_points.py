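"""Peripheral-comparison-point doses for the non-uniformly loaded plaques.

Recomputes the three-engine comparison (analytic TG-43, MC in TG-43 water
mode, full MC with plaque materials) of the dose at the peripheral
comparison point, expressed as a percentage of the TG-43 dose at the
central-axis prescription point, for both the standard 16 mm COMS plaque
and the 20 mm notched plaque.  Writes results/comparison_points.csv.

Run:  python analysis/02_comparison_points.py [--histories N] [--seed S]
"""

from __future__ import annotations

import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from plaquedose.dvh import COMPARISON_POINTS_MM, PRESCRIPTION_POINTS_MM, \
    point_dose
from plaquedose.pipeline import (mc_point_ratio_percent,
                                 mc_to_tg43_calibration, mc_water_run,
                                 seeds_for, tg43_point_doses)
from plaquedose.tg43 import dose_rate_single, load_default_dataset

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--histories", type=int, default=4_000_000)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    OUT.mkdir(parents=True, exist_ok=True)
    dataset = load_default_dataset()
    rows = []
    for preset in ("coms16", "notched20"):
        tg = tg43_point_doses(preset, "nonuniform", dataset)
        _, seeds = seeds_for(preset, "nonuniform")
        water = mc_water_run(preset, "nonuniform", "tg43_water",
                             args.histories, args.seed, dataset)
        p, c = PRESCRIPTION_POINTS_MM[preset], COMPARISON_POINTS_MM[preset]
        w_pct, w_sig = mc_point_ratio_percent(water, seeds, dataset, c, p)
        calib = mc_to_tg43_calibration(preset, "nonuniform",
                                       args.histories // 2, args.seed + 3,
                                       dataset, mc_grid=None)
        full = mc_water_run(preset, "nonuniform", "full", args.histories,
                            args.seed + 1, dataset)
        fc, uf = point_dose(full, c)
        rows.append({
            "plaque": preset,
            "tg43_pct": tg["comparison_percent"],
            "mc_tg43_pct": w_pct,
            "mc_tg43_unc_pct": w_sig,
            "mc_full_pct": 100 * calib * fc / tg["prescription"],
            "mc_full_unc_pct": 100 * uf,
        })
    path = OUT / "comparison_points.csv"
    with path.open("w") as fh:
        fh.write("plaque,tg43_pct,mc_tg43_pct,mc_full_pct\n")
        for r in rows:
            fh.write(f"{r['plaque']},{r['tg43_pct']:.1f},"
                     f"{r['mc_tg43_pct']:.1f},{r['mc_full_pct']:.1f}\n")
            print(f"{r['plaque']:10s}  TG-43 {r['tg43_pct']:6.1f}%   "
                  f"MC(TG-43 mode) {r['mc_tg43_pct']:6.1f}%   "
                  f"full MC {r['mc_full_pct']:6.1f}%")
    print(f"written to {path}")


if __name__ == "__main__":
    main()
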