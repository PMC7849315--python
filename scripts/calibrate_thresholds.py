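"""Regenerate the bundled elongation-threshold calibration.

Bisects the relative-auxin transition thresholds on the full dynamic
model so that default steady states place the epidermal elongation onset
at cell 11 on ammonium and cell 13 on nitrate, then (with --write)
rewrites src/rootzone/config/thresholds.yaml.

Run from the repository root:

    python scripts/calibrate_thresholds.py [--write]
"""

import argparse
from pathlib import Path

import yaml

from rootzone.calibrate import FIXED_CONSTANTS, bisect_threshold

HEADER = """\
# Calibrated artifact constants (regenerate with
# scripts/calibrate_thresholds.py).  A_thr_* are the relative-auxin
# (A/maxA) thresholds that trigger the meristem -> elongation transition,
# calibrated so that default steady states place the epidermal elongation
# onset at cell 11 on ammonium and cell 13 on nitrate.  DIV_thr /
# min_div_length set the division trigger; k_d is the passive lateral
# wall permeability coupling the epidermis and cortex files;
# A_min_transition guards the relative threshold during establishment.
"""


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--write", action="store_true")
    ap.add_argument("--iters", type=int, default=12)
    args = ap.parse_args()

    thr_amm = bisect_threshold(0, iters=args.iters)
    thr_nit = bisect_threshold(1, iters=args.iters)
    print(f"calibrated: A_thr_ammonium={thr_amm:.4f} "
          f"A_thr_nitrate={thr_nit:.4f}")

    if args.write:
        out = Path(__file__).resolve().parents[1] \
            / "src/rootzone/config/thresholds.yaml"
        payload = {"A_thr_ammonium": round(thr_amm, 4),
                   "A_thr_nitrate": round(thr_nit, 4),
                   **FIXED_CONSTANTS}
        out.write_text(HEADER + yaml.safe_dump(payload, sort_keys=False),
                       encoding="utf-8")
        print(f"wrote {out}")


if __name__ == "__main__":
    main()
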