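"""Fit the period and cohort coefficients to the observed mortality surface.

Per-sex Nelder-Mead fits of (p, c) on the log-rate least-squares objective
over the full age x year grid, starting from the neutral point (1, 1).
Writes calibration.csv (sex,p,c,loss,converged) to --out-dir.
"""

import argparse
from pathlib import Path

import saltcvd as sc


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    inputs = args.out_dir / "inputs"
    demo, _, _, _ = sc.read_inputs(inputs)
    m1950_df = sc.core_io.read_mortality_1950(inputs / "mortality_1950.csv")
    m1950 = {sex: m1950_df[sex].to_numpy() for sex in sc.SEXES}

    result = sc.calibrate(demo.observed_mortality, m1950)
    result.to_frame().to_csv(args.out_dir / "calibration.csv", index=False)
    for sex in sc.SEXES:
        print(
            f"{sex}: p = {result.p[sex]:.6f}, c = {result.c[sex]:.6f} "
            f"(loss {result.loss[sex]:.3e}, {result.iterations[sex]} iterations, "
            f"converged={result.converged[sex]})"
        )
    print(f"wrote {args.out_dir}/calibration.csv")


if __name__ == "__main__":
    main()
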