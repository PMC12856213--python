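#!/usr/bin/env python
"""Fit dissociation constants from the simulated EMSA titrations.

For each planted Kd (the bounds of the strong-binder range and the
hairpin-prone outlier) the noiseless table is refit to confirm exact
recovery, and the sigma = 0.05 table is refit with a 1000-replicate
residual bootstrap for a 95% CI. Writes results/tables/kd_fits.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common

from c4map import isotherm


def main() -> None:
    common.ensure_titrations()
    rows = []
    for name, kd in common.KDS_NM.items():
        noiseless = isotherm.read_titration_table(
            common.titration_path(f"{name}_noiseless"), T0=20.0
        )
        clean_fit = isotherm.fit_kd(noiseless)
        noisy = isotherm.read_titration_table(
            common.titration_path(f"{name}_noisy"), T0=20.0
        )
        noisy_fit = isotherm.bootstrap_ci(noisy, n_boot=1000, seed=common.SEED)
        rows.append(
            {
                "substrate": name,
                "planted_Kd_nM": kd,
                "noiseless_fit_nM": round(clean_fit.Kd, 4),
                "rel_err": abs(clean_fit.Kd - kd) / kd,
                "noisy_fit_nM": round(noisy_fit.Kd, 2),
                "ci_low_nM": round(noisy_fit.Kd_ci[0], 2),
                "ci_high_nM": round(noisy_fit.Kd_ci[1], 2),
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(common.TABLES / "kd_fits.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    worst = df["rel_err"].max()
    print(f"=> noiseless refits recover every planted Kd "
          f"(worst relative error {worst:.2e}); noisy fits carry "
          "bootstrap 95% intervals")


if __name__ == "__main__":
    main()
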