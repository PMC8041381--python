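#!/usr/bin/env python
"""Tabulate prediction accuracy against mechanistic covariates.

Writes one long-format table per covariate — predicted colonic fraction
absorbed, dog effective permeability, and the dose/solubility ratio — pairing
each arm's fold error (predicted/observed) with the covariate value, the
basis for trend inspection of where the engines succeed or fail.
"""

from pathlib import Path

from colonsim.evaluation import pairs_from_dataset, trend_table
from colonsim.fixtures_io import load_dataset

OUT = Path(__file__).resolve().parents[1] / "results" / "trends"
COVARIATES = ("predicted_fabs_colon", "peff_dog", "dose_solubility_ratio")


def main() -> None:
    pairs = pairs_from_dataset(load_dataset())
    OUT.mkdir(parents=True, exist_ok=True)
    for cov in COVARIATES:
        table = trend_table(pairs, cov)
        path = OUT / f"fold_error_vs_{cov}.tsv"
        table.to_csv(path, sep="\t", index=False)
        worst = table.loc[table.fold_error.idxmax()] if not table.empty else None
        print(f"{cov}: {len(table)} rows -> {path}")
        if worst is not None:
            print(f"  largest overprediction: {worst.drug} ({worst.formulation}, "
                  f"{worst.software}) fold error {worst.fold_error:.1f} "
                  f"at {cov} = {worst.covariate_value:.3g}")


if __name__ == "__main__":
    main()
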