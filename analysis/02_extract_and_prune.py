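"""Extract covariates at the sampling sites and prune correlated predictors.

Reads the simulated world from results/world/, builds the site x predictor
matrix (nearest-valid-cell fallback inside 50 km), drops predictor pairs
with |Pearson R| > 0.9, and writes the matrix and pruning report under
results/.
"""

import json
from pathlib import Path

from srscape.covariates import extract_at_points, prune_correlated
from srscape.grids import read_raster
from srscape.samples import read_sample_table

WORLD = Path("results/world")
OUT = Path("results")


def load_world():
    parsed = read_sample_table(WORLD / "samples.csv", schema="synthetic")
    stack = {p.stem: read_raster(p) for p in sorted(WORLD.glob("*.tif"))
             if p.stem != "truth"}
    return stack, parsed.records


def main() -> None:
    stack, records = load_world()
    matrix = extract_at_points(stack, records, max_fallback_km=50.0)
    n_fallback = int((matrix.provenance == "nearest-fallback").sum())
    print(f"matrix: {matrix.values.shape[0]} sites x {matrix.values.shape[1]} "
          f"predictors ({n_fallback} nearest-fallback cells)")

    report = prune_correlated(matrix.frame(), threshold=0.9)
    print(f"pruning: kept {len(report.retained)}, dropped {len(report.dropped)}")
    for d in report.dropped:
        print(f"  dropped {d['dropped']} (partner {d['partner']}, R={d['r']})")

    matrix.frame().assign(sr_ratio=matrix.response).to_csv(OUT / "covariate_matrix.csv")
    (OUT / "prune_report.json").write_text(json.dumps(report.as_dict(), indent=2))
    print(f"wrote covariate_matrix.csv and prune_report.json to {OUT}/")


if __name__ == "__main__":
    main()
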