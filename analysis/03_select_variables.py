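"""Three-step forest-based variable selection on the extracted matrix.

Ranks predictors by permutation importance, thresholds irrelevant ones,
then reduces to the smallest nested model within one SD of the best OOB
error, and finally gates redundant variables by the noise-level OOB
fluctuation.  Writes the full step report to results/selection.json.
"""

import json
from pathlib import Path

import pandas as pd

from srscape.selection import select_variables

OUT = Path("results")
SEED = 20250903


def main() -> None:
    frame = pd.read_csv(OUT / "covariate_matrix.csv", index_col=0)
    retained = json.loads((OUT / "prune_report.json").read_text())["retained"]
    y = frame.pop("sr_ratio").to_numpy()
    res = select_variables(frame[retained], y, n_forests=20,
                           n_forests_nested=10, n_trees=150, seed=SEED)
    print("ranking (mean permutation importance):")
    for name in res.ranking:
        marker = ("*" if name in res.prediction else
                  "+" if name in res.interpretation else " ")
        print(f"  {marker} {name:12s} {res.importance_mean[name]:.3e} "
              f"(sd {res.importance_sd[name]:.1e})")
    print(f"thresholded:    {res.thresholded}")
    print(f"interpretation: {res.interpretation}")
    print(f"prediction:     {res.prediction}   (* final, + interpretation)")
    (OUT / "selection.json").write_text(json.dumps(res.as_dict(), indent=2))
    print(f"wrote selection.json to {OUT}/")


if __name__ == "__main__":
    main()
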