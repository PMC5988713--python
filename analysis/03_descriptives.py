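#!/usr/bin/env python
"""Descriptive layer: pairwise correlations, correlation network, PCA.

Computes pairwise-complete Pearson correlations on the modeling (log)
scale, exports the signed edge list used for network plots, and runs a
3-component PCA of the standardized complete cases with group labels, to
show the non-smoker / smoker / COPD gradient.  Run 01_simulate_cohort.py
first.
"""

from pathlib import Path

from copdsem.estimation import Dataset
from copdsem.pipeline import describe

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    data = Dataset.from_csv(OUT / "cohort.csv")
    rep = describe(data)
    rep.to_json(OUT / "descriptives.json")
    rep.edges.to_csv(OUT / "correlation_edges.csv", index=False)
    rep.correlations.to_csv(OUT / "correlation_matrix.csv")

    strong = rep.edges[rep.edges.weight > 0.4].sort_values("weight", ascending=False)
    print("strongest correlations (|r| > 0.4):")
    print(strong.head(12).to_string(index=False))
    print()
    ve = rep.variance_explained
    print("PCA variance explained:", ", ".join(f"{v:.1%}" for v in ve))
    if rep.groups is not None:
        means = rep.pca_scores.groupby(rep.groups.values)["PC1"].mean()
        print("mean PC1 score by group (separation along the first axis):")
        print(means.round(2).to_string())
    print(f"wrote {OUT / 'descriptives.json'}, edge list and matrix CSVs")


if __name__ == "__main__":
    main()
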