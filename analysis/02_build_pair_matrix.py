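#!/usr/bin/env python
"""Build the binary gene-pair indicator matrix for the training platform.

Applies the filter cascade in pipeline order — restrict to the genes
shared with the validation platform (a cross-cohort signature can only
use common genes), drop low-dispersion genes (MAD > 0.5), form all
within-sample pair indicators, and drop pairs whose minority score occurs
in under 20% of samples — logging the attrition at every step.
"""

from pathlib import Path

import pairrank as pr

ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = Path(__file__).resolve().parent.parent / "scratch" / "data"


def main() -> None:
    expr_tr = pr.read_expression(DATA / "expr_train.tsv")
    expr_va = pr.read_expression(DATA / "expr_valid.tsv")

    shared = set(expr_va.index)
    step0 = len(expr_tr)
    expr_tr = pr.restrict_to_genes(expr_tr, shared)
    step1 = len(expr_tr)
    expr_tr = pr.mad_filter(expr_tr, threshold=0.5, log2_transform=True)
    step2 = len(expr_tr)
    indicators = pr.binarize_pairs(expr_tr)
    step3 = len(indicators)
    indicators = pr.prevalence_filter(indicators, min_frac=0.20)
    step4 = len(indicators)

    indicators.to_csv(ROOT / "pairs_train.tsv", sep="\t")
    print(f"genes on training platform:            {step0}")
    print(f"after cross-platform intersection:     {step1}")
    print(f"after MAD > 0.5 (log2 scale):          {step2}")
    print(f"candidate pairs (all combinations):    {step3}")
    print(f"after 20% prevalence filter:           {step4}")
    print(f"wrote {ROOT / 'pairs_train.tsv'}")


if __name__ == "__main__":
    main()
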