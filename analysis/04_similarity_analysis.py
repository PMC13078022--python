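#!/usr/bin/env python
"""Pair-class similarity analysis: are clonal pairs molecularly more
alike than non-clonal pairs, and are non-clonal pairs any more alike
than random inter-patient pairs?

Computes Spearman correlations of copy-number, signature and expression
profiles per biopsy pair, clinicopathological concordances, the
shared-driver-mutation fractions over clonal pairs, and the
between-class Mann-Whitney comparisons.

Input: results/cohort/, results/pairs.tsv.
Output: results/pair_classes.tsv, results/similarity_tests.tsv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mfclone.clonality import ClonalityResult, PairKey
from mfclone.io import load_cohort
from mfclone.similarity import (
    CLASS_CLONAL,
    CLASS_INTER,
    CLASS_NONCLONAL,
    compute_pair_metrics,
    enumerate_pair_classes,
    records_to_frame,
    shared_mutation_fraction,
)
from mfclone.simulate import DEFAULT_DRIVER_GENES
from mfclone.stats import compare_numeric_groups


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--pairs", type=Path, default=Path("results/pairs.tsv"))
    ap.add_argument("--n-inter", type=int, default=50)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = load_cohort(
        sample_sheet=args.cohort / "sample_sheet.tsv",
        mutations=args.cohort / "mutations.maf.tsv",
        copy_number=args.cohort / "copy_number.seg",
        expression=args.cohort / "expression.tsv",
        signatures=args.cohort / "signatures.tsv",
        driver_genes=DEFAULT_DRIVER_GENES,
    )
    pairs = pd.read_csv(args.pairs, sep="\t")
    results = [
        ClonalityResult(
            pair=PairKey.make(r.biopsy_a, r.biopsy_b),
            score=r.score, p_value=r.p_value, n_perm=0, call=r.call,
            seed=int(r.seed), n_shared=int(r.n_shared))
        for r in pairs.itertuples(index=False)
    ]
    records = enumerate_pair_classes(cohort, results, n_inter=args.n_inter,
                                     seed=args.seed)
    compute_pair_metrics(records, cohort, method="spearman")
    df = records_to_frame(records)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    df.to_csv(args.out_dir / "pair_classes.tsv", sep="\t", index=False)

    shared = shared_mutation_fraction(records, cohort.mutations, DEFAULT_DRIVER_GENES)
    print(f"driver mutations shared within clonal pairs (pooled): "
          f"{100 * shared.pooled_shared_fraction:.0f}%")
    print(shared.cooccurrence.to_string(index=False))

    rows = []
    for metric in ("cn_correlation", "signature_correlation",
                   "expression_correlation"):
        vals = {
            cls: df.loc[df.pair_class == cls, metric].dropna().tolist()
            for cls in (CLASS_CLONAL, CLASS_NONCLONAL, CLASS_INTER)
        }
        for a, b in ((CLASS_CLONAL, CLASS_NONCLONAL),
                     (CLASS_NONCLONAL, CLASS_INTER)):
            cmp = compare_numeric_groups({a: vals[a], b: vals[b]}, feature=metric)
            rows.append({
                "metric": metric, "group_a": a, "group_b": b,
                "median_a": np.median(vals[a]), "median_b": np.median(vals[b]),
                "p_value": cmp.p_value,
            })
            print(f"{metric}: {a} median {np.median(vals[a]):.3f} vs "
                  f"{b} median {np.median(vals[b]):.3f}, "
                  f"Mann-Whitney p = {cmp.p_value:.2e}")
    pd.DataFrame(rows).to_csv(args.out_dir / "similarity_tests.tsv",
                              sep="\t", index=False)


if __name__ == "__main__":
    main()
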