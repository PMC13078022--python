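#!/usr/bin/env python
"""Unit-level and NTL group comparisons.

TMP vs TNEM: fraction of genome altered (on the max-deviation CN
aggregate), tumor mutational burden (first biopsy per nodule), driver
alteration counts (on the mutation union), and cell-cycle gene-set
scores.  NTL: fibrosis gene-set scores of IM vs MO/mixed patients.

Input: results/cohort/, results/pairs.tsv.
Output: results/unit_comparisons.tsv, results/ntl_fibrosis.tsv.
"""

import argparse
import json
from pathlib import Path

import numpy as np
import pandas as pd

from mfclone.clonality import ClonalityResult, PairKey
from mfclone.io import load_cohort
from mfclone.lineage import classify_cohort
from mfclone.pipeline import PipelineConfig, unit_comparisons
from mfclone.similarity import gene_set_score
from mfclone.simulate import CELLCYCLE_GENES, DEFAULT_DRIVER_GENES, FIBROSIS_GENES
from mfclone.stats import compare_numeric_groups


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--pairs", type=Path, default=Path("results/pairs.tsv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = load_cohort(
        sample_sheet=args.cohort / "sample_sheet.tsv",
        mutations=args.cohort / "mutations.maf.tsv",
        copy_number=args.cohort / "copy_number.seg",
        expression=args.cohort / "expression.tsv",
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
    _, units, _ = classify_cohort(cohort, results)

    cfg = PipelineConfig(simulation=None, inputs={})  # only tunables used here
    cmp_df = unit_comparisons(cohort, units, cfg)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    cmp_df.to_csv(args.out_dir / "unit_comparisons.tsv", sep="\t", index=False)
    print("TMP vs TNEM comparisons:")
    print(cmp_df.to_string(index=False))

    # cell-cycle program in tumors: representative biopsies, NTL as reference
    ntl = [cohort.expression[s.biopsy_id] for s in cohort.samples
           if s.tissue == "NTL" and s.biopsy_id in cohort.expression]
    cc_scores = {"TMP": [], "TNEM": []}
    for u in units:
        for b in u.representative_biopsies:
            if b in cohort.expression:
                cc_scores[u.kind].append(
                    gene_set_score(cohort.expression[b], list(CELLCYCLE_GENES), ntl))
    cmp = compare_numeric_groups(cc_scores, feature="cellcycle_score")
    print(f"cell-cycle score: TMP median "
          f"{np.median(cc_scores['TMP']):.2f} vs TNEM median "
          f"{np.median(cc_scores['TNEM']):.2f}, p = {cmp.p_value:.2e}")

    # NTL fibrosis program by patient class
    truth = json.loads((args.cohort / "ground_truth.json").read_text())
    labels = truth["patient_label"]
    fib = {"IM": [], "MO_mixed": []}
    for s in cohort.samples:
        if s.tissue != "NTL" or s.biopsy_id not in cohort.expression:
            continue
        grp = "IM" if labels[s.patient_id] == "IM" else "MO_mixed"
        fib[grp].append(
            gene_set_score(cohort.expression[s.biopsy_id], list(FIBROSIS_GENES), ntl))
    cmp = compare_numeric_groups(fib, feature="fibrosis_score")
    pd.DataFrame({
        "group": [g for g, v in fib.items() for _ in v],
        "fibrosis_score": [x for v in fib.values() for x in v],
    }).to_csv(args.out_dir / "ntl_fibrosis.tsv", sep="\t", index=False)
    print(f"NTL fibrosis score: IM median {np.median(fib['IM']):.2f} vs "
          f"MO/mixed median {np.median(fib['MO_mixed']):.2f}, "
          f"p = {cmp.p_value:.2e}")


if __name__ == "__main__":
    main()
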