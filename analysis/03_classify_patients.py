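#!/usr/bin/env python
"""Classify patients as IM / MO / mixed from the pair calls, build
TMP/TNEM tumor units, and check the labels against the ground truth.

Input: results/cohort/, results/pairs.tsv.
Output: results/patients.tsv, results/units.tsv.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mfclone.clonality import ClonalityResult, PairKey
from mfclone.io import load_cohort
from mfclone.lineage import classify_cohort, unit_summaries


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--cohort", type=Path, default=Path("results/cohort"))
    ap.add_argument("--pairs", type=Path, default=Path("results/pairs.tsv"))
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    cohort = load_cohort(sample_sheet=args.cohort / "sample_sheet.tsv")
    pairs = pd.read_csv(args.pairs, sep="\t")
    results = [
        ClonalityResult(
            pair=PairKey.make(r.biopsy_a, r.biopsy_b),
            score=r.score, p_value=r.p_value, n_perm=0, call=r.call,
            seed=int(r.seed), n_shared=int(r.n_shared))
        for r in pairs.itertuples(index=False)
    ]
    classifications, units, relations = classify_cohort(cohort, results)

    patients = pd.DataFrame([
        {"patient_id": c.patient_id, "label": c.label,
         "n_clonal_pairs": c.n_clonal_pairs,
         "n_nonclonal_pairs": c.n_nonclonal_pairs}
        for c in classifications])
    units_df = pd.DataFrame([
        {"unit_id": u.unit_id, "patient_id": u.patient_id, "kind": u.kind,
         "nodules": ",".join(sorted(u.member_nodules)),
         "biopsies": ",".join(u.member_biopsies),
         "representatives": ",".join(u.representative_biopsies)}
        for u in units])
    args.out_dir.mkdir(parents=True, exist_ok=True)
    patients.to_csv(args.out_dir / "patients.tsv", sep="\t", index=False)
    units_df.to_csv(args.out_dir / "units.tsv", sep="\t", index=False)

    counts = patients["label"].value_counts().to_dict()
    print(f"patients: {counts.get('IM', 0)} IM, {counts.get('MO', 0)} MO, "
          f"{counts.get('mixed', 0)} mixed")
    s = unit_summaries(units)
    print(f"tumor units: {s.n_tmp} TMP, {s.n_tnem} TNEM; "
          f"TMP nodules mean {s.tmp_nodules_mean:.2f} range {s.tmp_nodules_range}")
    conflicts = [r for r in relations if r.conflict]
    if conflicts:
        print(f"note: {len(conflicts)} nodule pairs had conflicting biopsy-pair calls")

    truth_path = args.cohort / "ground_truth.json"
    if truth_path.exists():
        truth = json.loads(truth_path.read_text())["patient_label"]
        acc = (patients.set_index("patient_id")["label"]
               .eq(pd.Series(truth)).mean())
        print(f"label accuracy vs ground truth: {100 * acc:.1f}%")


if __name__ == "__main__":
    main()
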