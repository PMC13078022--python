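"""Pair-class similarity framework and tumor-unit comparison metrics.

Biopsy pairs fall in three classes: clonal and non-clonal (intra-patient,
inter-nodule, from the clonality calls) and inter-patient (random
cross-patient pairs, default n = 50).  For each pair, molecular similarity
is measured as the correlation (Spearman by default) between copy-number,
signature-activity or expression profiles, and clinicopathological
concordance as same/different/missing per feature.  Unit-level metrics
cover the fraction of genome altered, tumor mutational burden, driver
alteration counts, shared-mutation fractions over clonal pairs, and mean
z-score gene-set signatures.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clonality import ClonalityResult, PairKey, SCOPE_INTER
from .io import Cohort
from .types import BiopsySample, CopyNumberProfile, ExpressionProfile, MutationProfile

logger = logging.getLogger(__name__)

CLASS_CLONAL = "clonal"
CLASS_NONCLONAL = "non_clonal"
CLASS_INTER = "inter_patient"

DEFAULT_N_INTER = 50
DEFAULT_CALLABLE_MB = 35.0

# Couinaud segments sharing a common boundary (hepatic vein or portal triad)
# are considered neighboring; configurable.
COUINAUD_NEIGHBORS: Set[frozenset] = {
    frozenset(p)
    for p in [
        (1, 2), (1, 4), (1, 7), (1, 8),
        (2, 3), (2, 4), (3, 4), (4, 5),
        (4, 8), (5, 6), (5, 8), (6, 7), (7, 8),
    ]
}


@dataclass
class PairClassRecord:
    pair: PairKey
    pair_class: str  # clonal | non_clonal | inter_patient
    metrics: Dict[str, float] = field(default_factory=dict)
    concordances: Dict[str, str] = field(default_factory=dict)


def enumerate_pair_classes(
    cohort: Cohort,
    results: Sequence[ClonalityResult],
    n_inter: int = DEFAULT_N_INTER,
    seed: int = 0,
) -> List[PairClassRecord]:
    """Label intra-patient pairs by their clonality call and sample
    ``n_inter`` random cross-patient tumor biopsy pairs (uniform, without
    replacement, seed-deterministic)."""
    if n_inter < 1:
        raise ValueError("n_inter must be >= 1")
    records = [
        PairClassRecord(
            pair=r.pair,
            pair_class=CLASS_CLONAL if r.call == "clonal" else CLASS_NONCLONAL,
        )
        for r in results
    ]
    tumors = cohort.tumor_samples
    cross = [
        PairKey.make(a.biopsy_id, b.biopsy_id, scope=SCOPE_INTER)
        for i, a in enumerate(tumors)
        for b in tumors[i + 1 :]
        if a.patient_id != b.patient_id
    ]
    cross.sort(key=lambda p: (p.biopsy_a, p.biopsy_b))
    if n_inter > len(cross):
        raise ValueError(
            f"requested {n_inter} inter-patient pairs but only {len(cross)} exist"
        )
    rng = np.random.default_rng([seed])
    chosen = rng.choice(len(cross), size=n_inter, replace=False)
    records.extend(
        PairClassRecord(pair=cross[i], pair_class=CLASS_INTER) for i in sorted(chosen)
    )
    return records


def first_biopsy_filter(
    records: Sequence[PairClassRecord], samples: Sequence[BiopsySample]
) -> List[PairClassRecord]:
    """Keep pairs whose members are both the first biopsy of their nodule."""
    firsts = set()
    by_nodule: Dict[Tuple[str, str], List[BiopsySample]] = {}
    for s in samples:
        if s.is_tumor:
            by_nodule.setdefault((s.patient_id, s.nodule_id), []).append(s)
    for nod_samples in by_nodule.values():
        t_min = min(s.timepoint for s in nod_samples)
        firsts.add(min(s.biopsy_id for s in nod_samples if s.timepoint == t_min))
    return [
        r for r in records if r.pair.biopsy_a in firsts and r.pair.biopsy_b in firsts
    ]


def profile_correlation(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "spearman",
) -> Optional[float]:
    """Pearson or Spearman (average ranks for ties) correlation.

    Returns None (with a warning) when either profile has zero variance.
    """
    x = np.asarray(values_a, dtype=float)
    y = np.asarray(values_b, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("profiles must share a coordinate universe of >= 3 positions")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        logger.warning("zero-variance profile: correlation undefined")
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if method == "pearson":
            r = sps.pearsonr(x, y).statistic
        elif method == "spearman":
            r = sps.spearmanr(x, y).statistic
        else:
            raise ValueError(f"unknown correlation method {method!r}")
    return float(r)


def categorical_concordance(
    sample_a: BiopsySample,
    sample_b: BiopsySample,
    feature: str,
    segment_neighbors: Optional[Set[frozenset]] = None,
) -> str:
    """same / different / missing for one clinicopathological feature.

    For ``liver_segment``, identical or neighboring Couinaud segments both
    count as ``same``.
    """
    known = {"grade", "growth_pattern", "liver_segment"}
    if feature in known:
        va, vb = getattr(sample_a, feature), getattr(sample_b, feature)
    elif feature in sample_a.clinical or feature in sample_b.clinical:
        va = sample_a.clinical.get(feature)
        vb = sample_b.clinical.get(feature)
    else:
        raise ValueError(f"unknown feature {feature!r}")
    if va is None or vb is None:
        return "missing"
    if feature == "liver_segment":
        if segment_neighbors is None:
            segment_neighbors = COUINAUD_NEIGHBORS
        if int(va) == int(vb) or frozenset((int(va), int(vb))) in segment_neighbors:
            return "same"
        return "different"
    return "same" if va == vb else "different"


def fraction_genome_altered(profile: CopyNumberProfile) -> float:
    """Length-weighted fraction of the genome with non-neutral copy number."""
    if len(profile.bins) == 0:
        raise ValueError("empty copy-number profile")
    lengths = profile.bins.lengths
    altered = profile.states != profile.ploidy_neutral
    return float(lengths[altered].sum() / lengths.sum())


def tumor_mutational_burden(
    n_variants_or_profile, callable_mb: float = DEFAULT_CALLABLE_MB
) -> float:
    """Somatic mutations per callable megabase."""
    if callable_mb <= 0:
        raise ValueError("callable_mb must be positive")
    if isinstance(n_variants_or_profile, MutationProfile):
        n = len(n_variants_or_profile)
    elif isinstance(n_variants_or_profile, (int, np.integer)):
        n = int(n_variants_or_profile)
    else:
        n = len(n_variants_or_profile)
    return n / callable_mb


def driver_alteration_count(
    variants: Mapping[str, object], driver_genes: Sequence[str]
) -> int:
    """Number of driver genes with >= 1 alteration (gene counted once).

    For tumor units, pass the aggregated mutation union.
    """
    if not driver_genes:
        raise ValueError("empty driver gene list")
    drivers = set(driver_genes)
    hit = {v.gene for v in variants.values() if v.gene in drivers}
    return len(hit)


@dataclass
class SharedMutationSummary:
    """Driver-mutation sharing over clonal pairs and the non-clonal /
    inter-patient co-occurrence statistics."""

    pooled_shared_fraction: float          # shared occurrences / all occurrences, pooled
    mean_pair_shared_fraction: Optional[float]  # mean of per-pair fractions
    per_gene: pd.DataFrame                 # gene, n_shared, n_private, shared_fraction
    cooccurrence: pd.DataFrame             # pair_class, n_pairs, any_driver, same_gene_diff_variant


def _driver_keys(profile: MutationProfile, drivers: set) -> Dict[str, str]:
    return {k: v.gene for k, v in profile.variants.items() if v.gene in drivers}


def shared_mutation_fraction(
    records: Sequence[PairClassRecord],
    profiles: Mapping[str, MutationProfile],
    driver_genes: Sequence[str],
) -> SharedMutationSummary:
    """Fractions of driver-gene mutations shared within clonal pairs.

    The primary statistic pools variant occurrences across all clonal
    pairs: a driver variant present in both members of a pair counts as
    one shared occurrence; present in one member, one private occurrence.
    The per-pair mean is reported alongside.  For non-clonal and
    inter-patient pairs, counts pairs with any driver hit and with
    different variants of the same driver gene.
    """
    drivers = set(driver_genes)
    clonal = [r for r in records if r.pair_class == CLASS_CLONAL]
    if not clonal:
        raise ValueError("no clonal pairs available")
    per_gene_counts: Dict[str, List[int]] = {}
    pair_fracs = []
    for r in clonal:
        da = _driver_keys(profiles[r.pair.biopsy_a], drivers)
        db = _driver_keys(profiles[r.pair.biopsy_b], drivers)
        union = set(da) | set(db)
        shared = set(da) & set(db)
        for key in union:
            gene = da.get(key) or db.get(key)
            rec = per_gene_counts.setdefault(gene, [0, 0])
            rec[0 if key in shared else 1] += 1
        if union:
            pair_fracs.append(len(shared) / len(union))
    n_shared = sum(v[0] for v in per_gene_counts.values())
    n_total = sum(v[0] + v[1] for v in per_gene_counts.values())
    per_gene = pd.DataFrame(
        [
            {
                "gene": g,
                "n_shared": c[0],
                "n_private": c[1],
                "shared_fraction": c[0] / (c[0] + c[1]),
            }
            for g, c in sorted(per_gene_counts.items())
        ],
        columns=["gene", "n_shared", "n_private", "shared_fraction"],
    )
    co_rows = []
    for cls in (CLASS_NONCLONAL, CLASS_INTER):
        cls_records = [r for r in records if r.pair_class == cls]
        any_hit = same_gene = 0
        for r in cls_records:
            da = _driver_keys(profiles[r.pair.biopsy_a], drivers)
            db = _driver_keys(profiles[r.pair.biopsy_b], drivers)
            if da or db:
                any_hit += 1
            genes_a = {g for k, g in da.items()}
            genes_b = {g for k, g in db.items()}
            for gene in genes_a & genes_b:
                keys_a = {k for k, g in da.items() if g == gene}
                keys_b = {k for k, g in db.items() if g == gene}
                if not (keys_a & keys_b):  # hit in both, but no identical variant
                    same_gene += 1
                    break
        co_rows.append(
            {
                "pair_class": cls,
                "n_pairs": len(cls_records),
                "any_driver": any_hit,
                "same_gene_diff_variant": same_gene,
            }
        )
    return SharedMutationSummary(
        pooled_shared_fraction=n_shared / n_total if n_total else float("nan"),
        mean_pair_shared_fraction=float(np.mean(pair_fracs)) if pair_fracs else None,
        per_gene=per_gene,
        cooccurrence=pd.DataFrame(co_rows),
    )


def gene_set_score(
    profile: ExpressionProfile,
    gene_set: Sequence[str],
    reference: Sequence[ExpressionProfile],
) -> float:
    """Mean z-score of the set genes against a reference collection.

    Per gene, z = (value - reference mean) / reference SD; genes with zero
    reference SD (or absent from the universe) are excluded with a
    warning.  Errors if no set gene is usable.
    """
    if not reference:
        raise ValueError("reference collection is empty")
    present = [g for g in gene_set if g in profile.values.index]
    if not present:
        raise ValueError("no gene of the set is present in the expression universe")
    ref = pd.DataFrame({p.biopsy_id: p.values for p in reference})
    zs = []
    for g in present:
        mu = ref.loc[g].mean()
        sd = ref.loc[g].std(ddof=0)
        if sd == 0:
            logger.warning("gene %s has zero reference SD; excluded from score", g)
            continue
        zs.append((profile.values[g] - mu) / sd)
    if not zs:
        raise ValueError("all set genes have zero reference variance")
    return float(np.mean(zs))


def _cn_vector(profile: CopyNumberProfile) -> np.ndarray:
    return np.asarray(profile.states, dtype=float)


def compute_pair_metrics(
    records: Sequence[PairClassRecord],
    cohort: Cohort,
    method: str = "spearman",
    features: Sequence[str] = ("grade", "growth_pattern", "liver_segment"),
) -> List[PairClassRecord]:
    """Fill per-pair similarity metrics and concordances in place.

    Metrics: cn_correlation, signature_correlation, expression_correlation
    (None when a layer is missing for either member).
    """
    by_id = {s.biopsy_id: s for s in cohort.samples}
    for r in records:
        a, b = r.pair.biopsy_a, r.pair.biopsy_b
        if a in cohort.copy_number and b in cohort.copy_number:
            r.metrics["cn_correlation"] = profile_correlation(
                _cn_vector(cohort.copy_number[a]),
                _cn_vector(cohort.copy_number[b]),
                method=method,
            )
        if a in cohort.signatures and b in cohort.signatures:
            ea = cohort.signatures[a].exposures
            eb = cohort.signatures[b].exposures.reindex(ea.index)
            r.metrics["signature_correlation"] = profile_correlation(
                ea.to_numpy(), eb.to_numpy(), method=method
            )
        if a in cohort.expression and b in cohort.expression:
            xa = cohort.expression[a].values
            xb = cohort.expression[b].values.reindex(xa.index)
            r.metrics["expression_correlation"] = profile_correlation(
                xa.to_numpy(), xb.to_numpy(), method=method
            )
        for feat in features:
            r.concordances[feat] = categorical_concordance(by_id[a], by_id[b], feat)
    return list(records)


def records_to_frame(records: Sequence[PairClassRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "biopsy_a": r.pair.biopsy_a,
            "biopsy_b": r.pair.biopsy_b,
            "pair_class": r.pair_class,
        }
        row.update(r.metrics)
        row.update({f"concordance_{k}": v for k, v in r.concordances.items()})
        rows.append(row)
    return pd.DataFrame(rows)
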