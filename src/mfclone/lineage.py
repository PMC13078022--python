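"""Patient-level lineage classification and tumor-unit construction.

From pairwise biopsy clonality calls we derive nodule-level relations,
classify each patient as IM (intrahepatic metastasis: all nodule pairs
clonal), MO (multicentric occurrence: all pairs non-clonal) or mixed, and
partition nodules into tumor units: a TMP (tumor with metastatic
potential) is a connected component of >= 2 clonally related nodules; a
TNEM (tumor with no evidence of metastasis) is a singleton.

Unit-level aggregation follows the rules: mutations are the union over
member biopsies; copy number takes, per bin, the state deviating most from
neutral ploidy; representative biopsies are the earliest biopsy of each
member nodule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import networkx as nx
import numpy as np

from .clonality import ClonalityResult
from .io import Cohort
from .types import BiopsySample, CopyNumberProfile, MutationProfile, ValidationError

LABEL_IM = "IM"
LABEL_MO = "MO"
LABEL_MIXED = "mixed"

KIND_TMP = "TMP"
KIND_TNEM = "TNEM"


@dataclass(frozen=True)
class NoduleRelation:
    """Clonality relation between two distinct nodules of one patient."""

    patient_id: str
    nodule_a: str
    nodule_b: str
    call: str  # "clonal" | "non_clonal"
    n_clonal_biopsy_pairs: int = 0
    n_nonclonal_biopsy_pairs: int = 0
    conflict: bool = False

    def __post_init__(self):
        if self.nodule_a >= self.nodule_b:
            raise ValueError("NoduleRelation requires nodule_a < nodule_b")


@dataclass(frozen=True)
class PatientClassification:
    patient_id: str
    label: str
    n_clonal_pairs: int
    n_nonclonal_pairs: int


@dataclass
class TumorUnit:
    unit_id: str
    patient_id: str
    kind: str  # "TMP" | "TNEM"
    member_nodules: FrozenSet[str]
    member_biopsies: Tuple[str, ...]
    representative_biopsies: Tuple[str, ...] = ()
    representative_ties: Tuple[str, ...] = ()  # nodules whose representative was tie-broken


def nodule_relation(
    patient_id: str,
    nodule_a: str,
    nodule_b: str,
    biopsy_pair_results: Sequence[ClonalityResult],
) -> NoduleRelation:
    """Aggregate biopsy-pair calls between two nodules into one relation.

    Any-clonal rule: a single clonal biopsy pair makes the nodule pair
    clonal (dropout can mask sharing in other biopsies); conflicting calls
    are flagged.
    """
    if not biopsy_pair_results:
        raise ValidationError(
            f"no biopsy-pair results between nodules {nodule_a!r} and {nodule_b!r}"
        )
    n_clonal = sum(1 for r in biopsy_pair_results if r.call == "clonal")
    n_non = len(biopsy_pair_results) - n_clonal
    a, b = sorted((nodule_a, nodule_b))
    return NoduleRelation(
        patient_id=patient_id,
        nodule_a=a,
        nodule_b=b,
        call="clonal" if n_clonal else "non_clonal",
        n_clonal_biopsy_pairs=n_clonal,
        n_nonclonal_biopsy_pairs=n_non,
        conflict=bool(n_clonal and n_non),
    )


def relations_from_results(
    cohort: Cohort, results: Sequence[ClonalityResult]
) -> List[NoduleRelation]:
    """Group biopsy-pair results by nodule pair and aggregate each."""
    by_id = {s.biopsy_id: s for s in cohort.samples}
    grouped: Dict[Tuple[str, str, str], List[ClonalityResult]] = {}
    for r in results:
        sa, sb = by_id[r.pair.biopsy_a], by_id[r.pair.biopsy_b]
        if sa.patient_id != sb.patient_id:
            continue
        na, nb = sorted((sa.nodule_id, sb.nodule_id))
        grouped.setdefault((sa.patient_id, na, nb), []).append(r)
    return [
        nodule_relation(pid, na, nb, rs)
        for (pid, na, nb), rs in sorted(grouped.items())
    ]


def _patient_nodules(relations: Sequence[NoduleRelation]) -> List[str]:
    nodules = set()
    for r in relations:
        nodules.update((r.nodule_a, r.nodule_b))
    return sorted(nodules)


def _check_complete(patient_id: str, relations: Sequence[NoduleRelation]) -> List[str]:
    nodules = _patient_nodules(relations)
    have = {(r.nodule_a, r.nodule_b) for r in relations}
    missing = [
        (a, b)
        for i, a in enumerate(nodules)
        for b in nodules[i + 1 :]
        if (a, b) not in have
    ]
    if missing:
        raise ValidationError(
            f"patient {patient_id!r}: incomplete nodule relations, missing pairs {missing}"
        )
    return nodules


def classify_patient(
    patient_id: str, relations: Sequence[NoduleRelation]
) -> PatientClassification:
    """IM iff all nodule pairs clonal; MO iff all non-clonal; else mixed.

    Requires the complete relation graph over the patient's nodules.
    """
    if not relations:
        raise ValidationError(f"patient {patient_id!r}: no nodule relations")
    _check_complete(patient_id, relations)
    n_clonal = sum(1 for r in relations if r.call == "clonal")
    n_non = sum(1 for r in relations if r.call == "non_clonal")
    if n_clonal and not n_non:
        label = LABEL_IM
    elif n_non and not n_clonal:
        label = LABEL_MO
    else:
        label = LABEL_MIXED
    return PatientClassification(
        patient_id=patient_id,
        label=label,
        n_clonal_pairs=n_clonal,
        n_nonclonal_pairs=n_non,
    )


def build_tumor_units(
    patient_id: str,
    relations: Sequence[NoduleRelation],
    samples: Optional[Sequence[BiopsySample]] = None,
) -> List[TumorUnit]:
    """Partition a patient's nodules into TMPs and TNEMs.

    Clonality is treated as transitive: TMPs are connected components of
    the clonal-relation graph with >= 2 nodules; singletons become TNEMs.
    Intransitive triangles (A~B, B~C but A!~C) are absorbed into one
    component; they are detectable via the relation table.
    """
    nodules = _check_complete(patient_id, relations)
    graph = nx.Graph()
    graph.add_nodes_from(nodules)
    graph.add_edges_from(
        (r.nodule_a, r.nodule_b) for r in relations if r.call == "clonal"
    )
    components = sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0])
    biopsies_by_nodule: Dict[str, List[BiopsySample]] = {n: [] for n in nodules}
    if samples:
        for s in samples:
            if s.patient_id == patient_id and s.is_tumor and s.nodule_id in biopsies_by_nodule:
                biopsies_by_nodule[s.nodule_id].append(s)
    units = []
    for i, comp in enumerate(components, start=1):
        members = frozenset(comp)
        kind = KIND_TMP if len(members) >= 2 else KIND_TNEM
        member_biopsies = []
        reps, ties = [], []
        for nod in sorted(members):
            nod_samples = biopsies_by_nodule[nod]
            member_biopsies.extend(s.biopsy_id for s in nod_samples)
            if nod_samples:
                rep, tied = _first_biopsy(nod_samples)
                reps.append(rep)
                if tied:
                    ties.append(nod)
        units.append(
            TumorUnit(
                unit_id=f"{patient_id}_U{i}",
                patient_id=patient_id,
                kind=kind,
                member_nodules=members,
                member_biopsies=tuple(sorted(member_biopsies)),
                representative_biopsies=tuple(reps),
                representative_ties=tuple(ties),
            )
        )
    return units


def _first_biopsy(nod_samples: Sequence[BiopsySample]) -> Tuple[str, bool]:
    """Earliest-timepoint biopsy of a nodule; ties -> smallest biopsy_id."""
    t_min = min(s.timepoint for s in nod_samples)
    earliest = sorted(s.biopsy_id for s in nod_samples if s.timepoint == t_min)
    return earliest[0], len(earliest) > 1


def representative_biopsies(
    unit: TumorUnit, samples: Sequence[BiopsySample]
) -> List[str]:
    """First (earliest-timepoint) biopsy per member nodule of a unit."""
    reps = []
    for nod in sorted(unit.member_nodules):
        nod_samples = [
            s for s in samples
            if s.patient_id == unit.patient_id and s.nodule_id == nod
        ]
        if nod_samples:
            reps.append(_first_biopsy(nod_samples)[0])
    return reps


def aggregate_mutations(
    unit: TumorUnit, profiles: Mapping[str, MutationProfile]
) -> Dict[str, object]:
    """Union of variants over all member biopsies (variant_key -> call)."""
    merged: Dict[str, object] = {}
    for biopsy_id in unit.member_biopsies:
        if biopsy_id not in profiles:
            raise ValidationError(
                f"unit {unit.unit_id}: missing mutation profile for {biopsy_id!r}"
            )
        merged.update(profiles[biopsy_id].variants)
    return merged


def aggregate_copy_number(
    unit: TumorUnit, profiles: Mapping[str, CopyNumberProfile]
) -> CopyNumberProfile:
    """Per bin, the member state deviating most from neutral ploidy.

    Deep losses are preserved rather than overwritten by neutral states; a
    tie between a gain and a loss of equal magnitude resolves to the gain.
    """
    members = list(unit.member_biopsies)
    missing = [b for b in members if b not in profiles]
    if missing:
        raise ValidationError(f"unit {unit.unit_id}: missing CN profiles for {missing}")
    if not members:
        raise ValidationError(f"unit {unit.unit_id}: no member biopsies")
    first = profiles[members[0]]
    for b in members[1:]:
        if profiles[b].bins != first.bins:
            raise ValidationError(
                f"unit {unit.unit_id}: inconsistent binning between members"
            )
    states = np.stack([profiles[b].states for b in members])
    neutral = first.ploidy_neutral
    dev = np.abs(states - neutral)
    # among max-deviation states per bin, prefer the gain on gain/loss ties
    max_dev = dev.max(axis=0)
    candidate = np.where(dev == max_dev, states, -1)
    agg = candidate.max(axis=0)
    return CopyNumberProfile(
        biopsy_id=unit.unit_id, bins=first.bins, states=agg, ploidy_neutral=neutral
    )


def unit_clinical_status(unit: TumorUnit, samples: Sequence[BiopsySample]) -> BiopsySample:
    """Clinical status of a unit: the nodule holding the unit's globally
    earliest biopsy; returns that biopsy's sample record."""
    members = [
        s for s in samples
        if s.patient_id == unit.patient_id and s.biopsy_id in unit.member_biopsies
    ]
    if not members:
        raise ValidationError(f"unit {unit.unit_id}: no member samples found")
    return min(members, key=lambda s: (s.timepoint, s.biopsy_id))


@dataclass
class UnitSummary:
    n_tmp: int
    n_tnem: int
    tmp_nodules_mean: Optional[float]
    tmp_nodules_range: Optional[Tuple[int, int]]
    tmp_biopsies_mean: Optional[float]
    per_patient: Dict[str, Dict[str, int]] = field(default_factory=dict)


def unit_summaries(units: Sequence[TumorUnit]) -> UnitSummary:
    """Counts and nodule/biopsy statistics per unit kind.

    With no TMPs the mean and range are reported as absent (None), not 0.
    """
    tmps = [u for u in units if u.kind == KIND_TMP]
    tnems = [u for u in units if u.kind == KIND_TNEM]
    per_patient: Dict[str, Dict[str, int]] = {}
    for u in units:
        rec = per_patient.setdefault(u.patient_id, {KIND_TMP: 0, KIND_TNEM: 0})
        rec[u.kind] += 1
    if tmps:
        sizes = [len(u.member_nodules) for u in tmps]
        nb = [len(u.member_biopsies) for u in tmps]
        return UnitSummary(
            n_tmp=len(tmps),
            n_tnem=len(tnems),
            tmp_nodules_mean=float(np.mean(sizes)),
            tmp_nodules_range=(min(sizes), max(sizes)),
            tmp_biopsies_mean=float(np.mean(nb)) if any(nb) else None,
            per_patient=per_patient,
        )
    return UnitSummary(
        n_tmp=0,
        n_tnem=len(tnems),
        tmp_nodules_mean=None,
        tmp_nodules_range=None,
        tmp_biopsies_mean=None,
        per_patient=per_patient,
    )


def classify_cohort(
    cohort: Cohort, results: Sequence[ClonalityResult]
) -> Tuple[List[PatientClassification], List[TumorUnit], List[NoduleRelation]]:
    """Full patient classification and unit construction for a cohort.

    Patients with a single tumor nodule contribute no pairs and are
    classified as neither IM nor MO; they receive one TNEM unit.
    """
    relations = relations_from_results(cohort, results)
    by_patient: Dict[str, List[NoduleRelation]] = {}
    for r in relations:
        by_patient.setdefault(r.patient_id, []).append(r)
    classifications, units = [], []
    for patient_id in cohort.patients:
        rels = by_patient.get(patient_id, [])
        patient_tumors = [
            s for s in cohort.samples if s.patient_id == patient_id and s.is_tumor
        ]
        if not patient_tumors:
            continue
        if rels:
            classifications.append(classify_patient(patient_id, rels))
            units.extend(build_tumor_units(patient_id, rels, cohort.samples))
        else:
            # single-nodule patient: one TNEM, no classification
            nodule = patient_tumors[0].nodule_id
            rep, _ = _first_biopsy(patient_tumors)
            units.append(
                TumorUnit(
                    unit_id=f"{patient_id}_U1",
                    patient_id=patient_id,
                    kind=KIND_TNEM,
                    member_nodules=frozenset([nodule]),
                    member_biopsies=tuple(sorted(s.biopsy_id for s in patient_tumors)),
                    representative_biopsies=(rep,),
                )
            )
    return classifications, units, relations
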