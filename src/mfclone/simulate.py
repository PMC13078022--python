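"""Synthetic multifocal-HCC cohort generator with known ground truth.

The generator emulates the structure of a multifocal liver-cancer cohort:
patients carry 2-4 tumor nodules, each biopsied 1-2 times (serial
timepoints), plus 1-2 non-tumor liver (NTL) biopsies.  Patients are IM
(all nodules one clone), MO (all nodules independent) or mixed.  Clonally
related nodule sets share trunk variants drawn from the rare tail of a
power-law cohort variant pool and co-segregating copy-number events;
every nodule adds private frequency-proportional pool variants, so
recurrent hotspot mutations arise independently across patients.  Tumors
belonging to a multi-nodule clone carry a cell-cycle expression program
(metastatic phenotype); NTL of MO/mixed patients carries a fibrosis
program shift.  All output is fully determined by the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .clonality import VariantPool
from .io import (
    Cohort,
    compute_cohort_frequencies,
    write_copy_number,
    write_expression_matrix,
    write_mutations,
    write_sample_sheet,
    write_signature_matrix,
)
from .types import (
    BiopsySample,
    CopyNumberProfile,
    ExpressionProfile,
    GenomeBins,
    MutationProfile,
    SignatureActivity,
    ValidationError,
    VariantCall,
)

DEFAULT_DRIVER_GENES = (
    "CTNNB1", "TP53", "ALB", "ARID1A", "ARID2", "AXIN1", "PTEN",
    "CDKN2A", "RB1", "KEAP1", "NFE2L2", "TSC2", "BAP1", "PIK3CA",
    "TERT", "APOB", "CDKN1A", "HNF1A", "ACVR2A", "RPS6KA3",
)

CELLCYCLE_GENES = (
    "TTK", "BUB1", "NUF2", "CDCA3", "MKI67", "CCNB1", "CDK1", "PLK1",
    "AURKA", "E2F1",
) + tuple(f"CCS{i:03d}" for i in range(1, 41))

FIBROSIS_GENES = (
    "COL1A1", "COL3A1", "ACTA2", "TIMP1", "MMP9", "NFKB1", "ASNS",
    "BCL2", "TGFB1", "PDGFRB",
) + tuple(f"FIB{i:03d}" for i in range(1, 41))

SIGNATURE_IDS = ("SBS1", "SBS4", "SBS5", "SBS16", "SBS22")

GROWTH_PATTERNS = ("trabecular", "solid", "pseudoglandular", "macrotrabecular")
GRADES = ("I", "II", "III", "IV")

# Couinaud adjacency used to place clonal nodules near each other
_SEGMENT_NEIGHBORS = {
    1: (2, 4, 7, 8), 2: (1, 3, 4), 3: (2, 4), 4: (1, 2, 3, 5, 8),
    5: (4, 6, 8), 6: (5, 7), 7: (1, 6, 8), 8: (1, 4, 5, 7),
}


@dataclass
class SimulationConfig:
    """Tunable parameters of the cohort generator (see docs/methods.md)."""

    n_IM: int = 10
    n_MO: int = 9
    n_mixed: int = 3
    nodules_per_patient: Tuple[int, int] = (2, 4)
    biopsies_per_nodule: Tuple[int, int] = (1, 2)
    ntl_per_patient: Tuple[int, int] = (1, 2)
    pool_size: int = 10_000
    freq_spectrum: float = 1.0   # power-law exponent of pool frequencies
    freq_max: float = 0.3        # propensity of the most recurrent variant
    rare_threshold: float = 0.01  # trunk variants come from this tail
    lambda_trunk: float = 20.0
    lambda_private: float = 30.0
    dropout: float = 0.05        # per-biopsy variant dropout probability
    lambda_biopsy_private: float = 1.0
    n_cn_bins: int = 500
    n_cn_chroms: int = 10
    cn_bin_size: int = 1_000_000
    n_cn_candidate_events: int = 40
    p_shared_cn_event: float = 0.30
    p_private_cn_event: float = 0.15
    expr_genes: int = 2000
    cellcycle_effect: float = 1.0   # log2 shift in TMP-derived tumors
    fibrosis_effect: float = 1.0    # log2 shift in MO/mixed NTL
    component_expr_sd: float = 0.6
    nodule_expr_sd: float = 0.3
    noise_sd: float = 0.5
    n_signatures: int = 5
    driver_genes: Tuple[str, ...] = DEFAULT_DRIVER_GENES
    seed: int = 0

    def validate(self) -> None:
        n_patients = self.n_IM + self.n_MO + self.n_mixed
        if n_patients <= 0:
            raise ValidationError("cohort must contain at least one patient")
        if min(self.n_IM, self.n_MO, self.n_mixed) < 0:
            raise ValidationError("patient counts must be non-negative")
        lo, hi = self.nodules_per_patient
        if not (1 <= lo <= hi):
            raise ValidationError("nodules_per_patient range is empty")
        if self.n_mixed > 0 and hi < 3:
            raise ValidationError("mixed patients need >= 3 nodules")
        if self.n_IM > 0 and hi < 2:
            raise ValidationError("IM patients need >= 2 nodules")
        for p in (self.p_shared_cn_event, self.p_private_cn_event, self.dropout):
            if not 0 <= p <= 1:
                raise ValidationError(f"probability out of range: {p}")
        if self.pool_size <= 0 or self.expr_genes <= 0 or self.n_cn_bins <= 0:
            raise ValidationError("pool_size, expr_genes, n_cn_bins must be positive")


@dataclass
class GroundTruth:
    """The generating clonal structure of a simulated cohort."""

    patient_label: Dict[str, str]                 # patient -> IM | MO | mixed
    clonal_components: Dict[str, List[List[str]]]  # patient -> nodule partition
    trunk_variants: Dict[str, List[str]]          # "patient/idx" -> variant keys

    def validate(self) -> None:
        for patient, comps in self.clonal_components.items():
            label = self.patient_label[patient]
            multi = [c for c in comps if len(c) >= 2]
            single = [c for c in comps if len(c) == 1]
            if label == "IM" and (len(comps) != 1 or not multi):
                raise ValidationError(f"{patient}: IM must have one all-covering component")
            if label == "MO" and multi:
                raise ValidationError(f"{patient}: MO must have only singletons")
            if label == "mixed" and not (multi and single):
                raise ValidationError(f"{patient}: mixed needs both kinds")

    def to_json(self) -> str:
        return json.dumps(
            {
                "patient_label": self.patient_label,
                "clonal_components": self.clonal_components,
                "trunk_variants": self.trunk_variants,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        return cls(
            patient_label=d["patient_label"],
            clonal_components=d["clonal_components"],
            trunk_variants=d["trunk_variants"],
        )


# ---------------------------------------------------------------------------
# variant pool


def build_design_pool(config: SimulationConfig) -> Tuple[VariantPool, List[VariantCall]]:
    """Power-law rank-frequency pool with gene annotations.

    Every 50th rank is a driver-gene hotspot (round-robin over the driver
    panel), so recurrent driver mutations span the frequency spectrum.
    """
    n = config.pool_size
    ranks = np.arange(1, n + 1, dtype=float)
    freq = config.freq_max * ranks ** (-config.freq_spectrum)
    refs = ("A", "C", "G", "T")
    alts = ("G", "T", "A", "C")
    calls = []
    for i in range(n):
        if i % 50 == 0:
            gene = config.driver_genes[(i // 50) % len(config.driver_genes)]
        else:
            gene = f"GENE{i:05d}"
        calls.append(
            VariantCall(
                chrom=str((i % 22) + 1),
                pos=10_000 + 13 * i,
                ref=refs[i % 4],
                alt=alts[i % 4],
                gene=gene,
                is_driver=gene in config.driver_genes,
            )
        )
    freq_map = {c.variant_key: f for c, f in zip(calls, freq)}
    pool = VariantPool(freq_map, f_min=float(freq.min()))
    return pool, calls


def _draw_variant_indices(
    rng: np.random.Generator,
    probs: np.ndarray,
    count: int,
    eligible: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Frequency-proportional draw without replacement (numpy choice)."""
    if eligible is None:
        eligible = np.arange(len(probs))
    p = probs[eligible] / probs[eligible].sum()
    count = min(count, len(eligible))
    return rng.choice(eligible, size=count, replace=False, p=p)


# ---------------------------------------------------------------------------
# cohort assembly


def _partition_nodules(
    rng: np.random.Generator, label: str, nodules: List[str]
) -> List[List[str]]:
    if label == "IM":
        return [list(nodules)]
    if label == "MO":
        return [[n] for n in nodules]
    # mixed: one multi-nodule component, the rest singletons
    k = int(rng.integers(2, len(nodules)))
    members = sorted(rng.choice(len(nodules), size=k, replace=False).tolist())
    comp = [nodules[i] for i in members]
    rest = [[n] for n in nodules if n not in comp]
    return [comp] + rest


def simulate_cohort(config: SimulationConfig) -> Tuple[Cohort, GroundTruth]:
    """Generate a full cohort (all layers) plus its ground truth.

    Deterministic in ``config.seed``; layers are mutually consistent
    (shared biopsy ids, shared gene/signature/bin universes).
    """
    config.validate()
    root = np.random.default_rng([config.seed, 92821])
    rng_struct = np.random.default_rng(root.integers(2**31, size=4))
    rng_mut = np.random.default_rng(root.integers(2**31, size=4))
    rng_cn = np.random.default_rng(root.integers(2**31, size=4))
    rng_expr = np.random.default_rng(root.integers(2**31, size=4))
    rng_sig = np.random.default_rng(root.integers(2**31, size=4))
    rng_clin = np.random.default_rng(root.integers(2**31, size=4))

    pool, pool_calls = build_design_pool(config)
    probs = pool.freq / pool.freq.sum()
    key_to_call = {c.variant_key: c for c in pool_calls}
    pool_keys = pool.keys
    rare = np.flatnonzero(pool.freq <= config.rare_threshold)

    labels = ["IM"] * config.n_IM + ["MO"] * config.n_MO + ["mixed"] * config.n_mixed
    n_patients = len(labels)
    patients = [f"P{i + 1:02d}" for i in range(n_patients)]

    # genome bins for copy number
    per_chrom = max(1, config.n_cn_bins // config.n_cn_chroms)
    chroms, starts, ends = [], [], []
    for c in range(1, config.n_cn_chroms + 1):
        for b in range(per_chrom):
            chroms.append(str(c))
            starts.append(b * config.cn_bin_size)
            ends.append((b + 1) * config.cn_bin_size)
    bins = GenomeBins(tuple(chroms), tuple(starts), tuple(ends))
    n_bins = len(bins)
    # candidate CN events: (bin slice, state)
    events = []
    for _ in range(config.n_cn_candidate_events):
        start = int(rng_cn.integers(0, n_bins))
        length = int(rng_cn.integers(3, 26))
        state = int(rng_cn.choice([0, 1, 3, 4, 5]))
        events.append((start, min(start + length, n_bins), state))

    # expression universe
    n_named = len(CELLCYCLE_GENES) + len(FIBROSIS_GENES)
    fillers = [f"G{i:05d}" for i in range(max(0, config.expr_genes - n_named))]
    genes = list(CELLCYCLE_GENES) + list(FIBROSIS_GENES) + fillers
    gene_index = pd.Index(genes, name="gene_id")
    baseline = rng_expr.normal(5.0, 2.0, size=len(genes))
    cc_mask = np.isin(gene_index, CELLCYCLE_GENES)
    fib_mask = np.isin(gene_index, FIBROSIS_GENES)

    samples: List[BiopsySample] = []
    variants_by_biopsy: Dict[str, Dict[str, VariantCall]] = {}
    cn_profiles: Dict[str, CopyNumberProfile] = {}
    expr_profiles: Dict[str, ExpressionProfile] = {}
    sig_profiles: Dict[str, SignatureActivity] = {}
    patient_label: Dict[str, str] = {}
    clonal_components: Dict[str, List[List[str]]] = {}
    trunk_variants: Dict[str, List[str]] = {}

    nod_lo, nod_hi = config.nodules_per_patient
    b_lo, b_hi = config.biopsies_per_nodule
    alpha = np.ones(config.n_signatures)

    for patient, label in zip(patients, labels):
        patient_label[patient] = label
        lo = max(nod_lo, 3) if label == "mixed" else max(nod_lo, 2)
        n_nod = int(rng_struct.integers(lo, nod_hi + 1))
        nodules = [f"N{j + 1}" for j in range(n_nod)]
        components = _partition_nodules(rng_struct, label, nodules)
        clonal_components[patient] = [sorted(c) for c in components]

        nodule_variants: Dict[str, Dict[str, VariantCall]] = {n: {} for n in nodules}
        nodule_cn: Dict[str, np.ndarray] = {}
        nodule_segment: Dict[str, int] = {}
        nodule_grade: Dict[str, str] = {}
        nodule_growth: Dict[str, str] = {}
        comp_expr: Dict[str, np.ndarray] = {}
        comp_sig: Dict[str, np.ndarray] = {}
        comp_is_multi: Dict[str, bool] = {}

        for ci, comp in enumerate(components):
            # trunk variants from the rare tail (multi-nodule clones only)
            trunk_idx = np.array([], dtype=int)
            if len(comp) >= 2:
                k = int(rng_mut.poisson(config.lambda_trunk))
                if k:
                    trunk_idx = _draw_variant_indices(rng_mut, probs, k, rare)
            trunk_variants[f"{patient}/{ci}"] = sorted(
                pool_keys[i] for i in trunk_idx
            )
            # component-level CN events
            comp_states = np.full(n_bins, 2, dtype=int)
            take = rng_cn.random(len(events)) < config.p_shared_cn_event
            for (s, e, st), sel in zip(events, take):
                if sel:
                    comp_states[s:e] = st
            # component expression / signature programs
            ceff = rng_expr.normal(0.0, config.component_expr_sd, size=len(genes))
            comp_sig_vec = rng_sig.dirichlet(alpha)
            # clonal-component clinical seed
            home_seg = int(rng_clin.integers(1, 9))
            comp_grade = str(rng_clin.choice(["II", "III"]))
            comp_growth = str(rng_clin.choice(GROWTH_PATTERNS))
            for nod in comp:
                comp_expr[nod] = ceff
                comp_sig[nod] = comp_sig_vec
                comp_is_multi[nod] = len(comp) >= 2
                k_priv = int(rng_mut.poisson(config.lambda_private))
                priv_idx = (
                    _draw_variant_indices(rng_mut, probs, k_priv) if k_priv else []
                )
                variants = {pool_keys[i]: key_to_call[pool_keys[i]] for i in trunk_idx}
                variants.update(
                    {pool_keys[i]: key_to_call[pool_keys[i]] for i in priv_idx}
                )
                nodule_variants[nod] = variants
                states = comp_states.copy()
                take_p = rng_cn.random(len(events)) < config.p_private_cn_event
                for (s, e, st), sel in zip(events, take_p):
                    if sel:
                        states[s:e] = st
                nodule_cn[nod] = states
                if rng_clin.random() < 0.8:
                    seg = (
                        home_seg
                        if rng_clin.random() < 0.6
                        else int(rng_clin.choice(_SEGMENT_NEIGHBORS[home_seg]))
                    )
                else:
                    seg = int(rng_clin.integers(1, 9))
                nodule_segment[nod] = seg
                nodule_grade[nod] = (
                    comp_grade if rng_clin.random() < 0.85 else str(rng_clin.choice(GRADES))
                )
                nodule_growth[nod] = (
                    comp_growth
                    if rng_clin.random() < 0.85
                    else str(rng_clin.choice(GROWTH_PATTERNS))
                )

        # biopsies
        for j, nod in enumerate(nodules):
            n_biop = int(rng_struct.integers(b_lo, b_hi + 1))
            nod_expr_eff = rng_expr.normal(0.0, config.nodule_expr_sd, size=len(genes))
            for k in range(n_biop):
                biopsy_id = f"{patient}_{nod}_B{k + 1}"
                timepoint = float(k * n_nod + j)
                samples.append(
                    BiopsySample(
                        patient_id=patient,
                        biopsy_id=biopsy_id,
                        tissue="tumor",
                        nodule_id=nod,
                        timepoint=timepoint,
                        liver_segment=nodule_segment[nod],
                        grade=nodule_grade[nod],
                        growth_pattern=nodule_growth[nod],
                    )
                )
                # mutation profile: dropout + biopsy-private noise variants
                keep = {
                    key: call
                    for key, call in nodule_variants[nod].items()
                    if rng_mut.random() >= config.dropout
                }
                k_noise = int(rng_mut.poisson(config.lambda_biopsy_private))
                for i in (
                    _draw_variant_indices(rng_mut, probs, k_noise) if k_noise else []
                ):
                    keep.setdefault(pool_keys[i], key_to_call[pool_keys[i]])
                if not keep:  # clonality scoring requires non-empty profiles
                    i = int(_draw_variant_indices(rng_mut, probs, 1)[0])
                    keep[pool_keys[i]] = key_to_call[pool_keys[i]]
                variants_by_biopsy[biopsy_id] = keep
                cn_profiles[biopsy_id] = CopyNumberProfile(
                    biopsy_id=biopsy_id, bins=bins, states=nodule_cn[nod].copy()
                )
                vals = (
                    baseline
                    + comp_expr[nod]
                    + nod_expr_eff
                    + rng_expr.normal(0.0, config.noise_sd, size=len(genes))
                )
                if comp_is_multi[nod]:
                    vals = vals + config.cellcycle_effect * cc_mask
                expr_profiles[biopsy_id] = ExpressionProfile(
                    biopsy_id=biopsy_id, values=pd.Series(vals, index=gene_index)
                )
                sig_vec = 0.9 * comp_sig[nod] + 0.1 * rng_sig.dirichlet(alpha)
                sig_profiles[biopsy_id] = SignatureActivity(
                    biopsy_id=biopsy_id,
                    exposures=pd.Series(sig_vec, index=list(SIGNATURE_IDS)[: config.n_signatures]),
                )

        # NTL biopsies with class-dependent fibrosis program
        n_ntl = int(rng_struct.integers(config.ntl_per_patient[0], config.ntl_per_patient[1] + 1))
        pat_eff = rng_expr.normal(0.0, config.nodule_expr_sd, size=len(genes))
        for k in range(n_ntl):
            biopsy_id = f"{patient}_NTL_B{k + 1}"
            samples.append(
                BiopsySample(
                    patient_id=patient,
                    biopsy_id=biopsy_id,
                    tissue="NTL",
                    timepoint=float(k),
                )
            )
            vals = baseline + pat_eff + rng_expr.normal(0.0, config.noise_sd, size=len(genes))
            if label in ("MO", "mixed"):
                vals = vals + config.fibrosis_effect * fib_mask
            expr_profiles[biopsy_id] = ExpressionProfile(
                biopsy_id=biopsy_id, values=pd.Series(vals, index=gene_index)
            )

    biopsy_to_patient = {b: b.split("_")[0] for b in variants_by_biopsy}
    cohort_freq = compute_cohort_frequencies(variants_by_biopsy, biopsy_to_patient)
    mutations = {
        b: MutationProfile(biopsy_id=b, variants=v, cohort_freq=cohort_freq)
        for b, v in variants_by_biopsy.items()
    }
    cohort = Cohort(
        samples=sorted(
            samples,
            key=lambda s: (s.patient_id, s.nodule_id or "", s.timepoint, s.biopsy_id),
        ),
        mutations=mutations,
        copy_number=cn_profiles,
        expression=expr_profiles,
        signatures=sig_profiles,
        driver_genes=config.driver_genes,
    )
    truth = GroundTruth(
        patient_label=patient_label,
        clonal_components=clonal_components,
        trunk_variants=trunk_variants,
    )
    truth.validate()
    return cohort, truth


def write_fixture(cohort: Cohort, truth: GroundTruth, out_dir) -> Dict[str, Path]:
    """Write a simulated cohort in the cohort_io file formats."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "sample_sheet": out / "sample_sheet.tsv",
        "mutations": out / "mutations.maf.tsv",
        "copy_number": out / "copy_number.seg",
        "expression": out / "expression.tsv",
        "signatures": out / "signatures.tsv",
        "ground_truth": out / "ground_truth.json",
    }
    write_sample_sheet(cohort.samples, paths["sample_sheet"])
    write_mutations(cohort.mutations, paths["mutations"])
    write_copy_number(cohort.copy_number, paths["copy_number"])
    write_expression_matrix(cohort.expression, paths["expression"])
    write_signature_matrix(cohort.signatures, paths["signatures"])
    paths["ground_truth"].write_text(truth.to_json())
    return paths


def spike_shared_driver(
    cohort: Cohort, truth: GroundTruth, gene: str, patients: Sequence[str]
) -> Cohort:
    """Insert distinct variants of one driver gene into separate nodules.

    Each named patient's nodules each receive a unique (non-identical)
    variant of ``gene`` in all their biopsies, producing downstream
    "different mutations in the same gene" pairs.  An empty patient list
    leaves the cohort unchanged.
    """
    if gene not in cohort.driver_genes:
        raise ValidationError(f"{gene!r} is not in the configured driver panel")
    known = set(cohort.patients)
    for p in patients:
        if p not in known:
            raise ValidationError(f"unknown patient {p!r}")
    if not patients:
        return cohort
    counter = 0
    new_variants = {b: dict(m.variants) for b, m in cohort.mutations.items()}
    for patient in patients:
        nodules = sorted(
            {s.nodule_id for s in cohort.samples if s.patient_id == patient and s.is_tumor}
        )
        for nod in nodules:
            counter += 1
            call = VariantCall(
                chrom="X",
                pos=1_000_000 + counter,
                ref="C",
                alt="T",
                gene=gene,
                is_driver=True,
            )
            for s in cohort.samples:
                if s.patient_id == patient and s.nodule_id == nod:
                    new_variants[s.biopsy_id][call.variant_key] = call
    biopsy_to_patient = {b: cohort.sample_by_id(b).patient_id for b in new_variants}
    cohort_freq = compute_cohort_frequencies(new_variants, biopsy_to_patient)
    cohort.mutations = {
        b: MutationProfile(biopsy_id=b, variants=v, cohort_freq=cohort_freq)
        for b, v in new_variants.items()
    }
    return cohort


# ---------------------------------------------------------------------------
# helpers for calibration / sensitivity studies


def simulate_independent_profiles(
    config: SimulationConfig, n_profiles: int, seed: int
) -> Tuple[List[MutationProfile], VariantPool]:
    """Independent nodule mutation profiles drawn from the design pool.

    Used to study the null behavior of the clonality test: profiles share
    variants only through pool collisions, and ``cohort_freq`` is the
    design pool frequency, so the permutation null matches the generative
    process exactly.
    """
    pool, pool_calls = build_design_pool(config)
    probs = pool.freq / pool.freq.sum()
    key_to_call = {c.variant_key: c for c in pool_calls}
    rng = np.random.default_rng([seed, 70717])
    freq_map = dict(zip(pool.keys, pool.freq))
    profiles = []
    for i in range(n_profiles):
        k = max(1, int(rng.poisson(config.lambda_private)))
        idx = _draw_variant_indices(rng, probs, k)
        variants = {pool.keys[j]: key_to_call[pool.keys[j]] for j in idx}
        profiles.append(
            MutationProfile(biopsy_id=f"null_{i:04d}", variants=variants, cohort_freq=freq_map)
        )
    return profiles, pool


def simulate_clonal_pairs(
    config: SimulationConfig,
    n_pairs: int,
    seed: int,
    min_trunk: int = 5,
) -> Tuple[List[Tuple[MutationProfile, MutationProfile]], VariantPool]:
    """Clonal biopsy pairs sharing >= ``min_trunk`` rare trunk variants.

    Trunk counts are Poisson(lambda_trunk) truncated below at
    ``min_trunk``; trunk variants come from the pool tail with frequency
    <= ``rare_threshold``.  Each member adds Poisson(lambda_private)
    private variants.
    """
    pool, pool_calls = build_design_pool(config)
    probs = pool.freq / pool.freq.sum()
    key_to_call = {c.variant_key: c for c in pool_calls}
    rare = np.flatnonzero(pool.freq <= config.rare_threshold)
    rng = np.random.default_rng([seed, 80808])
    freq_map = dict(zip(pool.keys, pool.freq))
    pairs = []
    for i in range(n_pairs):
        k_trunk = max(min_trunk, int(rng.poisson(config.lambda_trunk)))
        trunk = _draw_variant_indices(rng, probs, k_trunk, rare)
        members = []
        for side in "ab":
            k_priv = int(rng.poisson(config.lambda_private))
            priv = _draw_variant_indices(rng, probs, k_priv) if k_priv else []
            variants = {pool.keys[j]: key_to_call[pool.keys[j]] for j in trunk}
            variants.update({pool.keys[j]: key_to_call[pool.keys[j]] for j in priv})
            members.append(
                MutationProfile(
                    biopsy_id=f"clonal_{i:04d}_{side}",
                    variants=variants,
                    cohort_freq=freq_map,
                )
            )
        pairs.append((members[0], members[1]))
    return pairs, pool
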