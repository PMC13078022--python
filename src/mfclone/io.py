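"""Readers, writers and validation for all cohort inputs and outputs.

File conventions
----------------
* Sample sheet: TSV with columns ``patient_id, nodule_id, biopsy_id,
  timepoint, tissue, liver_segment, grade, growth_pattern`` (tumor rows
  require ``nodule_id`` and ``timepoint``).
* Mutations: MAF-like TSV with ``Chromosome, Start_Position,
  Reference_Allele, Tumor_Seq_Allele2, Hugo_Symbol, Tumor_Sample_Barcode``.
* Copy number: SEG (``ID, chrom, loc.start, loc.end, CN``), rebinned onto
  fixed windows.
* Expression / signatures: TSV matrices with genes (signatures) as rows and
  biopsy ids as columns.

Variants are 1-based (MAF/VCF convention); copy-number bins are 0-based
half-open (BED convention).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .types import (
    BiopsySample,
    CopyNumberProfile,
    ExpressionProfile,
    FormatError,
    GenomeBins,
    MutationProfile,
    SignatureActivity,
    ValidationError,
    VariantCall,
    sort_samples,
)

logger = logging.getLogger(__name__)

SAMPLE_SHEET_COLUMNS = [
    "patient_id",
    "nodule_id",
    "biopsy_id",
    "timepoint",
    "tissue",
    "liver_segment",
    "grade",
    "growth_pattern",
]

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Tumor_Sample_Barcode",
]


@dataclass
class Cohort:
    """All loaded data layers of one cohort, keyed by biopsy_id.

    Layers may be partial (e.g. expression for a subset of biopsies);
    :func:`validate_cohort` reports coverage without failing.
    """

    samples: List[BiopsySample]
    mutations: Dict[str, MutationProfile] = field(default_factory=dict)
    copy_number: Dict[str, CopyNumberProfile] = field(default_factory=dict)
    expression: Dict[str, ExpressionProfile] = field(default_factory=dict)
    signatures: Dict[str, SignatureActivity] = field(default_factory=dict)
    driver_genes: Sequence[str] = ()

    def sample_by_id(self, biopsy_id: str) -> BiopsySample:
        for s in self.samples:
            if s.biopsy_id == biopsy_id:
                return s
        raise KeyError(biopsy_id)

    @property
    def tumor_samples(self) -> List[BiopsySample]:
        return [s for s in self.samples if s.is_tumor]

    @property
    def patients(self) -> List[str]:
        seen = []
        for s in self.samples:
            if s.patient_id not in seen:
                seen.append(s.patient_id)
        return seen


def _opt(value, cast):
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    return cast(value)


def read_sample_sheet(path) -> List[BiopsySample]:
    """Read and validate the cohort sample sheet.

    Returns samples in canonical order (patient, nodule, timepoint, biopsy).
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("patient_id", "biopsy_id", "tissue"):
        if col not in df.columns:
            raise FormatError(f"sample sheet {path}: missing required column {col!r}")
    dup = df["biopsy_id"][df["biopsy_id"].duplicated()]
    if len(dup):
        raise ValidationError(
            f"sample sheet {path}: duplicated biopsy_id(s): {sorted(set(dup))}"
        )
    samples = []
    for _, row in df.iterrows():
        clinical = {
            k: row[k]
            for k in df.columns
            if k not in SAMPLE_SHEET_COLUMNS and pd.notna(row[k])
        }
        samples.append(
            BiopsySample(
                patient_id=row["patient_id"],
                biopsy_id=row["biopsy_id"],
                tissue=row["tissue"],
                nodule_id=_opt(row.get("nodule_id"), str),
                timepoint=_opt(row.get("timepoint"), float),
                liver_segment=_opt(row.get("liver_segment"), lambda v: int(float(v))),
                grade=_opt(row.get("grade"), str),
                growth_pattern=_opt(row.get("growth_pattern"), str),
                clinical=clinical,
            )
        )
    for s in samples:
        if s.is_tumor and s.timepoint is None:
            raise ValidationError(f"tumor biopsy {s.biopsy_id!r} lacks a timepoint")
    return sort_samples(samples)


def write_sample_sheet(samples: Iterable[BiopsySample], path) -> None:
    rows = []
    for s in sort_samples(samples):
        rows.append(
            {
                "patient_id": s.patient_id,
                "nodule_id": s.nodule_id or "",
                "biopsy_id": s.biopsy_id,
                "timepoint": "" if s.timepoint is None else s.timepoint,
                "tissue": s.tissue,
                "liver_segment": "" if s.liver_segment is None else s.liver_segment,
                "grade": s.grade or "",
                "growth_pattern": s.growth_pattern or "",
            }
        )
    pd.DataFrame(rows, columns=SAMPLE_SHEET_COLUMNS).to_csv(path, sep="\t", index=False)


def compute_cohort_frequencies(
    variants_by_biopsy: Dict[str, Dict[str, VariantCall]],
    biopsy_to_patient: Dict[str, str],
    f_min: Optional[float] = None,
) -> Dict[str, float]:
    """Patient-level recurrence of each variant across the cohort.

    A variant is counted once per patient regardless of how many biopsies
    carry it (multiply-biopsied clones must not inflate frequency).  The
    result is floored at ``f_min`` (default ``1/(2*n_patients)``) so the
    rarity weight ``-log10(freq)`` is always finite.
    """
    patients = sorted({biopsy_to_patient[b] for b in variants_by_biopsy})
    n_patients = len(patients)
    if n_patients == 0:
        return {}
    if f_min is None:
        f_min = 1.0 / (2.0 * n_patients)
    carriers: Dict[str, set] = {}
    for biopsy_id, variants in variants_by_biopsy.items():
        patient = biopsy_to_patient[biopsy_id]
        for key in variants:
            carriers.setdefault(key, set()).add(patient)
    return {
        key: max(len(pats) / n_patients, f_min) for key, pats in carriers.items()
    }


def read_mutations(
    path,
    samples: Sequence[BiopsySample],
    f_min: Optional[float] = None,
) -> Dict[str, MutationProfile]:
    """Read a MAF-like TSV into per-biopsy mutation profiles.

    Every tumor biopsy of ``samples`` gets a profile (possibly empty);
    duplicate variant rows for one biopsy are deduplicated; cohort
    frequencies are computed at patient level and floored at ``f_min``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in MAF_COLUMNS:
        if col == "Hugo_Symbol":
            continue  # gene symbol is optional
        if col not in df.columns:
            raise FormatError(f"mutation table {path}: missing required column {col!r}")
    by_id = {s.biopsy_id: s for s in samples}
    tumor_ids = [s.biopsy_id for s in samples if s.is_tumor]
    variants_by_biopsy: Dict[str, Dict[str, VariantCall]] = {b: {} for b in tumor_ids}
    for i, row in enumerate(df.itertuples(index=False), start=2):
        barcode = row.Tumor_Sample_Barcode
        if barcode not in by_id:
            raise ValidationError(
                f"mutation table {path} line {i}: unknown biopsy_id {barcode!r}"
            )
        try:
            call = VariantCall(
                chrom=str(row.Chromosome),
                pos=int(row.Start_Position),
                ref=str(row.Reference_Allele),
                alt=str(row.Tumor_Seq_Allele2),
                gene=getattr(row, "Hugo_Symbol", None),
            )
        except (TypeError, ValueError) as exc:
            raise FormatError(f"mutation table {path} line {i}: {exc}") from exc
        variants_by_biopsy.setdefault(barcode, {})[call.variant_key] = call
    biopsy_to_patient = {b: by_id[b].patient_id for b in variants_by_biopsy}
    cohort_freq = compute_cohort_frequencies(variants_by_biopsy, biopsy_to_patient, f_min)
    return {
        b: MutationProfile(biopsy_id=b, variants=v, cohort_freq=cohort_freq)
        for b, v in variants_by_biopsy.items()
    }


def read_mutations_vcf(
    vcf_by_biopsy: Dict[str, object],
    samples: Sequence[BiopsySample],
    f_min: Optional[float] = None,
) -> Dict[str, MutationProfile]:
    """Read single-sample VCFs (one per biopsy) into mutation profiles.

    ``vcf_by_biopsy`` maps biopsy_id -> VCF path.  Multi-allelic records
    contribute one variant per ALT allele.  Cohort frequencies are computed
    exactly as for MAF input.
    """
    import pysam

    by_id = {s.biopsy_id: s for s in samples}
    unknown = sorted(set(vcf_by_biopsy) - set(by_id))
    if unknown:
        raise ValidationError(f"VCF(s) for unknown biopsy_id(s): {unknown}")
    tumor_ids = [s.biopsy_id for s in samples if s.is_tumor]
    variants_by_biopsy: Dict[str, Dict[str, VariantCall]] = {b: {} for b in tumor_ids}
    for biopsy_id, path in vcf_by_biopsy.items():
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf:
                for alt in rec.alts or ():
                    call = VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        gene=dict(rec.info).get("GENE"),
                    )
                    variants_by_biopsy.setdefault(biopsy_id, {})[call.variant_key] = call
    biopsy_to_patient = {b: by_id[b].patient_id for b in variants_by_biopsy}
    cohort_freq = compute_cohort_frequencies(variants_by_biopsy, biopsy_to_patient, f_min)
    return {
        b: MutationProfile(biopsy_id=b, variants=v, cohort_freq=cohort_freq)
        for b, v in variants_by_biopsy.items()
    }


def write_mutations(profiles: Dict[str, MutationProfile], path) -> None:
    rows = []
    for biopsy_id in sorted(profiles):
        for key in sorted(profiles[biopsy_id].variants):
            v = profiles[biopsy_id].variants[key]
            rows.append(
                {
                    "Hugo_Symbol": v.gene or "",
                    "Chromosome": v.chrom,
                    "Start_Position": v.pos,
                    "Reference_Allele": v.ref,
                    "Tumor_Seq_Allele2": v.alt,
                    "Tumor_Sample_Barcode": biopsy_id,
                }
            )
    pd.DataFrame(rows, columns=MAF_COLUMNS).to_csv(path, sep="\t", index=False)


def chrom_sort_key(chrom: str):
    """Natural chromosome order: numeric first (1 < 2 < 10), then X, Y, others."""
    c = chrom.removeprefix("chr")
    return (0, int(c), "") if c.isdigit() else (1, 0, c)


def _build_bins(chrom_ends: Dict[str, int], bin_size: int) -> GenomeBins:
    chroms, starts, ends = [], [], []
    for chrom in sorted(chrom_ends, key=chrom_sort_key):
        end = chrom_ends[chrom]
        for start in range(0, end, bin_size):
            chroms.append(chrom)
            starts.append(start)
            ends.append(min(start + bin_size, end))
    return GenomeBins(tuple(chroms), tuple(starts), tuple(ends))


def read_copy_number(
    path,
    bin_size: int = 1_000_000,
    ploidy_neutral: int = 2,
    bins: Optional[GenomeBins] = None,
    values: str = "integer",
) -> Dict[str, CopyNumberProfile]:
    """Read SEG segments and rebin them onto fixed windows.

    A bin takes the integer state of the segment covering its midpoint;
    bins covered by no segment default to ``ploidy_neutral`` (the number of
    such bins is logged).  Overlapping segments within one biopsy are an
    error.  If ``bins`` is given the segments are projected onto it;
    otherwise fixed windows of ``bin_size`` are laid over each chromosome up
    to the largest segment end seen in the file.

    ``values`` selects the CN column encoding: ``"integer"`` rounds
    absolute states (the default); ``"log_ratio"`` converts log2 ratios to
    states via round(ploidy_neutral * 2**value).
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if values not in ("integer", "log_ratio"):
        raise ValueError(f"values must be 'integer' or 'log_ratio', got {values!r}")
    df = pd.read_csv(path, sep="\t", dtype={"ID": str, "chrom": str})
    required = ["ID", "chrom", "loc.start", "loc.end", "CN"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"SEG file {path}: missing required column {col!r}")
    # overlap check per biopsy/chromosome
    for (sample, chrom), grp in df.groupby(["ID", "chrom"]):
        grp = grp.sort_values("loc.start")
        prev_end = -1
        for _, row in grp.iterrows():
            if row["loc.start"] < prev_end:
                raise ValidationError(
                    f"SEG file {path}: overlapping segments for {sample} on {chrom}"
                )
            prev_end = row["loc.end"]
    if bins is None:
        chrom_ends = df.groupby("chrom")["loc.end"].max().astype(int).to_dict()
        bins = _build_bins(chrom_ends, bin_size)
    mids = (np.asarray(bins.starts) + np.asarray(bins.ends)) / 2.0
    bin_chroms = np.asarray(bins.chroms)
    profiles = {}
    for sample, grp in df.groupby("ID"):
        states = np.full(len(bins), ploidy_neutral, dtype=int)
        covered = np.zeros(len(bins), dtype=bool)
        for _, row in grp.iterrows():
            mask = (
                (bin_chroms == row["chrom"])
                & (mids >= row["loc.start"])
                & (mids < row["loc.end"])
            )
            raw = float(row["CN"])
            state = (
                int(round(ploidy_neutral * 2.0**raw))
                if values == "log_ratio"
                else int(round(raw))
            )
            states[mask] = max(state, 0)
            covered |= mask
        n_uncovered = int((~covered).sum())
        if n_uncovered:
            logger.warning(
                "%s: %d/%d bins uncovered; set to neutral (%d)",
                sample, n_uncovered, len(bins), ploidy_neutral,
            )
        profiles[sample] = CopyNumberProfile(
            biopsy_id=sample, bins=bins, states=states, ploidy_neutral=ploidy_neutral
        )
    return profiles


def write_copy_number(profiles: Dict[str, CopyNumberProfile], path) -> None:
    """Write profiles as SEG, merging runs of equal-state adjacent bins."""
    rows = []
    for biopsy_id in sorted(profiles):
        p = profiles[biopsy_id]
        chroms, starts, ends = p.bins.chroms, p.bins.starts, p.bins.ends
        i = 0
        while i < len(p.bins):
            j = i
            while (
                j + 1 < len(p.bins)
                and chroms[j + 1] == chroms[i]
                and starts[j + 1] == ends[j]
                and p.states[j + 1] == p.states[i]
            ):
                j += 1
            rows.append(
                {
                    "ID": biopsy_id,
                    "chrom": chroms[i],
                    "loc.start": starts[i],
                    "loc.end": ends[j],
                    "CN": int(p.states[i]),
                }
            )
            i = j + 1
    pd.DataFrame(rows, columns=["ID", "chrom", "loc.start", "loc.end", "CN"]).to_csv(
        path, sep="\t", index=False
    )


def _read_matrix(path, kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValidationError(f"{kind} matrix {path}: duplicated row id(s): {dups}")
    arr = df.to_numpy()
    bad = ~np.isfinite(pd.to_numeric(arr.ravel(), errors="coerce").reshape(arr.shape))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{kind} matrix {path}: non-numeric value at row {df.index[r]!r}, "
            f"column {df.columns[c]!r}"
        )
    return df.astype(float)


def read_expression_matrix(path) -> Dict[str, ExpressionProfile]:
    """Read a genes x biopsies TSV of log2(TPM) values."""
    df = _read_matrix(path, "expression")
    return {col: ExpressionProfile(biopsy_id=col, values=df[col]) for col in df.columns}


def write_expression_matrix(profiles: Dict[str, ExpressionProfile], path) -> None:
    df = pd.DataFrame({b: profiles[b].values for b in sorted(profiles)})
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_signature_matrix(path) -> Dict[str, SignatureActivity]:
    """Read a signatures x biopsies TSV of non-negative activities."""
    df = _read_matrix(path, "signature")
    return {col: SignatureActivity(biopsy_id=col, exposures=df[col]) for col in df.columns}


def write_signature_matrix(profiles: Dict[str, SignatureActivity], path) -> None:
    df = pd.DataFrame({b: profiles[b].exposures for b in sorted(profiles)})
    df.index.name = "signature_id"
    df.to_csv(path, sep="\t", float_format="%.6g")


def read_gmt(path) -> Dict[str, List[str]]:
    """Read gene sets in GMT format: name <tab> description <tab> genes..."""
    sets: Dict[str, List[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"GMT file {path} line {i}: expected >= 3 tab-separated fields")
        name, genes = fields[0], [g for g in fields[2:] if g]
        if name in sets:
            raise ValidationError(f"GMT file {path}: duplicated set name {name!r}")
        if not genes:
            raise ValidationError(f"GMT file {path}: set {name!r} is empty")
        sets[name] = genes
    return sets


@dataclass
class ValidationReport:
    """Per-layer coverage and hard inconsistencies of a cohort (report-only)."""

    coverage: pd.DataFrame  # biopsy_id x layer booleans
    gaps: List[str]
    errors: List[str]

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Report which biopsies have which layers; never raises.

    Missing layers for a biopsy are coverage gaps (the study design itself
    profiles some layers on subsets); profiles attached to unknown biopsy
    ids are hard errors.
    """
    known = {s.biopsy_id for s in cohort.samples}
    tumor_ids = [s.biopsy_id for s in cohort.samples if s.is_tumor]
    layers = {
        "mutations": set(cohort.mutations),
        "copy_number": set(cohort.copy_number),
        "expression": set(cohort.expression),
        "signatures": set(cohort.signatures),
    }
    errors = []
    for layer, ids in layers.items():
        for unknown in sorted(ids - known):
            errors.append(f"{layer}: profile for unknown biopsy_id {unknown!r}")
    rows = {}
    for s in cohort.samples:
        rows[s.biopsy_id] = {layer: s.biopsy_id in ids for layer, ids in layers.items()}
    coverage = pd.DataFrame.from_dict(rows, orient="index").rename_axis("biopsy_id")
    gaps = []
    for layer in ("mutations", "copy_number", "signatures"):
        missing = [b for b in tumor_ids if b not in layers[layer]]
        if missing:
            gaps.append(f"{layer}: missing for {len(missing)} tumor biopsies: {missing}")
    expr_missing = [b for b in known if b not in layers["expression"]]
    if expr_missing:
        gaps.append(f"expression: missing for {len(expr_missing)} biopsies: {sorted(expr_missing)}")
    return ValidationReport(coverage=coverage, gaps=gaps, errors=errors)


def load_cohort(
    sample_sheet,
    mutations=None,
    copy_number=None,
    expression=None,
    signatures=None,
    f_min: Optional[float] = None,
    bin_size: int = 1_000_000,
    driver_genes: Sequence[str] = (),
) -> Cohort:
    """Load all available layers of a cohort from disk."""
    samples = read_sample_sheet(sample_sheet)
    cohort = Cohort(samples=samples, driver_genes=tuple(driver_genes))
    if mutations:
        cohort.mutations = read_mutations(mutations, samples, f_min=f_min)
    if copy_number:
        cohort.copy_number = read_copy_number(copy_number, bin_size=bin_size)
    if expression:
        cohort.expression = read_expression_matrix(expression)
    if signatures:
        cohort.signatures = read_signature_matrix(signatures)
    return cohort
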