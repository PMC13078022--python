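"""Core domain types for multifocal-tumor cohort analysis.

A cohort is a set of patients, each with one or more biopsied tumor nodules
and optionally non-tumor liver (NTL) biopsies.  Every molecular layer
(somatic mutations, copy number, expression, mutational-signature activity)
is keyed by the globally unique ``biopsy_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

TISSUE_TUMOR = "tumor"
TISSUE_NTL = "NTL"
TISSUE_NORMAL = "normal"
VALID_TISSUES = (TISSUE_TUMOR, TISSUE_NTL, TISSUE_NORMAL)


class CohortError(Exception):
    """Base class for cohort data errors."""


class FormatError(CohortError):
    """A file could not be parsed into the expected tabular shape."""


class ValidationError(CohortError):
    """Parsed data violate a cohort invariant."""


@dataclass(frozen=True)
class BiopsySample:
    """One biopsy: the unit of all molecular profiling.

    Tumor biopsies carry a ``nodule_id`` (unique within patient); NTL and
    normal-liver biopsies do not.  ``timepoint`` orders serial biopsies
    within a patient.
    """

    patient_id: str
    biopsy_id: str
    tissue: str
    nodule_id: Optional[str] = None
    timepoint: Optional[float] = None
    liver_segment: Optional[int] = None
    grade: Optional[str] = None
    growth_pattern: Optional[str] = None
    clinical: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tissue not in VALID_TISSUES:
            raise ValidationError(
                f"biopsy {self.biopsy_id!r}: tissue must be one of "
                f"{VALID_TISSUES}, got {self.tissue!r}"
            )
        if self.tissue == TISSUE_TUMOR and not self.nodule_id:
            raise ValidationError(
                f"tumor biopsy {self.biopsy_id!r} lacks a nodule_id"
            )
        if self.tissue != TISSUE_TUMOR and self.nodule_id:
            raise ValidationError(
                f"{self.tissue} biopsy {self.biopsy_id!r} must not carry a "
                f"nodule_id ({self.nodule_id!r})"
            )
        if self.liver_segment is not None and not 1 <= int(self.liver_segment) <= 8:
            raise ValidationError(
                f"biopsy {self.biopsy_id!r}: liver_segment must be in 1..8"
            )

    @property
    def is_tumor(self) -> bool:
        return self.tissue == TISSUE_TUMOR


@dataclass(frozen=True)
class VariantCall:
    """A somatic SNV or small indel, identified by chrom:pos:ref:alt."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: Optional[str] = None
    is_driver: bool = False

    def __post_init__(self) -> None:
        if self.ref == self.alt:
            raise ValidationError(
                f"variant at {self.chrom}:{self.pos}: ref equals alt ({self.ref!r})"
            )
        if self.pos < 1:
            raise ValidationError(f"variant position must be 1-based positive, got {self.pos}")

    @property
    def variant_key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"


@dataclass
class MutationProfile:
    """The somatic variant set of one biopsy plus cohort-level frequencies.

    ``cohort_freq`` maps variant_key -> fraction of cohort *patients*
    carrying the variant, floored at ``f_min``; it is shared across the
    cohort and feeds the rarity weights of the clonality score.
    """

    biopsy_id: str
    variants: dict  # variant_key -> VariantCall
    cohort_freq: Mapping[str, float]

    @property
    def variant_keys(self) -> frozenset:
        return frozenset(self.variants)

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class GenomeBins:
    """A fixed genome binning shared by all copy-number profiles of a cohort.

    Bins are 0-based half-open, non-overlapping and genome-ordered.
    """

    chroms: tuple
    starts: tuple
    ends: tuple

    def __post_init__(self) -> None:
        n = len(self.chroms)
        if not (len(self.starts) == len(self.ends) == n):
            raise ValidationError("bin coordinate arrays differ in length")
        for i in range(n):
            if self.ends[i] <= self.starts[i]:
                raise ValidationError(f"bin {i}: empty or inverted interval")
            if i and self.chroms[i] == self.chroms[i - 1] and self.starts[i] < self.ends[i - 1]:
                raise ValidationError(f"bin {i}: overlaps previous bin")

    def __len__(self) -> int:
        return len(self.chroms)

    @property
    def lengths(self) -> np.ndarray:
        return np.asarray(self.ends, dtype=float) - np.asarray(self.starts, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chroms, "start": self.starts, "end": self.ends})


@dataclass
class CopyNumberProfile:
    """Integer absolute copy-number states on a shared genome binning."""

    biopsy_id: str
    bins: GenomeBins
    states: np.ndarray  # integer state per bin
    ploidy_neutral: int = 2

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states)
        if len(self.states) != len(self.bins):
            raise ValidationError(
                f"{self.biopsy_id}: {len(self.states)} states for {len(self.bins)} bins"
            )
        if (self.states < 0).any():
            raise ValidationError(f"{self.biopsy_id}: negative copy-number state")


@dataclass
class ExpressionProfile:
    """Per-biopsy gene expression as log2(TPM+1), over the shared gene universe."""

    biopsy_id: str
    values: pd.Series  # index: gene_id

    def __post_init__(self) -> None:
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValidationError(f"{self.biopsy_id}: non-finite expression value")


@dataclass
class SignatureActivity:
    """Mutational-signature exposures of one biopsy (non-negative)."""

    biopsy_id: str
    exposures: pd.Series  # index: signature_id

    def __post_init__(self) -> None:
        vals = self.exposures.to_numpy(dtype=float)
        if (vals < 0).any() or not np.isfinite(vals).all():
            raise ValidationError(f"{self.biopsy_id}: invalid signature exposure")


def sort_samples(samples):
    """Canonical cohort ordering: (patient, nodule, timepoint, biopsy)."""
    return sorted(
        samples,
        key=lambda s: (
            s.patient_id,
            s.nodule_id or "",
            s.timepoint if s.timepoint is not None else float("inf"),
            s.biopsy_id,
        ),
    )
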