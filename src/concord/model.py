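"""Core domain types shared across the pipeline.

Coordinate conventions are fixed per type and enforced at construction:
variant and breakpoint positions are 1-based points; copy-number segments
are 0-based half-open intervals. Format readers/writers convert at the
boundary; nothing downstream ever shifts a coordinate again.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

SV_CATEGORIES = ("DEL", "DUP", "INV", "TRA")

#: Tumour / model roles a patient's samples can take. ``tumour`` here means the
#: donor tissue (resected primary or metastasis); ``pdx`` and ``pdo`` are the
#: disease models derived from it.
ROLES = ("tumour", "pdx", "pdo")

#: Pairwise comparison labels in canonical order: donor tumour (T) vs
#: xenograft (X), tumour vs organoid (O), and xenograft vs organoid.
PAIR_LABELS = ("TvsX", "TvsO", "XvsO")

#: Chromosome universe used for reporting: autosomes plus both sex chromosomes.
DEFAULT_CHROMOSOMES = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX", "chrY")


@dataclass(frozen=True)
class VariantCall:
    """One somatic SNV or small indel.

    Identity for concordance purposes is (chrom, pos, ref, alt) only;
    the annotation category and allele depths are carried along but never
    enter set membership.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    mutation_type: str = "Unannotated"
    ref_depth: Optional[int] = None
    alt_depth: Optional[int] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt must differ ({self.chrom}:{self.pos} {self.ref})")
        for depth in (self.ref_depth, self.alt_depth):
            if depth is not None and depth < 0:
                raise ValueError("allele depths must be nonnegative")


@dataclass(frozen=True)
class SvEvent:
    """A structural variant as an ordered breakpoint pair with a category.

    DEL/DUP/INV are intra-chromosomal (chrom_a == chrom_b, pos_a < pos_b);
    TRA joins two distinct chromosomes. Use :func:`make_sv_event` to build
    events from unordered caller output.
    """

    chrom_a: str
    pos_a: int  # 1-based
    chrom_b: str
    pos_b: int  # 1-based
    category: str
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.category not in SV_CATEGORIES:
            raise ValueError(
                f"SV category must be one of {SV_CATEGORIES}, got {self.category!r}"
            )
        if min(self.pos_a, self.pos_b) < 1:
            raise ValueError("breakpoint positions must be >= 1")
        if self.category == "TRA":
            if self.chrom_a == self.chrom_b:
                raise ValueError(
                    f"TRA requires two distinct chromosomes, got {self.chrom_a} twice"
                )
        else:
            if self.chrom_a != self.chrom_b:
                raise ValueError(
                    f"{self.category} must be intra-chromosomal "
                    f"({self.chrom_a} != {self.chrom_b})"
                )
            if self.pos_a >= self.pos_b:
                raise ValueError(
                    f"intra-chromosomal event needs pos_a < pos_b "
                    f"({self.pos_a} >= {self.pos_b})"
                )

    @property
    def is_translocation(self) -> bool:
        return self.category == "TRA"

    @property
    def chromosomes(self) -> tuple[str, ...]:
        """Chromosome(s) the event touches (one for intra, two for TRA)."""
        if self.chrom_a == self.chrom_b:
            return (self.chrom_a,)
        return (self.chrom_a, self.chrom_b)


def make_sv_event(
    chrom_a: str,
    pos_a: int,
    chrom_b: str,
    pos_b: int,
    category: str,
    sample_id: str = "",
) -> SvEvent:
    """Build an :class:`SvEvent`, canonicalising breakpoint order.

    Intra-chromosomal breakpoints are sorted by position; TRA breakpoints are
    sorted by (chromosome name, position) so the same physical junction always
    yields an identical event regardless of reporting order.
    """
    if chrom_a == chrom_b and pos_a > pos_b:
        pos_a, pos_b = pos_b, pos_a
    elif chrom_a != chrom_b and (chrom_b, pos_b) < (chrom_a, pos_a):
        chrom_a, chrom_b = chrom_b, chrom_a
        pos_a, pos_b = pos_b, pos_a
    return SvEvent(chrom_a, pos_a, chrom_b, pos_b, category, sample_id)


@dataclass(frozen=True)
class CnSegment:
    """A copy-number segment with its average integer copy number (imean).

    Interval is 0-based half-open. ``imean`` may be None when the caller
    could not fit a value; such segments cover bases but contribute nothing
    to "defined" base counts downstream.
    """

    chrom: str
    start: int
    end: int
    imean: Optional[float]
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"segment needs 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.imean is not None and self.imean < 0:
            raise ValueError(f"imean must be nonnegative, got {self.imean}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SamplePloidy:
    """Genome-average copy number of one sample, with optional purity fields."""

    sample_id: str
    ploidy: float
    normal_fraction: Optional[float] = None
    tumour_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ploidy <= 0:
            raise ValueError(f"ploidy must be positive, got {self.ploidy}")
        for frac in (self.normal_fraction, self.tumour_fraction):
            if frac is not None and not (0.0 <= frac <= 1.0):
                raise ValueError("cell fractions must lie in [0, 1]")


@dataclass
class SampleManifest:
    """One patient's samples: role -> sample id and role -> input file paths.

    ``paths[role]`` maps data kinds ("ssm", "sv", "cn", "ploidy") to file
    paths; kinds may be absent when an analysis is not requested.
    """

    patient_id: str
    samples: dict[str, str]  # role -> sample_id
    paths: dict[str, dict[str, str]] = field(default_factory=dict)
    cohort: str = "primary"

    def __post_init__(self) -> None:
        unknown = set(self.samples) - set(ROLES)
        if unknown:
            raise ValueError(f"unknown sample roles {sorted(unknown)}; expected {ROLES}")
        if "tumour" not in self.samples:
            raise ValueError(f"patient {self.patient_id} lacks a tumour sample")
        if not (set(self.samples) & {"pdx", "pdo"}):
            raise ValueError(f"patient {self.patient_id} has no model (pdx/pdo) sample")

    @property
    def roles(self) -> list[str]:
        return [r for r in ROLES if r in self.samples]

    @property
    def is_trio(self) -> bool:
        return set(self.roles) == set(ROLES)
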