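"""Core domain types shared across the pipeline.

Coordinate conventions: `VariantRecord.pos` is 1-based (VCF); all interval
arithmetic (`IntervalSet`, HMM segments, BED I/O) is 0-based half-open.
Conversion happens only at I/O boundaries.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Optional

from intervaltree import IntervalTree


class _Absent:
    """Marker for a value missing from an annotation source.

    Distinct from 0.0 (an observed frequency of zero) and from None
    (which some optional per-call fields use for "not reported by caller").
    """

    _instance: Optional["_Absent"] = None

    def __new__(cls) -> "_Absent":
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSENT"

    def __bool__(self) -> bool:
        return False


ABSENT = _Absent()


def is_absent(value: object) -> bool:
    return value is ABSENT


VALID_BASES = frozenset("ACGTN")


class CallStatus(enum.Enum):
    CALLED = "CALLED"
    NO_CALL = "NO_CALL"
    LOW_CONFIDENCE = "LOW_CONFIDENCE"


@dataclass(frozen=True)
class ConfidenceThresholds:
    """Depth/quality floor below which a called genotype is demoted to
    LOW_CONFIDENCE. Values are configurable; callers vary in what they
    mean by a confident genotype."""

    min_depth: int = 10
    min_gq: float = 20.0


@dataclass(frozen=True)
class GenotypeCall:
    """One sample's diploid call at one site.

    ``allele_indices`` are indices into [ref] + alts (0 = ref); ``None``
    when the genotype is missing. ``quality`` is the caller's GQ.
    """

    allele_indices: Optional[tuple[int, int]] = None
    phased: bool = False
    depth: Optional[int] = None
    quality: Optional[float] = None
    status: CallStatus = CallStatus.CALLED

    def __post_init__(self) -> None:
        if self.status is CallStatus.CALLED and self.allele_indices is None:
            raise ValueError("CALLED genotype requires allele indices")
        if self.depth is not None and self.depth < 0:
            raise ValueError("depth must be non-negative")

    @property
    def is_called(self) -> bool:
        return self.status is CallStatus.CALLED

    @property
    def alleles(self) -> tuple[int, int]:
        if self.allele_indices is None:
            raise ValueError("genotype has no alleles")
        return self.allele_indices

    @property
    def is_het(self) -> bool:
        return self.is_called and self.alleles[0] != self.alleles[1]

    @property
    def is_hom_ref(self) -> bool:
        return self.is_called and self.alleles == (0, 0)

    @property
    def is_hom_alt(self) -> bool:
        a, b = self.alleles if self.is_called else (0, 0)
        return self.is_called and a == b and a > 0

    def carries(self, allele_index: int) -> bool:
        """True if this (called) genotype contains ``allele_index``."""
        return self.is_called and allele_index in self.alleles

    @staticmethod
    def no_call(depth: Optional[int] = None) -> "GenotypeCall":
        return GenotypeCall(None, depth=depth, status=CallStatus.NO_CALL)

    @staticmethod
    def of(a: int, b: int, depth: Optional[int] = None,
           quality: Optional[float] = None, phased: bool = False,
           thresholds: Optional[ConfidenceThresholds] = None) -> "GenotypeCall":
        status = CallStatus.CALLED
        if thresholds is not None:
            low_dp = depth is not None and depth < thresholds.min_depth
            low_gq = quality is not None and quality < thresholds.min_gq
            if low_dp or low_gq:
                status = CallStatus.LOW_CONFIDENCE
        return GenotypeCall((a, b), phased=phased, depth=depth,
                            quality=quality, status=status)


@dataclass
class VariantRecord:
    """One VCF row; ``alt`` may hold several alternate alleles
    (see :func:`split_multiallelic`)."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: tuple[str, ...]
    ids: tuple[str, ...] = ()
    filters: tuple[str, ...] = ()
    genotypes: dict[str, GenotypeCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or set(self.ref) - VALID_BASES:
            raise ValueError(f"invalid ref allele {self.ref!r}")
        for a in self.alt:
            if not a:
                raise ValueError("empty alt allele")
            if a.startswith("<"):
                continue  # symbolic; screened upstream, <DEL> routed to SV handling
            if set(a) - VALID_BASES:
                raise ValueError(f"invalid alt allele {a!r}")
        self.alt = tuple(self.alt)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alt) == 1

    @property
    def is_snv(self) -> bool:
        return self.is_biallelic and len(self.ref) == 1 and len(self.alt[0]) == 1

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Normalized (chrom, pos, ref, alt) key; biallelic records only."""
        if not self.is_biallelic:
            raise ValueError("key defined for biallelic records only")
        return normalize_variant(self.chrom, self.pos, self.ref, self.alt[0])

    @property
    def end(self) -> int:
        """1-based inclusive end of the reference span."""
        return self.pos + len(self.ref) - 1


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Reduce (pos, ref, alt) to the left-aligned parsimonious form.

    Shared trailing bases are trimmed first, then shared leading bases
    (advancing ``pos``), always leaving at least one base in each allele.
    Idempotent; raises ``ValueError`` when ref == alt (not a variant).
    Reference-context left-shifting of homopolymer indels is outside the
    scope of a key normalizer: two keys compare equal iff their trimmed
    forms are identical.
    """
    if ref == alt:
        raise ValueError(f"ref == alt ({ref!r}) at {chrom}:{pos} is not a variant")
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def _remap_allele(allele: Optional[int], alt_index: int) -> Optional[int]:
    if allele is None:
        return None
    return 1 if allele == alt_index else 0


def split_multiallelic(record: VariantRecord) -> list[VariantRecord]:
    """Decompose a multiallelic record into one biallelic record per alt.

    Genotype indices are remapped per record: the focal alt becomes 1 and
    every other allele (reference or a different alt) becomes 0, so that
    across the split records the multiset of per-sample alt alleles is
    preserved.
    """
    if record.is_biallelic:
        return [record]
    out = []
    for k, alt in enumerate(record.alt, start=1):
        genos = {}
        for sample, call in record.genotypes.items():
            if call.allele_indices is None:
                genos[sample] = call
            else:
                a, b = call.allele_indices
                genos[sample] = replace(
                    call, allele_indices=(_remap_allele(a, k), _remap_allele(b, k)))
        out.append(VariantRecord(record.chrom, record.pos, record.ref, (alt,),
                                 ids=record.ids, filters=record.filters,
                                 genotypes=genos))
    return out


@dataclass
class Interval:
    chrom: str
    start: int  # 0-based
    end: int    # half-open
    label: str = ""


class IntervalSet:
    """Point-queryable set of labeled genomic intervals (0-based half-open)."""

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._intervals: list[Interval] = []
        for iv in intervals:
            self.add(iv)

    def add(self, iv: Interval) -> None:
        if iv.end <= iv.start:
            raise ValueError(f"empty interval {iv}")
        self._trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, iv)
        self._intervals.append(iv)

    def __len__(self) -> int:
        return len(self._intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(sorted(self._intervals, key=lambda i: (i.chrom, i.start, i.end)))

    def at(self, chrom: str, pos0: int) -> list[Interval]:
        """Intervals containing 0-based point ``pos0``."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in sorted(tree.at(pos0))]

    def overlapping(self, chrom: str, start0: int, end0: int) -> list[Interval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return [hit.data for hit in sorted(tree.overlap(start0, end0))]

    def covers_point(self, chrom: str, pos0: int) -> bool:
        return bool(self.at(chrom, pos0))


def harmonize_chrom(chrom: str, strip_prefix: str = "chr") -> str:
    """Map 'chr1' and '1' dialects onto one namespace."""
    if strip_prefix and chrom.startswith(strip_prefix) and chrom != strip_prefix:
        return chrom[len(strip_prefix):]
    return chrom


def screen_symbolic_alts(record: VariantRecord) -> tuple[Optional[VariantRecord], list[Interval]]:
    """Drop symbolic alt alleles, converting <DEL> to deletion intervals.

    Returns (record with sequence alts only, or None if none remain;
    deletion intervals from <DEL> alts). Other symbolic alts are dropped
    with a warning.
    """
    deletions: list[Interval] = []
    kept: list[str] = []
    for a in record.alt:
        if not a.startswith("<"):
            kept.append(a)
        elif a == "<DEL>":
            deletions.append(Interval(record.chrom, record.pos - 1, record.end, "DEL"))
        else:
            warnings.warn(f"symbolic alt {a} at {record.chrom}:{record.pos} ignored")
    if not kept:
        return None, deletions
    trimmed = replace(record, alt=tuple(kept))
    return trimmed, deletions
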