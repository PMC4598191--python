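"""Five trio candidate-variant discovery modes, run after HMM region
classification so systematic-artifact regions never feed candidates:

1. apparent de novo events,
2. compound heterozygosity per gene with at least one rare member,
3. rare homozygous genotypes,
4. apparent hemizygosity supported by a deletion interval (loss-of-
   function candidates),
5. rare variants in known inherited-disease genes under an autosomal
   dominant model with reduced penetrance (an unaffected carrier parent
   is allowed, so no segregation requirement).

Modes 1-4 are restricted to GOOD segments.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .annotate import AnnotatedVariant, is_rare
from .model import GenotypeCall, Interval, IntervalSet
from .triohmm import InheritanceSegment, State, segments_to_intervalset

VariantKey = tuple[str, int, str, str]


class PhaseStatus(enum.Enum):
    TRANS_CONFIRMED = "TRANS_CONFIRMED"
    PHASE_UNKNOWN = "PHASE_UNKNOWN"


@dataclass(frozen=True)
class CompoundHetPair:
    gene: str
    first: VariantKey
    second: VariantKey
    phase: PhaseStatus

    def unordered(self) -> frozenset:
        return frozenset((self.first, self.second))


@dataclass
class CandidateSet:
    de_novo: list[VariantKey] = field(default_factory=list)
    compound_het: list[CompoundHetPair] = field(default_factory=list)
    rare_homozygous: list[VariantKey] = field(default_factory=list)
    hemizygous: list[tuple[VariantKey, Interval]] = field(default_factory=list)
    ad_reduced_penetrance: list[VariantKey] = field(default_factory=list)


def _good_regions(segments: Iterable[InheritanceSegment]) -> IntervalSet:
    return segments_to_intervalset(segments, states={State.GOOD})


def _trio(av: AnnotatedVariant, father: str, mother: str, child: str
          ) -> tuple[GenotypeCall, GenotypeCall, GenotypeCall]:
    g = av.record.genotypes
    return g[father], g[mother], g[child]


def _in_good(good: IntervalSet, av: AnnotatedVariant) -> bool:
    return good.covers_point(av.record.chrom, av.record.pos - 1)


def find_de_novo(annotated: Sequence[AnnotatedVariant],
                 segments: Sequence[InheritanceSegment],
                 father: str, mother: str, child: str,
                 strict: bool = True) -> list[VariantKey]:
    """Child carries an alternate allele absent from both parents, in a
    GOOD segment. Strict mode (default) demands both parents CALLED
    hom-ref; lenient mode tolerates parental LOW_CONFIDENCE calls whose
    indices are hom-ref."""
    good = _good_regions(segments)
    out, seen = [], set()
    for av in annotated:
        f, m, c = _trio(av, father, mother, child)
        if not (c.is_called and c.carries(1)):
            continue
        if strict:
            parents_ok = f.is_hom_ref and m.is_hom_ref
        else:
            parents_ok = all(
                g.allele_indices == (0, 0) for g in (f, m))
        if not parents_ok or not _in_good(good, av):
            continue
        if av.key not in seen:
            seen.add(av.key)
            out.append(av.key)
    return out


def transmissible_from(parent: GenotypeCall) -> bool:
    """Whether this parent could have transmitted the alt allele."""
    return parent.is_called and parent.carries(1)


def classify_pair_phase(v1_parents: tuple[GenotypeCall, GenotypeCall],
                        v2_parents: tuple[GenotypeCall, GenotypeCall]
                        ) -> Optional[PhaseStatus]:
    """Phase a pair of child-het variants from parental carriage.

    TRANS_CONFIRMED when one variant can only come from the father and
    the other only from the mother; None (cis, excluded) when both can
    come from only the same single parent; PHASE_UNKNOWN otherwise.
    Uncalled parents make carriage unknown, hence PHASE_UNKNOWN.
    """
    f1, m1 = v1_parents
    f2, m2 = v2_parents
    if not all(g.is_called for g in (f1, m1, f2, m2)):
        return PhaseStatus.PHASE_UNKNOWN
    v1_from = (transmissible_from(f1), transmissible_from(m1))
    v2_from = (transmissible_from(f2), transmissible_from(m2))
    only = {}
    for name, (pf, pm) in (("v1", v1_from), ("v2", v2_from)):
        if pf and not pm:
            only[name] = "father"
        elif pm and not pf:
            only[name] = "mother"
        else:
            only[name] = None  # both parents possible, or de novo
    if only["v1"] and only["v2"]:
        if only["v1"] != only["v2"]:
            return PhaseStatus.TRANS_CONFIRMED
        return None  # provably cis: same single-parent origin
    return PhaseStatus.PHASE_UNKNOWN


def find_compound_het(annotated: Sequence[AnnotatedVariant],
                      segments: Sequence[InheritanceSegment],
                      father: str, mother: str, child: str,
                      maf_threshold: float = 0.01) -> list[CompoundHetPair]:
    """All unordered pairs of child-heterozygous variants in one gene
    where at least one member is rare, excluding pairs provably in cis."""
    good = _good_regions(segments)
    by_gene: dict[str, list[AnnotatedVariant]] = {}
    for av in annotated:
        if av.gene is None or not _in_good(good, av):
            continue
        _, _, c = _trio(av, father, mother, child)
        if c.is_het and c.carries(1):
            by_gene.setdefault(av.gene, []).append(av)
    pairs: list[CompoundHetPair] = []
    for gene, avs in sorted(by_gene.items()):
        avs = sorted(avs, key=lambda a: a.key)
        for a1, a2 in combinations(avs, 2):
            if not (is_rare(a1.frequencies, maf_threshold)
                    or is_rare(a2.frequencies, maf_threshold)):
                continue
            f1, m1, _ = _trio(a1, father, mother, child)
            f2, m2, _ = _trio(a2, father, mother, child)
            phase = classify_pair_phase((f1, m1), (f2, m2))
            if phase is None:
                continue
            pairs.append(CompoundHetPair(gene, a1.key, a2.key, phase))
    return pairs


def find_rare_homozygous(annotated: Sequence[AnnotatedVariant],
                         segments: Sequence[InheritanceSegment],
                         father: str, mother: str, child: str,
                         maf_threshold: float = 0.01) -> list[VariantKey]:
    """Child hom-alt at a rare variant in a GOOD segment, with both
    parents carrying the allele (a hom-alt child with a non-carrier
    parent is an inheritance abnormality, not a recessive candidate)."""
    good = _good_regions(segments)
    out = []
    for av in annotated:
        f, m, c = _trio(av, father, mother, child)
        if not c.is_hom_alt:
            continue
        if not (f.is_called and m.is_called and f.carries(1) and m.carries(1)):
            continue
        if not is_rare(av.frequencies, maf_threshold):
            continue
        if _in_good(good, av):
            out.append(av.key)
    return out


def find_hemizygous(annotated: Sequence[AnnotatedVariant],
                    segments: Sequence[InheritanceSegment],
                    deletions: IntervalSet,
                    father: str, mother: str, child: str
                    ) -> list[tuple[VariantKey, Interval]]:
    """Apparent hemizygosity: the child looks hom-alt while only one
    parent carries the allele, and an overlapping deletion interval can
    explain the missing homolog. The deletion list is not
    lineage-resolved, so any overlapping deletion qualifies (putative);
    each variant+deletion pair is a loss-of-function candidate."""
    good = _good_regions(segments)
    out = []
    for av in annotated:
        f, m, c = _trio(av, father, mother, child)
        if not c.is_hom_alt:
            continue
        if not (f.is_called and m.is_called):
            continue
        carriers = sum(1 for g in (f, m) if g.carries(1))
        if carriers != 1:
            continue
        if not _in_good(good, av):
            continue
        for dele in deletions.at(av.record.chrom, av.record.pos - 1):
            out.append((av.key, dele))
    return out


def find_ad_reduced_penetrance(annotated: Sequence[AnnotatedVariant],
                               disease_genes: set[str],
                               father: str, mother: str, child: str,
                               maf_threshold: float = 0.01) -> list[VariantKey]:
    """Rare child-carried variants in known inherited-disease genes.
    Under reduced penetrance an unaffected carrier parent is expected, so
    inherited variants are kept alongside de novo ones."""
    out = []
    for av in annotated:
        if av.gene is None or av.gene not in disease_genes:
            continue
        _, _, c = _trio(av, father, mother, child)
        if not (c.is_called and c.carries(1)):
            continue
        if is_rare(av.frequencies, maf_threshold):
            out.append(av.key)
    return out


def discover_candidates(annotated: Sequence[AnnotatedVariant],
                        segments: Sequence[InheritanceSegment],
                        father: str, mother: str, child: str,
                        deletions: Optional[IntervalSet] = None,
                        disease_genes: Optional[set[str]] = None,
                        maf_threshold: float = 0.01,
                        strict_de_novo: bool = True) -> CandidateSet:
    """Run all five modes over one annotated trio callset."""
    annotated = list(annotated)
    return CandidateSet(
        de_novo=find_de_novo(annotated, segments, father, mother, child,
                             strict=strict_de_novo),
        compound_het=find_compound_het(annotated, segments, father, mother,
                                       child, maf_threshold),
        rare_homozygous=find_rare_homozygous(annotated, segments, father,
                                             mother, child, maf_threshold),
        hemizygous=find_hemizygous(annotated, segments,
                                   deletions or IntervalSet(),
                                   father, mother, child),
        ad_reduced_penetrance=find_ad_reduced_penetrance(
            annotated, disease_genes or set(), father, mother, child,
            maf_threshold),
    )
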