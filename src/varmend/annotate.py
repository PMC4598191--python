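"""Variant effect classification and annotation joins.

Produces the derived predicates the tiering logic consumes: loss of
function, rarity across population surveys, conservation consensus
(GERP++ and PhyloP jointly), and pathogenicity-prediction consensus
(three or more of SIFT / LRT / PolyPhen2 / MutationTaster calling the
variant damaging).
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

from .genes import GeneModel, Transcript
from .model import ABSENT, VariantRecord, is_absent
from .tables import FREQUENCY_SOURCES, AnnotationDB


class EffectClass(enum.IntEnum):
    """Functional consequence classes; smaller value = more severe.

    The order is total, so a variant's gene-level class is simply the
    minimum over its per-transcript classes.
    """

    SPLICE_DINUCLEOTIDE = 0
    NONSENSE = 1
    NONSTOP = 2
    FRAMESHIFT_INDEL = 3
    LARGE_CODING_INDEL = 4
    NONFRAMESHIFT_INDEL = 5
    MISSENSE = 6
    SYNONYMOUS = 7
    UTR = 8
    INTRONIC = 9
    INTERGENIC = 10
    OTHER = 11


LOF_CLASSES = frozenset({
    EffectClass.SPLICE_DINUCLEOTIDE,
    EffectClass.NONSENSE,
    EffectClass.NONSTOP,
    EffectClass.FRAMESHIFT_INDEL,
})

CODING_INDEL_CLASSES = frozenset({
    EffectClass.FRAMESHIFT_INDEL,
    EffectClass.LARGE_CODING_INDEL,
    EffectClass.NONFRAMESHIFT_INDEL,
})


@dataclass(frozen=True)
class EffectAnnotation:
    effect: EffectClass
    gene: Optional[str] = None
    transcript: Optional[str] = None
    indel_length: int = 0


MaybeFloat = Union[float, object]  # float or ABSENT
MaybeStr = Union[str, object]


@dataclass
class FrequencyProfile:
    """Per-source minor allele frequencies; ABSENT means the survey has
    no record of the variant, which is evidence of novelty, not a zero."""

    maf: dict[str, MaybeFloat] = field(
        default_factory=lambda: {s: ABSENT for s in FREQUENCY_SOURCES})
    local_cohort_af: MaybeFloat = ABSENT

    def __post_init__(self) -> None:
        for src, v in self.maf.items():
            if not is_absent(v):
                self.maf[src] = min(1.0, max(0.0, float(v)))
        if not is_absent(self.local_cohort_af):
            self.local_cohort_af = min(1.0, max(0.0, float(self.local_cohort_af)))

    def present_values(self) -> list[float]:
        return [v for v in self.maf.values() if not is_absent(v)]


@dataclass
class EvidenceProfile:
    gerp: MaybeFloat = ABSENT
    phylop_new: MaybeFloat = ABSENT
    sift: MaybeStr = ABSENT
    lrt: MaybeStr = ABSENT
    polyphen2: MaybeStr = ABSENT
    mutation_taster: MaybeStr = ABSENT
    reported: bool = False
    in_monogenic_gene: bool = False


@dataclass
class AnnotatedVariant:
    """A biallelic variant joined to its effect, frequencies and evidence."""

    record: VariantRecord
    effect: EffectAnnotation
    frequencies: FrequencyProfile
    evidence: EvidenceProfile

    @property
    def key(self) -> tuple[str, int, str, str]:
        return self.record.key

    @property
    def gene(self) -> Optional[str]:
        return self.effect.gene


def _classify_in_transcript(variant: VariantRecord, tx: Transcript,
                            model: GeneModel,
                            threshold_large: int) -> EffectClass:
    start0 = variant.pos - 1
    end0 = start0 + len(variant.ref)
    span = set(range(start0, end0))
    if span & tx.splice_dinucleotide_positions():
        return EffectClass.SPLICE_DINUCLEOTIDE
    in_cds = any(s < end0 and start0 < e for s, e in tx.cds)
    alt = variant.alt[0]
    if in_cds:
        if len(variant.ref) == 1 and len(alt) == 1:
            change = model.codon_change(tx, start0, alt)
            if change is None:
                return EffectClass.OTHER
            ref_aa, alt_aa = change
            if ref_aa != "*" and alt_aa == "*":
                return EffectClass.NONSENSE
            if ref_aa == "*" and alt_aa != "*":
                return EffectClass.NONSTOP
            return (EffectClass.SYNONYMOUS if ref_aa == alt_aa
                    else EffectClass.MISSENSE)
        net = abs(len(variant.ref) - len(alt))
        if net % 3 != 0:
            return EffectClass.FRAMESHIFT_INDEL
        if net >= threshold_large:
            return EffectClass.LARGE_CODING_INDEL
        return EffectClass.NONFRAMESHIFT_INDEL
    in_exon = any(s < end0 and start0 < e for s, e in tx.exons)
    return EffectClass.UTR if in_exon else EffectClass.INTRONIC


def classify_effect(variant: VariantRecord, gene_model: GeneModel,
                    threshold_large: int = 50) -> EffectAnnotation:
    """Most-severe consequence of a biallelic variant over all overlapping
    transcripts. A variant outside every transcript is INTERGENIC."""
    if not variant.is_biallelic:
        raise ValueError("classify_effect expects biallelic records")
    start0 = variant.pos - 1
    end0 = start0 + len(variant.ref)
    # include flanking so splice dinucleotides just outside the exon hit
    hits = gene_model.transcripts_at(variant.chrom, start0 - 2, end0 + 2)
    indel_len = abs(len(variant.ref) - len(variant.alt[0]))
    best: Optional[tuple[EffectClass, Transcript]] = None
    for tx in hits:
        s, e = tx.span
        if end0 <= s - 2 or start0 >= e + 2:
            continue
        eff = _classify_in_transcript(variant, tx, gene_model, threshold_large)
        if best is None or eff < best[0]:
            best = (eff, tx)
    if best is None:
        return EffectAnnotation(EffectClass.INTERGENIC, indel_length=indel_len)
    return EffectAnnotation(best[0], gene=best[1].gene,
                            transcript=best[1].tx_id, indel_length=indel_len)


def is_lof(effect: EffectAnnotation, threshold_large: int = 50) -> bool:
    """Loss of function: splice-dinucleotide, nonsense, nonstop,
    frameshift, or a coding indel at least ``threshold_large`` bp."""
    if effect.effect in LOF_CLASSES:
        return True
    return (effect.effect in CODING_INDEL_CLASSES
            and effect.indel_length >= threshold_large)


def is_rare(freq: FrequencyProfile, maf_threshold: float = 0.01) -> bool:
    """Rare iff MAF <= threshold in every survey that has the variant.

    A variant absent from all surveys is novel, hence rare; one common
    observation anywhere disqualifies.
    """
    return all(v <= maf_threshold for v in freq.present_values())


def conservation_consensus(evidence: EvidenceProfile) -> bool:
    """Both constraint scores present and over threshold:
    GERP++ > 2 and PhyloP (rescaled) > 0.95. Missing scores fail."""
    if is_absent(evidence.gerp) or is_absent(evidence.phylop_new):
        return False
    return evidence.gerp > 2.0 and evidence.phylop_new > 0.95


_DAMAGING_VOTES = {
    "sift": {"Damaging"},
    "lrt": {"Deleterious"},
    "polyphen2": {"Probably damaging", "Possibly damaging"},
    "mutation_taster": {"Disease causing automatic", "Disease causing"},
}

_KNOWN_VOCABULARY = {
    "sift": {"Damaging", "Tolerated"},
    "lrt": {"Deleterious", "Neutral", "Unknown"},
    "polyphen2": {"Probably damaging", "Possibly damaging", "Benign"},
    "mutation_taster": {"Disease causing automatic", "Disease causing",
                        "Polymorphism", "Polymorphism automatic"},
}


def pathogenicity_consensus(evidence: EvidenceProfile, min_votes: int = 3) -> bool:
    """Three or more of the four prediction algorithms call the variant
    damaging; an ABSENT or unrecognized prediction is a non-vote."""
    votes = 0
    for algo, damaging in _DAMAGING_VOTES.items():
        value = getattr(evidence, algo)
        if is_absent(value):
            continue
        if value in damaging:
            votes += 1
        elif value not in _KNOWN_VOCABULARY[algo]:
            warnings.warn(f"unknown {algo} prediction {value!r}; not counted")
    return votes >= min_votes


def annotate_stream(records: Iterable[VariantRecord], db: AnnotationDB,
                    gene_model: GeneModel,
                    threshold_large: int = 50) -> Iterator[AnnotatedVariant]:
    """Join each biallelic record to effect + frequency + evidence.

    Every input record is emitted exactly once; lookups that miss leave
    ABSENT markers in place.
    """
    for rec in records:
        key = rec.key
        effect = classify_effect(rec, gene_model, threshold_large)
        freq = FrequencyProfile(maf=db.frequency_map(key),
                                local_cohort_af=db.local_af(key))
        scores = db.scores(key)
        evidence = EvidenceProfile(
            gerp=scores.get("gerp", ABSENT),
            phylop_new=scores.get("phylop", ABSENT),
            sift=scores.get("sift", ABSENT),
            lrt=scores.get("lrt", ABSENT),
            polyphen2=scores.get("polyphen2", ABSENT),
            mutation_taster=scores.get("mutation_taster", ABSENT),
            reported=db.is_reported(key),
            in_monogenic_gene=(effect.gene is not None
                               and db.is_monogenic_gene(effect.gene)),
        )
        yield AnnotatedVariant(rec, effect, freq, evidence)
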