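"""Two-track four-tier prioritization of Mendelian disease-risk variants.

Track REPORTED ranks variants already present in a disease-mutation
catalog (pathogenicity first, then rarity; frequency filters deliberately
skipped for tiers 1 and 3 so well-known common pathogenic alleles such as
CFTR deltaF508 survive). Track NOVEL ranks previously unreported rare
variants in monogenic disease genes by loss of function, then
conservation consensus, then pathogenicity-prediction consensus. Tiers
1-3 of either track form the review set; a final local-cohort frequency
filter strips platform-specific systematic artifacts.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .annotate import (
    AnnotatedVariant,
    EffectClass,
    conservation_consensus,
    is_lof,
    is_rare,
    pathogenicity_consensus,
)
from .model import is_absent

EXCLUDED = "EXCLUDED"


class Track(enum.Enum):
    REPORTED = "REPORTED"
    NOVEL = "NOVEL"


@dataclass(frozen=True)
class TierAssignment:
    track: Track
    tier: Optional[int]  # 1..4, or None == EXCLUDED (not eligible for track)
    rationale: tuple[str, ...] = ()

    @property
    def excluded(self) -> bool:
        return self.tier is None

    @property
    def retained(self) -> bool:
        """Tiers 1-3 go forward for manual review."""
        return self.tier is not None and self.tier <= 3


_TIER3_REPORTED_CLASSES = {EffectClass.MISSENSE, EffectClass.NONFRAMESHIFT_INDEL}


def tier_reported(av: AnnotatedVariant, maf_threshold: float = 0.01,
                  threshold_large: int = 50) -> TierAssignment:
    """Tier a catalog-reported variant. Tiers are evaluated 1 -> 4, first
    match wins: 1 = LOF (no frequency filter), 2 = any rare reported
    variant, 3 = common missense / non-frameshift indel, 4 = the rest."""
    if not av.evidence.reported:
        return TierAssignment(Track.REPORTED, None, ("not_reported",))
    if is_lof(av.effect, threshold_large):
        return TierAssignment(Track.REPORTED, 1, ("reported", "lof"))
    if is_rare(av.frequencies, maf_threshold):
        return TierAssignment(Track.REPORTED, 2, ("reported", "rare"))
    if av.effect.effect in _TIER3_REPORTED_CLASSES:
        return TierAssignment(Track.REPORTED, 3,
                              ("reported", "missense_or_nonframeshift"))
    return TierAssignment(Track.REPORTED, 4, ("reported", "fallthrough"))


def tier_novel(av: AnnotatedVariant, maf_threshold: float = 0.01,
               threshold_large: int = 50) -> TierAssignment:
    """Tier a previously unreported variant. Eligibility: not in the
    reported catalog, rare, and in a monogenic disease gene. Within the
    track: 1 = LOF, 2 = conserved missense or non-frameshift indel,
    3 = missense with damaging consensus, 4 = remaining rare variants."""
    if av.evidence.reported:
        return TierAssignment(Track.NOVEL, None, ("reported_elsewhere",))
    if not av.evidence.in_monogenic_gene:
        return TierAssignment(Track.NOVEL, None, ("not_monogenic_gene",))
    if not is_rare(av.frequencies, maf_threshold):
        return TierAssignment(Track.NOVEL, None, ("not_rare",))
    if is_lof(av.effect, threshold_large):
        return TierAssignment(Track.NOVEL, 1, ("rare", "lof"))
    if (av.effect.effect is EffectClass.MISSENSE
            and conservation_consensus(av.evidence)):
        return TierAssignment(Track.NOVEL, 2, ("rare", "missense", "conserved"))
    if av.effect.effect is EffectClass.NONFRAMESHIFT_INDEL:
        return TierAssignment(Track.NOVEL, 2, ("rare", "nonframeshift_indel"))
    if (av.effect.effect is EffectClass.MISSENSE
            and pathogenicity_consensus(av.evidence)):
        return TierAssignment(Track.NOVEL, 3,
                              ("rare", "missense", "pathogenic_consensus"))
    return TierAssignment(Track.NOVEL, 4, ("rare", "fallthrough"))


def assign_tiers(av: AnnotatedVariant, maf_threshold: float = 0.01,
                 threshold_large: int = 50) -> dict[Track, TierAssignment]:
    return {
        Track.REPORTED: tier_reported(av, maf_threshold, threshold_large),
        Track.NOVEL: tier_novel(av, maf_threshold, threshold_large),
    }


def local_cohort_filter(
    assignments: Iterable[tuple[AnnotatedVariant, TierAssignment]],
    cutoff: float = 0.25,
) -> list[tuple[AnnotatedVariant, TierAssignment]]:
    """Drop retained variants seen at >= ``cutoff`` allele frequency in
    the local sequencing cohort (likely platform-specific artifact or
    locally common variation); variants with no local record pass."""
    kept = []
    for av, ta in assignments:
        af = av.frequencies.local_cohort_af
        if ta.retained and not is_absent(af) and af >= cutoff:
            continue
        kept.append((av, ta))
    return kept


def restrict_to_genes(annotated: Iterable[AnnotatedVariant],
                      gene_set: set[str],
                      sample_sex: Optional[str] = None,
                      y_genes: Optional[set[str]] = None,
                      y_chroms: Sequence[str] = ("Y", "chrY")) -> list[AnnotatedVariant]:
    """Keep variants in the queried gene set; for female samples,
    Y-chromosome genes are dropped from the effective set."""
    if not gene_set:
        raise ValueError("gene set must be non-empty")
    effective = set(gene_set)
    if sample_sex == "female":
        effective -= set(y_genes or ())
    out = []
    for av in annotated:
        if av.gene is None or av.gene not in effective:
            continue
        if sample_sex == "female" and av.record.chrom in y_chroms:
            continue
        out.append(av)
    return out


def prioritize_variants(annotated: Iterable[AnnotatedVariant],
                        maf_threshold: float = 0.01,
                        local_af_cutoff: float = 0.25,
                        threshold_large: int = 50,
                        gene_set: Optional[set[str]] = None,
                        sample_sex: Optional[str] = None) -> pd.DataFrame:
    """Full prioritization pass -> tidy table of retained tier 1-3 calls.

    One output row per (variant, track) that survives tiering and the
    local-cohort filter, with the rationale predicates that fired.
    """
    annotated = list(annotated)
    if gene_set is not None:
        annotated = restrict_to_genes(annotated, gene_set, sample_sex=sample_sex)
    pairs: list[tuple[AnnotatedVariant, TierAssignment]] = []
    for av in annotated:
        for ta in assign_tiers(av, maf_threshold, threshold_large).values():
            if ta.retained:
                pairs.append((av, ta))
    pairs = local_cohort_filter(pairs, cutoff=local_af_cutoff)
    rows = []
    for av, ta in pairs:
        chrom, pos, ref, alt = av.key
        rows.append({
            "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
            "gene": av.gene or "", "effect": av.effect.effect.name,
            "track": ta.track.value, "tier": ta.tier,
            "rationale": ",".join(ta.rationale),
        })
    cols = ["chrom", "pos", "ref", "alt", "gene", "effect", "track", "tier",
            "rationale"]
    return pd.DataFrame(rows, columns=cols)
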