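"""Two-track tiering against an independently coded decision-table
oracle, plus the local-cohort filter and gene-set restriction."""
import pytest

from varmend.annotate import (
    AnnotatedVariant,
    EffectAnnotation,
    EffectClass,
    EvidenceProfile,
    FrequencyProfile,
    annotate_stream,
)
from varmend.model import ABSENT, VariantRecord, is_absent
from varmend.prioritize import (
    Track,
    assign_tiers,
    local_cohort_filter,
    prioritize_variants,
    restrict_to_genes,
    tier_novel,
    tier_reported,
)
from varmend.simulate import random_annotated_variants
from varmend.tables import AnnotationDB, FREQUENCY_SOURCES


# ---------------------------------------------------------------------------
# Independent oracle: flat decision table over explicit predicates.
# Deliberately structured differently from the implementation (predicates
# precomputed, tier picked from a literal table).
# ---------------------------------------------------------------------------

def _oracle_predicates(av: AnnotatedVariant, maf_thr=0.01, large=50):
    present = [v for v in av.frequencies.maf.values() if not is_absent(v)]
    rare = max(present) <= maf_thr if present else True
    cls = av.effect.effect
    lof = cls.name in ("SPLICE_DINUCLEOTIDE", "NONSENSE", "NONSTOP",
                       "FRAMESHIFT_INDEL")
    if cls.name in ("FRAMESHIFT_INDEL", "LARGE_CODING_INDEL",
                    "NONFRAMESHIFT_INDEL") and av.effect.indel_length >= large:
        lof = True
    ev = av.evidence
    conserved = (not is_absent(ev.gerp) and not is_absent(ev.phylop_new)
                 and ev.gerp > 2 and ev.phylop_new > 0.95)
    votes = 0
    votes += (not is_absent(ev.sift)) and ev.sift == "Damaging"
    votes += (not is_absent(ev.lrt)) and ev.lrt == "Deleterious"
    votes += (not is_absent(ev.polyphen2)) and ev.polyphen2 in (
        "Probably damaging", "Possibly damaging")
    votes += (not is_absent(ev.mutation_taster)) and ev.mutation_taster in (
        "Disease causing automatic", "Disease causing")
    return {
        "rare": rare, "lof": lof, "conserved": conserved,
        "damaging3": votes >= 3, "cls": cls,
        "missense": cls is EffectClass.MISSENSE,
        "nonframeshift": cls is EffectClass.NONFRAMESHIFT_INDEL,
    }


def oracle_reported_tier(av, maf_thr=0.01, large=50):
    if not av.evidence.reported:
        return None
    p = _oracle_predicates(av, maf_thr, large)
    table = [
        (p["lof"], 1),
        (p["rare"], 2),
        (p["missense"] or p["nonframeshift"], 3),
        (True, 4),
    ]
    return next(t for cond, t in table if cond)


def oracle_novel_tier(av, maf_thr=0.01, large=50):
    p = _oracle_predicates(av, maf_thr, large)
    if av.evidence.reported or not av.evidence.in_monogenic_gene or not p["rare"]:
        return None
    table = [
        (p["lof"], 1),
        ((p["missense"] and p["conserved"]) or p["nonframeshift"], 2),
        (p["missense"] and p["damaging3"], 3),
        (True, 4),
    ]
    return next(t for cond, t in table if cond)


def _make_av(effect=EffectClass.MISSENSE, indel_length=0, reported=False,
             monogenic=True, local_af=ABSENT, gerp=ABSENT, phylop=ABSENT,
             votes=0, **mafs):
    maf = {s: ABSENT for s in FREQUENCY_SOURCES}
    maf.update(mafs)
    damaging = [("sift", "Damaging"), ("lrt", "Deleterious"),
                ("polyphen2", "Possibly damaging"),
                ("mutation_taster", "Disease causing")]
    ev_kwargs = dict(damaging[:votes])
    ev = EvidenceProfile(gerp=gerp, phylop_new=phylop, reported=reported,
                         in_monogenic_gene=monogenic, **ev_kwargs)
    return AnnotatedVariant(
        VariantRecord("1", 500, "A", ("C",)),
        EffectAnnotation(effect, gene="TOYA" if monogenic else None,
                         indel_length=indel_length),
        FrequencyProfile(maf=maf, local_cohort_af=local_af), ev)


class TestReportedTrack:
    def test_common_reported_lof_is_tier1(self):
        """Frequency filters are skipped for tier 1 so established common
        pathogenic alleles are not lost."""
        av = _make_av(effect=EffectClass.NONSENSE, reported=True,
                      kg_global=0.30)
        assert tier_reported(av).tier == 1

    def test_rare_reported_synonymous_is_tier2(self):
        av = _make_av(effect=EffectClass.SYNONYMOUS, reported=True,
                      kg_global=0.001)
        assert tier_reported(av).tier == 2

    def test_common_reported_missense_is_tier3(self):
        av = _make_av(effect=EffectClass.MISSENSE, reported=True,
                      kg_global=0.30)
        assert tier_reported(av).tier == 3

    def test_common_reported_synonymous_falls_through_to_tier4(self):
        av = _make_av(effect=EffectClass.SYNONYMOUS, reported=True,
                      kg_global=0.30)
        assert tier_reported(av).tier == 4

    def test_unreported_variant_is_excluded(self):
        av = _make_av(reported=False, kg_global=0.001)
        assert tier_reported(av).excluded


class TestNovelTrack:
    def test_rare_frameshift_in_monogenic_gene_is_tier1(self):
        av = _make_av(effect=EffectClass.FRAMESHIFT_INDEL, indel_length=2,
                      kg_global=0.001)
        assert tier_novel(av).tier == 1

    def test_conserved_rare_missense_is_tier2(self):
        av = _make_av(gerp=3.0, phylop=0.97, kg_global=0.001)
        assert tier_novel(av).tier == 2

    def test_rare_nonframeshift_indel_is_tier2(self):
        av = _make_av(effect=EffectClass.NONFRAMESHIFT_INDEL, indel_length=3,
                      kg_global=0.001)
        assert tier_novel(av).tier == 2

    def test_damaging_consensus_missense_is_tier3(self):
        av = _make_av(gerp=1.0, votes=3, kg_global=0.001)
        assert tier_novel(av).tier == 3

    def test_non_rare_is_excluded(self):
        av = _make_av(kg_global=0.30)
        assert tier_novel(av).excluded

    def test_outside_monogenic_genes_is_excluded(self):
        av = _make_av(monogenic=False, kg_global=0.001)
        assert tier_novel(av).excluded

    def test_reducing_worst_maf_never_demotes(self):
        """Monotonicity: making the variant rarer can only keep or lower
        the novel-track tier number."""
        for maf_hi, maf_lo in [(0.30, 0.001), (0.02, 0.005)]:
            hi = tier_novel(_make_av(gerp=3.0, phylop=0.97, kg_global=maf_hi))
            lo = tier_novel(_make_av(gerp=3.0, phylop=0.97, kg_global=maf_lo))
            hi_rank = hi.tier if hi.tier is not None else 99
            lo_rank = lo.tier if lo.tier is not None else 99
            assert lo_rank <= hi_rank


class TestOracleEquivalence:
    def test_rules_match_decision_table_on_random_variants(self):
        for av in random_annotated_variants(seed=7, n=2000):
            got = assign_tiers(av)
            assert got[Track.REPORTED].tier == oracle_reported_tier(av)
            assert got[Track.NOVEL].tier == oracle_novel_tier(av)

    def test_exactly_one_outcome_per_track(self):
        """Tiers 1-4 + EXCLUDED are mutually exclusive and exhaustive."""
        for av in random_annotated_variants(seed=8, n=500):
            for ta in assign_tiers(av).values():
                assert ta.tier in (1, 2, 3, 4, None)


class TestFixtureTiers:
    """The annotation fixture's probes map to hand-derived tiers."""

    EXPECTED = {
        # probe -> (reported tier, novel tier); None == excluded
        "nonsense_codon5": (1, None),       # reported common LOF
        "synonymous_codon6": (2, None),     # reported rare
        "missense_codon11": (3, None),      # reported common missense
        "nonstop_codon79": (1, None),       # reported common stop-loss
        "missense_codon7": (None, 2),       # novel rare conserved missense
        "missense_codon8": (None, 3),       # novel rare damaging-consensus
        "missense_codon9": (None, 4),       # boundary gerp=2.0 fails strict >
        "frameshift_del2": (None, 1),       # novel rare frameshift
        "nonframeshift_del3": (None, 2),    # novel rare in-frame indel
        "splice_donor": (None, 1),          # novel rare splice dinucleotide
        "intergenic_snv": (None, None),     # outside monogenic genes
    }

    def test_probe_tiers(self, annotation_fixture):
        fx = annotation_fixture
        db = AnnotationDB.from_frames(freq=fx.freq, scores=fx.scores,
                                      reported=fx.reported, genes=fx.genes,
                                      local=fx.local)
        annotated = dict(zip(fx.probes.keys(),
                             annotate_stream(list(fx.probes.values()), db,
                                             fx.gene_model)))
        for name, (rep, nov) in self.EXPECTED.items():
            got = assign_tiers(annotated[name])
            assert got[Track.REPORTED].tier == rep, name
            assert got[Track.NOVEL].tier == nov, name

    def test_reported_common_missense_also_reported_track_only(self,
                                                               annotation_fixture):
        fx = annotation_fixture
        db = AnnotationDB.from_frames(freq=fx.freq, scores=fx.scores,
                                      reported=fx.reported, genes=fx.genes)
        annotated = dict(zip(fx.probes.keys(),
                             annotate_stream(list(fx.probes.values()), db,
                                             fx.gene_model)))
        got = assign_tiers(annotated["missense_codon10"])
        assert got[Track.REPORTED].tier == 3
        assert got[Track.NOVEL].excluded  # reported variants leave the novel track


class TestLocalCohortFilter:
    def test_removes_exactly_high_local_af(self):
        high = _make_av(reported=True, effect=EffectClass.NONSENSE,
                        local_af=0.40)
        low = _make_av(reported=True, effect=EffectClass.NONSENSE,
                       local_af=0.10)
        absent = _make_av(reported=True, effect=EffectClass.NONSENSE)
        boundary = _make_av(reported=True, effect=EffectClass.NONSENSE,
                            local_af=0.25)
        pairs = [(av, tier_reported(av)) for av in (high, low, absent, boundary)]
        kept = local_cohort_filter(pairs, cutoff=0.25)
        assert [av for av, _ in kept] == [low, absent]

    def test_empty_local_table_is_identity(self):
        avs = [_make_av(reported=True, effect=EffectClass.NONSENSE)
               for _ in range(3)]
        pairs = [(av, tier_reported(av)) for av in avs]
        assert local_cohort_filter(pairs) == pairs


class TestRestrictToGenes:
    def test_membership_and_sex_handling(self):
        in_set = _make_av()
        out_set = AnnotatedVariant(
            VariantRecord("1", 600, "A", ("C",)),
            EffectAnnotation(EffectClass.MISSENSE, gene="OTHER"),
            FrequencyProfile(), EvidenceProfile())
        y_var = AnnotatedVariant(
            VariantRecord("Y", 600, "A", ("C",)),
            EffectAnnotation(EffectClass.MISSENSE, gene="SRY"),
            FrequencyProfile(), EvidenceProfile())
        genes = {"TOYA", "SRY"}
        assert restrict_to_genes([in_set, out_set, y_var], genes) == [in_set, y_var]
        assert restrict_to_genes([in_set, out_set, y_var], genes,
                                 sample_sex="female",
                                 y_genes={"SRY"}) == [in_set]

    def test_empty_gene_set_is_an_error(self):
        with pytest.raises(ValueError):
            restrict_to_genes([], set())


class TestPrioritizeTable:
    def test_end_to_end_table(self, annotation_fixture):
        fx = annotation_fixture
        db = AnnotationDB.from_frames(freq=fx.freq, scores=fx.scores,
                                      reported=fx.reported, genes=fx.genes,
                                      local=fx.local)
        annotated = list(annotate_stream(list(fx.probes.values()), db,
                                         fx.gene_model))
        table = prioritize_variants(annotated)
        assert set(table.track) <= {"REPORTED", "NOVEL"}
        assert table.tier.max() <= 3
        # local-cohort filter removed the high-local-AF conserved missense
        p7 = fx.probes["missense_codon7"]
        assert not ((table.pos == p7.pos) & (table.alt == p7.alt[0])).any()
        # deterministic: identical on a second run
        table2 = prioritize_variants(annotated)
        assert table.equals(table2)
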