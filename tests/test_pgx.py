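"""Star-allele calling: skeleton construction, diplotype enumeration,
perfect-match search with missing data, truth-in-set on seeded fixtures,
and single-variant drug-response annotation."""
import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varmend.model import GenotypeCall, VariantRecord
from varmend.pgx import (
    REF,
    UNKNOWN,
    CallResolution,
    GeneDefinitions,
    annotate_single_variant_pgx,
    build_skeleton,
    call_diplotype,
    compatible_alleles,
    definitions_from_frame,
    enumerate_diplotypes,
    match_star_alleles,
)
from varmend.simulate import make_star_fixture


def gt(a, b):
    return GenotypeCall.of(a, b, depth=40, quality=99.0)


POSITIONS = (100, 110, 120)


def genos(*calls):
    return {p: ("G", c) for p, c in zip(POSITIONS, calls)}


class TestBuildSkeleton:
    def test_all_hom_ref(self):
        a, b, hets = build_skeleton(genos(gt(0, 0), gt(0, 0), gt(0, 0)),
                                    POSITIONS)
        assert a == b == [REF, REF, REF] and hets == []

    def test_hom_alt_fixed_on_both_haplotypes(self):
        a, b, _ = build_skeleton(genos(gt(1, 1), gt(0, 0), gt(0, 0)), POSITIONS)
        assert a[0] == b[0] == "G"

    def test_low_confidence_becomes_unknown(self):
        low = GenotypeCall.of(0, 1, depth=3, quality=99.0,
                              thresholds=__import__("varmend").ConfidenceThresholds())
        a, b, hets = build_skeleton(genos(low, gt(0, 0), gt(0, 0)), POSITIONS)
        assert a[0] == b[0] == UNKNOWN and hets == []

    def test_uncovered_position_unknown(self):
        a, b, _ = build_skeleton({POSITIONS[0]: ("G", gt(0, 0))}, POSITIONS)
        assert a[1] == b[1] == UNKNOWN


class TestEnumerateDiplotypes:
    @pytest.mark.parametrize("h", range(0, 11))
    def test_pair_count_law(self, h):
        positions = tuple(100 + 10 * i for i in range(h))
        g = {p: ("G", gt(0, 1)) for p in positions}
        a, b, hets = build_skeleton(g, positions)
        pairs = enumerate_diplotypes((a, b), hets, list(positions),
                                     {p: "G" for p in hets})
        assert len(pairs) == max(1, 2 ** (h - 1))
        assert len(set(pairs)) == len(pairs)

    def test_cap_raises_toward_manual_curation(self):
        positions = tuple(100 + i for i in range(13))
        g = {p: ("G", gt(0, 1)) for p in positions}
        a, b, hets = build_skeleton(g, positions)
        with pytest.raises(ValueError, match="curation"):
            enumerate_diplotypes((a, b), hets, list(positions), cap=12)

    @given(st.integers(min_value=0, max_value=6), st.integers(0, 1000))
    @settings(max_examples=60, derandomize=True)
    def test_complementarity_at_every_called_position(self, h, seed):
        """Every pair recombines to the called genotype at every position."""
        positions = tuple(100 + 10 * i for i in range(max(h, 1) + 2))
        import numpy as np
        rng = np.random.default_rng(seed)
        calls = {}
        for p in positions:
            z = rng.integers(3)
            calls[p] = ("G", gt(*{0: (0, 0), 1: (0, 1), 2: (1, 1)}[z]))
        a, b, hets = build_skeleton(calls, positions)
        pairs = enumerate_diplotypes((a, b), hets, list(positions),
                                     {p: calls[p][0] for p in hets})
        for pair in pairs:
            for i, p in enumerate(positions):
                alt, call = calls[p]
                want = sorted(("G" if x else REF) for x in sorted(call.alleles))
                got = sorted((pair.hap_a[i], pair.hap_b[i]))
                assert got == want


def brute_force_compatible(hap, defs):
    return {name for name, vec in defs.alleles.items()
            if all(h == UNKNOWN or h == v for h, v in zip(hap, vec))}


class TestMatchStarAlleles:
    DEFS = GeneDefinitions("CYPX", POSITIONS, {
        "*1": (REF, REF, REF),
        "*2": ("G", REF, REF),
        "*17": ("G", REF, "G"),
    })

    def test_unique_perfect_match_resolved(self):
        call = call_diplotype(genos(gt(0, 1), gt(0, 0), gt(0, 0)), self.DEFS)
        assert call.status is CallResolution.RESOLVED
        assert call.star_pairs == [("*1", "*2")]

    def test_unknown_at_discriminating_position_is_ambiguous(self):
        # position 120 separates *2 from *17; mask it
        g = genos(gt(0, 1), gt(0, 0), GenotypeCall.no_call())
        call = call_diplotype(g, self.DEFS)
        assert call.status is CallResolution.AMBIGUOUS
        assert set(call.star_pairs) == {("*1", "*2"), ("*1", "*17")}
        assert call.unknown_positions == [120]

    def test_no_match_reports_raw_haplotypes(self):
        # hom-alt at 110 matches no defined allele
        call = call_diplotype(genos(gt(0, 0), gt(1, 1), gt(0, 0)), self.DEFS)
        assert call.status is CallResolution.UNASSIGNED
        assert call.star_pairs == [] and call.raw_pairs

    def test_compatible_set_matches_exhaustive_oracle(self):
        entries = [REF, "G", UNKNOWN]
        for hap in itertools.product(entries, repeat=3):
            assert compatible_alleles(hap, self.DEFS) == \
                brute_force_compatible(hap, self.DEFS)

    def test_duplicate_haplotypes_rejected(self):
        with pytest.raises(ValueError):
            GeneDefinitions("X", (1, 2), {"*1": (REF, REF), "*2": (REF, REF)})


class TestFixtures:
    @pytest.mark.parametrize("seed", range(100))
    def test_truth_pair_always_in_candidate_set(self, seed):
        fx = make_star_fixture(seed, n_alleles=5, n_positions=4)
        call = call_diplotype(fx.genotypes, fx.defs)
        assert tuple(sorted(fx.truth)) in {tuple(p) for p in call.star_pairs}

    @pytest.mark.parametrize("seed", range(30))
    def test_fully_informative_tag_fixture_resolves_uniquely(self, seed):
        """With a private tag variant per allele and every position
        confidently called, the caller must return exactly one pair —
        the truth."""
        from varmend.simulate import make_tag_star_fixture
        fx = make_tag_star_fixture(seed, n_alleles=5)
        call = call_diplotype(fx.genotypes, fx.defs)
        assert call.status is CallResolution.RESOLVED
        assert call.star_pairs == [tuple(sorted(fx.truth))]

    def test_masking_never_shrinks_candidate_set(self):
        for seed in range(20):
            fx = make_star_fixture(seed, n_alleles=5, n_positions=4)
            base = call_diplotype(fx.genotypes, fx.defs)
            masked_fx = make_star_fixture(seed, n_alleles=5, n_positions=4,
                                          mask_positions=(5000,))
            masked = call_diplotype(masked_fx.genotypes, masked_fx.defs)
            assert set(map(tuple, base.star_pairs)) <= \
                set(map(tuple, masked.star_pairs))

    def test_masked_discriminating_position_yields_oracle_sets(self):
        fx = make_star_fixture(11, n_alleles=6, n_positions=4,
                               mask_positions=(5000, 5010))
        call = call_diplotype(fx.genotypes, fx.defs)
        # oracle: recompute candidate pairs by exhaustive compatibility
        from varmend.pgx import enumerate_diplotypes, build_skeleton
        a, b, hets = build_skeleton(fx.genotypes, fx.defs.positions)
        pairs = enumerate_diplotypes((a, b), hets, list(fx.defs.positions),
                                     {p: fx.genotypes[p][0] for p in hets})
        want = set()
        for pair in pairs:
            for x in brute_force_compatible(pair.hap_a, fx.defs):
                for y in brute_force_compatible(pair.hap_b, fx.defs):
                    want.add(tuple(sorted((x, y))))
        assert set(map(tuple, call.star_pairs)) == want

    def test_definitions_round_trip_through_table(self):
        fx = make_star_fixture(2, n_alleles=4, n_positions=3)
        defs = definitions_from_frame(fx.definitions_table)["PGX1"]
        assert defs.alleles == fx.defs.alleles


class TestSingleVariantKb:
    import pandas as pd
    KB = pd.DataFrame([
        {"chrom": "1", "pos": 100, "ref": "A", "alt": "G", "drug": "warfarin",
         "level": "1A", "annotation": "dose down"},
        {"chrom": "1", "pos": 200, "ref": "C", "alt": "T", "drug": "clopidogrel",
         "level": "3", "annotation": "poor response"},
        {"chrom": "1", "pos": 300, "ref": "G", "alt": "A", "drug": "simvastatin",
         "level": "2B", "annotation": "myopathy"},
    ])

    def _records(self, gts):
        out = []
        for (pos, ref, alt), g in gts.items():
            out.append(VariantRecord("1", pos, ref, (alt,),
                                     genotypes={"S": g}))
        return out

    def test_level_filtering_and_genotype_match(self):
        recs = self._records({(100, "A", "G"): gt(0, 1),
                              (200, "C", "T"): gt(0, 1),
                              (300, "G", "A"): gt(0, 0)})
        table = annotate_single_variant_pgx(recs, self.KB, "S", min_level="2B")
        # level 1A passes, level 3 is below cutoff, hom-ref never matches
        assert table.drug.tolist() == ["warfarin"]
        assert table.zygosity.tolist() == ["het"]

    def test_loose_cutoff_admits_level3(self):
        recs = self._records({(200, "C", "T"): gt(1, 1)})
        table = annotate_single_variant_pgx(recs, self.KB, "S", min_level="4")
        assert table.drug.tolist() == ["clopidogrel"]
        assert table.zygosity.tolist() == ["hom"]

    def test_unknown_level_row_skipped_with_warning(self):
        import pandas as pd
        kb = pd.concat([self.KB, pd.DataFrame([
            {"chrom": "1", "pos": 100, "ref": "A", "alt": "G",
             "drug": "x", "level": "5C", "annotation": ""}])])
        recs = self._records({(100, "A", "G"): gt(0, 1)})
        with pytest.warns(UserWarning, match="level"):
            table = annotate_single_variant_pgx(recs, kb, "S", min_level="4")
        assert "x" not in set(table.drug)
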