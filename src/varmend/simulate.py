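"""Deterministic, seeded generators for every input the pipeline
consumes: trio VCFs with planted inheritance-state segments and candidate
events (plus ground-truth manifests), star-allele definition fixtures
with known diplotypes, and annotation-table fixtures covering every
tiering predicate combination.

Each generator draws from its own named pseudo-random stream derived from
the single user seed, so adding a generator never perturbs another's
output. All outputs are plain text in the formats the pipeline reads.

What these fixtures emulate — and what they do not: genotype
configurations, inheritance-error and compression artifact tracts,
per-survey allele frequencies and star-allele structure are realistic in
form; linkage disequilibrium, read-level error processes and realistic
site-frequency spectra are not modeled.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotatedVariant, EffectAnnotation, EffectClass, EvidenceProfile, FrequencyProfile
from .genes import GeneModel, Transcript
from .model import ABSENT, GenotypeCall, Interval, IntervalSet, VariantRecord
from .pgx import GeneDefinitions, REF
from .tables import FREQUENCY_SOURCES
from .triohmm import HmmParams, State, Symbol

_STREAMS = {"trio": 11, "star": 23, "annotation": 37, "variants": 53, "hmm": 71}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


# ---------------------------------------------------------------------------
# Trio simulation
# ---------------------------------------------------------------------------

_BASES = "ACGT"

# genotype patterns, as (father, mother, child) allele pairs
_PAT_DENOVO = ((0, 0), (0, 0), (0, 1))
_PAT_MIA_BG = ((1, 1), (1, 1), (0, 1))   # MIA that mimics no candidate mode
_PAT_ALLHET = ((0, 1), (0, 1), (0, 1))
_PAT_RAREHOM = ((0, 1), (0, 1), (1, 1))
_PAT_HEMI = ((0, 1), (0, 0), (1, 1))
_PAT_AD = ((0, 1), (0, 0), (0, 1))
_PAT_CH_FATHER = ((0, 1), (0, 0), (0, 1))
_PAT_CH_MOTHER = ((0, 0), (0, 1), (0, 1))

COMMON_MAF = 0.30
RARE_MAF = 0.001


@dataclass
class TrioSimSpec:
    """Study conditions for one simulated trio.

    ``layouts`` gives, per chromosome, runs of (state, n_sites); inter-site
    gaps are uniform on mean_gap +/- gap_jitter bp. Gene blocks tile each
    chromosome every ``gene_block_bp``. Planted events are placed in GOOD
    runs with a margin from segment boundaries; their host gene blocks are
    kept free of background heterozygosity so the truth manifest fully
    determines expected candidate output.
    """

    seed: int = 0
    layouts: dict[str, list[tuple[str, int]]] = field(default_factory=lambda: {
        "1": [("GOOD", 120), ("COMPRESSION", 60), ("GOOD", 120),
              ("MIA_RICH", 60), ("GOOD", 140)],
        "2": [("GOOD", 150), ("MIA_RICH", 60), ("GOOD", 90)],
    })
    mean_gap: int = 400
    gap_jitter: int = 200
    gene_block_bp: int = 10_000
    n_de_novo: int = 2
    n_compound_het_trans: int = 1
    n_compound_het_unknown: int = 1
    n_rare_homozygous: int = 2
    n_hemizygous: int = 1
    n_ad: int = 1
    boundary_margin: int = 5
    common_maf: float = COMMON_MAF
    rare_maf: float = RARE_MAF
    params: HmmParams = field(default_factory=HmmParams)


@dataclass
class TrioFixture:
    records: list[VariantRecord]
    manifest: dict
    freq_table: pd.DataFrame
    gene_intervals: IntervalSet
    deletions: IntervalSet
    disease_genes: set[str]
    samples: tuple[str, str, str] = ("F", "M", "C")

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        from .vcfio import write_bed, write_vcf
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "trio.vcf",
            "manifest": out / "truth.json",
            "freq": out / "frequencies.tsv",
            "genes": out / "genes.bed",
            "deletions": out / "deletions.bed",
            "disease_genes": out / "disease_genes.txt",
        }
        write_vcf(self.records, paths["vcf"], samples=list(self.samples))
        paths["manifest"].write_text(json.dumps(self.manifest, indent=1))
        self.freq_table.to_csv(paths["freq"], sep="\t", index=False)
        write_bed(self.gene_intervals, paths["genes"])
        write_bed(self.deletions, paths["deletions"])
        paths["disease_genes"].write_text(
            "".join(g + "\n" for g in sorted(self.disease_genes)))
        return paths


def _gene_name(chrom: str, pos: int, block_bp: int) -> str:
    return f"G{chrom}_{(pos - 1) // block_bp}"


def _draw_consistent(rng: np.random.Generator, p: float):
    """HWE parents + random transmission, rejecting the all-het pattern
    (which would read as a compression signature)."""
    for _ in range(100):
        f = tuple(sorted(rng.binomial(1, p, size=2)))
        m = tuple(sorted(rng.binomial(1, p, size=2)))
        c = tuple(sorted((f[rng.integers(2)], m[rng.integers(2)])))
        if not (f == (0, 1) and m == (0, 1) and c == (0, 1)):
            return f, m, c
    return (0, 0), (0, 0), (0, 0)


def simulate_trio(spec: TrioSimSpec) -> TrioFixture:
    """Generate a trio callset whose per-site symbols follow the planted
    segments' emission distributions, with candidate events planted in
    GOOD segments and artifact (de-novo-mimicking) patterns confined to
    flagged segments. Pure function of the spec; same spec, same output."""
    rng = _rng(spec.seed, "trio")
    emissions = spec.params.emissions

    site_rows = []  # (chrom, pos, state, symbol)
    segments_truth = []
    for chrom, layout in spec.layouts.items():
        pos = int(rng.integers(1_000, 2_000))
        for state_name, n_sites in layout:
            state = State[state_name]
            first = None
            for _ in range(n_sites):
                pos += int(rng.integers(spec.mean_gap - spec.gap_jitter,
                                        spec.mean_gap + spec.gap_jitter + 1))
                first = pos if first is None else first
                sym = Symbol(int(rng.choice(3, p=emissions[int(state)])))
                site_rows.append([chrom, pos, state, sym])
            segments_truth.append({"chrom": chrom, "start_pos": first,
                                   "end_pos": pos, "state": state.name,
                                   "n_sites": n_sites})

    # choose planted-event sites among interior GOOD sites
    good_idx_by_chrom: dict[str, list[int]] = {}
    i = 0
    for chrom, layout in spec.layouts.items():
        for state_name, n_sites in layout:
            if state_name == "GOOD":
                lo = i + spec.boundary_margin
                hi = i + n_sites - spec.boundary_margin
                good_idx_by_chrom.setdefault(chrom, []).extend(range(lo, hi))
            i += n_sites

    # one anchor site per event, each in its own gene block so planted
    # events never share a gene (compound-het partners are co-located
    # with their anchor explicitly below)
    all_good = [ix for idxs in good_idx_by_chrom.values() for ix in idxs]
    rng.shuffle(all_good)
    needed = (spec.n_de_novo + spec.n_compound_het_trans
              + spec.n_compound_het_unknown + spec.n_rare_homozygous
              + spec.n_hemizygous + spec.n_ad)
    used_blocks: set[str] = set()
    anchors: list[int] = []
    for ix in all_good:
        chrom, pos = site_rows[ix][0], site_rows[ix][1]
        block = _gene_name(chrom, pos, spec.gene_block_bp)
        if block in used_blocks:
            continue
        used_blocks.add(block)
        anchors.append(ix)
        if len(anchors) == needed:
            break
    if len(anchors) < needed:
        raise ValueError("not enough interior GOOD sites for planted events")
    it = iter(anchors)

    planted: dict[int, tuple[str, tuple, float]] = {}  # site idx -> (kind, pattern, maf)
    manifest_planted: dict[str, list] = {
        "de_novo": [], "compound_het": [], "rare_homozygous": [],
        "hemizygous": [], "ad_reduced_penetrance": [],
        "artifact_de_novo_like": [],
    }
    for _ in range(spec.n_de_novo):
        planted[next(it)] = ("de_novo", _PAT_DENOVO, spec.rare_maf)
    def _partner_site(anchor: int) -> int:
        """A GOOD, unplanted site adjacent to ``anchor`` in the same gene
        block, to host the second member of a compound-het pair."""
        chrom, pos = site_rows[anchor][0], site_rows[anchor][1]
        block = _gene_name(chrom, pos, spec.gene_block_bp)
        for off in (1, -1, 2, -2, 3, -3, 4, -4):
            nb = anchor + off
            if not (0 <= nb < len(site_rows)) or nb in planted:
                continue
            c2, p2, st2, _ = site_rows[nb]
            if (c2 == chrom and st2 is State.GOOD
                    and _gene_name(c2, p2, spec.gene_block_bp) == block):
                return nb
        raise ValueError("could not co-locate compound-het pair in one gene")

    ch_pairs = []
    for _ in range(spec.n_compound_het_trans):
        a = next(it)
        planted[a] = ("ch", _PAT_CH_FATHER, spec.rare_maf)
        b = _partner_site(a)
        planted[b] = ("ch", _PAT_CH_MOTHER, spec.common_maf)
        ch_pairs.append((a, b, "TRANS_CONFIRMED"))
    for _ in range(spec.n_compound_het_unknown):
        a = next(it)
        planted[a] = ("ch", _PAT_ALLHET, spec.rare_maf)
        b = _partner_site(a)
        planted[b] = ("ch", _PAT_ALLHET, spec.common_maf)
        ch_pairs.append((a, b, "PHASE_UNKNOWN"))
    for _ in range(spec.n_rare_homozygous):
        planted[next(it)] = ("rare_hom", _PAT_RAREHOM, spec.rare_maf)
    hemi_sites = []
    for _ in range(spec.n_hemizygous):
        ix = next(it)
        planted[ix] = ("hemi", _PAT_HEMI, spec.rare_maf)
        hemi_sites.append(ix)
    ad_sites = []
    for _ in range(spec.n_ad):
        ix = next(it)
        planted[ix] = ("ad", _PAT_AD, spec.rare_maf)
        ad_sites.append(ix)

    reserved_genes = {
        _gene_name(site_rows[ix][0], site_rows[ix][1], spec.gene_block_bp)
        for ix in planted
    }

    from .triohmm import encode_observation

    records: list[VariantRecord] = []
    freq_rows = []
    keys: list[tuple] = []
    actual_syms: list[Symbol] = []
    for ix, (chrom, pos, state, sym) in enumerate(site_rows):
        ref, alt = rng.choice(4, size=2, replace=False)
        ref_b, alt_b = _BASES[ref], _BASES[alt]
        gene = _gene_name(chrom, pos, spec.gene_block_bp)
        maf: Optional[float] = spec.common_maf
        if ix in planted:
            kind, (f, m, c), maf = planted[ix]
        elif gene in reserved_genes:
            f, m, c = (0, 0), (0, 0), (0, 0)  # keep planted genes quiet
        elif sym is Symbol.CONSISTENT:
            f, m, c = _draw_consistent(rng, spec.common_maf)
        elif sym is Symbol.ALLHET:
            f, m, c = _PAT_ALLHET
        else:  # MIA
            if state is State.GOOD:
                f, m, c = _PAT_MIA_BG
            else:
                f, m, c = _PAT_DENOVO
                manifest_planted["artifact_de_novo_like"].append(
                    [chrom, pos, ref_b, alt_b])
        genos = {
            "F": GenotypeCall.of(*f, depth=40, quality=99.0),
            "M": GenotypeCall.of(*m, depth=40, quality=99.0),
            "C": GenotypeCall.of(*c, depth=40, quality=99.0),
        }
        rec = VariantRecord(chrom, pos, ref_b, (alt_b,), genotypes=genos)
        records.append(rec)
        actual_syms.append(encode_observation(genos["F"], genos["M"],
                                              genos["C"]))
        key = [chrom, pos, ref_b, alt_b]
        keys.append(tuple(key))
        if maf is not None:
            for source in ("kg_global", "exac"):
                freq_rows.append({"chrom": chrom, "pos": pos, "ref": ref_b,
                                  "alt": alt_b, "source": source, "maf": maf})
        if ix in planted:
            kind = planted[ix][0]
            if kind == "de_novo":
                manifest_planted["de_novo"].append(key)
            elif kind == "rare_hom":
                manifest_planted["rare_homozygous"].append(key)

    deletions = IntervalSet()
    for ix in hemi_sites:
        chrom, pos = site_rows[ix][0], site_rows[ix][1]
        iv = Interval(chrom, pos - 500, pos + 500, "DEL")
        deletions.add(iv)
        manifest_planted["hemizygous"].append(
            {"key": list(keys[ix]), "deletion": [chrom, iv.start, iv.end]})
    disease_genes = set()
    for ix in ad_sites:
        chrom, pos = site_rows[ix][0], site_rows[ix][1]
        gene = _gene_name(chrom, pos, spec.gene_block_bp)
        disease_genes.add(gene)
        manifest_planted["ad_reduced_penetrance"].append(list(keys[ix]))
    for a, b, phase in ch_pairs:
        chrom, pos = site_rows[a][0], site_rows[a][1]
        manifest_planted["compound_het"].append({
            "gene": _gene_name(chrom, pos, spec.gene_block_bp),
            "first": list(keys[a]), "second": list(keys[b]), "phase": phase,
        })

    gene_intervals = IntervalSet()
    for chrom, layout in spec.layouts.items():
        last_pos = max(p for c, p, _, _ in site_rows if c == chrom)
        n_blocks = (last_pos - 1) // spec.gene_block_bp + 1
        for b in range(n_blocks):
            gene_intervals.add(Interval(chrom, b * spec.gene_block_bp,
                                        (b + 1) * spec.gene_block_bp,
                                        f"G{chrom}_{b}"))

    manifest = {
        "seed": spec.seed,
        "samples": {"father": "F", "mother": "M", "child": "C"},
        "segments": segments_truth,
        "sites": [[row[0], row[1], row[2].name, sym.name]
                  for row, sym in zip(site_rows, actual_syms)],
        "planted": manifest_planted,
    }
    freq_table = pd.DataFrame(
        freq_rows, columns=["chrom", "pos", "ref", "alt", "source", "maf"])
    return TrioFixture(records, manifest, freq_table, gene_intervals,
                       deletions, disease_genes)


def gene_model_from_intervals(gene_intervals: IntervalSet) -> GeneModel:
    """Gene membership without transcript structure: each interval becomes
    a single-exon non-coding transcript, so classification yields the gene
    symbol (effect UTR) — sufficient for trio candidate discovery."""
    model = GeneModel(genome={})
    for iv in gene_intervals:
        model.add(Transcript(iv.label, f"{iv.label}.t1", iv.chrom, "+",
                             exons=((iv.start, iv.end),)))
    return model


# ---------------------------------------------------------------------------
# Star-allele fixtures
# ---------------------------------------------------------------------------

@dataclass
class StarFixture:
    defs: GeneDefinitions
    definitions_table: pd.DataFrame
    genotypes: dict[int, tuple[str, GenotypeCall]]
    truth: tuple[str, str]
    alt_by_pos: dict[int, str]


def make_star_fixture(seed: int, n_alleles: int = 4, n_positions: int = 3,
                      mask_positions: Sequence[int] = (),
                      gene: str = "PGX1") -> StarFixture:
    """Random pairwise-distinct star-allele definitions, a sampled true
    diplotype, and genotypes derived from that truth. Masked positions are
    emitted as NO_CALL to probe ambiguity handling."""
    if n_alleles > 2 ** n_positions:
        raise ValueError("n_alleles exceeds number of distinct haplotypes")
    if n_alleles < 1:
        raise ValueError("need at least one allele")
    rng = _rng(seed, "star")
    positions = tuple(5000 + 10 * i for i in range(n_positions))
    alt_by_pos = {p: "G" for p in positions}  # ref A, alt G at every site
    codes = {0}
    while len(codes) < n_alleles:
        codes.add(int(rng.integers(0, 2 ** n_positions)))
    ordered = [0] + sorted(codes - {0})
    alleles = {}
    for k, code in enumerate(ordered, start=1):
        vec = tuple(alt_by_pos[p] if (code >> i) & 1 else REF
                    for i, p in enumerate(positions))
        alleles[f"*{k}"] = vec
    defs = GeneDefinitions(gene, positions, alleles)

    names = sorted(alleles)
    truth = tuple(sorted(rng.choice(names, size=2, replace=True).tolist()))
    va, vb = alleles[truth[0]], alleles[truth[1]]
    genotypes: dict[int, tuple[str, GenotypeCall]] = {}
    for i, p in enumerate(positions):
        if p in mask_positions:
            genotypes[p] = (alt_by_pos[p], GenotypeCall.no_call())
            continue
        n_alt = (va[i] != REF) + (vb[i] != REF)
        gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[n_alt]
        genotypes[p] = (alt_by_pos[p], GenotypeCall.of(*gt, depth=40,
                                                       quality=99.0))
    rows = []
    for name, vec in alleles.items():
        for i, p in enumerate(positions):
            if vec[i] != REF:
                rows.append({"gene": gene, "allele": name, "chrom": "10",
                             "pos": p, "ref": "A", "alt": vec[i]})
    table = pd.DataFrame(rows,
                         columns=["gene", "allele", "chrom", "pos", "ref", "alt"])
    return StarFixture(defs, table, genotypes, truth, alt_by_pos)


def make_tag_star_fixture(seed: int, n_alleles: int = 5,
                          gene: str = "PGX1") -> StarFixture:
    """Star fixture where every non-reference allele carries one private
    ("tag") defining variant, mirroring real star tables. With all
    positions confidently genotyped, any true diplotype has exactly one
    compatible star pair, so calls must come back RESOLVED."""
    if n_alleles < 2:
        raise ValueError("need at least two alleles")
    rng = _rng(seed, "star")
    n_positions = n_alleles - 1
    positions = tuple(5000 + 10 * i for i in range(n_positions))
    alt_by_pos = {p: "G" for p in positions}
    alleles = {"*1": tuple([REF] * n_positions)}
    for k in range(2, n_alleles + 1):
        vec = [REF] * n_positions
        vec[k - 2] = alt_by_pos[positions[k - 2]]
        alleles[f"*{k}"] = tuple(vec)
    defs = GeneDefinitions(gene, positions, alleles)
    names = sorted(alleles)
    truth = tuple(sorted(rng.choice(names, size=2, replace=True).tolist()))
    va, vb = alleles[truth[0]], alleles[truth[1]]
    genotypes = {}
    for i, p in enumerate(positions):
        n_alt = (va[i] != REF) + (vb[i] != REF)
        gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[n_alt]
        genotypes[p] = (alt_by_pos[p],
                        GenotypeCall.of(*gt, depth=40, quality=99.0))
    rows = [{"gene": gene, "allele": name, "chrom": "10", "pos": p,
             "ref": "A", "alt": v}
            for name, vec in alleles.items()
            for p, v in zip(positions, vec) if v != REF]
    table = pd.DataFrame(rows,
                         columns=["gene", "allele", "chrom", "pos", "ref", "alt"])
    return StarFixture(defs, table, genotypes, truth, alt_by_pos)


# ---------------------------------------------------------------------------
# Annotation / tiering fixtures
# ---------------------------------------------------------------------------

def toy_gene_model() -> GeneModel:
    """Two engineered genes on a 2-chromosome toy genome.

    TOYA (chrom 1, + strand, 3 exons): CDS reads ATG, then 78 CAG (Gln)
    codons, then TAA, so stop-gain/stop-loss/synonymous probes have known
    coordinates. TOYB (chrom 2, - strand) carries the same design reverse
    complemented, exercising strand handling.
    """
    rng = np.random.default_rng(20150810)
    genome = {c: list("".join(rng.choice(list("ACGT"), size=6000)))
              for c in ("1", "2")}

    exons_a = ((1000, 1100), (1200, 1320), (1400, 1500))
    cds_a = ((1040, 1100), (1200, 1320), (1400, 1460))
    tx_a = Transcript("TOYA", "TOYA.t1", "1", "+", exons_a, cds_a)
    mrna = "ATG" + "CAG" * 78 + "TAA"
    for p, b in zip(tx_a.cds_positions(), mrna):
        genome["1"][p] = b
    # canonical splice dinucleotides
    for p, b in ((1100, "G"), (1101, "T"), (1198, "A"), (1199, "G"),
                 (1320, "G"), (1321, "T"), (1398, "A"), (1399, "G")):
        genome["1"][p] = b

    exons_b = ((2000, 2100), (2200, 2341))
    cds_b = ((2022, 2100), (2200, 2281))  # 78 + 81 = 159 bases, 53 codons
    tx_b = Transcript("TOYB", "TOYB.t1", "2", "-", exons_b, cds_b)
    mrna_b = "ATG" + "CAG" * 51 + "TAA"
    from Bio.Seq import Seq
    for p, b in zip(tx_b.cds_positions(), mrna_b):
        genome["2"][p] = str(Seq(b).complement())

    model = GeneModel(genome={c: "".join(s) for c, s in genome.items()})
    model.add(tx_a)
    model.add(tx_b)
    return model


@dataclass
class AnnotationFixture:
    gene_model: GeneModel
    probes: dict[str, VariantRecord]
    freq: pd.DataFrame
    scores: pd.DataFrame
    reported: pd.DataFrame
    genes: pd.DataFrame
    local: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("freq", "scores", "reported", "genes", "local"):
            p = out / f"{name}.tsv"
            getattr(self, name).to_csv(p, sep="\t", index=False)
            paths[name] = p
        return paths


def make_annotation_fixture(seed: int = 0) -> AnnotationFixture:
    """Probe variants on the toy genes covering every tiering predicate
    combination at least once, with the matching TSV join tables.

    Probe names encode the intent (track, rarity, evidence); expected
    tiers are derived independently in the test suite, not here.
    """
    model = toy_gene_model()
    genome = model.genome["1"]
    # codon k of TOYA (+ strand): CDS base index 3k
    cds = [t for t in model.transcripts if t.gene == "TOYA"][0].cds_positions()

    def snv(codon: int, offset: int, alt: str) -> VariantRecord:
        p0 = cds[3 * codon + offset]
        return VariantRecord("1", p0 + 1, genome[p0], (alt,))

    probes: dict[str, VariantRecord] = {}
    probes["nonsense_codon5"] = snv(5, 0, "T")          # CAG -> TAG
    probes["synonymous_codon6"] = snv(6, 2, "A")        # CAG -> CAA
    probes["missense_codon7"] = snv(7, 1, "T")          # CAG -> CTG
    probes["missense_codon8"] = snv(8, 1, "T")
    probes["missense_codon9"] = snv(9, 1, "T")
    probes["missense_codon10"] = snv(10, 1, "T")
    probes["missense_codon11"] = snv(11, 1, "T")
    probes["nonstop_codon79"] = snv(79, 1, "C")         # TAA -> TCA
    p0 = cds[30]
    probes["frameshift_del2"] = VariantRecord(
        "1", p0 + 1, genome[p0] + genome[p0 + 1] + genome[p0 + 2],
        (genome[p0],))
    probes["nonframeshift_del3"] = VariantRecord(
        "1", p0 + 1, "".join(genome[p0:p0 + 4]), (genome[p0],))
    probes["splice_donor"] = VariantRecord("1", 1101, genome[1100], ("C",))
    probes["intergenic_snv"] = VariantRecord("1", 5001, genome[5000],
                                             ("A" if genome[5000] != "A" else "C",))

    rng = _rng(seed, "annotation")

    def rows_for(name: str, maf: Optional[float], sources=("kg_global", "exac")):
        rec = probes[name]
        return [{"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                 "alt": rec.alt[0], "source": s, "maf": maf} for s in sources]

    freq_rows = []
    rare = {"synonymous_codon6", "missense_codon7", "missense_codon8",
            "missense_codon9", "frameshift_del2", "nonframeshift_del3",
            "splice_donor", "intergenic_snv"}
    common = {"nonsense_codon5", "missense_codon10", "missense_codon11",
              "nonstop_codon79"}
    for name in rare:
        freq_rows += rows_for(name, 0.001)
    for name in common:
        freq_rows += rows_for(name, 0.30)

    def score_row(name, gerp=None, phylop=None, sift=None, lrt=None,
                  pp2=None, mt=None):
        rec = probes[name]
        return {"chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                "alt": rec.alt[0], "gerp": gerp, "phylop": phylop,
                "sift": sift, "lrt": lrt, "polyphen2": pp2,
                "mutation_taster": mt}

    scores = pd.DataFrame([
        score_row("missense_codon7", gerp=3.1, phylop=0.97,
                  sift="Tolerated", lrt="Neutral", pp2="Benign",
                  mt="Polymorphism"),
        score_row("missense_codon8", gerp=1.0, phylop=0.50,
                  sift="Damaging", lrt="Deleterious",
                  pp2="Possibly damaging", mt="Polymorphism"),
        score_row("missense_codon9", gerp=2.0, phylop=0.99,  # boundary: fails strict >
                  sift="Tolerated", lrt="Neutral", pp2="Benign",
                  mt="Polymorphism"),
        score_row("missense_codon10", gerp=4.0, phylop=0.99,
                  sift="Damaging", lrt="Deleterious", pp2="Probably damaging",
                  mt="Disease causing"),
    ])

    reported_names = ("nonsense_codon5", "synonymous_codon6",
                      "nonstop_codon79", "missense_codon10",
                      "missense_codon11")
    reported = pd.DataFrame([
        {"chrom": probes[n].chrom, "pos": probes[n].pos,
         "ref": probes[n].ref, "alt": probes[n].alt[0],
         "reported_effect": "DM"} for n in reported_names
    ])
    genes = pd.DataFrame([{"gene": "TOYA", "monogenic_flag": 1},
                          {"gene": "TOYB", "monogenic_flag": 1}])
    local = pd.DataFrame([
        {"chrom": probes["missense_codon7"].chrom,
         "pos": probes["missense_codon7"].pos,
         "ref": probes["missense_codon7"].ref,
         "alt": probes["missense_codon7"].alt[0], "af": 0.40},
        {"chrom": probes["missense_codon8"].chrom,
         "pos": probes["missense_codon8"].pos,
         "ref": probes["missense_codon8"].ref,
         "alt": probes["missense_codon8"].alt[0], "af": 0.10},
    ])
    freq = pd.DataFrame(freq_rows,
                        columns=["chrom", "pos", "ref", "alt", "source", "maf"])
    # shuffle row order so lookups can't rely on it
    freq = freq.sample(frac=1.0, random_state=int(rng.integers(2**31))
                       ).reset_index(drop=True)
    return AnnotationFixture(model, probes, freq, scores, reported, genes, local)


# ---------------------------------------------------------------------------
# Random AnnotatedVariants for oracle comparisons
# ---------------------------------------------------------------------------

_CATEGORICALS = {
    "sift": ["Damaging", "Tolerated"],
    "lrt": ["Deleterious", "Neutral"],
    "polyphen2": ["Probably damaging", "Possibly damaging", "Benign"],
    "mutation_taster": ["Disease causing automatic", "Disease causing",
                        "Polymorphism"],
}


def random_annotated_variants(seed: int, n: int) -> list[AnnotatedVariant]:
    """Random AnnotatedVariants spanning the tiering predicate space,
    including boundary values (MAF exactly at threshold, GERP exactly 2,
    PhyloP exactly 0.95, local AF exactly 0.25)."""
    rng = _rng(seed, "variants")
    classes = list(EffectClass)
    out = []
    for i in range(n):
        eff_class = classes[int(rng.integers(len(classes)))]
        indel_len = 0
        if eff_class in (EffectClass.FRAMESHIFT_INDEL,
                         EffectClass.LARGE_CODING_INDEL,
                         EffectClass.NONFRAMESHIFT_INDEL):
            indel_len = int(rng.integers(1, 81))
        maf = {}
        for s in FREQUENCY_SOURCES:
            u = rng.random()
            if u < 0.4:
                maf[s] = ABSENT
            elif u < 0.45:
                maf[s] = 0.01  # boundary
            else:
                maf[s] = float(10 ** rng.uniform(-4, -0.3))
        u = rng.random()
        local_af = (ABSENT if u < 0.5 else 0.25 if u < 0.55
                    else float(rng.random()))
        gerp = (ABSENT if rng.random() < 0.3
                else 2.0 if rng.random() < 0.1 else float(rng.uniform(-3, 6)))
        phylop = (ABSENT if rng.random() < 0.3
                  else 0.95 if rng.random() < 0.1 else float(rng.random()))
        cats = {}
        for algo, vocab in _CATEGORICALS.items():
            cats[algo] = (ABSENT if rng.random() < 0.3
                          else vocab[int(rng.integers(len(vocab)))])
        ev = EvidenceProfile(gerp=gerp, phylop_new=phylop,
                             sift=cats["sift"], lrt=cats["lrt"],
                             polyphen2=cats["polyphen2"],
                             mutation_taster=cats["mutation_taster"],
                             reported=bool(rng.random() < 0.5),
                             in_monogenic_gene=bool(rng.random() < 0.7))
        gene = "TOYA" if ev.in_monogenic_gene else None
        rec = VariantRecord("1", 1000 + i, "A", ("C",))
        out.append(AnnotatedVariant(
            rec,
            EffectAnnotation(eff_class, gene=gene, indel_length=indel_len),
            FrequencyProfile(maf=maf, local_cohort_af=local_af),
            ev,
        ))
    return out


def random_hmm_instance(seed: int, n_max: int = 8
                        ) -> tuple[list, HmmParams]:
    """A short random observation sequence with irregular gaps and mildly
    perturbed default parameters, for exhaustive-path comparison."""
    from .triohmm import TrioObservation
    rng = _rng(seed, "hmm")
    n = int(rng.integers(1, n_max + 1))
    pos = np.cumsum(rng.integers(50, 50_000, size=n)) + 1
    syms = rng.integers(0, 3, size=n)
    base = HmmParams()
    em = base.emissions * rng.uniform(0.5, 1.5, size=(3, 3))
    em = em / em.sum(axis=1, keepdims=True)
    pi = base.pi * rng.uniform(0.5, 1.5, size=3)
    pi = pi / pi.sum()
    lengths = base.tract_lengths * rng.uniform(0.3, 3.0, size=3)
    params = HmmParams(emissions=em, tract_lengths=lengths, pi=pi)
    obs = [TrioObservation(int(p), Symbol(int(s)))
           for p, s in zip(pos, syms)]
    return obs, params
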