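"""Star-allele diplotype assignment from unphased genotypes, plus
single-variant drug-response annotation.

The caller builds a skeleton haplotype pair from confidently called
homozygous genotypes, expands heterozygous sites into the full set of
complementary haplotype pairs (2^(h-1) unordered pairs for h het sites),
and perfect-matches each haplotype against the gene's defined star
alleles. Positions that are uncovered or not confidently called stay
UNKNOWN, and any allele consistent with the known positions remains a
candidate: the design only commits when the data do, reporting every
compatible star-allele combination otherwise and handing truly
unresolved haplotypes to a human curator as raw vectors.
"""
from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .model import CallStatus, GenotypeCall

REF = "REF"
UNKNOWN = "UNKNOWN"

EVIDENCE_LEVELS = ("1A", "1B", "2A", "2B", "3", "4")


class CallResolution(enum.Enum):
    RESOLVED = "RESOLVED"
    AMBIGUOUS = "AMBIGUOUS"
    UNASSIGNED = "UNASSIGNED"


@dataclass
class GeneDefinitions:
    """Star-allele definitions for one gene over a shared universe of
    defining positions. The reference allele (*1 by convention) is
    all-REF; other alleles list only their non-reference positions."""

    gene: str
    positions: tuple[int, ...]  # sorted, 1-based
    alleles: dict[str, tuple[str, ...]]  # name -> vector over positions

    def __post_init__(self) -> None:
        vecs = list(self.alleles.values())
        if len(set(vecs)) != len(vecs):
            raise ValueError(f"{self.gene}: duplicate allele haplotypes")
        for name, v in self.alleles.items():
            if len(v) != len(self.positions):
                raise ValueError(f"{self.gene} {name}: vector length mismatch")


def load_star_definitions(path: str | Path,
                          reference_allele: str = "*1"
                          ) -> dict[str, GeneDefinitions]:
    """Long TSV `gene allele chrom pos ref alt`; positions absent from an
    allele's rows are reference. The all-reference allele is added as
    ``reference_allele`` if not listed."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return definitions_from_frame(df, reference_allele=reference_allele)


def definitions_from_frame(df: pd.DataFrame, reference_allele: str = "*1"
                           ) -> dict[str, GeneDefinitions]:
    out: dict[str, GeneDefinitions] = {}
    for gene, sub in df.groupby("gene"):
        positions = tuple(sorted(sub["pos"].unique()))
        pos_index = {p: i for i, p in enumerate(positions)}
        alleles: dict[str, list[str]] = {}
        for _, row in sub.iterrows():
            vec = alleles.setdefault(str(row["allele"]), [REF] * len(positions))
            vec[pos_index[int(row["pos"])]] = str(row["alt"])
        named = {name: tuple(v) for name, v in alleles.items()}
        ref_vec = tuple([REF] * len(positions))
        if reference_allele not in named and ref_vec not in named.values():
            named[reference_allele] = ref_vec
        out[str(gene)] = GeneDefinitions(str(gene), positions, named)
    return out


@dataclass(frozen=True)
class HaplotypePair:
    """Unordered pair of allele-vectors over the gene's defining
    positions; entries are REF, an alt allele string, or UNKNOWN."""

    hap_a: tuple[str, ...]
    hap_b: tuple[str, ...]

    def canonical(self) -> "HaplotypePair":
        a, b = sorted((self.hap_a, self.hap_b))
        return HaplotypePair(a, b)


@dataclass
class StarCall:
    gene: str
    status: CallResolution
    star_pairs: list[tuple[str, str]] = field(default_factory=list)
    raw_pairs: list[HaplotypePair] = field(default_factory=list)
    unknown_positions: list[int] = field(default_factory=list)


def build_skeleton(genotypes: Mapping[int, tuple[str, GenotypeCall]],
                   defining_positions: Sequence[int]
                   ) -> tuple[list[str], list[str], list[int]]:
    """Skeleton haplotype pair from confident homozygous calls.

    ``genotypes`` maps defining position -> (alt allele at that position,
    call). Returns (hap_a, hap_b, het_positions): homozygous positions
    are fixed on both haplotypes, het positions left open (None-free:
    marked REF/alt later by enumeration), uncalled or low-confidence
    positions UNKNOWN on both.
    """
    hap_a: list[str] = []
    hap_b: list[str] = []
    het_positions: list[int] = []
    for pos in defining_positions:
        entry = genotypes.get(pos)
        if entry is None:
            hap_a.append(UNKNOWN)
            hap_b.append(UNKNOWN)
            continue
        alt, call = entry
        if call.status is not CallStatus.CALLED:
            hap_a.append(UNKNOWN)
            hap_b.append(UNKNOWN)
        elif call.is_hom_ref:
            hap_a.append(REF)
            hap_b.append(REF)
        elif call.is_hom_alt:
            hap_a.append(alt)
            hap_b.append(alt)
        else:  # heterozygous: placeholder, filled in by enumeration
            hap_a.append(REF)
            hap_b.append(alt)
            het_positions.append(pos)
    return hap_a, hap_b, het_positions


def enumerate_diplotypes(skeleton: tuple[list[str], list[str]],
                         het_positions: Sequence[int],
                         defining_positions: Sequence[int],
                         het_alleles: Optional[Mapping[int, str]] = None,
                         cap: int = 12) -> list[HaplotypePair]:
    """All distinct unordered complementary pairs: max(1, 2^(h-1)).

    The first heterozygous site is pinned to haplotype A, which removes
    mirror-image duplicates. More than ``cap`` het sites aborts with an
    error: that many unphased sites is a curation problem, not a calling
    problem.
    """
    hap_a, hap_b = (list(skeleton[0]), list(skeleton[1]))
    h = len(het_positions)
    if h > cap:
        raise ValueError(
            f"{h} heterozygous defining sites exceeds cap {cap}; "
            "manual curation advised")
    if h == 0:
        return [HaplotypePair(tuple(hap_a), tuple(hap_b)).canonical()]
    idx = {p: defining_positions.index(p) for p in het_positions}
    alts = {p: (het_alleles[p] if het_alleles else hap_b[idx[p]])
            for p in het_positions}
    pairs = []
    free = het_positions[1:]
    first = het_positions[0]
    for mask in range(2 ** len(free)):
        a, b = list(hap_a), list(hap_b)
        a[idx[first]] = alts[first]  # pinned
        b[idx[first]] = REF
        for bit, p in enumerate(free):
            if (mask >> bit) & 1:
                a[idx[p]], b[idx[p]] = alts[p], REF
            else:
                a[idx[p]], b[idx[p]] = REF, alts[p]
        pairs.append(HaplotypePair(tuple(a), tuple(b)).canonical())
    uniq = list(dict.fromkeys(pairs))
    return uniq


def compatible_alleles(hap: tuple[str, ...], defs: GeneDefinitions) -> set[str]:
    """Star alleles identical to ``hap`` at every known position. With no
    UNKNOWN entries this is exact perfect-match."""
    out = set()
    for name, vec in defs.alleles.items():
        if all(h == UNKNOWN or h == v for h, v in zip(hap, vec)):
            out.add(name)
    return out


def match_star_alleles(pairs: Sequence[HaplotypePair],
                       defs: GeneDefinitions) -> StarCall:
    """Perfect-match search of each haplotype pair against the defined
    star alleles; pair candidates are the cross-product of per-haplotype
    matches. Exactly one surviving star pair is RESOLVED, several are
    AMBIGUOUS (all reported), none is UNASSIGNED with raw haplotypes."""
    star_pairs: set[tuple[str, str]] = set()
    raw: list[HaplotypePair] = []
    unknown_positions: set[int] = set()
    for pair in pairs:
        for hap in (pair.hap_a, pair.hap_b):
            unknown_positions.update(
                p for p, h in zip(defs.positions, hap) if h == UNKNOWN)
        m_a = compatible_alleles(pair.hap_a, defs)
        m_b = compatible_alleles(pair.hap_b, defs)
        if not m_a or not m_b:
            raw.append(pair)
            continue
        for a in m_a:
            for b in m_b:
                star_pairs.add(tuple(sorted((a, b))))
    if not star_pairs:
        status = CallResolution.UNASSIGNED
    elif len(star_pairs) == 1:
        status = CallResolution.RESOLVED
    else:
        status = CallResolution.AMBIGUOUS
    return StarCall(defs.gene, status, sorted(star_pairs), raw,
                    sorted(unknown_positions))


def call_diplotype(genotypes: Mapping[int, tuple[str, GenotypeCall]],
                   defs: GeneDefinitions, cap: int = 12) -> StarCall:
    """End-to-end star-allele call for one gene from per-position calls."""
    hap_a, hap_b, het_positions = build_skeleton(genotypes, defs.positions)
    het_alleles = {p: genotypes[p][0] for p in het_positions}
    pairs = enumerate_diplotypes((hap_a, hap_b), het_positions,
                                 list(defs.positions), het_alleles, cap=cap)
    return match_star_alleles(pairs, defs)


def annotate_single_variant_pgx(records, kb: pd.DataFrame, sample: str,
                                min_level: str = "2B") -> pd.DataFrame:
    """Emit drug-response associations for carried genotypes at or above
    a clinical evidence level (1A strongest .. 4 weakest). KB columns:
    chrom pos ref alt drug level annotation. Rows with unknown level
    strings are skipped with a warning; hom-ref genotypes never match."""
    if min_level not in EVIDENCE_LEVELS:
        raise ValueError(f"unknown evidence level {min_level!r}")
    rank = {lv: i for i, lv in enumerate(EVIDENCE_LEVELS)}
    cutoff = rank[min_level]
    by_key = {}
    for rec in records:
        call = rec.genotypes.get(sample)
        if call is not None and call.is_called and call.carries(1):
            by_key[rec.key] = call
    rows = []
    for _, row in kb.iterrows():
        level = str(row["level"])
        if level not in rank:
            warnings.warn(f"unknown evidence level {level!r}; row skipped")
            continue
        if rank[level] > cutoff:
            continue
        from .model import normalize_variant
        key = normalize_variant(str(row["chrom"]), int(row["pos"]),
                                str(row["ref"]), str(row["alt"]))
        call = by_key.get(key)
        if call is None:
            continue
        zygosity = "hom" if call.is_hom_alt else "het"
        rows.append({"chrom": key[0], "pos": key[1], "ref": key[2],
                     "alt": key[3], "drug": row["drug"], "level": level,
                     "zygosity": zygosity,
                     "annotation": row.get("annotation", "")})
    cols = ["chrom", "pos", "ref", "alt", "drug", "level", "zygosity",
            "annotation"]
    return pd.DataFrame(rows, columns=cols)
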