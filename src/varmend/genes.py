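"""Minimal transcript/gene model with enough structure for effect
classification: exon intervals, CDS intervals with frame, strand, and the
underlying (toy) genome sequence for codon lookups."""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from Bio.Seq import Seq
from intervaltree import IntervalTree


@dataclass(frozen=True)
class Transcript:
    gene: str
    tx_id: str
    chrom: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]       # 0-based half-open, sorted
    cds: tuple[tuple[int, int], ...] = ()    # subset of exon space

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        for s, e in self.exons + self.cds:
            if e <= s:
                raise ValueError("empty exon/CDS interval")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def splice_dinucleotide_positions(self) -> set[int]:
        """The 2 intronic bases flanking each internal exon edge (0-based)."""
        pos: set[int] = set()
        for i, (s, e) in enumerate(self.exons):
            if i > 0:  # acceptor side of this exon
                pos.update((s - 2, s - 1))
            if i < len(self.exons) - 1:  # donor side
                pos.update((e, e + 1))
        return pos

    def cds_positions(self) -> list[int]:
        """Genomic positions of coding bases in translation order."""
        flat = [p for s, e in self.cds for p in range(s, e)]
        return flat[::-1] if self.strand == "-" else flat


@dataclass
class GeneModel:
    """Transcripts over a genome given as plain chrom -> sequence dict."""

    genome: dict[str, str]
    transcripts: list[Transcript] = field(default_factory=list)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        for tx in self.transcripts:
            self._index(tx)

    def _index(self, tx: Transcript) -> None:
        s, e = tx.span
        self._trees.setdefault(tx.chrom, IntervalTree()).addi(s, e, tx)

    def add(self, tx: Transcript) -> None:
        self.transcripts.append(tx)
        self._index(tx)

    def transcripts_at(self, chrom: str, start0: int, end0: int) -> list[Transcript]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [h.data for h in tree.overlap(start0, max(end0, start0 + 1))]
        return sorted(hits, key=lambda t: t.tx_id)

    def base(self, chrom: str, pos0: int) -> str:
        return self.genome[chrom][pos0]

    def codon_change(self, tx: Transcript, pos0: int, alt_base: str
                     ) -> Optional[tuple[str, str]]:
        """(ref_aa, alt_aa) for a SNV at coding position ``pos0``, or None
        when the site is not coding in this transcript."""
        cds_pos = tx.cds_positions()
        try:
            i = cds_pos.index(pos0)
        except ValueError:
            return None
        codon_idx = i // 3
        codon_sites = cds_pos[codon_idx * 3: codon_idx * 3 + 3]
        if len(codon_sites) < 3:
            return None  # trailing partial codon in a toy model
        ref_bases = [self.genome[tx.chrom][p] for p in codon_sites]
        alt_bases = list(ref_bases)
        alt_bases[codon_sites.index(pos0)] = alt_base
        if tx.strand == "-":
            ref_codon = str(Seq("".join(ref_bases)).complement())
            alt_codon = str(Seq("".join(alt_bases)).complement())
        else:
            ref_codon = "".join(ref_bases)
            alt_codon = "".join(alt_bases)
        ref_aa = str(Seq(ref_codon).translate())
        alt_aa = str(Seq(alt_codon).translate())
        return ref_aa, alt_aa
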