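"""Readers and writers for VCF, BED intervals, gene lists, and the
per-site clinical genotyping report.

VCF access goes through pysam; records come out as
:class:`~varmend.model.VariantRecord` with multiallelics split and indel
keys trimmed, so every downstream module sees biallelic, normalized
variants.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

import pandas as pd
import pysam

from .model import (
    ABSENT,
    CallStatus,
    ConfidenceThresholds,
    GenotypeCall,
    Interval,
    IntervalSet,
    VariantRecord,
    harmonize_chrom,
    split_multiallelic,
)

REGION_FILTER_LABELS = ("COMPRESSION", "MIA_RICH")


def _call_from_pysam(sample_rec, thresholds: ConfidenceThresholds) -> GenotypeCall:
    gt = sample_rec.get("GT")
    depth = sample_rec.get("DP")
    gq = sample_rec.get("GQ")
    if gt is None or any(a is None for a in gt) or len(gt) != 2:
        return GenotypeCall(None, depth=depth, status=CallStatus.NO_CALL)
    return GenotypeCall.of(gt[0], gt[1], depth=depth,
                           quality=None if gq is None else float(gq),
                           phased=sample_rec.phased, thresholds=thresholds)


def read_vcf(
    path: str | Path,
    sample_ids: Optional[Sequence[str]] = None,
    thresholds: ConfidenceThresholds = ConfidenceThresholds(),
    split: bool = True,
    chrom_prefix_strip: str = "chr",
) -> Iterator[VariantRecord]:
    """Stream VariantRecords from a VCF in coordinate order.

    Multiallelic rows are split into biallelic records (allele indices
    remapped); symbolic alts other than <DEL> are dropped with a warning;
    <DEL> alleles are skipped here (collect them with
    :func:`read_deletion_intervals`). A missing requested sample is fatal;
    a malformed genotype demotes that call to NO_CALL with a warning.
    """
    with pysam.VariantFile(str(path)) as vf:
        header_samples = list(vf.header.samples)
        if sample_ids is None:
            sample_ids = header_samples
        for s in sample_ids:
            if s not in header_samples:
                raise ValueError(f"sample {s!r} not present in {path}")
        for rec in vf:
            alts = rec.alts or ()
            seq_alts = []
            for a in alts:
                if a is None or a.startswith("<"):
                    if a not in (None, "<DEL>"):
                        warnings.warn(
                            f"symbolic alt {a} at {rec.chrom}:{rec.pos} ignored")
                    continue
                seq_alts.append(a)
            if not seq_alts:
                continue
            genotypes = {}
            for s in sample_ids:
                try:
                    genotypes[s] = _call_from_pysam(rec.samples[s], thresholds)
                except (ValueError, KeyError) as exc:  # malformed per-sample field
                    warnings.warn(
                        f"malformed genotype for {s} at {rec.chrom}:{rec.pos}: {exc}")
                    genotypes[s] = GenotypeCall.no_call()
            filters = tuple(rec.filter.keys())
            record = VariantRecord(
                chrom=harmonize_chrom(rec.chrom, chrom_prefix_strip),
                pos=rec.pos,
                ref=rec.ref,
                alt=tuple(seq_alts),
                ids=tuple(rec.id.split(";")) if rec.id else (),
                filters=filters,
                genotypes=genotypes,
            )
            if split:
                yield from split_multiallelic(record)
            else:
                yield record


def read_deletion_intervals(path: str | Path,
                            chrom_prefix_strip: str = "chr") -> IntervalSet:
    """Collect deletion spans from <DEL> records (using INFO/END when
    present) for the hemizygosity detector."""
    out = IntervalSet()
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for a in rec.alts or ():
                if a == "<DEL>":
                    end = rec.stop  # pysam: INFO/END if set, else ref span
                    out.add(Interval(harmonize_chrom(rec.chrom, chrom_prefix_strip),
                                     rec.start, end, "DEL"))
    return out


_FILTER_DESCRIPTIONS = {
    "COMPRESSION": "Site lies in a reference-compression segment called by the trio inheritance HMM",
    "MIA_RICH": "Site lies in a Mendelian-inheritance-abnormality-rich segment called by the trio inheritance HMM",
}


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | Path,
    samples: Sequence[str],
    contigs: Optional[dict[str, int]] = None,
    filter_labels: Sequence[str] = REGION_FILTER_LABELS,
) -> None:
    """Write coordinate-sorted biallelic records to a plain-text VCF.

    FILTER header lines are declared for ``filter_labels`` (region labels
    appended by the HMM stage) plus any label seen on the records, so the
    output round-trips through any compliant parser. Unsorted input is
    fatal.
    """
    records = list(records)
    header = pysam.VariantHeader()
    header.add_meta("source", "varmend")
    seen_contigs: dict[str, int] = dict(contigs or {})
    seen_filters: set[str] = set(filter_labels)
    for r in records:
        seen_contigs.setdefault(r.chrom, 0)
        seen_contigs[r.chrom] = max(seen_contigs[r.chrom], r.end + 1000)
        seen_filters.update(r.filters)
    for chrom, length in seen_contigs.items():
        header.contigs.add(chrom, length=length)
    for lab in sorted(seen_filters):
        if lab == "PASS":
            continue
        desc = _FILTER_DESCRIPTIONS.get(lab, "Filter label")
        header.filters.add(lab, None, None, desc)
    header.formats.add("GT", 1, "String", "Genotype")
    header.formats.add("DP", 1, "Integer", "Read depth")
    header.formats.add("GQ", 1, "Integer", "Genotype quality")
    for s in samples:
        header.add_sample(s)

    last: tuple[str, int] | None = None
    order = {c: i for i, c in enumerate(seen_contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for r in records:
            here = (r.chrom, r.pos)
            if last is not None and order[last[0]] == order[here[0]] and last[1] > here[1]:
                raise ValueError(f"records not coordinate-sorted at {r.chrom}:{r.pos}")
            last = here
            rec = out.new_record(contig=r.chrom, start=r.pos - 1,
                                 alleles=(r.ref, *r.alt))
            if r.ids:
                rec.id = ";".join(r.ids)
            for lab in (r.filters or ("PASS",)):
                rec.filter.add(lab)
            for s in samples:
                call = r.genotypes.get(s, GenotypeCall.no_call())
                rec.samples[s]["GT"] = call.allele_indices or (None, None)
                rec.samples[s].phased = call.phased
                if call.depth is not None:
                    rec.samples[s]["DP"] = call.depth
                if call.quality is not None:
                    rec.samples[s]["GQ"] = int(round(call.quality))
            out.write(rec)


def clinical_site_report(
    records: Iterable[VariantRecord],
    intervals: IntervalSet,
    sample: Optional[str] = None,
    depth_threshold: int = 10,
) -> pd.DataFrame:
    """Account for every queried clinical locus, present in the VCF or not.

    For each position inside each interval the status is one of
    HOM_REF_CALLED / VARIANT_CALLED / NO_CALL / LOW_COVERAGE, so a locus
    where the disease allele is absent is distinguishable from one that
    was simply under-sequenced. Reference-call (0/0) records count as
    evidence of absence when confidently covered.
    """
    by_pos: dict[tuple[str, int], VariantRecord] = {}
    for r in records:
        for off in range(len(r.ref)):
            by_pos.setdefault((r.chrom, r.pos + off), r)
    rows = []
    for iv in intervals:
        for pos0 in range(iv.start, iv.end):
            pos = pos0 + 1
            rec = by_pos.get((iv.chrom, pos))
            status = "NO_CALL"
            depth: object = pd.NA
            if rec is not None:
                s = sample or next(iter(rec.genotypes), None)
                call = rec.genotypes.get(s) if s else None
                if call is not None and call.depth is not None:
                    depth = call.depth
                if call is None or call.status is CallStatus.NO_CALL:
                    status = "NO_CALL"
                elif call.depth is not None and call.depth < depth_threshold:
                    status = "LOW_COVERAGE"
                elif call.is_hom_ref:
                    status = "HOM_REF_CALLED"
                else:
                    status = "VARIANT_CALLED"
            rows.append({"chrom": iv.chrom, "pos": pos, "label": iv.label,
                         "status": status, "depth": depth})
    return pd.DataFrame(rows, columns=["chrom", "pos", "label", "status", "depth"])


def read_bed(path: str | Path, chrom_prefix_strip: str = "chr") -> IntervalSet:
    """BED is 0-based half-open; column 4 (if present) is the label."""
    out = IntervalSet()
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            chrom = harmonize_chrom(parts[0], chrom_prefix_strip)
            label = parts[3] if len(parts) > 3 else ""
            out.add(Interval(chrom, int(parts[1]), int(parts[2]), label))
    return out


def write_bed(intervals: Iterable[Interval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label}\n")


def read_gene_list(path: str | Path) -> set[str]:
    """One gene symbol per line; blank lines and '#' comments ignored."""
    genes = set()
    with open(path) as fh:
        for line in fh:
            sym = line.strip()
            if sym and not sym.startswith("#"):
                genes.add(sym)
    return genes
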