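"""High-level runs the CLI wraps: trio discovery and single-genome
prioritization. Parallelism is per chromosome with a deterministic,
order-fixed merge, so output is invariant to the worker count."""
from __future__ import annotations

import multiprocessing as mp
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .annotate import AnnotatedVariant, annotate_stream
from .candidates import CandidateSet, discover_candidates
from .genes import GeneModel
from .model import IntervalSet
from .prioritize import prioritize_variants
from .simulate import gene_model_from_intervals, toy_gene_model
from .tables import AnnotationDB
from .triohmm import (
    HmmParams,
    InheritanceSegment,
    TrioObservation,
    apply_region_filters,
    observe_trio,
    viterbi_decode,
)
from .vcfio import read_bed, read_gene_list, read_vcf, write_bed, write_vcf


def _decode_one(args) -> list[InheritanceSegment]:
    chrom, obs_data, params = args
    obs = [TrioObservation(p, s) for p, s in obs_data]
    _, segs = viterbi_decode(obs, params, chrom=chrom)
    return segs


def decode_segments(tracks: dict[str, list[TrioObservation]],
                    params: HmmParams,
                    threads: int = 1) -> list[InheritanceSegment]:
    """Viterbi-decode every chromosome; chromosomes are independent, so
    they can go to a worker pool, and the merge follows sorted chromosome
    order regardless of completion order."""
    jobs = [(chrom, [(o.position, o.symbol) for o in tracks[chrom]], params)
            for chrom in sorted(tracks)]
    if threads > 1 and len(jobs) > 1:
        with mp.get_context("spawn").Pool(min(threads, len(jobs))) as pool:
            per_chrom = pool.map(_decode_one, jobs)
    else:
        per_chrom = [_decode_one(j) for j in jobs]
    return [seg for segs in per_chrom for seg in segs]


@dataclass
class TrioRunResult:
    segments: list[InheritanceSegment]
    candidates: CandidateSet
    annotated: list[AnnotatedVariant]
    paths: dict[str, Path]
    counts: dict[str, int]


def _candidates_frames(cands: CandidateSet) -> dict[str, pd.DataFrame]:
    key_cols = ["chrom", "pos", "ref", "alt"]

    def keys_df(keys):
        return pd.DataFrame([dict(zip(key_cols, k)) for k in keys],
                            columns=key_cols)

    ch = pd.DataFrame(
        [{"gene": p.gene,
          **{f"{c}_1": v for c, v in zip(key_cols, p.first)},
          **{f"{c}_2": v for c, v in zip(key_cols, p.second)},
          "phase": p.phase.value}
         for p in cands.compound_het],
        columns=["gene"] + [f"{c}_1" for c in key_cols]
        + [f"{c}_2" for c in key_cols] + ["phase"])
    hemi = pd.DataFrame(
        [{**dict(zip(key_cols, k)),
          "del_chrom": iv.chrom, "del_start": iv.start, "del_end": iv.end}
         for k, iv in cands.hemizygous],
        columns=key_cols + ["del_chrom", "del_start", "del_end"])
    return {
        "de_novo": keys_df(cands.de_novo),
        "compound_het": ch,
        "rare_homozygous": keys_df(cands.rare_homozygous),
        "hemizygous": hemi,
        "ad_reduced_penetrance": keys_df(cands.ad_reduced_penetrance),
    }


def run_trio(vcf: str | Path, father: str, mother: str, child: str,
             out_dir: str | Path,
             freq_tsv: Optional[str | Path] = None,
             genes_bed: Optional[str | Path] = None,
             deletions_bed: Optional[str | Path] = None,
             disease_genes_path: Optional[str | Path] = None,
             params: Optional[HmmParams] = None,
             maf_threshold: float = 0.01,
             child_sex: Optional[str] = None,
             threads: int = 1) -> TrioRunResult:
    """annotate -> inheritance HMM -> soft region filters -> five
    candidate modes; writes labeled VCF, segments BED and one TSV per
    candidate mode into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = params or HmmParams()
    records = list(read_vcf(vcf, [father, mother, child]))
    db = AnnotationDB.from_paths(freq_tsv=freq_tsv)
    if genes_bed is not None:
        model = gene_model_from_intervals(read_bed(genes_bed))
    else:
        model = GeneModel(genome={})
    annotated = list(annotate_stream(records, db, model))
    tracks = observe_trio(records, father, mother, child, child_sex=child_sex)
    segments = decode_segments(tracks, params, threads=threads)
    labeled = apply_region_filters(records, segments)
    deletions = read_bed(deletions_bed) if deletions_bed else IntervalSet()
    disease = read_gene_list(disease_genes_path) if disease_genes_path else set()
    cands = discover_candidates(annotated, segments, father, mother, child,
                                deletions=deletions, disease_genes=disease,
                                maf_threshold=maf_threshold)
    paths: dict[str, Path] = {
        "labeled_vcf": out / "labeled.vcf",
        "segments_bed": out / "segments.bed",
    }
    write_vcf(labeled, paths["labeled_vcf"], samples=[father, mother, child])
    write_bed((s.as_interval() for s in segments), paths["segments_bed"])
    for mode, df in _candidates_frames(cands).items():
        p = out / f"candidates_{mode}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[mode] = p
    counts = {
        "records": len(records),
        "observations": sum(len(v) for v in tracks.values()),
        "segments": len(segments),
        "de_novo": len(cands.de_novo),
        "compound_het": len(cands.compound_het),
        "rare_homozygous": len(cands.rare_homozygous),
        "hemizygous": len(cands.hemizygous),
        "ad_reduced_penetrance": len(cands.ad_reduced_penetrance),
    }
    return TrioRunResult(segments, cands, annotated, paths, counts)


def run_prioritize(vcf: str | Path,
                   freq_tsv: Optional[str | Path] = None,
                   scores_tsv: Optional[str | Path] = None,
                   reported_tsv: Optional[str | Path] = None,
                   genes_tsv: Optional[str | Path] = None,
                   local_tsv: Optional[str | Path] = None,
                   gene_model: Optional[GeneModel] = None,
                   gene_list: Optional[str | Path] = None,
                   sample_sex: Optional[str] = None,
                   maf_threshold: float = 0.01,
                   local_af_cutoff: float = 0.25,
                   out_tsv: Optional[str | Path] = None) -> pd.DataFrame:
    """Single-genome prioritization -> retained tier 1-3 table.

    With no gene model supplied, the bundled toy genome/gene fixture is
    used (real deployments pass their own transcript model).
    """
    records = list(read_vcf(vcf))
    db = AnnotationDB.from_paths(freq_tsv=freq_tsv, scores_tsv=scores_tsv,
                                 reported_tsv=reported_tsv,
                                 genes_tsv=genes_tsv, local_tsv=local_tsv)
    model = gene_model or toy_gene_model()
    annotated = annotate_stream(records, db, model)
    genes = read_gene_list(gene_list) if gene_list else None
    table = prioritize_variants(annotated, maf_threshold=maf_threshold,
                                local_af_cutoff=local_af_cutoff,
                                gene_set=genes, sample_sex=sample_sex)
    if out_tsv is not None:
        table.to_csv(out_tsv, sep="\t", index=False)
    return table
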