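"""Tabular annotation databases: population frequencies, conservation and
pathogenicity scores, the reported-disease catalog, the monogenic-gene
catalog, and an optional local-cohort site-frequency table.

All variant-keyed tables are exact-matched on normalized
(chrom, pos, ref, alt) keys; a miss yields ABSENT, never zero.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .model import ABSENT, normalize_variant

# Population surveys the rarity filter consults: ethnically-matched HapMap,
# matched 1000 Genomes super-population and global phase-1 frequencies, the
# 1000 Genomes pilot, Complete Genomics 69, ESP global, and ExAC.
FREQUENCY_SOURCES = (
    "hapmap_matched",
    "kg_superpop_matched",
    "kg_global",
    "kg_pilot_global",
    "cg69",
    "esp_global",
    "exac",
)

SCORE_COLUMNS = ("gerp", "phylop", "sift", "lrt", "polyphen2", "mutation_taster")

VariantKey = tuple[str, int, str, str]


def _norm_key(chrom, pos, ref, alt) -> VariantKey:
    return normalize_variant(str(chrom), int(pos), str(ref), str(alt))


def _keyed(df: pd.DataFrame) -> pd.DataFrame:
    df = df.copy()
    df["key"] = [
        _norm_key(c, p, r, a)
        for c, p, r, a in zip(df["chrom"], df["pos"], df["ref"], df["alt"])
    ]
    return df


@dataclass
class AnnotationDB:
    """In-memory join tables backed by plain TSV files."""

    frequencies: dict[VariantKey, dict[str, float]] = field(default_factory=dict)
    score_table: dict[VariantKey, dict[str, object]] = field(default_factory=dict)
    reported_catalog: dict[VariantKey, str] = field(default_factory=dict)
    monogenic_genes: set[str] = field(default_factory=set)
    local_cohort: dict[VariantKey, float] = field(default_factory=dict)

    # -- loaders ---------------------------------------------------------
    @classmethod
    def from_frames(cls, freq: Optional[pd.DataFrame] = None,
                    scores: Optional[pd.DataFrame] = None,
                    reported: Optional[pd.DataFrame] = None,
                    genes: Optional[pd.DataFrame] = None,
                    local: Optional[pd.DataFrame] = None) -> "AnnotationDB":
        db = cls()
        if freq is not None and len(freq):
            for _, row in _keyed(freq).iterrows():
                src = str(row["source"])
                if src not in FREQUENCY_SOURCES:
                    raise ValueError(f"unknown frequency source {src!r}")
                db.frequencies.setdefault(row["key"], {})[src] = float(row["maf"])
        if scores is not None and len(scores):
            for _, row in _keyed(scores).iterrows():
                entry: dict[str, object] = {}
                for col in SCORE_COLUMNS:
                    v = row.get(col)
                    if v is None or (isinstance(v, float) and pd.isna(v)) or v == ".":
                        continue
                    entry[col] = float(v) if col in ("gerp", "phylop") else str(v)
                db.score_table[row["key"]] = entry
        if reported is not None and len(reported):
            for _, row in _keyed(reported).iterrows():
                db.reported_catalog[row["key"]] = str(row.get("reported_effect", ""))
        if genes is not None and len(genes):
            for _, row in genes.iterrows():
                if bool(int(row.get("monogenic_flag", 1))):
                    db.monogenic_genes.add(str(row["gene"]))
        if local is not None and len(local):
            for _, row in _keyed(local).iterrows():
                db.local_cohort[row["key"]] = float(row["af"])
        return db

    @classmethod
    def from_paths(cls, freq_tsv: Optional[str | Path] = None,
                   scores_tsv: Optional[str | Path] = None,
                   reported_tsv: Optional[str | Path] = None,
                   genes_tsv: Optional[str | Path] = None,
                   local_tsv: Optional[str | Path] = None) -> "AnnotationDB":
        def load(p):
            return pd.read_csv(p, sep="\t", dtype={"chrom": str}) if p else None

        return cls.from_frames(load(freq_tsv), load(scores_tsv),
                               load(reported_tsv), load(genes_tsv),
                               load(local_tsv))

    # -- lookups (exact on normalized keys) ------------------------------
    def frequency_map(self, key: VariantKey) -> dict[str, object]:
        found = self.frequencies.get(key, {})
        return {src: found.get(src, ABSENT) for src in FREQUENCY_SOURCES}

    def scores(self, key: VariantKey) -> dict[str, object]:
        return dict(self.score_table.get(key, {}))

    def is_reported(self, key: VariantKey) -> bool:
        return key in self.reported_catalog

    def is_monogenic_gene(self, gene: str) -> bool:
        return gene in self.monogenic_genes

    def local_af(self, key: VariantKey):
        return self.local_cohort.get(key, ABSENT)
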