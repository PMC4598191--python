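"""Three-state HMM over trio genotype observations.

Each biallelic site where father, mother and child are all confidently
called is encoded as one of three symbols: CONSISTENT (some transmission
of one allele per parent yields the child), MIA (no transmission does —
a Mendelian inheritance abnormality), or ALLHET (all three members
heterozygous, the signature of reference-compression artifact; takes
precedence over CONSISTENT but not MIA).

Hidden states are GOOD (clean data), COMPRESSION (reference collapsed
relative to repeats, excess universal heterozygosity) and MIA_RICH
(systematic-artifact regions dense in inheritance errors). Transitions
are scaled by the chromosomal distance between adjacent markers: the
probability of staying in state s across a gap of d bp is exp(-d / L_s)
with L_s the state's expected tract length, and the leave mass is split
between the other two states in proportion to their stationary weights.
This makes the decoder usable on exome data, where inter-marker gaps are
wildly uneven. Decoding is by Viterbi in log space, with ties broken
toward GOOD so filtering stays conservative.
"""
from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import yaml

from .model import GenotypeCall, Interval, IntervalSet, VariantRecord


class State(enum.IntEnum):
    GOOD = 0
    COMPRESSION = 1
    MIA_RICH = 2


class Symbol(enum.IntEnum):
    CONSISTENT = 0
    MIA = 1
    ALLHET = 2


@dataclass(frozen=True)
class TrioObservation:
    position: int  # 1-based
    symbol: Symbol
    key: Optional[tuple] = None


@dataclass
class HmmParams:
    """Emission rows are per-state distributions over
    (CONSISTENT, MIA, ALLHET); tract lengths are in bp.

    Defaults encode: good data emits MIA at roughly the sequencing-error
    rate and stray heterozygosity at ~1%; compression tracts are short
    and dominated by universal heterozygosity; MIA-rich tracts are short
    and dense in inheritance errors. Stationary weights put 98% of the
    genome in GOOD.
    """

    emissions: np.ndarray = field(default_factory=lambda: np.array([
        [0.989, 0.001, 0.010],   # GOOD
        [0.400, 0.100, 0.500],   # COMPRESSION
        [0.550, 0.400, 0.050],   # MIA_RICH
    ]))
    tract_lengths: np.ndarray = field(
        default_factory=lambda: np.array([10e6, 100e3, 100e3]))
    pi: np.ndarray = field(default_factory=lambda: np.array([0.98, 0.01, 0.01]))

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.tract_lengths = np.asarray(self.tract_lengths, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.emissions.shape != (3, 3):
            raise ValueError("emissions must be 3x3")
        if np.any(self.emissions <= 0) or np.any(self.emissions >= 1):
            raise ValueError("emission probabilities must lie in (0,1)")
        if not np.allclose(self.emissions.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("emission rows must sum to 1")
        if np.any(self.tract_lengths <= 0):
            raise ValueError("tract lengths must be positive")
        if not np.isclose(self.pi.sum(), 1.0) or np.any(self.pi <= 0):
            raise ValueError("pi must be a positive distribution")

    @classmethod
    def from_yaml(cls, path) -> "HmmParams":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        kwargs = {}
        if "emissions" in cfg:
            kwargs["emissions"] = np.array(cfg["emissions"], dtype=float)
        if "tract_lengths" in cfg:
            kwargs["tract_lengths"] = np.array(cfg["tract_lengths"], dtype=float)
        if "pi" in cfg:
            kwargs["pi"] = np.array(cfg["pi"], dtype=float)
        return cls(**kwargs)


@dataclass(frozen=True)
class InheritanceSegment:
    chrom: str
    start: int  # 0-based half-open
    end: int
    state: State
    n_sites: int

    def as_interval(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.state.name)


def mendelian_consistent(father: GenotypeCall, mother: GenotypeCall,
                         child: GenotypeCall) -> bool:
    """True if some choice of one allele from each parent reproduces the
    child's (unordered) genotype."""
    ca, cb = child.alleles
    for fa in father.alleles:
        for ma in mother.alleles:
            if (fa, ma) == (ca, cb) or (fa, ma) == (cb, ca):
                return True
    return False


def encode_observation(father: GenotypeCall, mother: GenotypeCall,
                       child: GenotypeCall) -> Optional[Symbol]:
    """Symbol for one site, or None if any member is not confidently
    called. Precedence: MIA > ALLHET > CONSISTENT."""
    if not (father.is_called and mother.is_called and child.is_called):
        return None
    if not mendelian_consistent(father, mother, child):
        return Symbol.MIA
    if father.is_het and mother.is_het and child.is_het:
        return Symbol.ALLHET
    return Symbol.CONSISTENT


def observe_trio(records: Iterable[VariantRecord], father: str, mother: str,
                 child: str, snvs_only: bool = True,
                 child_sex: Optional[str] = None,
                 sex_chroms: Sequence[str] = ("X", "Y", "chrX", "chrY"),
                 ) -> dict[str, list[TrioObservation]]:
    """Build per-chromosome observation tracks from trio records.

    Only biallelic sites with all three samples CALLED contribute.
    For a male child, X/Y sites are excluded (hemizygous call conventions
    vary by caller); for a female child X is treated as autosomal and Y
    is skipped.
    """
    tracks: dict[str, list[TrioObservation]] = {}
    for rec in records:
        if not rec.is_biallelic:
            continue
        if snvs_only and not rec.is_snv:
            continue
        if rec.chrom in sex_chroms:
            if child_sex == "male":
                continue
            if rec.chrom in ("Y", "chrY"):
                continue
        try:
            f, m, c = (rec.genotypes[s] for s in (father, mother, child))
        except KeyError as exc:
            raise ValueError(f"sample {exc} missing from record") from exc
        sym = encode_observation(f, m, c)
        if sym is None:
            continue
        tracks.setdefault(rec.chrom, []).append(
            TrioObservation(rec.pos, sym, rec.key))
    for obs in tracks.values():
        obs.sort(key=lambda o: o.position)
    return tracks


def transition_matrix(distance_bp: float, params: HmmParams) -> np.ndarray:
    """Distance-scaled 3x3 transition matrix.

    stay(s) = exp(-d / L_s); the leave mass goes to the other two states
    in proportion to their stationary weights. d = 0 gives the identity;
    d -> inf sends row s to the renormalized stationary weights of the
    other states.
    """
    if distance_bp < 0:
        raise ValueError("distance must be non-negative")
    stay = np.exp(-distance_bp / params.tract_lengths)
    mat = np.empty((3, 3))
    for s in range(3):
        others = [t for t in range(3) if t != s]
        w = params.pi[others]
        w = w / w.sum()
        mat[s, s] = stay[s]
        for t, wt in zip(others, w):
            mat[s, t] = (1.0 - stay[s]) * wt
    return mat


def viterbi_path(observations: Sequence[TrioObservation],
                 params: HmmParams) -> np.ndarray:
    """Most probable joint state path (log-space Viterbi).

    Ties break toward GOOD then the lower state index (first argmax).
    """
    n = len(observations)
    if n == 0:
        return np.empty(0, dtype=int)
    log_e = np.log(params.emissions)
    log_pi = np.log(params.pi)
    syms = np.array([int(o.symbol) for o in observations])
    pos = np.array([o.position for o in observations])
    delta = log_pi + log_e[:, syms[0]]
    back = np.zeros((n, 3), dtype=int)
    for t in range(1, n):
        log_a = np.log(transition_matrix(pos[t] - pos[t - 1], params))
        scores = delta[:, None] + log_a  # [from, to]
        back[t] = np.argmax(scores, axis=0)
        delta = scores[back[t], np.arange(3)] + log_e[:, syms[t]]
    path = np.empty(n, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


def path_to_segments(chrom: str, observations: Sequence[TrioObservation],
                     path: np.ndarray) -> list[InheritanceSegment]:
    """Collapse a per-site path into maximal segments.

    Boundaries between adjacent runs fall at the midpoint between the
    flanking observed sites; chromosome ends extend only to the first and
    last observation.
    """
    if len(observations) == 0:
        return []
    pos = [o.position for o in observations]
    segs: list[InheritanceSegment] = []
    run_start = 0
    for i in range(1, len(path) + 1):
        if i == len(path) or path[i] != path[run_start]:
            start0 = (pos[run_start] - 1 if run_start == 0
                      else (pos[run_start - 1] + pos[run_start]) // 2)
            end0 = pos[i - 1] if i == len(path) else (pos[i - 1] + pos[i]) // 2
            segs.append(InheritanceSegment(chrom, start0, end0,
                                           State(int(path[run_start])),
                                           n_sites=i - run_start))
            run_start = i
    return segs


def viterbi_decode(observations: Sequence[TrioObservation], params: HmmParams,
                   chrom: str = "") -> tuple[np.ndarray, list[InheritanceSegment]]:
    path = viterbi_path(observations, params)
    return path, path_to_segments(chrom, observations, path)


def segment_trio(tracks: dict[str, list[TrioObservation]],
                 params: Optional[HmmParams] = None) -> list[InheritanceSegment]:
    """Decode every chromosome track; chromosomes sort lexicographically
    in the output (decoding is per-chromosome, so order is cosmetic)."""
    params = params or HmmParams()
    segments: list[InheritanceSegment] = []
    for chrom in sorted(tracks):
        _, segs = viterbi_decode(tracks[chrom], params, chrom=chrom)
        segments.extend(segs)
    return segments


def segments_to_intervalset(segments: Iterable[InheritanceSegment],
                            states: Optional[set[State]] = None) -> IntervalSet:
    ivs = IntervalSet()
    for seg in segments:
        if states is None or seg.state in states:
            ivs.add(seg.as_interval())
    return ivs


def apply_region_filters(records: Iterable[VariantRecord],
                         segments: Iterable[InheritanceSegment]
                         ) -> list[VariantRecord]:
    """Append COMPRESSION / MIA_RICH labels to the FILTER field of records
    inside flagged segments (soft filtering: nothing is dropped)."""
    flagged = segments_to_intervalset(
        segments, states={State.COMPRESSION, State.MIA_RICH})
    out = []
    for rec in records:
        labels = [iv.label for iv in flagged.at(rec.chrom, rec.pos - 1)]
        if labels:
            new = tuple(dict.fromkeys(
                [f for f in rec.filters if f != "PASS"] + labels))
            rec = VariantRecord(rec.chrom, rec.pos, rec.ref, rec.alt,
                                ids=rec.ids, filters=new,
                                genotypes=rec.genotypes)
        out.append(rec)
    return out
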