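"""Read assignment, RPKM matrices, isoform junction counts, time-course.

Reads are assigned to edited-reference features by exact k-mer seeding:
the candidate set of a pair is the intersection of the feature sets of
every indexed k-mer found in either mate.  This is a deterministic,
self-contained substitute for an external aligner; it does not reproduce
soft-clipping behaviour and is documented as such.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reference import EditedReference, JunctionContig

logger = logging.getLogger(__name__)

DEFAULT_KMER = 21

UNIQUE_ONLY = "unique_only"
FRACTIONAL = "fractional"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    """Strand-canonical form: the lexicographic min of a k-mer and its
    reverse complement.  Mate 2 of a pair is sequenced on the opposite
    strand, so the index and all lookups use canonical k-mers."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


@dataclass(frozen=True)
class ReadPair:
    """One paired-end fragment; ``truth`` is the simulator's source label."""

    read1: str
    read2: str
    pair_id: str
    truth: str | None = None

    def __post_init__(self) -> None:
        if not self.read1 or not self.read2:
            raise ValueError(f"pair {self.pair_id!r}: both mates must be non-empty")


@dataclass
class ReadSet:
    """A collection of read pairs, optionally with per-pair truth labels."""

    pairs: list[ReadPair] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self):
        return iter(self.pairs)

    def sequences(self) -> list[str]:
        """Flatten to single-end sequences (mate 1 then mate 2 per pair)."""
        out = []
        for p in self.pairs:
            out.append(p.read1)
            out.append(p.read2)
        return out

    def truth_counts(self) -> Counter:
        """Count pairs per truth label (simulator-produced sets only)."""
        return Counter(p.truth for p in self.pairs if p.truth is not None)


@dataclass(frozen=True)
class SampleMeta:
    """Metadata of one sequencing library."""

    sample_id: str
    shrna: str = "none"  # one of sh2 / sh3 / NT / none
    dox: bool = False
    timepoint_h: float = 0.0

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "shrna": self.shrna,
            "dox": self.dox,
            "timepoint_h": self.timepoint_h,
        }


# ---------------------------------------------------------------------------
# k-mer index and assignment

class KmerIndex:
    """Exact k-mer -> feature-id-set index over counting features."""

    def __init__(self, k: int, kmer_to_features: dict[str, frozenset[str]]):
        self.k = k
        self._index = kmer_to_features

    def __len__(self) -> int:
        return len(self._index)

    def get(self, kmer: str) -> frozenset[str] | None:
        return self._index.get(kmer)

    def kmers(self):
        return self._index.keys()


def index_reference(ref: EditedReference, k_mer: int = DEFAULT_KMER) -> KmerIndex:
    """Build the k-mer index over half + background features.

    Junction-panel contigs are deliberately excluded: junction reads are
    visible only to the junction panel, mirroring the split-reference
    logic.  Features shorter than ``k_mer`` are skipped with a warning.
    """
    if not 15 <= k_mer <= 31:
        raise ValueError(f"k_mer must be in [15, 31], got {k_mer}")
    accum: dict[str, set[str]] = {}
    for fid, seq in ref.feature_sequences().items():
        if len(seq) < k_mer:
            logger.warning(
                "feature %s (length %d) shorter than k=%d; excluded from index",
                fid, len(seq), k_mer,
            )
            continue
        for i in range(len(seq) - k_mer + 1):
            accum.setdefault(canonical(seq[i : i + k_mer]), set()).add(fid)
    return KmerIndex(k_mer, {km: frozenset(v) for km, v in accum.items()})


@dataclass
class AssignmentResult:
    """Per-feature pair counts plus assignment accounting."""

    counts: dict[str, float]
    assigned_total: float
    unassigned: int
    policy: str

    def counts_series(self, feature_ids) -> pd.Series:
        return pd.Series(
            [self.counts.get(fid, 0.0) for fid in feature_ids],
            index=list(feature_ids),
            dtype=float,
        )


def _candidate_features(pair: ReadPair, index: KmerIndex) -> frozenset[str] | None:
    """Intersect feature sets over all indexed k-mers of both mates.

    k-mers absent from the index (junction- or error-spanning, N-bearing)
    are skipped; a pair with no indexed k-mer at all yields ``None``.
    """
    k = index.k
    cand: frozenset[str] | None = None
    for seq in (pair.read1, pair.read2):
        for i in range(len(seq) - k + 1):
            hit = index.get(canonical(seq[i : i + k]))
            if hit is None:
                continue
            cand = hit if cand is None else cand & hit
            if not cand:
                return frozenset()
    return cand


def assign_reads(
    reads: ReadSet, index: KmerIndex, policy: str = UNIQUE_ONLY
) -> AssignmentResult:
    """Assign read pairs to features by k-mer set intersection.

    ``unique_only`` counts a pair iff its candidate set is a singleton;
    ``fractional`` splits one count equally over the candidates.
    Unassignable pairs (empty or no candidate set, or ambiguous under
    ``unique_only``) are tallied, never fatal.
    """
    if policy not in (UNIQUE_ONLY, FRACTIONAL):
        raise ValueError(f"unknown policy {policy!r}")
    counts: dict[str, float] = {}
    assigned = 0.0
    unassigned = 0
    for pair in reads:
        cand = _candidate_features(pair, index)
        if not cand:
            unassigned += 1
            continue
        if policy == UNIQUE_ONLY:
            if len(cand) == 1:
                (fid,) = cand
                counts[fid] = counts.get(fid, 0.0) + 1.0
                assigned += 1
            else:
                unassigned += 1
        else:
            share = 1.0 / len(cand)
            for fid in cand:
                counts[fid] = counts.get(fid, 0.0) + share
            assigned += 1
    if unassigned:
        logger.info("%d of %d pairs unassigned", unassigned, len(reads))
    return AssignmentResult(counts, assigned, unassigned, policy)


# ---------------------------------------------------------------------------
# RPKM

def compute_rpkm(
    counts: np.ndarray, lengths: np.ndarray, assigned_totals: np.ndarray
) -> np.ndarray:
    """RPKM matrix: ``counts * 1e9 / (N_s * L_i)`` per cell.

    ``counts`` is features x samples; ``lengths`` per-feature nt lengths;
    ``assigned_totals`` per-sample assigned pair counts (the RPKM
    denominator is assigned, not raw, pairs — this makes the conservation
    identity sum_i rpkm*L = 1e9 exact).  A zero total yields an all-zero
    column with a warning.
    """
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    totals = np.asarray(assigned_totals, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be a 2-D features x samples array")
    if lengths.shape != (counts.shape[0],):
        raise ValueError(
            f"lengths shape {lengths.shape} does not match {counts.shape[0]} features"
        )
    if totals.shape != (counts.shape[1],):
        raise ValueError(
            f"assigned_totals shape {totals.shape} does not match "
            f"{counts.shape[1]} samples"
        )
    if np.any(lengths <= 0):
        raise ValueError("all feature lengths must be positive")
    if np.any(totals < 0):
        raise ValueError("assigned totals must be non-negative")
    zero = totals == 0
    if zero.any():
        logger.warning("%d sample(s) have zero assigned reads; RPKM set to 0", zero.sum())
    safe = np.where(zero, 1.0, totals)
    rpkm = counts * 1e9 / (safe[None, :] * lengths[:, None])
    rpkm[:, zero] = 0.0
    return rpkm


@dataclass
class ExpressionMatrix:
    """Feature x sample counts and RPKM with sample metadata."""

    feature_ids: list[str]
    lengths: np.ndarray
    samples: list[SampleMeta]
    counts: np.ndarray
    assigned_totals: np.ndarray
    rpkm: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        self.assigned_totals = np.asarray(self.assigned_totals, dtype=float)
        n_feat, n_samp = len(self.feature_ids), len(self.samples)
        if self.counts.shape != (n_feat, n_samp):
            raise ValueError(
                f"counts shape {self.counts.shape} != ({n_feat}, {n_samp})"
            )
        self.rpkm = compute_rpkm(self.counts, self.lengths, self.assigned_totals)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def rpkm_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rpkm, index=self.feature_ids, columns=self.sample_ids)

    def counts_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample {sample_id!r}") from None

    def feature_index(self, feature_id: str) -> int:
        try:
            return self.feature_ids.index(feature_id)
        except ValueError:
            raise KeyError(f"unknown feature {feature_id!r}") from None

    def select_samples(self, shrna=None, dox=None, timepoint_h=None) -> list[SampleMeta]:
        out = []
        for s in self.samples:
            if shrna is not None and s.shrna != shrna:
                continue
            if dox is not None and s.dox != dox:
                continue
            if timepoint_h is not None and s.timepoint_h != timepoint_h:
                continue
            out.append(s)
        return out

    @classmethod
    def from_assignments(
        cls, ref: EditedReference, assignments: dict[str, AssignmentResult], samples
    ) -> "ExpressionMatrix":
        """Assemble a matrix from per-sample :func:`assign_reads` results."""
        seqs = ref.feature_sequences()
        feature_ids = list(seqs)
        lengths = np.array([len(seqs[f]) for f in feature_ids], dtype=float)
        metas = list(samples)
        counts = np.zeros((len(feature_ids), len(metas)))
        totals = np.zeros(len(metas))
        for j, meta in enumerate(metas):
            res = assignments[meta.sample_id]
            counts[:, j] = res.counts_series(feature_ids).to_numpy()
            totals[j] = res.assigned_total
        return cls(feature_ids, lengths, metas, counts, totals)

    def to_tsv(self, counts_path, rpkm_path=None, meta_path=None) -> None:
        from .io import write_json, write_matrix_tsv

        write_matrix_tsv(counts_path, self.counts_frame())
        if rpkm_path is not None:
            write_matrix_tsv(rpkm_path, self.rpkm_frame())
        if meta_path is not None:
            write_json(
                meta_path,
                {
                    "samples": [s.to_dict() for s in self.samples],
                    "lengths": dict(zip(self.feature_ids, self.lengths)),
                    "assigned_totals": dict(
                        zip(self.sample_ids, self.assigned_totals)
                    ),
                },
            )

    @classmethod
    def from_tsv(cls, counts_path, meta_path) -> "ExpressionMatrix":
        from .io import read_json, read_matrix_tsv

        counts = read_matrix_tsv(counts_path)
        meta = read_json(meta_path)
        samples = [SampleMeta(**s) for s in meta["samples"]]
        lengths = np.array([meta["lengths"][f] for f in counts.index], dtype=float)
        totals = np.array(
            [meta["assigned_totals"][s.sample_id] for s in samples], dtype=float
        )
        counts = counts[[s.sample_id for s in samples]]
        return cls(list(counts.index), lengths, samples, counts.to_numpy(), totals)


# ---------------------------------------------------------------------------
# Isoform junction counting

@dataclass(frozen=True)
class IsoformCounts:
    plus_kts: int
    minus_kts: int
    unclassified_junction: int

    @property
    def total_classified(self) -> int:
        return self.plus_kts + self.minus_kts

    def plus_fraction(self) -> float | None:
        if self.total_classified == 0:
            return None
        return self.plus_kts / self.total_classified


def _wmers(seq: str, w: int) -> set[str]:
    """Strand-canonical w-mer set (mate 2 is on the opposite strand)."""
    return {canonical(seq[i : i + w]) for i in range(len(seq) - w + 1)}


def count_isoform_junctions(
    reads, junction_panel: list[JunctionContig], flank_w: int | None = None
) -> IsoformCounts:
    """Classify junction-overlapping reads into +KTS / -KTS / unclassified.

    A read is +KTS if it contains a ``w``-mer unique to the +KTS contig
    (w = ``flank_w``, default the panel's construction width), -KTS
    likewise; reads carrying only w-mers shared by both contigs (or
    conflicting evidence, possible with sequencing errors) stay
    unclassified.  The partition is disjoint by construction.

    ``reads`` may be a :class:`ReadSet` (pairs classified as a unit) or an
    iterable of sequences.
    """
    diag = [c for c in junction_panel if c.diagnostic]
    plus = [c for c in diag if c.junction_id.endswith("plusKTS")]
    minus = [c for c in diag if c.junction_id.endswith("minusKTS")]
    if len(plus) != 1 or len(minus) != 1:
        raise ValueError(
            "junction panel must contain exactly one diagnostic contig per "
            f"isoform; found {len(plus)} plusKTS and {len(minus)} minusKTS"
        )
    w = flank_w if flank_w is not None else min(30, len(minus[0].sequence))
    plus_all = _wmers(plus[0].sequence, w)
    minus_all = _wmers(minus[0].sequence, w)
    plus_unique = plus_all - minus_all
    minus_unique = minus_all - plus_all
    shared = plus_all & minus_all

    if isinstance(reads, ReadSet):
        units = [(p.read1, p.read2) for p in reads]
    else:
        units = [(seq,) for seq in reads]

    n_plus = n_minus = n_unclassified = 0
    for unit in units:
        wmers = set()
        for seq in unit:
            wmers |= _wmers(seq, w)
        has_plus = not wmers.isdisjoint(plus_unique)
        has_minus = not wmers.isdisjoint(minus_unique)
        if has_plus and not has_minus:
            n_plus += 1
        elif has_minus and not has_plus:
            n_minus += 1
        elif has_plus or has_minus or not wmers.isdisjoint(shared):
            n_unclassified += 1
        # else: read does not touch the junction region at all; ignored
    return IsoformCounts(n_plus, n_minus, n_unclassified)


# ---------------------------------------------------------------------------
# Knockdown time-course

@dataclass
class TimecoursePoint:
    shrna: str
    dox: bool
    timepoint_h: float
    rpkm: float


@dataclass
class FeatureTimecourse:
    feature_id: str
    points: list[TimecoursePoint]
    decreasing: bool


def knockdown_timecourse(
    expr: ExpressionMatrix,
    features,
    tolerance: float = 0.10,
) -> dict[str, FeatureTimecourse]:
    """Summarise per-feature RPKM over (shRNA, DOX, timepoint).

    A feature is flagged ``decreasing`` when, over the DOX-induced samples
    of every targeting shRNA (NT and untreated series are reported but do
    not veto) with >= 2 timepoints, the series is non-increasing up to a
    ``tolerance`` fractional allowance per step AND at least one series
    ends more than ``tolerance`` below its start — a flat (control-only)
    series is therefore not flagged.
    """
    dox_tps = sorted({s.timepoint_h for s in expr.samples if s.dox})
    if len(dox_tps) < 2:
        raise ValueError("need at least two DOX timepoints for a time-course")
    out: dict[str, FeatureTimecourse] = {}
    rpkm = expr.rpkm_frame()
    for fid in features:
        if fid not in rpkm.index:
            raise KeyError(f"unknown feature {fid!r}")
        row = rpkm.loc[fid]
        points = sorted(
            (
                TimecoursePoint(s.shrna, s.dox, s.timepoint_h, float(row[s.sample_id]))
                for s in expr.samples
            ),
            key=lambda p: (p.shrna, not p.dox, p.timepoint_h),
        )
        decreasing = _decreasing_flag(expr, row, tolerance)
        out[fid] = FeatureTimecourse(fid, points, decreasing)
    return out


def _decreasing_flag(expr: ExpressionMatrix, row: pd.Series, tolerance: float) -> bool:
    any_decline = False
    dox_shrnas = {s.shrna for s in expr.samples if s.dox}
    targeting = dox_shrnas - {"NT", "none"}
    for shrna in sorted(targeting or dox_shrnas):
        metas = sorted(expr.select_samples(shrna=shrna, dox=True), key=lambda s: s.timepoint_h)
        if len(metas) < 2:
            continue
        series = [float(row[m.sample_id]) for m in metas]
        for prev, nxt in zip(series, series[1:]):
            if nxt > prev * (1 + tolerance):
                return False
        first, last = series[0], series[-1]
        if first > 0 and last < first * (1 - tolerance):
            any_decline = True
    return any_decline
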