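"""Split ("edited") reference construction and breakpoint detection.

A fusion partner gene is replaced in the reference by two half-transcripts
cut at the breakpoint exon, so that reads can disambiguate fusion-derived
from wild-type-derived fragments.  Fusion isoform evidence (breakpoint and
splice-variant junctions) is carried by a small panel of junction contigs
that sit alongside, but separate from, the counting features.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGT")

#: Default in-frame insertion distinguishing the "+KTS" splice variant
#: (Lys-Thr-Ser codons).  Configurable per FusionSpec; the real variant
#: sequence belongs in a fixture, not in code.
DEFAULT_KTS_INSERTION = "AAGACTTCT"

PLUS_KTS = "plusKTS"
MINUS_KTS = "minusKTS"


class AnnotationError(ValueError):
    """Malformed gene annotation (bad exon structure, duplicate ids...)."""


@dataclass(frozen=True)
class Exon:
    """One exon: 1-based index within its transcript plus its sequence."""

    index: int
    sequence: str


@dataclass(frozen=True)
class GeneModel:
    """Ordered exon structure of one transcript, stored 5'->3'.

    Sequences are transcript-oriented; strand is resolved by whatever
    produced the annotation, so all downstream logic is strand-free.
    """

    gene_id: str
    transcript_id: str
    exons: tuple[Exon, ...]

    def __post_init__(self) -> None:
        if not self.exons:
            raise AnnotationError(f"gene {self.gene_id!r} has no exons")
        for i, exon in enumerate(self.exons, start=1):
            if exon.index != i:
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exon indices must be 1..n "
                    f"consecutive, found index {exon.index} at position {i}"
                )
            if not exon.sequence:
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exon {exon.index} is empty"
                )
            if not set(exon.sequence) <= _VALID_BASES:
                bad = sorted(set(exon.sequence) - _VALID_BASES)
                raise AnnotationError(
                    f"gene {self.gene_id!r}: exon {exon.index} contains "
                    f"non-ACGT characters {bad}"
                )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def sequence(self) -> str:
        """Full transcript sequence (concatenation of exons in order)."""
        return "".join(e.sequence for e in self.exons)

    def exon_slice(self, first: int, last: int) -> str:
        """Concatenated sequence of exons ``first..last`` (1-based, incl.)."""
        if not (1 <= first <= last <= self.n_exons):
            raise ValueError(
                f"gene {self.gene_id!r}: exon range ({first},{last}) outside "
                f"1..{self.n_exons}"
            )
        return "".join(e.sequence for e in self.exons[first - 1 : last])


@dataclass(frozen=True)
class FusionSpec:
    """Description of a two-partner fusion and its splice-variant insertion.

    The fusion joins exons ``1..last_5p_exon`` of the 5' partner to exons
    ``first_3p_exon..n`` of the 3' partner.  The "+KTS" variant carries
    ``kts_insertion`` immediately after 3'-partner exon
    ``kts_junction_after_exon``.
    """

    five_prime_gene: str
    last_5p_exon: int
    three_prime_gene: str
    first_3p_exon: int
    kts_insertion: str = DEFAULT_KTS_INSERTION
    kts_junction_after_exon: int = 9

    def __post_init__(self) -> None:
        if self.last_5p_exon < 1:
            raise ValueError("last_5p_exon must be >= 1")
        if self.first_3p_exon < 2:
            raise ValueError("first_3p_exon must be > 1")
        if len(self.kts_insertion) % 3 != 0:
            raise ValueError(
                "kts_insertion length must be a multiple of 3 (in-frame); "
                f"got {len(self.kts_insertion)} nt"
            )

    @classmethod
    def from_json(cls, path) -> "FusionSpec":
        with open(path) as fh:
            payload = json.load(fh)
        required = {
            "five_prime_gene",
            "last_5p_exon",
            "three_prime_gene",
            "first_3p_exon",
        }
        missing = required - payload.keys()
        if missing:
            raise ValueError(
                f"fusion spec {path} is missing required fields: "
                f"{sorted(missing)}"
            )
        known = required | {"kts_insertion", "kts_junction_after_exon"}
        unknown = payload.keys() - known
        if unknown:
            raise ValueError(
                f"fusion spec {path} has unknown fields: {sorted(unknown)}"
            )
        return cls(**payload)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)
            fh.write("\n")


@dataclass(frozen=True)
class HalfFeature:
    """One half of a split gene, used as a counting unit."""

    feature_id: str
    source_gene: str
    exon_range: tuple[int, int]
    sequence: str


@dataclass(frozen=True)
class JunctionContig:
    """A short contig spanning a junction of interest.

    ``diagnostic`` marks contigs whose unique w-mers classify isoform
    reads (the +/-KTS pair); the plain breakpoint contig is not diagnostic.
    """

    junction_id: str
    sequence: str
    diagnostic: bool
    junction_pos: int  # 0-based position of the first base right of the junction


@dataclass
class EditedReference:
    """Quantification feature space: split halves + background + junctions."""

    half_features: list[HalfFeature] = field(default_factory=list)
    background_features: list[tuple[str, str]] = field(default_factory=list)
    junction_panel: list[JunctionContig] = field(default_factory=list)
    flank_w: int = 30

    @property
    def feature_ids(self) -> list[str]:
        return [h.feature_id for h in self.half_features] + [
            fid for fid, _ in self.background_features
        ]

    def feature_sequences(self) -> dict[str, str]:
        """All counting features (halves + background), id -> sequence."""
        seqs = {h.feature_id: h.sequence for h in self.half_features}
        seqs.update(dict(self.background_features))
        return seqs

    def junction_contig(self, junction_id: str) -> JunctionContig:
        for contig in self.junction_panel:
            if contig.junction_id == junction_id:
                return contig
        raise KeyError(f"no junction contig {junction_id!r} in panel")

    def to_fasta(self, path) -> None:
        from .io import write_fasta

        records = list(self.feature_sequences().items())
        records += [(c.junction_id, c.sequence) for c in self.junction_panel]
        write_fasta(path, records)

    @classmethod
    def from_fasta(cls, path, flank_w: int = 30) -> "EditedReference":
        """Load a previously serialised reference.

        Junction contigs are recognised by the ``|`` in their record id
        (feature ids never contain one); everything else becomes a counting
        feature.  The 5'/3' half distinction is not needed for
        quantification, so all counting features are loaded as background.
        The junction point of a loaded contig is taken as ``flank_w``
        (its construction offset).
        """
        from .io import read_fasta

        ref = cls(flank_w=flank_w)
        for rid, seq in read_fasta(path):
            if "|" in rid:
                ref.junction_panel.append(
                    JunctionContig(
                        junction_id=rid,
                        sequence=seq,
                        diagnostic=rid.endswith((PLUS_KTS, MINUS_KTS)),
                        junction_pos=min(flank_w, len(seq) // 2),
                    )
                )
            else:
                ref.background_features.append((rid, seq))
        return ref


def split_transcript(gene: GeneModel, last_5p_exon: int) -> tuple[HalfFeature, HalfFeature]:
    """Split ``gene`` after exon ``last_5p_exon`` into 5' and 3' halves.

    The halves carry ids ``<gene>_5p`` and ``<gene>_3p`` and their
    concatenation reproduces the original transcript exactly.
    """
    n = gene.n_exons
    k = last_5p_exon
    if not 1 <= k < n:
        raise ValueError(
            f"cannot split gene {gene.gene_id!r} after exon {k}: "
            f"valid range is 1..{n - 1} (gene has {n} exons)"
        )
    five = HalfFeature(
        feature_id=f"{gene.gene_id}_5p",
        source_gene=gene.gene_id,
        exon_range=(1, k),
        sequence=gene.exon_slice(1, k),
    )
    three = HalfFeature(
        feature_id=f"{gene.gene_id}_3p",
        source_gene=gene.gene_id,
        exon_range=(k + 1, n),
        sequence=gene.exon_slice(k + 1, n),
    )
    return five, three


def build_fusion_sequence(
    g5: GeneModel, g3: GeneModel, spec: FusionSpec, isoform: str
) -> str:
    """Assemble the fusion transcript sequence for one splice variant.

    The sequence is exons ``1..k`` of the 5' partner followed by exons
    ``m..n`` of the 3' partner; the ``plusKTS`` variant additionally carries
    ``spec.kts_insertion`` immediately after 3'-partner exon
    ``spec.kts_junction_after_exon``.
    """
    if isoform not in (PLUS_KTS, MINUS_KTS):
        raise ValueError(
            f"unknown isoform {isoform!r}: expected {PLUS_KTS!r} or {MINUS_KTS!r}"
        )
    if spec.five_prime_gene != g5.gene_id or spec.three_prime_gene != g3.gene_id:
        raise ValueError(
            f"fusion spec names partners ({spec.five_prime_gene!r}, "
            f"{spec.three_prime_gene!r}) but got ({g5.gene_id!r}, {g3.gene_id!r})"
        )
    k, m = spec.last_5p_exon, spec.first_3p_exon
    if not 1 <= k < g5.n_exons:
        raise ValueError(
            f"last_5p_exon {k} outside 1..{g5.n_exons - 1} for {g5.gene_id!r}"
        )
    if not 1 < m <= g3.n_exons:
        raise ValueError(
            f"first_3p_exon {m} outside 2..{g3.n_exons} for {g3.gene_id!r}"
        )
    head = g5.exon_slice(1, k)
    if isoform == MINUS_KTS:
        return head + g3.exon_slice(m, g3.n_exons)
    j = spec.kts_junction_after_exon
    if j < m or j >= g3.n_exons:
        raise ValueError(
            f"kts_junction_after_exon {j} not an internal junction of the "
            f"fused 3' portion (exons {m}..{g3.n_exons} of {g3.gene_id!r})"
        )
    return (
        head
        + g3.exon_slice(m, j)
        + spec.kts_insertion
        + g3.exon_slice(j + 1, g3.n_exons)
    )


def _tail(seq: str, w: int, label: str) -> str:
    if len(seq) < w:
        logger.warning(
            "%s is shorter than flank width %d; using %d bases", label, w, len(seq)
        )
    return seq[-w:]


def _head(seq: str, w: int, label: str) -> str:
    if len(seq) < w:
        logger.warning(
            "%s is shorter than flank width %d; using %d bases", label, w, len(seq)
        )
    return seq[:w]


def build_edited_reference(
    annotation: list[GeneModel],
    specs: list[FusionSpec],
    flank_w: int = 30,
) -> EditedReference:
    """Build the edited reference from an annotation and fusion specs.

    Fusion partner genes are *replaced* by their two halves (a retained
    full-length entry would absorb every read and defeat the split); all
    other genes pass through unchanged as background features.  For each
    spec the junction panel gains a breakpoint contig plus one diagnostic
    contig per splice variant, each carrying ``flank_w`` bases on either
    side of the junction point.
    """
    by_id: dict[str, GeneModel] = {}
    for gene in annotation:
        if gene.gene_id in by_id:
            raise AnnotationError(f"duplicate gene id {gene.gene_id!r} in annotation")
        by_id[gene.gene_id] = gene

    split_at: dict[str, int] = {}
    for spec in specs:
        for gene_id in (spec.five_prime_gene, spec.three_prime_gene):
            if gene_id not in by_id:
                raise AnnotationError(
                    f"fusion spec references unknown gene {gene_id!r}"
                )
        split_at[spec.five_prime_gene] = spec.last_5p_exon
        split_at[spec.three_prime_gene] = spec.first_3p_exon - 1

    ref = EditedReference(flank_w=flank_w)
    for gene in annotation:
        if gene.gene_id in split_at:
            five, three = split_transcript(gene, split_at[gene.gene_id])
            ref.half_features += [five, three]
        else:
            ref.background_features.append((gene.gene_id, gene.sequence))

    for spec in specs:
        g5 = by_id[spec.five_prime_gene]
        g3 = by_id[spec.three_prime_gene]
        k, m = spec.last_5p_exon, spec.first_3p_exon
        head = g5.exon_slice(1, k)
        minus_fused = g3.exon_slice(m, g3.n_exons)
        left = _tail(head, flank_w, f"5' portion of {g5.gene_id}")
        right = _head(minus_fused, flank_w, f"fused 3' portion of {g3.gene_id}")
        ref.junction_panel.append(
            JunctionContig(
                junction_id=f"{g5.gene_id}|{g3.gene_id}_breakpoint",
                sequence=left + right,
                diagnostic=False,
                junction_pos=len(left),
            )
        )
        # Splice-variant contigs around the insertion junction: the two
        # differ only by the insertion, so w-mers unique to one of them
        # are the diagnostic evidence.
        j = spec.kts_junction_after_exon
        before = _tail(g3.exon_slice(m, j), flank_w, f"{g3.gene_id} exon {j} flank")
        after = _head(
            g3.exon_slice(j + 1, g3.n_exons), flank_w, f"{g3.gene_id} exon {j + 1} flank"
        )
        ref.junction_panel.append(
            JunctionContig(
                junction_id=f"{g5.gene_id}|{g3.gene_id}_{PLUS_KTS}",
                sequence=before + spec.kts_insertion + after,
                diagnostic=True,
                junction_pos=len(before),
            )
        )
        ref.junction_panel.append(
            JunctionContig(
                junction_id=f"{g5.gene_id}|{g3.gene_id}_{MINUS_KTS}",
                sequence=before + after,
                diagnostic=True,
                junction_pos=len(before),
            )
        )
    return ref


@dataclass(frozen=True)
class BreakpointCall:
    """Result of exon-level breakpoint detection."""

    five_prime_exon: int | None
    three_prime_exon: int | None
    support: int

    @property
    def found(self) -> bool:
        return self.support > 0


def detect_breakpoint(
    junction_reads,
    g5: GeneModel,
    g3: GeneModel,
    min_anchor: int = 20,
) -> BreakpointCall:
    """Locate the fusion junction at exon resolution from spanning reads.

    Every exon pair ``(k, m)`` is scored by the number of reads that match
    the 3' end of 5'-partner exons ``1..k`` with an exact prefix of at
    least ``min_anchor`` bases and the start of 3'-partner exons ``m..``
    with an exact suffix of at least ``min_anchor`` bases.  Ties are broken
    by larger support, then smaller ``k``, then smaller ``m``.

    ``junction_reads`` is an iterable of transcript-oriented read strings
    (a ReadSet may be flattened with :meth:`ReadSet.sequences`).

    Returns a :class:`BreakpointCall` with support 0 (and ``None`` exon
    indices) when no read supports any junction.
    """
    if min_anchor < 10:
        raise ValueError(f"min_anchor must be >= 10, got {min_anchor}")
    reads = [r.upper() for r in junction_reads]
    if not reads:
        return BreakpointCall(None, None, 0)

    max_len = max(len(r) for r in reads)
    best: tuple[int, int, int] | None = None  # (support, k, m)
    for k in range(1, g5.n_exons):
        head = g5.exon_slice(1, k)
        left = head[-max_len:]
        for m in range(2, g3.n_exons + 1):
            right = g3.exon_slice(m, g3.n_exons)[: max_len - min_anchor]
            support = 0
            for read in reads:
                if _spans_junction(read, left, right, min_anchor):
                    support += 1
            if support > 0:
                cand = (support, k, m)
                if best is None or (support, -k, -m) > (best[0], -best[1], -best[2]):
                    best = cand
    if best is None:
        return BreakpointCall(None, None, 0)
    support, k, m = best
    return BreakpointCall(k, m, support)


def _spans_junction(read: str, left: str, right: str, min_anchor: int) -> bool:
    """True if ``read`` = (suffix of left) + (prefix of right) with both
    parts at least ``min_anchor`` long."""
    lo, hi = min_anchor, len(read) - min_anchor
    if hi < lo:
        return False
    for p in range(lo, hi + 1):
        if len(left) >= p and left.endswith(read[:p]) and right.startswith(read[p:]):
            return True
    return False
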