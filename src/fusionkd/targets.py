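"""Knockdown target calling, gene-set overlap, Z-score gene sets.

The target caller is a deterministic filter, not a statistical test: a
gene is a target when BOTH hairpins move it by at least the fold-change
threshold in the same direction versus the non-targeting control, and the
comparison involves a truly-expressed value (the RPKM gate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quantify import ExpressionMatrix

logger = logging.getLogger(__name__)

UP = "up"
DOWN = "down"
NONE = "none"


class ConfigurationError(ValueError):
    """A required sample or panel element is absent."""


@dataclass
class RpkmTable:
    """A gene x sample RPKM table with sample metadata.

    The lightweight counterpart of :class:`~fusionkd.quantify.ExpressionMatrix`
    for workflows that start from an already-normalised table (TSV +
    metadata JSON) rather than from read assignment.  Exposes the same
    ``rpkm_frame``/``select_samples``/``feature_ids`` surface that
    :func:`call_targets` needs.
    """

    rpkm: pd.DataFrame  # genes x samples
    samples: list  # of quantify.SampleMeta

    def __post_init__(self) -> None:
        sample_ids = [s.sample_id for s in self.samples]
        missing = set(sample_ids) - set(self.rpkm.columns)
        if missing:
            raise ValueError(f"metadata names samples absent from table: {sorted(missing)}")
        self.rpkm = self.rpkm[sample_ids]

    @property
    def feature_ids(self) -> list[str]:
        return list(self.rpkm.index)

    def rpkm_frame(self) -> pd.DataFrame:
        return self.rpkm

    def select_samples(self, shrna=None, dox=None, timepoint_h=None) -> list:
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

    def to_tsv(self, rpkm_path, meta_path) -> None:
        from .io import write_json, write_matrix_tsv

        write_matrix_tsv(rpkm_path, self.rpkm)
        write_json(meta_path, {"samples": [s.to_dict() for s in self.samples]})

    @classmethod
    def from_tsv(cls, rpkm_path, meta_path) -> "RpkmTable":
        from .io import read_json, read_matrix_tsv
        from .quantify import SampleMeta

        rpkm = read_matrix_tsv(rpkm_path)
        meta = read_json(meta_path)
        return cls(rpkm, [SampleMeta(**s) for s in meta["samples"]])


@dataclass(frozen=True)
class TargetCallConfig:
    """Thresholds of the two-hairpin intersection rule.

    ``fc_threshold`` is the fractional change theta: down means
    fc <= 1 - theta, up means fc >= 1 + theta (multiplicative reading of
    "at least 25% up- or downregulated").  ``expr_cutoff`` gates each
    comparison on max(control, knockdown) RPKM.
    """

    fc_threshold: float = 0.25
    expr_cutoff: float = 5.0
    timepoint_h: float = 32.0
    require_both_shrnas: bool = True
    shrnas: tuple[str, ...] = ("sh2", "sh3")
    control: str = "NT"

    def __post_init__(self) -> None:
        if not 0 < self.fc_threshold < 1:
            raise ValueError(f"fc_threshold must be in (0, 1), got {self.fc_threshold}")
        if self.expr_cutoff <= 0:
            raise ValueError(f"expr_cutoff must be > 0, got {self.expr_cutoff}")


@dataclass
class GeneRecord:
    """Per-gene evidence behind a call."""

    gene: str
    rpkm_nt: float
    rpkm_sh: dict[str, float]
    fc_sh: dict[str, float]
    direction: str


@dataclass
class TargetCallResult:
    up: set[str]
    down: set[str]
    records: dict[str, GeneRecord]
    config: TargetCallConfig

    def __post_init__(self) -> None:
        assert not (self.up & self.down), "up/down sets must be disjoint"


def _pick_sample_column(expr, shrna: str, timepoint_h: float, dox: bool) -> pd.Series:
    """Average replicate RPKM columns for (shrna, dox, timepoint).

    Falls back to the nearest available DOX timepoint for that hairpin
    when the requested one is absent (logged), since harvest times may
    differ per hairpin.
    """
    metas = expr.select_samples(shrna=shrna, dox=dox, timepoint_h=timepoint_h)
    if not metas:
        candidates = expr.select_samples(shrna=shrna, dox=dox)
        if not candidates:
            raise ConfigurationError(
                f"no sample with shRNA {shrna!r}, dox={dox} in the matrix"
            )
        nearest = min({s.timepoint_h for s in candidates}, key=lambda t: abs(t - timepoint_h))
        logger.warning(
            "no %s sample at %g h; using nearest DOX timepoint %g h",
            shrna, timepoint_h, nearest,
        )
        metas = expr.select_samples(shrna=shrna, dox=dox, timepoint_h=nearest)
    frame = expr.rpkm_frame()[[m.sample_id for m in metas]]
    return frame.mean(axis=1)


def _direction(nt: float, sh: float, theta: float, cutoff: float) -> tuple[str, float]:
    """Evaluate one hairpin-vs-control comparison.

    Returns (direction, fold change).  Zero denominators follow explicit
    rules rather than a pseudocount: nt==0 with sh above the gate is an
    "up" with infinite fc; sh==0 with nt above the gate is a "down" with
    fc 0.  Comparisons failing the expression gate return NONE.
    """
    if max(nt, sh) <= cutoff:
        return NONE, (sh / nt if nt > 0 else math.inf if sh > 0 else math.nan)
    if nt == 0:
        return (UP, math.inf) if sh > cutoff else (NONE, math.inf)
    fc = sh / nt
    if fc <= 1 - theta:
        return DOWN, fc
    if fc >= 1 + theta:
        return UP, fc
    return NONE, fc


def call_targets(
    expr: "ExpressionMatrix | RpkmTable", cfg: TargetCallConfig | None = None
) -> TargetCallResult:
    """Apply the two-hairpin intersection rule to an RPKM matrix.

    ``expr`` is an :class:`~fusionkd.quantify.ExpressionMatrix` or an
    :class:`RpkmTable`; its features are gene symbols.  Per gene and hairpin the fold
    change versus the control is computed on DOX-induced samples at
    ``cfg.timepoint_h`` (replicates averaged); a gene enters ``down``
    (``up``) when every required hairpin calls it down (up) and passes the
    expression gate.  Genes with conflicting directions are excluded.
    """
    cfg = cfg or TargetCallConfig()
    nt = _pick_sample_column(expr, cfg.control, cfg.timepoint_h, dox=True)
    sh_cols = {sh: _pick_sample_column(expr, sh, cfg.timepoint_h, dox=True) for sh in cfg.shrnas}

    up: set[str] = set()
    down: set[str] = set()
    records: dict[str, GeneRecord] = {}
    for gene in expr.feature_ids:
        nt_val = float(nt[gene])
        directions: dict[str, str] = {}
        fcs: dict[str, float] = {}
        rpkms: dict[str, float] = {}
        for sh, col in sh_cols.items():
            sh_val = float(col[gene])
            d, fc = _direction(nt_val, sh_val, cfg.fc_threshold, cfg.expr_cutoff)
            directions[sh] = d
            fcs[sh] = fc
            rpkms[sh] = sh_val
        calls = set(directions.values())
        if cfg.require_both_shrnas:
            # unanimous non-NONE verdict required; conflicts are excluded
            final = calls.pop() if len(calls) == 1 else NONE
        else:
            non_none = calls - {NONE}
            final = non_none.pop() if len(non_none) == 1 else NONE
        if final == UP:
            up.add(gene)
        elif final == DOWN:
            down.add(gene)
        records[gene] = GeneRecord(gene, nt_val, rpkms, fcs, final)
    return TargetCallResult(up, down, records, cfg)


# ---------------------------------------------------------------------------
# Gene sets

@dataclass(frozen=True)
class GeneSet:
    """A named set of gene symbols (case-normalised to upper)."""

    name: str
    genes: frozenset[str]
    provenance: str = ""

    def __init__(self, name: str, genes, provenance: str = ""):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", frozenset(str(g).upper() for g in genes))
        object.__setattr__(self, "provenance", provenance)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OverlapReport:
    """Pairwise and triple intersections among up to three gene sets."""

    set_sizes: dict[str, int]
    pairwise: dict[tuple[str, str], frozenset[str]]
    triple: frozenset[str] | None
    fraction_of_a: float
    percent_of_a: int

    def to_dict(self) -> dict:
        return {
            "set_sizes": self.set_sizes,
            "pairwise": {
                " & ".join(k): sorted(v) for k, v in self.pairwise.items()
            },
            "triple": sorted(self.triple) if self.triple is not None else None,
            "fraction_of_a": self.fraction_of_a,
            "percent_of_a": self.percent_of_a,
        }


def overlap_sets(a: GeneSet, b: GeneSet, c: GeneSet | None = None) -> OverlapReport:
    """Intersect gene sets and report the shared fraction of ``a``.

    With three sets the headline fraction is ``|a & b & c| / |a|``; with
    two it is ``|a & b| / |a|``.  Reported raw and rounded to integer
    percent.
    """
    sets = [a, b] + ([c] if c is not None else [])
    sizes = {s.name: len(s) for s in sets}
    pairwise = {}
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            pairwise[(sets[i].name, sets[j].name)] = sets[i].genes & sets[j].genes
    if c is not None:
        shared = a.genes & b.genes & c.genes
        triple: frozenset[str] | None = frozenset(shared)
    else:
        shared = a.genes & b.genes
        triple = None
    fraction = len(shared) / len(a) if len(a) else 0.0
    return OverlapReport(
        set_sizes=sizes,
        pairwise={k: frozenset(v) for k, v in pairwise.items()},
        triple=triple,
        fraction_of_a=fraction,
        percent_of_a=round(fraction * 100),
    )


def zscore_gene_sets(
    expression: pd.Series | dict,
    z_hi: float = 1.0,
    z_lo: float = -1.0,
    name_prefix: str = "expression",
) -> tuple[GeneSet, GeneSet]:
    """Split genes into high/low sets by Z-score of their expression.

    Z uses the sample standard deviation (ddof=1) over genes; membership
    is strict (Z > z_hi, Z < z_lo).  Zero variance yields two empty sets
    with a warning.
    """
    values = pd.Series(expression, dtype=float)
    if len(values) < 3:
        raise ValueError(f"need at least 3 genes, got {len(values)}")
    if not np.isfinite(values.to_numpy()).all():
        raise ValueError("expression values must be finite")
    sd = values.std(ddof=1)
    if sd == 0:
        logger.warning("zero variance across genes; high/low sets are empty")
        z = pd.Series(0.0, index=values.index)
    else:
        z = (values - values.mean()) / sd
    high = GeneSet(f"{name_prefix}_high", z.index[z > z_hi], f"Z > {z_hi}")
    low = GeneSet(f"{name_prefix}_low", z.index[z < z_lo], f"Z < {z_lo}")
    return high, low


@dataclass
class GeneSetMeans:
    """Mean per-set expression per sample group, plus bookkeeping."""

    means: dict[tuple[str, str], float | None]  # (set name, group) -> mean or None
    missing_genes: dict[str, list[str]] = field(default_factory=dict)


def geneset_mean_expression(
    rpm: pd.DataFrame,
    sets: list[GeneSet],
    groups: dict[str, list[str]],
) -> GeneSetMeans:
    """Mean reads-per-million of each gene set within each sample group.

    For each (set, group): the mean over the set's genes of each gene's
    mean RPM across the group's samples.  Genes absent from the matrix are
    skipped and reported; a set with no genes present yields ``None``
    (missing), never a silent zero.
    """
    matrix = rpm.copy()
    matrix.index = matrix.index.astype(str).str.upper()
    means: dict[tuple[str, str], float | None] = {}
    missing: dict[str, list[str]] = {}
    for gs in sets:
        present = sorted(gs.genes & set(matrix.index))
        absent = sorted(gs.genes - set(matrix.index))
        if absent:
            missing[gs.name] = absent
        for group, sample_ids in groups.items():
            unknown = [s for s in sample_ids if s not in matrix.columns]
            if unknown:
                raise KeyError(f"group {group!r} names unknown samples {unknown}")
            if not present:
                means[(gs.name, group)] = None
                continue
            per_gene = matrix.loc[present, sample_ids].mean(axis=1)
            means[(gs.name, group)] = float(per_gene.mean())
    return GeneSetMeans(means=means, missing_genes=missing)
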