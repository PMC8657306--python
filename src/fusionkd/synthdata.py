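"""Synthetic data generators with full truth tables.

Every generator is deterministic under its seed and emits, alongside the
data, the ground truth needed for recovery testing: per-read source
labels, planted target-gene sets with their fold changes, the fusion
breakpoint, the splice-variant mixing fraction, and per-compound
dose-response parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .quantify import ReadPair, ReadSet, SampleMeta, revcomp
from .reference import (
    DEFAULT_KTS_INSERTION,
    MINUS_KTS,
    PLUS_KTS,
    Exon,
    FusionSpec,
    GeneModel,
    build_fusion_sequence,
)
from .screen import PLATE_COLUMNS, PlateData
from .targets import RpkmTable

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with desk-scale defaults.

    Knockdown schedule values are residual fusion fractions per DOX
    timepoint; they are placeholders shaped like a gradual decay, not
    measured values.  Read length defaults to 100 nt for test speed and
    may be raised to 150.
    """

    seed: int = 0

    # transcriptome
    n_background_genes: int = 50
    exon_count_range: tuple[int, int] = (3, 10)
    exon_length_range: tuple[int, int] = (80, 300)
    five_prime_gene: str = "FUSA"
    five_prime_exons: int = 17
    three_prime_gene: str = "FUSB"
    three_prime_exons: int = 10
    fusion_last_5p_exon: int = 7
    fusion_first_3p_exon: int = 8
    kts_insertion: str = DEFAULT_KTS_INSERTION
    kts_junction_after_exon: int = 9

    # expression / knockdown
    timepoints_h: tuple[float, ...] = (8.0, 24.0, 32.0)
    knockdown_schedule: dict[float, float] = field(
        default_factory=lambda: {8.0: 0.8, 16.0: 0.6, 24.0: 0.45, 32.0: 0.3, 40.0: 0.25}
    )
    shrnas: tuple[str, ...] = ("sh2", "sh3")
    kts_fraction: float = 0.5
    fusion_abundance: float = 30.0
    wt_five_prime_abundance: float = 8.0
    background_abundance_mean_log: float = 1.0
    background_abundance_sd_log: float = 1.0
    n_up_targets: int = 5
    n_down_targets: int = 5
    up_fc: float = 2.0
    down_fc: float = 0.5

    # reads
    n_pairs: int = 5000
    read_length: int = 100
    fragment_mean: float = 250.0
    fragment_sd: float = 30.0
    error_rate: float = 0.005

    # shortcut RPKM table
    rpkm_n_genes: int = 2000
    rpkm_planted_up: int = 200
    rpkm_planted_down: int = 200
    rpkm_up_fc: float = 2.0
    rpkm_down_fc: float = 0.5
    rpkm_base_mean_log: float = np.log(20.0)
    rpkm_base_sd_log: float = 1.0
    rpkm_planted_min_base: float = 12.0
    nb_dispersion: float = 0.05
    rpkm_depth_scale: float = 100.0

    # screen
    n_compounds: int = 201
    n_sensitive: int = 10
    sensitivity_factor: float = 10.0
    screen_models: tuple[str, ...] = ("model1", "model2", "model3")
    screen_model_ic50_bias: tuple[float, ...] = (1.0, 1.0, 2.0)
    screen_doses_uM: tuple[float, ...] = (0.001, 0.00464, 0.0215, 0.1, 0.464, 2.15, 10.0)
    screen_replicates: int = 3
    # base IC50s are log-uniform inside the dose window so every compound
    # responds in range; sensitive compounds draw from the upper band so
    # the planted model-1 shift stays inside the window too
    screen_ic50_range_uM: tuple[float, float] = (0.05, 1.0)
    screen_sensitive_base_ic50_uM: tuple[float, float] = (0.5, 1.0)
    screen_hill_range: tuple[float, float] = (0.8, 2.5)
    screen_bottom_range: tuple[float, float] = (0.0, 0.2)
    screen_noise_sd: float = 0.02
    screen_dmso_wells: int = 16
    screen_signal_scale: float = 1e5

    def __post_init__(self) -> None:
        if not 0 <= self.kts_fraction <= 1:
            raise ValueError("kts_fraction must be in [0, 1]")
        if not 0 <= self.error_rate <= 0.05:
            raise ValueError("error_rate must be in [0, 0.05]")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if any(not 0 <= f <= 1 for f in self.knockdown_schedule.values()):
            raise ValueError("knockdown schedule fractions must be in [0, 1]")
        lo, hi = self.exon_length_range
        if lo < 1 or hi < lo:
            raise ValueError(f"infeasible exon length range ({lo}, {hi})")
        lo, hi = self.exon_count_range
        if lo < 2 or hi < lo:
            raise ValueError(f"infeasible exon count range ({lo}, {hi})")
        if len(self.screen_model_ic50_bias) != len(self.screen_models):
            raise ValueError("need one ic50 bias per screen model")
        if len(self.screen_doses_uM) < 4:
            raise ValueError("need >= 4 doses per compound")

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        unknown = set(payload) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("timepoints_h", "shrnas", "screen_models", "screen_doses_uM",
                    "screen_model_ic50_bias", "exon_count_range", "exon_length_range",
                    "screen_hill_range", "screen_bottom_range"):
            if key in payload and isinstance(payload[key], list):
                payload[key] = tuple(payload[key])
        if "knockdown_schedule" in payload:
            payload["knockdown_schedule"] = {
                float(k): float(v) for k, v in payload["knockdown_schedule"].items()
            }
        return cls(**payload)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Ground truth emitted alongside generated data."""

    breakpoint: tuple[int, int] | None = None
    kts_fraction: float | None = None
    read_labels: dict[str, str] | None = None
    feature_counts: dict[str, int] | None = None
    abundances: dict[str, dict[str, float]] | None = None
    planted_up: set[str] | None = None
    planted_down: set[str] | None = None
    planted_fc: dict[str, float] | None = None
    screen_params: dict[tuple[str, str], dict[str, float]] | None = None
    sensitive_compounds: list[str] | None = None


# ---------------------------------------------------------------------------
# Transcriptome

def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _random_gene(
    rng: np.random.Generator, gene_id: str, n_exons: int, length_range: tuple[int, int]
) -> GeneModel:
    lo, hi = length_range
    exons = tuple(
        Exon(i, _random_sequence(rng, int(rng.integers(lo, hi + 1))))
        for i in range(1, n_exons + 1)
    )
    return GeneModel(gene_id, f"{gene_id}_T1", exons)


def simulate_transcriptome(cfg: SimConfig) -> tuple[list[GeneModel], FusionSpec]:
    """Random background genes plus the two fusion partner genes.

    Partner shapes default to a 17-exon 5' partner and a 10-exon 3'
    partner fused 7|8, with the splice-variant insertion after 3'-partner
    exon 9.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = [
        _random_gene(rng, cfg.five_prime_gene, cfg.five_prime_exons, cfg.exon_length_range),
        _random_gene(rng, cfg.three_prime_gene, cfg.three_prime_exons, cfg.exon_length_range),
    ]
    clo, chi = cfg.exon_count_range
    for i in range(cfg.n_background_genes):
        n_exons = int(rng.integers(clo, chi + 1))
        genes.append(
            _random_gene(rng, f"BG{i + 1:04d}", n_exons, cfg.exon_length_range)
        )
    spec = FusionSpec(
        five_prime_gene=cfg.five_prime_gene,
        last_5p_exon=cfg.fusion_last_5p_exon,
        three_prime_gene=cfg.three_prime_gene,
        first_3p_exon=cfg.fusion_first_3p_exon,
        kts_insertion=cfg.kts_insertion,
        kts_junction_after_exon=cfg.kts_junction_after_exon,
    )
    return genes, spec


# ---------------------------------------------------------------------------
# Expression schedules

FUSION_PLUS = "fusion_plusKTS"
FUSION_MINUS = "fusion_minusKTS"
WT_FIVE_PRIME = "wt_five_prime"


@dataclass
class ExpressionSim:
    """Per-sample true transcript abundances plus truth."""

    samples: list[SampleMeta]
    abundances: dict[str, dict[str, float]]  # sample_id -> transcript -> abundance
    truth: SimTruth


def simulate_expression(cfg: SimConfig, annotation: list[GeneModel]) -> ExpressionSim:
    """True transcript abundances across (shRNA, DOX, timepoint).

    Fusion abundance follows the knockdown schedule under targeting
    hairpins with DOX and stays flat under the NT control; the wild-type
    3' partner is never expressed (its 5' half must read out as zero).
    Planted up/down background genes scale linearly with the knocked-down
    fusion fraction, reaching their full planted fold change at residual
    fraction 0.
    """
    ids = {g.gene_id for g in annotation}
    if cfg.five_prime_gene not in ids or cfg.three_prime_gene not in ids:
        raise ValueError("annotation must contain both fusion partner genes")
    background = [
        g.gene_id for g in annotation
        if g.gene_id not in (cfg.five_prime_gene, cfg.three_prime_gene)
    ]
    n_planted = cfg.n_up_targets + cfg.n_down_targets
    if n_planted > len(background):
        raise ValueError(
            f"{n_planted} planted targets exceed {len(background)} background genes"
        )
    rng = np.random.default_rng(cfg.seed + 1)
    base = {
        g: float(
            np.exp(rng.normal(cfg.background_abundance_mean_log, cfg.background_abundance_sd_log))
        )
        for g in background
    }
    planted = list(rng.choice(background, size=n_planted, replace=False))
    up = set(planted[: cfg.n_up_targets])
    down = set(planted[cfg.n_up_targets :])
    planted_fc = {g: cfg.up_fc for g in up} | {g: cfg.down_fc for g in down}

    samples: list[SampleMeta] = []
    abundances: dict[str, dict[str, float]] = {}
    for shrna in (*cfg.shrnas, "NT"):
        for tp in cfg.timepoints_h:
            meta = SampleMeta(f"{shrna}_dox_{tp:g}h", shrna=shrna, dox=True, timepoint_h=tp)
            residual = 1.0 if shrna == "NT" else _schedule_at(cfg.knockdown_schedule, tp)
            table: dict[str, float] = {}
            table[FUSION_PLUS] = cfg.fusion_abundance * cfg.kts_fraction * residual
            table[FUSION_MINUS] = cfg.fusion_abundance * (1 - cfg.kts_fraction) * residual
            table[WT_FIVE_PRIME] = cfg.wt_five_prime_abundance
            for g in background:
                fc = planted_fc.get(g, 1.0)
                effect = 1.0 + (fc - 1.0) * (1.0 - residual)
                table[g] = base[g] * effect
            samples.append(meta)
            abundances[meta.sample_id] = table
    truth = SimTruth(
        breakpoint=(cfg.fusion_last_5p_exon, cfg.fusion_first_3p_exon),
        kts_fraction=cfg.kts_fraction,
        abundances=abundances,
        planted_up=up,
        planted_down=down,
        planted_fc=planted_fc,
    )
    return ExpressionSim(samples, abundances, truth)


def _schedule_at(schedule: dict[float, float], timepoint: float) -> float:
    if timepoint in schedule:
        return schedule[timepoint]
    raise ValueError(
        f"timepoint {timepoint} h not in knockdown schedule {sorted(schedule)}"
    )


# ---------------------------------------------------------------------------
# Reads

def _transcript_sequences(
    cfg: SimConfig, annotation: list[GeneModel]
) -> tuple[dict[str, str], dict[str, list[tuple[int, str]]]]:
    """Sequences of every transcript that can be expressed, plus the
    feature segmentation of each (cut positions and segment feature ids)."""
    by_id = {g.gene_id: g for g in annotation}
    g5 = by_id[cfg.five_prime_gene]
    g3 = by_id[cfg.three_prime_gene]
    spec = FusionSpec(
        cfg.five_prime_gene, cfg.fusion_last_5p_exon,
        cfg.three_prime_gene, cfg.fusion_first_3p_exon,
        cfg.kts_insertion, cfg.kts_junction_after_exon,
    )
    head_len = len(g5.exon_slice(1, spec.last_5p_exon))
    seqs: dict[str, str] = {}
    segments: dict[str, list[tuple[int, str]]] = {}
    for g in annotation:
        if g.gene_id in (cfg.five_prime_gene, cfg.three_prime_gene):
            continue
        seqs[g.gene_id] = g.sequence
        segments[g.gene_id] = [(len(g.sequence), g.gene_id)]
    seqs[WT_FIVE_PRIME] = g5.sequence
    segments[WT_FIVE_PRIME] = [
        (head_len, f"{g5.gene_id}_5p"),
        (len(g5.sequence) - head_len, f"{g5.gene_id}_3p"),
    ]
    minus = build_fusion_sequence(g5, g3, spec, MINUS_KTS)
    seqs[FUSION_MINUS] = minus
    segments[FUSION_MINUS] = [
        (head_len, f"{g5.gene_id}_5p"),
        (len(minus) - head_len, f"{g3.gene_id}_3p"),
    ]
    if spec.first_3p_exon <= spec.kts_junction_after_exon < g3.n_exons:
        plus = build_fusion_sequence(g5, g3, spec, PLUS_KTS)
        ins_at = head_len + len(
            g3.exon_slice(spec.first_3p_exon, spec.kts_junction_after_exon)
        )
        seqs[FUSION_PLUS] = plus
        # treat the insertion as its own (junction) segment
        segments[FUSION_PLUS] = [
            (head_len, f"{g5.gene_id}_5p"),
            (ins_at - head_len, f"{g3.gene_id}_3p"),
            (len(spec.kts_insertion), "kts_insertion"),
            (len(plus) - ins_at - len(spec.kts_insertion), f"{g3.gene_id}_3p"),
        ]
    else:
        logger.info(
            "insertion junction after exon %d is not internal to the fused "
            "portion; +KTS transcript omitted", spec.kts_junction_after_exon,
        )
    return seqs, segments


def _fragment_label(segments: list[tuple[int, str]], start: int, end: int) -> str:
    """Feature label of a fragment [start, end): the feature id when fully
    inside one segment, else a junction label."""
    pos = 0
    touched: list[str] = []
    for length, fid in segments:
        seg_start, seg_end = pos, pos + length
        if start < seg_end and end > seg_start:
            touched.append(fid)
        pos = seg_end
    if len(touched) == 1:
        return touched[0]
    if "kts_insertion" in touched:
        return "junction:plusKTS"
    return "junction:" + "|".join(dict.fromkeys(touched))


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.flatnonzero(rng.random(len(arr)) < error_rate)
    for i in hits:
        current = arr[i].decode()
        choices = [b for b in "ACGT" if b != current]
        arr[i] = rng.choice(choices).encode()
    return arr.tobytes().decode()


def simulate_reads(
    cfg: SimConfig,
    annotation: list[GeneModel],
    abundances: dict[str, float],
    n_pairs: int | None = None,
) -> ReadSet:
    """Paired-end reads for one sample, with per-pair truth labels.

    Fragments are drawn per transcript proportional to abundance x length,
    start positions uniform; mate 1 is the fragment 5' prefix, mate 2 the
    reverse complement of its 3' suffix (reads truncate to short
    fragments).  Substitution errors are applied at ``cfg.error_rate``.
    The truth label is the fragment's unique counting feature, or a
    ``junction:`` label when it spans a split or insertion boundary.
    """
    rng = np.random.default_rng(cfg.seed + 2)
    n_pairs = cfg.n_pairs if n_pairs is None else n_pairs
    seqs, segments = _transcript_sequences(cfg, annotation)
    unknown = set(abundances) - set(seqs)
    if unknown:
        raise ValueError(f"abundances name unknown transcripts: {sorted(unknown)}")
    names = [t for t, a in abundances.items() if a > 0]
    weights = np.array([abundances[t] * len(seqs[t]) for t in names], dtype=float)
    if not names or weights.sum() <= 0:
        logger.warning("zero total abundance; returning an empty read set")
        return ReadSet([])
    probs = weights / weights.sum()
    choices = rng.choice(len(names), size=n_pairs, p=probs)
    frag_lens = rng.normal(cfg.fragment_mean, cfg.fragment_sd, size=n_pairs)
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        t = names[choices[i]]
        seq = seqs[t]
        flen = int(np.clip(round(frag_lens[i]), 30, len(seq)))
        start = int(rng.integers(0, len(seq) - flen + 1))
        frag = seq[start : start + flen]
        r1 = _mutate(rng, frag[: cfg.read_length], cfg.error_rate)
        r2 = _mutate(rng, revcomp(frag)[: cfg.read_length], cfg.error_rate)
        label = _fragment_label(segments[t], start, start + flen)
        pairs.append(ReadPair(r1, r2, f"p{i + 1:06d}", truth=label))
    return ReadSet(pairs)


def simulate_breakpoint_reads(
    cfg: SimConfig,
    annotation: list[GeneModel],
    n_reads: int = 100,
    min_flank: int = 20,
    error_rate: float | None = None,
) -> tuple[list[str], SimTruth]:
    """Single-end transcript-oriented reads spanning the fusion breakpoint.

    Every read overlaps the junction by at least ``min_flank`` bases on
    each side, so with zero errors each read supports the true exon pair.
    """
    rng = np.random.default_rng(cfg.seed + 3)
    seqs, _ = _transcript_sequences(cfg, annotation)
    by_id = {g.gene_id: g for g in annotation}
    head_len = len(by_id[cfg.five_prime_gene].exon_slice(1, cfg.fusion_last_5p_exon))
    seq = seqs[FUSION_MINUS]
    rl = cfg.read_length
    err = cfg.error_rate if error_rate is None else error_rate
    lo = max(0, head_len - rl + min_flank)
    hi = min(len(seq) - rl, head_len - min_flank)
    if hi < lo:
        raise ValueError("read length too short for the requested junction flanks")
    reads = []
    for _ in range(n_reads):
        start = int(rng.integers(lo, hi + 1))
        reads.append(_mutate(rng, seq[start : start + rl], err))
    truth = SimTruth(breakpoint=(cfg.fusion_last_5p_exon, cfg.fusion_first_3p_exon))
    return reads, truth


def simulate_kts_junction_reads(
    cfg: SimConfig,
    annotation: list[GeneModel],
    n_reads: int = 1000,
    flank_w: int = 30,
    error_rate: float | None = None,
) -> tuple[list[str], SimTruth]:
    """Single-end reads over the splice-variant junction, isoform chosen
    per read with probability ``cfg.kts_fraction`` of the +KTS variant.

    Each read fully covers the diagnostic window (``flank_w`` bases either
    side of the junction, plus the insertion for the +KTS variant), so an
    error-free read always carries a diagnostic w-mer.
    """
    rng = np.random.default_rng(cfg.seed + 4)
    seqs, segments = _transcript_sequences(cfg, annotation)
    if FUSION_PLUS not in seqs:
        raise ValueError(
            "the +KTS isoform is not constructible under this configuration "
            "(insertion junction outside the fused portion)"
        )
    by_id = {g.gene_id: g for g in annotation}
    g5 = by_id[cfg.five_prime_gene]
    g3 = by_id[cfg.three_prime_gene]
    head_len = len(g5.exon_slice(1, cfg.fusion_last_5p_exon))
    j_minus = head_len + len(
        g3.exon_slice(cfg.fusion_first_3p_exon, cfg.kts_junction_after_exon)
    )
    rl = cfg.read_length
    err = cfg.error_rate if error_rate is None else error_rate
    ins = len(cfg.kts_insertion)
    windows = {
        PLUS_KTS: (seqs[FUSION_PLUS], j_minus - flank_w, j_minus + ins + flank_w),
        MINUS_KTS: (seqs[FUSION_MINUS], j_minus - flank_w, j_minus + flank_w),
    }
    for name, (seq, w_lo, w_hi) in windows.items():
        if w_hi - w_lo > rl or w_lo < 0 or w_hi > len(seq):
            raise ValueError(
                f"read length {rl} cannot cover the {name} diagnostic window"
            )
    is_plus = rng.random(n_reads) < cfg.kts_fraction
    reads = []
    n_plus = 0
    for i in range(n_reads):
        seq, w_lo, w_hi = windows[PLUS_KTS if is_plus[i] else MINUS_KTS]
        n_plus += int(is_plus[i])
        lo = max(0, w_hi - rl)
        hi = min(len(seq) - rl, w_lo)
        start = int(rng.integers(lo, hi + 1))
        reads.append(_mutate(rng, seq[start : start + rl], err))
    truth = SimTruth(kts_fraction=cfg.kts_fraction)
    truth.feature_counts = {PLUS_KTS: n_plus, MINUS_KTS: n_reads - n_plus}
    return reads, truth


# ---------------------------------------------------------------------------
# Shortcut RPKM table

def simulate_rpkm_table(cfg: SimConfig) -> tuple[RpkmTable, SimTruth]:
    """Negative-binomial RPKM table with planted up/down target genes.

    ``nb_dispersion`` is the biological coefficient of variation of a
    mean-one Gamma factor mixed into a Poisson draw (variance
    mu + (d*mu)^2); dispersion 0 bypasses sampling entirely so expected
    fold changes are realised exactly.  Planted genes are drawn from
    genes whose base expression clears the expression gate so recovery is
    well-defined.
    """
    rng = np.random.default_rng(cfg.seed + 5)
    n = cfg.rpkm_n_genes
    n_planted = cfg.rpkm_planted_up + cfg.rpkm_planted_down
    if n_planted > n:
        raise ValueError(f"{n_planted} planted genes exceed {n} total genes")
    genes = [f"G{i + 1:05d}" for i in range(n)]
    base = np.exp(rng.normal(cfg.rpkm_base_mean_log, cfg.rpkm_base_sd_log, size=n))
    eligible = np.flatnonzero(base >= cfg.rpkm_planted_min_base)
    if eligible.size < n_planted:
        raise ValueError(
            f"only {eligible.size} genes clear the planted-base floor "
            f"{cfg.rpkm_planted_min_base}; need {n_planted}"
        )
    chosen = rng.choice(eligible, size=n_planted, replace=False)
    up_idx = chosen[: cfg.rpkm_planted_up]
    down_idx = chosen[cfg.rpkm_planted_up :]
    fc = np.ones(n)
    fc[up_idx] = cfg.rpkm_up_fc
    fc[down_idx] = cfg.rpkm_down_fc

    tp = 32.0
    samples = [
        SampleMeta("NT_dox_32h", shrna="NT", dox=True, timepoint_h=tp),
        SampleMeta("sh2_dox_32h", shrna="sh2", dox=True, timepoint_h=tp),
        SampleMeta("sh3_dox_32h", shrna="sh3", dox=True, timepoint_h=tp),
    ]
    expected = np.column_stack([base, base * fc, base * fc])
    if cfg.nb_dispersion == 0:
        values = expected
    else:
        scale = cfg.rpkm_depth_scale
        mu = expected * scale
        d = cfg.nb_dispersion
        gamma = rng.gamma(shape=1.0 / d**2, scale=d**2, size=mu.shape)
        values = rng.poisson(mu * gamma).astype(float) / scale
    table = RpkmTable(
        pd.DataFrame(values, index=genes, columns=[s.sample_id for s in samples]),
        samples,
    )
    truth = SimTruth(
        planted_up={genes[i] for i in up_idx},
        planted_down={genes[i] for i in down_idx},
        planted_fc={genes[i]: float(fc[i]) for i in chosen},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Screen plates

def simulate_screen(cfg: SimConfig) -> tuple[PlateData, SimTruth]:
    """384-well-style screen plates with known dose-response truth.

    Each compound has one true 4PL curve shared across models, subject to
    a fixed per-model IC50 bias; a planted subset is additionally
    sensitised in the first model by ``sensitivity_factor``.  One plate
    per model, DMSO wells included, multiplicative log-normal noise.
    """
    rng = np.random.default_rng(cfg.seed + 6)
    compounds = [f"C{i + 1:03d}" for i in range(cfg.n_compounds)]
    sensitive = list(rng.choice(compounds, size=cfg.n_sensitive, replace=False)) \
        if cfg.n_sensitive else []
    lo, hi = cfg.screen_ic50_range_uM
    ic50 = np.exp(rng.uniform(np.log(lo), np.log(hi), size=cfg.n_compounds))
    hill = rng.uniform(*cfg.screen_hill_range, size=cfg.n_compounds)
    bottom = rng.uniform(*cfg.screen_bottom_range, size=cfg.n_compounds)
    sens = set(sensitive)
    band_lo, band_hi = cfg.screen_sensitive_base_ic50_uM
    for c_idx, compound in enumerate(compounds):
        if compound in sens:
            ic50[c_idx] = np.exp(rng.uniform(np.log(band_lo), np.log(band_hi)))

    params: dict[tuple[str, str], dict[str, float]] = {}
    rows = []
    noise_sd = cfg.screen_noise_sd
    for m_idx, model in enumerate(cfg.screen_models):
        plate_id = f"plate_{model}"
        bias = cfg.screen_model_ic50_bias[m_idx]
        for w in range(cfg.screen_dmso_wells):
            signal = cfg.screen_signal_scale * _lognoise(rng, noise_sd)
            rows.append((plate_id, f"D{w + 1:03d}", "DMSO", 0.0, "uM", model, signal))
        well = 0
        for c_idx, compound in enumerate(compounds):
            c_ic50 = ic50[c_idx] * bias
            if m_idx == 0 and compound in sens:
                c_ic50 /= cfg.sensitivity_factor
            p = {
                "top": 1.0,
                "bottom": float(bottom[c_idx]),
                "ic50": float(c_ic50),
                "hill": float(hill[c_idx]),
            }
            params[(compound, model)] = p
            for dose in cfg.screen_doses_uM:
                v = p["bottom"] + (p["top"] - p["bottom"]) / (
                    1.0 + (dose / p["ic50"]) ** p["hill"]
                )
                for _ in range(cfg.screen_replicates):
                    signal = cfg.screen_signal_scale * v * _lognoise(rng, noise_sd)
                    well += 1
                    rows.append(
                        (plate_id, f"W{well:04d}", compound, dose, "uM", model, signal)
                    )
    plate = PlateData(pd.DataFrame(rows, columns=PLATE_COLUMNS))
    truth = SimTruth(screen_params=params, sensitive_compounds=sorted(sens))
    return plate, truth


def _lognoise(rng: np.random.Generator, sd: float) -> float:
    if sd <= 0:
        return 1.0
    return float(np.exp(rng.normal(0.0, sd) - sd**2 / 2))
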