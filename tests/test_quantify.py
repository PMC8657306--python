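import numpy as np
import pytest

from fusionkd.quantify import (
    FRACTIONAL,
    UNIQUE_ONLY,
    ExpressionMatrix,
    ReadPair,
    ReadSet,
    SampleMeta,
    assign_reads,
    canonical,
    compute_rpkm,
    count_isoform_junctions,
    index_reference,
    knockdown_timecourse,
    revcomp,
)
from fusionkd.reference import EditedReference, FusionSpec, build_edited_reference
from fusionkd.synthdata import (
    SimConfig,
    simulate_expression,
    simulate_kts_junction_reads,
    simulate_reads,
    simulate_transcriptome,
)

from .conftest import make_gene


def _bg_ref(seqs: dict[str, str]) -> EditedReference:
    return EditedReference(background_features=list(seqs.items()))


class TestKmerIndex:
    def test_disjoint_features_map_to_singletons(self):
        ref = _bg_ref({"A": "ACGT" * 10, "B": "GGCA" * 10})
        idx = index_reference(ref, k_mer=15)
        hits = {tuple(sorted(idx.get(km))) for km in idx.kmers()}
        assert hits <= {("A",), ("B",)}

    def test_split_boundary_kmers_absent(self, small_reference, small_annotation):
        annotation, spec = small_annotation
        g5 = annotation[0]
        idx = index_reference(small_reference, k_mer=21)
        boundary = g5.sequence[
            len(g5.exon_slice(1, spec.last_5p_exon)) - 10 :
        ][:21]
        assert idx.get(canonical(boundary)) is None

    def test_kmer_count_bounded_by_positions(self, rng):
        # oracle: 1000 - 21 + 1 = 980 positions
        seq = "".join(rng.choice(list("ACGT"), 1000))
        idx = index_reference(_bg_ref({"X": seq}), k_mer=21)
        assert len(idx) <= 980

    def test_short_feature_excluded_with_warning(self, caplog):
        ref = _bg_ref({"short": "ACGTACGT", "long": "ACGT" * 20})
        with caplog.at_level("WARNING"):
            idx = index_reference(ref, k_mer=21)
        assert "excluded from index" in caplog.text
        assert all(idx.get(km) == frozenset({"long"}) for km in idx.kmers())

    @pytest.mark.parametrize("k", [14, 32])
    def test_k_range_enforced(self, k):
        with pytest.raises(ValueError, match=r"\[15, 31\]"):
            index_reference(_bg_ref({"A": "ACGT" * 20}), k_mer=k)


class TestAssignReads:
    def test_truth_exactness_on_contained_reads(self, small_cfg, small_annotation, small_reference):
        annotation, _ = small_annotation
        background = [g.gene_id for g in annotation[2:]]
        abundances = {g: 1.0 for g in background}
        reads = simulate_reads(small_cfg, annotation, abundances, n_pairs=1500)
        idx = index_reference(small_reference)
        result = assign_reads(reads, idx, policy=UNIQUE_ONLY)
        truth = reads.truth_counts()
        assert all(not t.startswith("junction") for t in truth)
        assert {f: int(c) for f, c in result.counts.items()} == dict(truth)
        assert result.assigned_total == len(reads)
        assert result.unassigned == 0

    def test_chimeric_pair_unassigned(self, rng):
        a = "".join(rng.choice(list("ACGT"), 200))
        b = "".join(rng.choice(list("ACGT"), 200))
        idx = index_reference(_bg_ref({"A": a, "B": b}))
        pair = ReadPair(a[:50], revcomp(b[:50]), "chimera")
        result = assign_reads(ReadSet([pair]), idx)
        assert result.counts == {}
        assert result.unassigned == 1

    def test_fusion_5p_portion_assigned_to_half(self, partners_only_cfg, partner_annotation):
        annotation, spec = partner_annotation
        ref = build_edited_reference(annotation, [spec])
        idx = index_reference(ref)
        from fusionkd.synthdata import FUSION_MINUS

        reads = simulate_reads(
            partners_only_cfg, annotation, {FUSION_MINUS: 1.0}, n_pairs=400
        )
        contained = ReadSet([p for p in reads if p.truth == "FUSA_5p"])
        assert len(contained) > 0
        result = assign_reads(contained, idx)
        assert result.counts == {"FUSA_5p": float(len(contained))}

    def test_fractional_conserves_mass(self, rng):
        shared = "".join(rng.choice(list("ACGT"), 120))
        a = shared + "".join(rng.choice(list("ACGT"), 100))
        b = shared + "".join(rng.choice(list("ACGT"), 100))
        idx = index_reference(_bg_ref({"A": a, "B": b}))
        pairs = [
            ReadPair(shared[:60], revcomp(shared[40:100]), "amb"),  # ambiguous
            ReadPair(a[150:210], revcomp(a[160:220]), "uniq"),
        ]
        result = assign_reads(ReadSet(pairs), idx, policy=FRACTIONAL)
        assert result.counts["A"] == pytest.approx(1.5)
        assert result.counts["B"] == pytest.approx(0.5)
        assert sum(result.counts.values()) == pytest.approx(result.assigned_total)

    def test_unique_only_drops_ambiguous(self, rng):
        shared = "".join(rng.choice(list("ACGT"), 120))
        idx = index_reference(
            _bg_ref({"A": shared + "A" * 30, "B": shared + "C" * 30})
        )
        pair = ReadPair(shared[:60], revcomp(shared[40:100]), "amb")
        result = assign_reads(ReadSet([pair]), idx, policy=UNIQUE_ONLY)
        assert result.counts == {}
        assert result.unassigned == 1

    def test_unknown_policy(self):
        idx = index_reference(_bg_ref({"A": "ACGT" * 20}))
        with pytest.raises(ValueError, match="policy"):
            assign_reads(ReadSet([]), idx, policy="best_hit")


class TestComputeRpkm:
    def test_textbook_value(self):
        rpkm = compute_rpkm(np.array([[10.0]]), np.array([1000.0]), np.array([1e6]))
        assert rpkm[0, 0] == pytest.approx(10.0)

    def test_zero_counts(self):
        rpkm = compute_rpkm(np.array([[0.0]]), np.array([500.0]), np.array([1e4]))
        assert rpkm[0, 0] == 0.0

    def test_conservation(self, rng):
        counts = rng.integers(0, 500, size=(30, 4)).astype(float)
        lengths = rng.integers(200, 3000, size=30).astype(float)
        totals = counts.sum(axis=0)
        rpkm = compute_rpkm(counts, lengths, totals)
        np.testing.assert_allclose(
            (rpkm * lengths[:, None]).sum(axis=0), 1e9, rtol=1e-6
        )

    def test_zero_total_column_warns(self, caplog):
        with caplog.at_level("WARNING"):
            rpkm = compute_rpkm(np.zeros((2, 1)), np.array([100.0, 200.0]), np.array([0.0]))
        assert (rpkm == 0).all()
        assert "zero assigned reads" in caplog.text

    def test_shape_mismatch(self):
        with pytest.raises(ValueError, match="lengths shape"):
            compute_rpkm(np.zeros((2, 2)), np.array([100.0]), np.array([1.0, 1.0]))
        with pytest.raises(ValueError, match="assigned_totals shape"):
            compute_rpkm(np.zeros((2, 2)), np.array([100.0, 100.0]), np.array([1.0]))


class TestIsoformCounting:
    def test_minus_only_reads_have_zero_plus(self, partners_only_cfg, partner_annotation):
        from dataclasses import replace

        annotation, spec = partner_annotation
        ref = build_edited_reference(annotation, [spec])
        cfg = replace(partners_only_cfg, kts_fraction=0.0)
        reads, _ = simulate_kts_junction_reads(cfg, annotation, n_reads=300, error_rate=0.0)
        counts = count_isoform_junctions(reads, ref.junction_panel, flank_w=30)
        assert counts.plus_kts == 0
        assert counts.minus_kts == 300

    def test_mixture_recovery_within_binomial_noise(self, partner_annotation):
        from dataclasses import replace

        annotation, spec = partner_annotation
        ref = build_edited_reference(annotation, [spec])
        cfg = SimConfig(seed=21, n_background_genes=0, kts_fraction=0.7)
        reads, truth = simulate_kts_junction_reads(cfg, annotation, n_reads=1000, error_rate=0.0)
        counts = count_isoform_junctions(reads, ref.junction_panel, flank_w=30)
        assert counts.plus_kts == truth.feature_counts["plusKTS"]
        sd = np.sqrt(1000 * 0.7 * 0.3)
        assert abs(counts.plus_kts - 700) <= 3 * sd
        assert counts.plus_kts + counts.minus_kts + counts.unclassified_junction <= 1000
        assert counts.plus_kts + counts.minus_kts == 1000  # error-free: all classified

    def test_knockdown_preserves_isoform_ratio(self, partner_annotation):
        annotation, spec = partner_annotation
        ref = build_edited_reference(annotation, [spec])
        cfg = SimConfig(seed=8, n_background_genes=0, kts_fraction=0.6)
        full, _ = simulate_kts_junction_reads(cfg, annotation, n_reads=1000, error_rate=0.0)
        knocked, _ = simulate_kts_junction_reads(
            cfg.with_seed(9), annotation, n_reads=250, error_rate=0.0
        )
        c_full = count_isoform_junctions(full, ref.junction_panel, flank_w=30)
        c_kd = count_isoform_junctions(knocked, ref.junction_panel, flank_w=30)
        assert c_kd.plus_kts < c_full.plus_kts
        assert c_kd.minus_kts < c_full.minus_kts
        p, n = 0.6, 250
        assert abs(c_kd.plus_fraction() - p) <= 3 * np.sqrt(p * (1 - p) / n)

    def test_error_at_junction_is_unclassified(self, partner_annotation):
        annotation, spec = partner_annotation
        ref = build_edited_reference(annotation, [spec])
        minus = ref.junction_contig("FUSA|FUSB_minusKTS")
        read = minus.sequence  # 60 nt over the junction
        j = minus.junction_pos
        plus_seq = ref.junction_contig("FUSA|FUSB_plusKTS").sequence
        # corrupt every junction-straddling w-mer by mutating the base just
        # right of the junction
        base = read[j]
        swap = {"A": "C", "C": "A", "G": "T", "T": "G"}[base]
        corrupted = read[:j] + swap + read[j + 1 :]
        counts = count_isoform_junctions([corrupted], ref.junction_panel, flank_w=30)
        assert counts.plus_kts == 0 and counts.minus_kts == 0
        assert counts.unclassified_junction == 1

    def test_missing_isoform_contig_is_config_error(self, partner_annotation):
        annotation, spec = partner_annotation
        ref = build_edited_reference(annotation, [spec])
        panel = [c for c in ref.junction_panel if not c.junction_id.endswith("plusKTS")]
        with pytest.raises(ValueError, match="exactly one diagnostic contig"):
            count_isoform_junctions([], panel, flank_w=30)

    def test_reverse_complement_reads_classified(self, partner_annotation):
        annotation, spec = partner_annotation
        ref = build_edited_reference(annotation, [spec])
        plus = ref.junction_contig("FUSA|FUSB_plusKTS").sequence
        counts = count_isoform_junctions([revcomp(plus)], ref.junction_panel, flank_w=30)
        assert counts.plus_kts == 1


@pytest.fixture(scope="module")
def expr():
    cfg = SimConfig(seed=17, n_background_genes=12, n_pairs=4000)
    annotation, spec = simulate_transcriptome(cfg)
    ref = build_edited_reference(annotation, [spec])
    idx = index_reference(ref)
    sim = simulate_expression(cfg, annotation)
    metas = [m for m in sim.samples if m.shrna in ("sh3", "NT")]
    assigns = {}
    for i, meta in enumerate(metas):
        reads = simulate_reads(
            cfg.with_seed(1000 + i), annotation, sim.abundances[meta.sample_id]
        )
        assigns[meta.sample_id] = assign_reads(reads, idx)
    return ExpressionMatrix.from_assignments(ref, assigns, metas)


class TestKnockdownTimecourse:
    def test_fusion_halves_flagged_decreasing(self, expr):
        tc = knockdown_timecourse(expr, ["FUSA_5p", "FUSB_3p"])
        assert tc["FUSA_5p"].decreasing
        assert tc["FUSB_3p"].decreasing

    def test_nt_series_flat(self, expr):
        tc = knockdown_timecourse(expr, ["FUSB_3p"])
        nt = [p.rpkm for p in tc["FUSB_3p"].points if p.shrna == "NT"]
        assert len(nt) == 3
        assert max(nt) / min(nt) < 1.3  # sampling noise only

    def test_wildtype_3p_partner_5p_half_is_zero(self, expr):
        tc = knockdown_timecourse(expr, ["FUSB_5p"])
        assert all(p.rpkm == 0 for p in tc["FUSB_5p"].points)
        assert not tc["FUSB_5p"].decreasing

    def test_nt_only_matrix_not_flagged(self, expr):
        nt_ids = [s.sample_id for s in expr.samples if s.shrna == "NT"]
        sub = ExpressionMatrix(
            expr.feature_ids,
            expr.lengths,
            [s for s in expr.samples if s.shrna == "NT"],
            expr.counts_frame()[nt_ids].to_numpy(),
            np.array([expr.assigned_totals[expr.sample_index(s)] for s in nt_ids]),
        )
        tc = knockdown_timecourse(sub, ["FUSA_5p"])
        assert not tc["FUSA_5p"].decreasing

    def test_unknown_feature_raises(self, expr):
        with pytest.raises(KeyError, match="NOPE"):
            knockdown_timecourse(expr, ["NOPE"])

    def test_needs_two_timepoints(self, expr):
        one_tp = [s for s in expr.samples if s.timepoint_h == 8.0]
        ids = [s.sample_id for s in one_tp]
        sub = ExpressionMatrix(
            expr.feature_ids,
            expr.lengths,
            one_tp,
            expr.counts_frame()[ids].to_numpy(),
            np.array([expr.assigned_totals[expr.sample_index(s)] for s in ids]),
        )
        with pytest.raises(ValueError, match="two DOX timepoints"):
            knockdown_timecourse(sub, ["FUSA_5p"])


class TestExpressionMatrixIO:
    def test_tsv_round_trip(self, tmp_path, rng):
        features = ["F1", "F2", "F3"]
        samples = [SampleMeta("s1", "sh2", True, 32.0), SampleMeta("s2", "NT", True, 32.0)]
        counts = rng.integers(0, 100, size=(3, 2)).astype(float)
        expr = ExpressionMatrix(
            features, np.array([100.0, 200.0, 300.0]), samples, counts, counts.sum(axis=0)
        )
        expr.to_tsv(tmp_path / "c.tsv", tmp_path / "r.tsv", tmp_path / "m.json")
        back = ExpressionMatrix.from_tsv(tmp_path / "c.tsv", tmp_path / "m.json")
        np.testing.assert_allclose(back.counts, expr.counts)
        np.testing.assert_allclose(back.rpkm, expr.rpkm)
        assert back.samples == samples
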