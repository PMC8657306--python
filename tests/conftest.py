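import numpy as np
import pytest

from fusionkd.reference import Exon, FusionSpec, GeneModel, build_edited_reference
from fusionkd.synthdata import SimConfig, simulate_transcriptome


def make_gene(gene_id: str, exon_seqs, transcript_id: str | None = None) -> GeneModel:
    exons = tuple(Exon(i + 1, s) for i, s in enumerate(exon_seqs))
    return GeneModel(gene_id, transcript_id or f"{gene_id}_T1", exons)


@pytest.fixture
def toy_g5():
    return make_gene("G5", ["AT", "GC"])


@pytest.fixture
def toy_g3():
    return make_gene("G3", ["TT", "AA", "GG"])


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(seed=11, n_background_genes=10, n_pairs=2000)


@pytest.fixture(scope="session")
def partners_only_cfg():
    return SimConfig(seed=5, n_background_genes=0)


@pytest.fixture(scope="session")
def partner_annotation(partners_only_cfg):
    annotation, spec = simulate_transcriptome(partners_only_cfg)
    return annotation, spec


@pytest.fixture(scope="session")
def small_annotation(small_cfg):
    annotation, spec = simulate_transcriptome(small_cfg)
    return annotation, spec


@pytest.fixture(scope="session")
def small_reference(small_annotation):
    annotation, spec = small_annotation
    return build_edited_reference(annotation, [spec], flank_w=30)


@pytest.fixture
def rng():
    return np.random.default_rng(123)
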