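import numpy as np
import pytest

from panelsv.align import AnchorIndex, chain_anchors
from panelsv.detect import DetectorConfig, annotate_te_insertions, classify_svs, flag_complex
from panelsv.simulate import GenomeSpec, PanelSpec, generate_reference, plant_variants


@pytest.fixture(scope="session")
def small_ref():
    spec = GenomeSpec(
        chrom_lengths={"2L": 300_000, "2R": 300_000},
        n_genes=60,
        n_te_families=4,
        te_family_length_range=(500, 2_000),
    )
    return generate_reference(spec, seed=11)


@pytest.fixture(scope="session")
def small_panel(small_ref):
    """A 5-strain panel with ~22 planted SVs and labeled SNPs."""
    panel = PanelSpec(
        n_strains=5,
        sv_rates={"TE_insertion": 8, "duplication": 4, "insertion": 4, "deletion": 4, "inversion": 2},
        snp_spec={"n_syn": 120, "n_nonsyn": 120},
        min_spacing=10_000,
        seed=12,
    )
    genomes, te_ann, truth = plant_variants(small_ref, panel)
    return small_ref, panel, genomes, te_ann, truth


def call_panel(ref, genomes, te_annotations, cfg=None):
    """Align and call every strain against the reference."""
    cfg = cfg or DetectorConfig()
    indexes = {c: AnchorIndex(s, 20, c) for c, s in ref.chromosomes.items()}
    per_strain = {}
    for g in genomes:
        calls = []
        for chrom, seq in g.chromosomes.items():
            anchors = indexes[chrom].anchors(seq, chrom)
            chains, _sec = chain_anchors(anchors, min_anchor_len=40)
            calls += classify_svs(chains, ref, g, cfg)
        calls = annotate_te_insertions(
            calls, te_annotations[g.strain_id], cfg.te_overlap_frac, set(g.chromosomes)
        )
        calls = flag_complex(calls, cfg)
        per_strain[g.strain_id] = sorted(calls, key=lambda c: (c.ref_chrom, c.ref_start))
    return per_strain


@pytest.fixture(scope="session")
def panel_calls(small_panel):
    ref, panel, genomes, te_ann, _truth = small_panel
    return call_panel(ref, genomes, te_ann)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
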