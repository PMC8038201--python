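import pytest

import secretomics as sx


@pytest.fixture(scope="session")
def default_proteome():
    """Default synthetic proteome: 48 runs, truth, and the aPSM matrix."""
    runs, truth = sx.generate_psm_runs(sx.ProteomeDesign(seed=0))
    matrix = sx.build_apsm_matrix(runs)
    return runs, truth, matrix


@pytest.fixture(scope="session")
def default_mirna():
    """Default synthetic miRNA read pools, QC-filtered and UMI-collapsed."""
    design = sx.MirnaDesign(seed=0)
    pools, samples, truth = sx.generate_mirna_reads(design)
    kept = {s: sx.qc_filter(p)[0] for s, p in pools.items()}
    matrix = sx.umi_collapse(kept, samples=samples)
    return design, pools, samples, truth, matrix


@pytest.fixture
def tiny_runs():
    """Two hand-built runs in one condition plus one in another."""
    mk = sx.synthetic_data.PsmRunTable
    return [
        mk(run_id="c1_b1t1", condition="c1", bio_replicate=1, tech_replicate=1,
           counts={"A": 3, "B": 5}),
        mk(run_id="c1_b1t2", condition="c1", bio_replicate=1, tech_replicate=2,
           counts={"A": 5, "C": 2}),
        mk(run_id="c2_b1t1", condition="c2", bio_replicate=1, tech_replicate=1,
           counts={"B": 4}),
    ]
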