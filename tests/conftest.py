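import pytest

from protlift import pipeline, synthetic


@pytest.fixture(scope="session")
def default_world():
    """One instance of every scenario, plus non-coding passthrough genes."""
    return synthetic.make_world(synthetic.default_specs(1),
                                include_noncoding=True)


@pytest.fixture(scope="session")
def default_run(default_world):
    w = default_world
    return pipeline.run_objects(w.ref_genome, w.ref_db, w.target_genome,
                                w.dna_db, w.prot_db,
                                pipeline.RunConfig(copies=True))


@pytest.fixture(scope="session")
def truth_by_tx(default_world):
    return {t.transcript_id: t for t in default_world.truth}
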