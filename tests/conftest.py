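import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from zgene import classifier as clf
from zgene import gene_caller, orf_model, synthetic, zcurve

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def truth_stop_keys(truth):
    """3'-terminus keys of an annotation list (1-based convention)."""
    return {
        (r.contig_id, r.strand, r.end if r.strand == "+" else r.start)
        for r in truth
    }


def orf_stop_key(orf):
    """3'-terminus key of an OrfCandidate in the 1-based convention."""
    return (
        orf.contig_id,
        orf.strand,
        orf.end if orf.strand == "+" else orf.start + 1,
    )


def random_orf_seq(rng, n_codons=60):
    """A syntactically valid ORF: ATG + random sense codons + stop."""
    codons = rng.choice(synthetic.SENSE_CODONS, size=n_codons - 2)
    return "ATG" + "".join(codons) + "TAA"


@pytest.fixture(scope="session")
def synth_main():
    """The reference study conditions: 200 kb, 150 planted genes, bias 0.5."""
    return synthetic.generate_genome(synthetic.SyntheticGenomeSpec(seed=1))


@pytest.fixture(scope="session")
def pipeline_main(synth_main):
    """Full pipeline state on the reference genome (seed 1), shared across
    tests to keep the suite fast."""
    g = synth_main
    config = gene_caller.CallerConfig(seed=1)
    orfs = orf_model.extract_orfs(g.genome)
    encodings = zcurve.encode_many([o.seq for o in orfs])
    model = gene_caller.train_model([g.genome], config, orfs=orfs, encodings=encodings)
    predictions = gene_caller.predict_genes([g.genome], config, model=model)
    return {
        "synth": g,
        "config": config,
        "orfs": orfs,
        "encodings": encodings,
        "model": model,
        "predictions": predictions,
    }


@pytest.fixture(scope="session")
def training_sets_main(pipeline_main):
    return clf.build_training_sets(pipeline_main["orfs"], seed=1)
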