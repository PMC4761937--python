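import numpy as np
import pandas as pd
import pytest

from translatome import reference, synthetic


@pytest.fixture(scope="session")
def toy_records():
    return synthetic.generate_toy_transcriptome(
        20, paralog_pairs=2, utr_edge_cases=True, seed=3
    )


@pytest.fixture(scope="session")
def toy_models(toy_records):
    return [reference.assemble_transcript(r) for r in toy_records]


@pytest.fixture(scope="session")
def toy_genes(toy_models):
    return reference.build_gene_models(toy_models)


@pytest.fixture(scope="session")
def toy_seqs(toy_models):
    return {m.transcript_id: m.full_seq for m in toy_models}


@pytest.fixture(scope="session")
def toy_reads(toy_seqs):
    abundance = pd.Series(
        np.random.default_rng(0).uniform(1, 10, len(toy_seqs)), index=list(toy_seqs)
    )
    return synthetic.generate_reads(
        toy_seqs, abundance, 2000, contaminant_frac=0.1, seed=4
    )


@pytest.fixture(scope="session")
def small_study():
    cfg = synthetic.StudyConfig(n_genes=2000, rng_seed=7)
    return synthetic.generate_expression_study(cfg)
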