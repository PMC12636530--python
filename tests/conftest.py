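import numpy as np
import pytest

import bridgesyn as bs
from bridgesyn.model import ModelConfig


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small synthetic dataset shared by model-level tests."""
    cfg = bs.SynthConfig(n_drugs=10, n_cells=4, n_genes=40,
                         n_gene_modules=4, tokens_per_drug=4,
                         d_in=8, d_p=6, n_triplets=120, seed=7)
    dataset, truth = bs.gen_dataset(cfg)
    return dataset, truth, cfg


@pytest.fixture(scope="session")
def tiny_pipeline(tiny_dataset):
    dataset, _, _ = tiny_dataset
    return bs.FeaturePipeline(dataset, ccf=bs.CCFConfig(k=3, n_clusters=4))


@pytest.fixture(scope="session")
def tiny_model(tiny_pipeline):
    """An untrained model at very small width for fast forward passes."""
    cfg = ModelConfig.small(tiny_pipeline.drug_width,
                            tiny_pipeline.cell_width, seed=3)
    cfg.d = 16
    cfg.fusion.n_heads = 2
    model = bs.BridgeSynModel(cfg)
    model.eval()
    return model
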