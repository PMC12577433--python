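import warnings

import pytest

from textora import TrainConfig, train
from textora.corpus import DescriptionRecord, PhraseLexicon
from textora.synthetic import SyntheticSpec, generate_corpus

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture()
def toy_records():
    """A tiny hand-written corpus exercising phrases, casing and synonyms."""
    return [
        DescriptionRecord(
            "BRAF", "refseq",
            "This oncogene activates the unfolded protein response. "
            "Mutations cause noonan syndrome. Binds Ca2+.",
        ),
        DescriptionRecord(
            "RAF1", "refseq",
            "A kinase related to known oncogenes. Associated with noonan syndrome.",
        ),
        DescriptionRecord(
            "EGFR", "uniprot",
            "Receptor kinase that binds DNA. It signals downstream.",
        ),
    ]


@pytest.fixture()
def toy_lexicon():
    return PhraseLexicon(
        phrases={
            ("unfolded", "protein", "response"),
            ("protein", "response"),
            ("noonan", "syndrome"),
        }
    )


@pytest.fixture(scope="session")
def planted():
    """Default planted corpus (5 modules x 20 genes, 3 markers) and its model."""
    spec = SyntheticSpec(seed=1)
    records, truth = generate_corpus(spec)
    model = train(records)
    return spec, records, truth, model


@pytest.fixture(scope="session")
def null_small():
    """A small structure-free corpus and model for calibration properties."""
    spec = SyntheticSpec(
        n_genes=400, n_modules=0, genes_per_module=0, background_vocab_size=800, seed=3
    )
    records, truth = generate_corpus(spec)
    model = train(records)
    return spec, records, truth, model
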