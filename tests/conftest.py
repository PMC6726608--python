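import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from evicalib import (
    GeneSpec,
    PredictorModel,
    SimConfig,
    default_study_config,
    generate_variant_table,
)


def single_gene_config(
    beta0: float,
    beta1: float,
    n: int,
    prevalence: float = 0.5,
    sd: float = 0.6,
    seed: int = 0,
    predictor: str = "metasvm",
    gene: str = "GENE1",
) -> SimConfig:
    """One gene, one unbounded predictor with a known logistic law."""
    model = PredictorModel(beta0=beta0, beta1=beta1, sd=sd)
    return SimConfig(
        genes=(
            GeneSpec(
                symbol=gene,
                n_variants=n,
                prevalence=prevalence,
                predictors={predictor: model},
                anchor=predictor,
            ),
        ),
        missingness={predictor: 0.0},
        seed=seed,
    )


@pytest.fixture(scope="session")
def study_variants():
    """The default 20-gene cohort (2,153 variants), fixed seed."""
    return generate_variant_table(default_study_config(seed=11))
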