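import numpy as np
import pandas as pd
import pytest

from dyadgwas import GenotypeDataset, Variant


@pytest.fixture
def tiny_dataset() -> GenotypeDataset:
    """Four samples x three SNPs with one missing genotype."""
    variants = [
        Variant("rs1", "1", 100, "G", "A"),
        Variant("rs2", "1", 2000, "C", "T"),
        Variant("rs3", "2", 500, "C", "A", gene="PPARG"),
    ]
    dosage = np.array([
        [0.0, 1.0, 2.0],
        [1.0, 0.0, 0.0],
        [2.0, np.nan, 1.0],
        [0.0, 2.0, 0.0],
    ])
    return GenotypeDataset(
        variants=variants,
        samples=["s1", "s2", "s3", "s4"],
        dosage=dosage,
        phenotype=np.array([1, 0, 1, 0]),
        covariates=pd.DataFrame({"sex": [1.0, 2.0, 1.0, 2.0]}),
    )
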