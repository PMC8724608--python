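import numpy as np
import pytest

from glycodia.chem import Glycopeptide, ModifiedPeptide, parse_glycan
from glycodia import simulate


@pytest.fixture(scope="session")
def worked_glycopeptides():
    """The three reference glycopeptides with recorded observations:
    (glycopeptide, charge, observed m/z, expected ppm error)."""
    return [
        (
            Glycopeptide(
                ModifiedPeptide("VITGVPWYSSR", protein_accession="P43575"),
                parse_glycan("Hex6"),
                "O",
                site=9,
            ),
            3,
            746.3205,
            -17.15,
        ),
        (
            Glycopeptide(
                ModifiedPeptide("VNLVELGVYVSDIR", protein_accession="PAU1-24"),
                parse_glycan("Hex2"),
                "O",
                site=11,
            ),
            2,
            950.4798,
            -14.42,
        ),
        (
            Glycopeptide(
                ModifiedPeptide("VVRPppTpKPpT", protein_accession="NP_001268136.1"),
                parse_glycan("Pent6"),
                "O",
                site=5,
            ),
            3,
            714.6610,
            -12.74,
        ),
    ]


@pytest.fixture()
def noiseless_config():
    return simulate.default_config(
        seed=11, cv=0.0, ppm_mean=0.0, ppm_sd=0.0, dropout=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20200501)
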