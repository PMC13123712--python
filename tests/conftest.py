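import numpy as np
import pandas as pd
import pytest

from guildshift.tables import RANKS, CountTable


@pytest.fixture
def tiny_counts() -> CountTable:
    """Four samples x three taxa with a genus-level taxonomy."""
    data = pd.DataFrame(
        [[5, 0, 10], [3, 7, 2], [8, 1, 4], [2, 2, 4]],
        index=["S1", "S2", "S3", "S4"],
        columns=["asv1", "asv2", "asv3"],
    )
    taxonomy = pd.DataFrame(
        {
            "kingdom": ["Bacteria"] * 3,
            "phylum": ["Bacillota", "Bacillota", "Actinomycetota"],
            "class": [None] * 3,
            "order": [None] * 3,
            "family": ["Peptoniphilaceae", "Peptoniphilaceae", "Bifidobacteriaceae"],
            "genus": ["Peptoniphilus", "Peptoniphilus", "Gardnerella"],
        },
        index=pd.Index(["asv1", "asv2", "asv3"], name="taxon_id"),
    )[list(RANKS)]
    return CountTable(data, taxonomy=taxonomy)


@pytest.fixture
def tiny_metadata() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3", "S4"],
            "cohort": ["pediatric"] * 4,
            "subject_id": ["P1", "P2", "P3", "P4"],
            "timepoint": ["pre"] * 4,
            "indication": ["elective", "elective", "pathological_phimosis", "none"],
            "age_years": [8.5, 3.0, 12.0, 6.0],
            "ethnicity": ["caucasian", "asian", "caucasian", "other"],
            "dna_conc": [0.8, 1.2, 0.5, np.nan],
            "is_negative_control": [False, False, False, False],
        }
    )
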