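import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from nullsnp.io_formats import META_COLUMNS, GenotypeMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def make_genotype_matrix(columns, individual_ids=None) -> GenotypeMatrix:
    """Build a GenotypeMatrix from {snp_id: score list} (NaN = missing)."""
    snp_ids = list(columns)
    scores = np.column_stack([np.asarray(columns[s], dtype=float) for s in snp_ids])
    n = scores.shape[0]
    if individual_ids is None:
        individual_ids = [f"I{i + 1:03d}" for i in range(n)]
    meta = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": "1",
            "pos": np.arange(1, len(snp_ids) + 1) * 100,
            "ref_allele": "A",
            "alt_allele": "G",
            "counted_allele": "G",
        },
        columns=META_COLUMNS,
    )
    return GenotypeMatrix(scores=scores, individual_ids=np.array(individual_ids, dtype=object), snp_meta=meta)


@pytest.fixture
def tiny_panel():
    """Small covariate-driven null panel for pipeline tests."""
    from nullsnp.synthetic_data import make_null_panel

    return make_null_panel(n=60, m=40, seed=11)
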