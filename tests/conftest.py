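import numpy as np
import pandas as pd
import pytest

from soilweb import AbundanceTable


def make_table(values: np.ndarray, taxa=None, samples=None, stages=None,
               subgroups=None, main_groups=None) -> AbundanceTable:
    """Assemble a valid AbundanceTable from a raw matrix with defaults."""
    values = np.asarray(values, dtype=float)
    n_taxa, n_samples = values.shape
    taxa = taxa or [f"t{i}" for i in range(n_taxa)]
    samples = samples or [f"s{j}" for j in range(n_samples)]
    stages = stages or ["recent"] * n_samples
    subgroups = subgroups or ["g0"] * n_taxa
    main_groups = main_groups or subgroups
    taxon_meta = pd.DataFrame({
        "subgroup": subgroups,
        "main_group": main_groups,
        "trophic_function": ["unknown"] * n_taxa,
    }, index=pd.Index(taxa, name="taxon_id"))
    sample_meta = pd.DataFrame({
        "site": [f"SITE{j}" for j in range(n_samples)],
        "subplot": [1] * n_samples,
        "stage": stages,
    }, index=pd.Index(samples, name="sample_id"))
    return AbundanceTable(
        values=pd.DataFrame(values, index=taxa, columns=samples),
        taxon_meta=taxon_meta, sample_meta=sample_meta)


@pytest.fixture
def four_taxon_table() -> AbundanceTable:
    """One perfectly correlated taxon pair among four taxa, one stage.

    Spearman: rho(t0,t1) = 1; all other pairs stay below 0.9.
    """
    return make_table(
        np.array([
            [1.0, 2.0, 3.0, 4.0],
            [2.0, 4.0, 6.0, 8.0],
            [4.0, 3.0, 2.0, 2.0],
            [1.0, 3.0, 2.0, 4.0],
        ]),
        subgroups=["A", "A", "B", "B"],
    )
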