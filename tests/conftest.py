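import numpy as np
import pandas as pd
import pytest

from slcfuncmap import OntologyGraph


@pytest.fixture
def toy_graph() -> OntologyGraph:
    """Small fixed ontology exercising every relation type.

    taurine —is_a→ amino_sulfonic_acid —is_a→ root ←is_a— sugar ←is_a— glucose;
    citrate —is_conjugate_base_of— citric_acid (citric_acid —is_a→ root);
    taurine —has_role→ osmolyte (osmolyte —is_a→ root).
    """
    terms = {
        "root", "amino_sulfonic_acid", "taurine", "sugar", "glucose",
        "citrate", "citric_acid", "osmolyte",
    }
    edges = {
        ("amino_sulfonic_acid", "is_a", "root"),
        ("taurine", "is_a", "amino_sulfonic_acid"),
        ("sugar", "is_a", "root"),
        ("glucose", "is_a", "sugar"),
        ("citric_acid", "is_a", "root"),
        ("citrate", "is_conjugate_base_of", "citric_acid"),
        ("osmolyte", "is_a", "root"),
        ("taurine", "has_role", "osmolyte"),
    }
    return OntologyGraph(terms=terms, edges=edges, labels={t: t for t in terms})


def random_labeling(rng: np.random.Generator, n_items: int, k: int) -> pd.Series:
    """Random item→cluster assignment used by coherence tests."""
    return pd.Series(
        rng.integers(1, k + 1, n_items), index=[f"i{j}" for j in range(n_items)]
    )
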