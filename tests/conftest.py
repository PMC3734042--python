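import numpy as np
import pytest

from mirimpact.io import ExpressionMatrix


def make_expr(case_rows, control_rows, feature_ids=None):
    """Build a small ExpressionMatrix from per-feature case/control values."""
    case_rows = np.atleast_2d(np.asarray(case_rows, float))
    control_rows = np.atleast_2d(np.asarray(control_rows, float))
    n_feat = case_rows.shape[0]
    values = np.hstack([case_rows, control_rows])
    if feature_ids is None:
        feature_ids = [f"f{i}" for i in range(n_feat)]
    samples = [f"c{i}" for i in range(case_rows.shape[1])] + [
        f"k{i}" for i in range(control_rows.shape[1])
    ]
    groups = {s: ("case" if s.startswith("c") else "control") for s in samples}
    return ExpressionMatrix(list(feature_ids), samples, values, groups)


@pytest.fixture
def expr_factory():
    return make_expr


@pytest.fixture(scope="session")
def null_study():
    """A no-effect synthetic study shared across read-only tests."""
    from mirimpact.simulate import SimulationConfig, generate_study

    cfg = SimulationConfig(
        n_gene=2000,
        n_mirna=100,
        n_de_mirna=0,
        n_de_gene_independent=0,
        repression_transfer_max=0.0,
        n_go_terms=20,
        n_enriched_terms=0,
        seed=101,
    )
    return generate_study(cfg)


@pytest.fixture(scope="session")
def planted_study():
    """A small study with planted miRNA down-regulation and de-repression."""
    from mirimpact.simulate import SimulationConfig, generate_study

    cfg = SimulationConfig(
        n_gene=2000,
        n_mirna=20,
        n_de_mirna=8,
        n_de_gene_independent=100,
        repression_transfer_max=0.5,
        targets_per_mirna_mean=100,
        n_go_terms=20,
        n_enriched_terms=2,
        go_term_size_range=(10, 40),
        seed=202,
    )
    return generate_study(cfg)
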