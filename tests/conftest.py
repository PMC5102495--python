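import pytest
from hypothesis import settings

from bovig import SimConfig, make_toy_germline_db, simulate_repertoire

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


CLEAN = dict(
    mutation_rate=0.0,
    junction_trim_range=(0, 0),
    conversion={"prob": 0.0},
    qc_defect_probs={"premature_stop": 0.0, "truncation": 0.0},
)


@pytest.fixture(scope="session")
def toy_db():
    """Small prepared germline database shared across tests."""
    cfg = SimConfig(seed=42, n_v_functional=6, n_v_pseudo=3, identical_v_pairs=1,
                    n_d=5, n_j=2, **CLEAN)
    return make_toy_germline_db(cfg)


@pytest.fixture(scope="session")
def clean_repertoire(toy_db):
    """60 mutation-free, defect-free records with ground truth."""
    cfg = SimConfig(seed=42, n_v_functional=6, n_v_pseudo=3, identical_v_pairs=1,
                    n_d=5, n_j=2, groups=("A",), n_records_per_group=60,
                    antisense_d_prob=0.25, **CLEAN)
    records, truths = simulate_repertoire(toy_db, cfg)
    return records, truths
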