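import numpy as np
import pytest
from hypothesis import settings

from mycomediate.io_model import read_inputs
from mycomediate.synthetic_data import SyntheticTruth, generate

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

_PLOTS = """\
plot_id\tspecies_id\tstratum\tbb_code
P1\tW1\twoody\t4
P1\tH1\therbaceous\t2m
P1\tH2\therbaceous\t+
P2\tW1\twoody\t3
P2\tW2\twoody\t2a
P2\tH1\therbaceous\t1
P2\tH3\therbaceous\tr
P3\tW2\twoody\t5
P3\tH2\therbaceous\t2b
P3\tH1\therbaceous\t+
"""

_TRAITS = """\
species_id\tlife_form\tmyc_status\tellenberg_R\tellenberg_N\tellenberg_F
W1\twoody\tNON_AM\t5\t6\tx
W2\twoody\tAM_MIXED\t7\t\t5
H1\therbaceous\tAM_ONLY\t6\t7\t6
H2\therbaceous\tNON_AM\tx\t4\t5
H3\therbaceous\tUNKNOWN\t3\t3\t3
"""

_META = """\
plot_id\tx\ty\tarea\tforest_id\tmeasured_ph
P1\t0\t0\t200\tF1\t4.8
P2\t100\t50\t100\tF1\t
P3\t5000\t4000\t400\tF2\t5.6
"""


@pytest.fixture
def toy_paths(tmp_path):
    paths = {}
    for name, text in [("plots", _PLOTS), ("traits", _TRAITS), ("meta", _META)]:
        p = tmp_path / f"{name}.tsv"
        p.write_text(text)
        paths[name] = p
    return paths


@pytest.fixture
def toy_bundle(toy_paths):
    return read_inputs(toy_paths["plots"], toy_paths["traits"], toy_paths["meta"])


@pytest.fixture(scope="session")
def small_truth():
    """Down-scaled study conditions for fast pipeline-level tests."""
    return SyntheticTruth(seed=11, n_plots=150, n_forests=30, n_ph_plots=60)


@pytest.fixture(scope="session")
def small_bundle(small_truth):
    return generate(small_truth)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
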