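import io

import pytest
from hypothesis import HealthCheck, settings

import textfunc as tf

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

TINY_OBO = """format-version: 1.2
ontology: tiny

[Term]
id: GO:0000001
name: root
namespace: molecular_function

[Term]
id: GO:0000010
name: binding
namespace: molecular_function
alt_id: GO:0000099
is_a: GO:0000001 ! root

[Term]
id: GO:0000011
name: catalytic activity
namespace: molecular_function
is_a: GO:0000001 ! root

[Term]
id: GO:0000020
name: ion binding
namespace: molecular_function
is_a: GO:0000010 ! binding

[Term]
id: GO:0000021
name: catalytic ion binding
namespace: molecular_function
is_a: GO:0000010 ! binding
is_a: GO:0000011 ! catalytic activity

[Term]
id: GO:0000030
name: deep leaf
namespace: molecular_function
is_a: GO:0000021 ! catalytic ion binding

[Term]
id: GO:0000066
name: gone
namespace: molecular_function
is_obsolete: true
"""


@pytest.fixture(scope="session")
def tiny_graph():
    return tf.parse_obo(io.StringIO(TINY_OBO))


@pytest.fixture(scope="session")
def default_dataset():
    """The default synthetic fixture: 5 classes x 100 proteins."""
    return tf.generate(tf.SynthConfig(seed=1))


@pytest.fixture(scope="session")
def small_dataset():
    """A fast fixture for pipeline-level tests."""
    return tf.generate(
        tf.SynthConfig(
            n_classes=3,
            proteins_per_class=25,
            vocab_size=400,
            planted_terms_per_class=5,
            multi_label_fraction=0.0,
            seq_length=80,
            seed=7,
        )
    )
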