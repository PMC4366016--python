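import pytest

from ontosieve.lexicon_io import RawConcept, build_profiles
from ontosieve.synthetic_fixtures import FixtureSpec, make_ontology

OBO_SAMPLE = """\
format-version: 1.2

[Term]
id: GO:0000010
name: trans-hexaprenyltranstransferase activity
synonym: "all-trans-heptaprenyl-diphosphate synthase activity" EXACT []
synonym: "HepPP synthase activity" RELATED []
synonym: "heptaprenyl pyrophosphate synthase activity" EXACT []
synonym: "heptaprenyl pyrophosphate synthetase activity" RELATED []
synonym: "hexaprenyl pyrophosphate synthetase" NARROW []

[Term]
id: GO:0000011
name: vacuole inheritance

[Term]
id: GO:0000012
name: obsolete thing
is_obsolete: true
"""


@pytest.fixture
def obo_file(tmp_path):
    path = tmp_path / "sample.obo"
    path.write_text(OBO_SAMPLE, encoding="utf-8")
    return path


@pytest.fixture
def toy_concepts():
    """Hand-built GO-flavoured lexicon: 'activity' saturates most labels,
    'adenine' is moderately frequent, 'aminase' rare."""
    labels = [
        ("GO:0000034", "adenine aminase activity"),
        ("GO:0000035", "adenine deaminase activity"),
        ("GO:0000036", "guanine hydrolase activity"),
        ("GO:0000037", "cytosine transport activity"),
        ("GO:0000038", "thymine kinase activity"),
        ("GO:0000039", "uracil binding activity"),
        ("GO:0000040", "purine salvage"),
        ("GO:0000041", "pyrimidine catabolism"),
    ]
    return [RawConcept(cid, (label,)) for cid, label in labels]


@pytest.fixture
def toy_profiles(toy_concepts):
    return build_profiles(toy_concepts)


@pytest.fixture(scope="session")
def suffix_spec():
    """The planted-suffix fixture used by the headline pipeline property."""
    return FixtureSpec(
        n_concepts=150,
        vocab_size=400,
        zipf_exponent=0.5,
        suffix_prevalence=0.8,
        seed=7,
        docs=5,
        mentions_per_doc=4,
    )


@pytest.fixture(scope="session")
def suffix_concepts(suffix_spec):
    return make_ontology(suffix_spec)


@pytest.fixture(scope="session")
def case_spec():
    return FixtureSpec(
        n_concepts=80,
        vocab_size=400,
        zipf_exponent=0.5,
        cs_fraction=0.5,
        seed=3,
        docs=4,
        mentions_per_doc=3,
    )


@pytest.fixture(scope="session")
def case_concepts(case_spec):
    return make_ontology(case_spec)
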