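import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from glycolit import Dictionary, Entry

#: The ten synonyms of Neoplasm (MONDO:0005070) used as a polymorphism fixture.
NEOPLASM_SYNONYMS = [
    "neoplasm",
    "cell process disease",
    "tumor disease",
    "tumor",
    "tumour disease",
    "neoplastic growth",
    "tumour",
    "neoplastic disease",
    "disease of cellular proliferation",
    "neoplasia",
]

TOY_OBO = """format-version: 1.2
ontology: toy

[Term]
id: D:0
name: disease

[Term]
id: D:1
name: colon carcinoma
synonym: "carcinoma of colon" EXACT []
is_a: D:0

[Term]
id: D:2
name: melanoma
is_a: D:0

[Term]
id: D:3
name: obsolete thing
is_obsolete: true
is_a: D:0

[Term]
id: X:9
name: sibling branch

[Term]
id: X:10
name: excluded leaf
is_a: X:9
"""


@pytest.fixture
def neoplasm_dict() -> Dictionary:
    d = Dictionary("MONDO")
    for label in NEOPLASM_SYNONYMS:
        d.add_entry(Entry(label, "MONDO:0005070"))
    return d


@pytest.fixture
def glycan_dict() -> Dictionary:
    return Dictionary(
        "Glycan",
        entries=[
            Entry("sialyl Lewis x", "Glycan:G00054MO"),
            Entry("sialyl Lewis A", "Glycan:GSYN0001A"),
            Entry("Lewis x", "Glycan:GSYN0002X"),
            Entry("GM1", "Glycan:G48558GR"),
        ],
    )


@pytest.fixture
def toy_obo() -> str:
    return TOY_OBO
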