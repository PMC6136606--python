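import pytest

import labsafescore as ls

MINIMAL_SCHEMA = """\
schema: questionnaire-taxonomy
schema_version: 1
name: mini
version: "1"
areas:
- id: a
  name: Area A
  categories:
  - id: a.c
    name: Cat C
    subcategories:
    - id: a.c.1
      name: Sub 1
      guidance: check the logbook
      rubric:
        1: basic practice
        2: better practice
        3: good practice
        4: optimal practice
"""

TINY_SCHEMA = """\
schema: questionnaire-taxonomy
schema_version: 1
name: tiny
version: "1"
areas:
- id: alpha
  name: Alpha
  categories:
  - id: alpha.one
    name: One
    subcategories:
    - {id: alpha.one.1, name: s11, rubric: {1: p1, 2: p2, 3: p3, 4: p4}}
    - {id: alpha.one.2, name: s12, rubric: {1: p1, 2: p2, 3: p3, 4: p4}}
  - id: alpha.two
    name: Two
    subcategories:
    - {id: alpha.two.1, name: s21, rubric: {1: p1, 2: p2, 3: p3, 4: p4}}
    - {id: alpha.two.2, name: s22, rubric: {1: p1, 2: p2, 3: p3, 4: p4}}
    - {id: alpha.two.3, name: s23, rubric: {1: p1, 2: p2, 3: p3, 4: p4}}
- id: beta
  name: Beta
  categories:
  - id: beta.one
    name: BOne
    subcategories:
    - {id: beta.one.1, name: t11, rubric: {1: p1, 2: p2, 3: p3, 4: p4}}
    - {id: beta.one.2, name: t12, rubric: {1: p1, 2: p2, 3: p3, 4: p4}}
"""


@pytest.fixture(scope="session")
def taxonomy():
    return ls.builtin_lmt_s()


@pytest.fixture(scope="session")
def tiny():
    return ls.parse_taxonomy(TINY_SCHEMA)


@pytest.fixture(scope="session")
def minimal_schema_text():
    return MINIMAL_SCHEMA


def uniform_assessment(taxonomy, level, label="uniform"):
    return ls.Assessment.from_levels(
        {sid: level for sid in taxonomy.subcategory_ids()}, label=label)


@pytest.fixture(scope="session")
def all4(taxonomy):
    return uniform_assessment(taxonomy, 4, label="all4")


@pytest.fixture(scope="session")
def all1(taxonomy):
    return uniform_assessment(taxonomy, 1, label="all1")
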