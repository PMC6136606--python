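import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import labsafescore as ls
from labsafescore.errors import SchemaParseError, TaxonomyValidationError
from labsafescore.taxonomy import (Area, Category, RubricLevel, Subcategory,
                                   Taxonomy)

# per-category subcategory counts of the built-in instrument
EXPECTED_COUNTS = {
    "administration": {"General": 5, "Personnel health and safety": 4,
                       "Training and competency": 4,
                       "Biosafety manual/Standard operating procedures (SOPs)": 2},
    "operations": {"Good lab practices": 7, "Containment": 6,
                   "Containment BSL3": 8, "Waste disposal": 5,
                   "Shipping of infectious substances": 5,
                   "Animal facilities": 7},
    "engineering": {"Premises": 7, "Chemical hazard containment": 6,
                    "Chemical security": 4, "Emergencies": 4,
                    "Fire hazard": 4, "Electrical": 4,
                    "Biological safety cabinet (BSC)": 3},
    "ppe": {"General situation": 4, "Use of PPE": 4, "PPE disposal": 5},
}


class TestBuiltin:
    def test_shape(self, taxonomy):
        assert len(taxonomy.areas) == 4
        assert len(taxonomy.categories) == 20
        assert taxonomy.n_subcategories == 98

    def test_per_category_counts(self, taxonomy):
        for area_id, cats in EXPECTED_COUNTS.items():
            area = taxonomy.area(area_id)
            names = {taxonomy.category(cid).name: len(
                taxonomy.category(cid).subcategory_ids)
                for cid in area.category_ids}
            assert names == cats

    def test_counts_sum_to_total(self, taxonomy):
        total = sum(len(c.subcategory_ids) for c in taxonomy.categories)
        assert total == taxonomy.n_subcategories == 98

    def test_operations_has_six_categories(self, taxonomy):
        assert len(taxonomy.area("operations").category_ids) == 6

    def test_containment_bsl3_count(self, taxonomy):
        cat = taxonomy.find_category("Containment BSL3")
        assert len(cat.subcategory_ids) == 8

    def test_glove_rubric_is_the_published_exemplar(self, taxonomy):
        sub = taxonomy.subcategory("ppe.use_of_ppe.1")
        assert sub.name == "Disposable glove usage"
        assert "disposable gloves may be washed and reused" in sub.practice(1)
        assert sub.practice(2).startswith(
            "Gloves are required whenever handling potentially "
            "toxic/infectious materials")
        assert "are not reused" in sub.practice(4)
        assert sub.guidance  # the exemplar ships with assessor guidance

    def test_placeholders_are_labelled(self, taxonomy):
        sub = taxonomy.subcategory("administration.general.1")
        assert "placeholder" in sub.practice(1)

    def test_builtin_validates_clean(self, taxonomy):
        assert ls.validate_taxonomy(taxonomy) == []

    def test_instrument_order_is_stable(self, taxonomy):
        ids = taxonomy.subcategory_ids()
        assert ids[0] == "administration.general.1"
        assert ids[-1] == "ppe.ppe_disposal.5"
        assert len(ids) == len(set(ids))


class TestLoad:
    def test_minimal_schema(self, minimal_schema_text):
        t = ls.parse_taxonomy(minimal_schema_text)
        assert (len(t.areas), len(t.categories), t.n_subcategories) == (1, 1, 1)
        assert t.subcategory("a.c.1").guidance == "check the logbook"

    def test_load_from_file(self, tmp_path, minimal_schema_text):
        p = tmp_path / "mini.yaml"
        p.write_text(minimal_schema_text)
        t = ls.load_taxonomy(p)
        assert t.name == "mini"

    def test_missing_rubric_level_names_node_and_level(
            self, minimal_schema_text):
        broken = minimal_schema_text.replace("        4: optimal practice\n",
                                             "")
        with pytest.raises(TaxonomyValidationError) as exc:
            ls.parse_taxonomy(broken)
        (finding,) = exc.value.findings
        assert finding.rule == "missing-rubric-level"
        assert "a.c.1" in finding.path
        assert "4" in finding.message

    def test_not_yaml(self):
        with pytest.raises(SchemaParseError):
            ls.parse_taxonomy("{unclosed: [")

    def test_wrong_schema_name(self, minimal_schema_text):
        with pytest.raises(SchemaParseError, match="schema"):
            ls.parse_taxonomy(minimal_schema_text.replace(
                "questionnaire-taxonomy", "other-schema"))

    def test_missing_key_reports_path(self):
        doc = "schema: questionnaire-taxonomy\nschema_version: 1\nname: x\n"
        with pytest.raises(SchemaParseError, match="version"):
            ls.parse_taxonomy(doc)

    @pytest.mark.parametrize("schema_text_fixture",
                             ["minimal_schema_text"])
    def test_round_trip_identity(self, request, schema_text_fixture):
        t = ls.parse_taxonomy(request.getfixturevalue(schema_text_fixture))
        assert ls.parse_taxonomy(ls.dump_taxonomy(t)) == t

    def test_builtin_round_trip(self, taxonomy):
        assert ls.parse_taxonomy(ls.dump_taxonomy(taxonomy)) == taxonomy


def _sub(sid, cid):
    return Subcategory(
        id=sid, name=f"sub {sid}", category_id=cid,
        rubric=tuple(RubricLevel(k, f"practice {k}") for k in (1, 2, 3, 4)))


def _small_taxonomy():
    subs = [_sub("a.c.1", "a.c"), _sub("a.c.2", "a.c")]
    cats = [Category(id="a.c", name="C", area_id="a",
                     subcategory_ids=("a.c.1", "a.c.2"))]
    areas = [Area(id="a", name="A", category_ids=("a.c",))]
    return Taxonomy(name="t", version="1", areas=areas, categories=cats,
                    subcategories=subs)


class TestValidate:
    def test_valid(self):
        assert ls.validate_taxonomy(_small_taxonomy()) == []

    def test_duplicate_subcategory_id(self):
        t = _small_taxonomy()
        t.subcategories.append(_sub("a.c.1", "a.c"))
        rules = {f.rule for f in ls.validate_taxonomy(t)}
        assert "duplicate-id" in rules

    def test_dangling_area_reference(self):
        t = _small_taxonomy()
        t.categories[0] = dataclasses.replace(t.categories[0],
                                              area_id="nowhere")
        findings = ls.validate_taxonomy(t)
        assert any(f.rule == "dangling-reference"
                   and f.path == "category/a.c" for f in findings)

    def test_dangling_subcategory_reference(self):
        t = _small_taxonomy()
        t.categories[0] = dataclasses.replace(
            t.categories[0], subcategory_ids=("a.c.1", "a.c.2", "ghost"))
        findings = ls.validate_taxonomy(t)
        assert any(f.rule == "dangling-reference" and "ghost" in f.message
                   for f in findings)

    def test_orphan_subcategory(self):
        t = _small_taxonomy()
        t.subcategories.append(_sub("a.c.3", "a.c"))
        assert any(f.rule == "orphan" and "a.c.3" in f.path
                   for f in ls.validate_taxonomy(t))

    def test_empty_category(self):
        t = _small_taxonomy()
        t.categories.append(Category(id="a.d", name="D", area_id="a",
                                     subcategory_ids=()))
        t.areas[0] = dataclasses.replace(t.areas[0],
                                         category_ids=("a.c", "a.d"))
        assert any(f.rule == "empty-category"
                   for f in ls.validate_taxonomy(t))

    def test_empty_practice_text(self):
        t = _small_taxonomy()
        bad = dataclasses.replace(
            t.subcategories[0],
            rubric=(RubricLevel(1, ""),) + t.subcategories[0].rubric[1:])
        t.subcategories[0] = bad
        assert any(f.rule == "empty-practice-text"
                   for f in ls.validate_taxonomy(t))

    def test_duplicate_rubric_level(self):
        t = _small_taxonomy()
        sub = t.subcategories[0]
        t.subcategories[0] = dataclasses.replace(
            sub, rubric=sub.rubric + (RubricLevel(4, "again"),))
        assert any(f.rule == "duplicate-rubric-level"
                   for f in ls.validate_taxonomy(t))


# --- property: generated valid instruments validate clean and round-trip ---

@st.composite
def taxonomies(draw):
    n_areas = draw(st.integers(1, 3))
    areas, cats, subs = [], [], []
    for ai in range(n_areas):
        aid = f"area{ai}"
        cat_ids = []
        for ci in range(draw(st.integers(1, 3))):
            cid = f"{aid}.cat{ci}"
            sub_ids = []
            for si in range(draw(st.integers(1, 4))):
                sid = f"{cid}.{si + 1}"
                subs.append(_sub(sid, cid))
                sub_ids.append(sid)
            cats.append(Category(id=cid, name=f"Cat {cid}", area_id=aid,
                                 subcategory_ids=tuple(sub_ids)))
            cat_ids.append(cid)
        areas.append(Area(id=aid, name=f"Area {aid}",
                          category_ids=tuple(cat_ids)))
    return Taxonomy(name="gen", version="1", areas=areas, categories=cats,
                    subcategories=subs)


@settings(max_examples=40, deadline=None)
@given(t=taxonomies())
def test_generated_taxonomies_validate_clean(t):
    assert ls.validate_taxonomy(t) == []


@settings(max_examples=40, deadline=None)
@given(t=taxonomies())
def test_generated_taxonomies_round_trip(t):
    assert ls.parse_taxonomy(ls.dump_taxonomy(t)) == t


@settings(max_examples=40, deadline=None)
@given(t=taxonomies(), data=st.data())
def test_mutated_taxonomies_are_flagged(t, data):
    mutation = data.draw(st.sampled_from(
        ["dup-sub", "dangle-cat", "drop-level", "blank-text"]))
    sub = data.draw(st.sampled_from(t.subcategories))
    idx = t.subcategories.index(sub)
    if mutation == "dup-sub":
        t.subcategories.append(sub)
    elif mutation == "dangle-cat":
        t.subcategories[idx] = dataclasses.replace(sub, category_id="ghost")
    elif mutation == "drop-level":
        t.subcategories[idx] = dataclasses.replace(sub, rubric=sub.rubric[1:])
    else:
        t.subcategories[idx] = dataclasses.replace(
            sub, rubric=(RubricLevel(1, " "),) + sub.rubric[1:])
    assert ls.validate_taxonomy(t) != []
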