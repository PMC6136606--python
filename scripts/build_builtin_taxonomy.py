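"""One-off: emit src/labsafescore/data/lmt_s.yaml from the structure table."""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from labsafescore.taxonomy import (
    Area, Category, RubricLevel, Subcategory, Taxonomy, dump_taxonomy,
    validate_taxonomy,
)

STRUCTURE = [
    ("administration", "Administration", [
        ("general", "General", 5),
        ("personnel_health_and_safety", "Personnel health and safety", 4),
        ("training_and_competency", "Training and competency", 4),
        ("biosafety_manual_sops",
         "Biosafety manual/Standard operating procedures (SOPs)", 2),
    ]),
    ("operations", "Operations", [
        ("good_lab_practices", "Good lab practices", 7),
        ("containment", "Containment", 6),
        ("containment_bsl3", "Containment BSL3", 8),
        ("waste_disposal", "Waste disposal", 5),
        ("shipping_of_infectious_substances",
         "Shipping of infectious substances", 5),
        ("animal_facilities", "Animal facilities", 7),
    ]),
    ("engineering", "Engineering", [
        ("premises", "Premises", 7),
        ("chemical_hazard_containment", "Chemical hazard containment", 6),
        ("chemical_security", "Chemical security", 4),
        ("emergencies", "Emergencies", 4),
        ("fire_hazard", "Fire hazard", 4),
        ("electrical", "Electrical", 4),
        ("bsc", "Biological safety cabinet (BSC)", 3),
    ]),
    ("ppe", "Personal protective equipment (PPE)", [
        ("general_situation", "General situation", 4),
        ("use_of_ppe", "Use of PPE", 4),
        ("ppe_disposal", "PPE disposal", 5),
    ]),
]

GLOVE_RUBRIC = {
    4: ("Disposable gloves (and double gloves when appropriate) are worn per "
        "chemical/pathogenic agent-specific or procedural SOP, are inspected "
        "frequently for contamination or loss of integrity, and are not "
        "reused."),
    3: ("Disposable gloves are worn whenever working with potentially toxic "
        "or infectious materials and biologicals, are changed frequently "
        "during a work shift, and are not reused."),
    2: ("Gloves are required whenever handling potentially toxic/infectious "
        "materials and biologicals. Disposable gloves may be worn for all or "
        "most of a work shift and are not reused."),
    1: ("Gloves are generally worn when working with toxic/infectious "
        "materials; disposable gloves may be washed and reused."),
}
GLOVE_GUIDANCE = (
    "Documentation that can be checked during the assessment may include "
    "training materials, laboratory-specific or general biosafety manuals or "
    "SOPs, don-doff procedures; on-site observation."
)


def build():
    areas, categories, subcategories = [], [], []
    for aslug, aname, cats in STRUCTURE:
        cat_ids = []
        for cslug, cname, count in cats:
            cid = f"{aslug}.{cslug}"
            sub_ids = []
            for k in range(1, count + 1):
                sid = f"{cid}.{k}"
                if cid == "ppe.use_of_ppe" and k == 1:
                    name = "Disposable glove usage"
                    rubric = tuple(
                        RubricLevel(lvl, GLOVE_RUBRIC[lvl])
                        for lvl in (1, 2, 3, 4))
                    guidance = GLOVE_GUIDANCE
                else:
                    name = f"Subcategory {k} of {cname}"
                    rubric = tuple(
                        RubricLevel(
                            lvl,
                            f"Level {lvl} practice for {name} (placeholder "
                            "rubric text; the published instrument defines "
                            "the actual wording).")
                        for lvl in (1, 2, 3, 4))
                    guidance = ""
                subcategories.append(Subcategory(
                    id=sid, name=name, category_id=cid,
                    rubric=rubric, guidance=guidance))
                sub_ids.append(sid)
            categories.append(Category(
                id=cid, name=cname, area_id=aslug,
                subcategory_ids=tuple(sub_ids)))
            cat_ids.append(cid)
        areas.append(Area(id=aslug, name=aname, category_ids=tuple(cat_ids)))
    return Taxonomy(name="LMT-S", version="1.0", areas=areas,
                    categories=categories, subcategories=subcategories)


if __name__ == "__main__":
    t = build()
    findings = validate_taxonomy(t)
    assert not findings, findings
    assert t.n_subcategories == 98, t.n_subcategories
    out = Path(__file__).resolve().parents[1] / "src/labsafescore/data/lmt_s.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(dump_taxonomy(t), encoding="utf-8")
    print("wrote", out)
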