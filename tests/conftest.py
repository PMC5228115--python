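import pytest

from patheval import default_acmg_guideline
from patheval.guideline import Guideline


@pytest.fixture(scope="session")
def acmg() -> Guideline:
    return default_acmg_guideline()


@pytest.fixture()
def guideline_dict(acmg) -> dict:
    """Mutable plain-document copy of the default guideline for perturbation."""
    return acmg.model_dump(mode="json")


@pytest.fixture()
def metabolite_guideline(guideline_dict) -> Guideline:
    """Custom guideline with a novel evidence-type row and a code in it."""
    guideline_dict["meta"]["id"] = "custom_metabolite"
    guideline_dict["evidence_types"].append(
        {"type_id": "metabolite", "label": "Metabolite Levels"})
    guideline_dict["codes"].append(
        {"code_id": "ML1", "direction": "pathogenic", "default_strength": "supporting",
         "evidence_type": "metabolite",
         "description": "Metabolite profile consistent with loss of enzyme function."})
    return Guideline.model_validate(guideline_dict)
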