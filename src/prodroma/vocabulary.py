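"""Controlled vocabulary of clinical event categories.

Input records carry *category labels*, not raw Read/SNOMED codes: the mapping
from a practice's coding terminology onto these categories is the user's
responsibility and is documented in the README.  The vocabulary is closed —
every operation in the package rejects labels outside this list.

Each category belongs to exactly one group: spinal symptoms/disorders,
musculoskeletal and AS-related features, other related disorders, diagnostic
tests and procedures, or treatments.
"""

from __future__ import annotations

from enum import Enum


class CategoryGroup(str, Enum):
    SPINAL = "spinal"
    MUSCULOSKELETAL = "musculoskeletal_as_related"
    RELATED_DISORDER = "related_disorder"
    DIAGNOSTIC_TEST = "diagnostic_test"
    TREATMENT = "treatment"


class EventCategory(str, Enum):
    """Closed set of clinical categories recognised in event tables."""

    AXIAL_PAIN = "axial_pain"
    OTHER_SPINE_DIAGNOSIS = "other_spine_diagnosis"
    SCIATICA = "sciatica"
    ENTHESOPATHY_TENDON = "enthesopathy_tendon"
    LARGE_JOINT = "large_joint"
    OTHER_JOINT = "other_joint"
    IRITIS = "iritis"
    URETHRAL = "urethral"
    FATIGUE = "fatigue"
    IBD = "ibd"
    OTHER_INFLAMMATORY_ARTHRITIS = "other_inflammatory_arthritis"
    FBC = "fbc"
    ESR = "esr"
    THYROID_FUNCTION = "thyroid_function"
    XRAY_SPINE = "xray_spine"
    XRAY_PELVIS = "xray_pelvis"
    CT = "ct"
    MRI = "mri"
    NSAID = "nsaid"
    ANALGESIC = "analgesic"
    OPIOID = "opioid"
    TRICYCLIC = "tricyclic"
    SSRI = "ssri"
    AS_DIAGNOSIS = "as_diagnosis"
    DMARD = "dmard"

    @property
    def group(self) -> CategoryGroup:
        return CATEGORY_GROUPS[self]


CATEGORY_GROUPS: dict[EventCategory, CategoryGroup] = {
    EventCategory.AXIAL_PAIN: CategoryGroup.SPINAL,
    EventCategory.OTHER_SPINE_DIAGNOSIS: CategoryGroup.SPINAL,
    EventCategory.SCIATICA: CategoryGroup.SPINAL,
    EventCategory.AS_DIAGNOSIS: CategoryGroup.SPINAL,
    EventCategory.ENTHESOPATHY_TENDON: CategoryGroup.MUSCULOSKELETAL,
    EventCategory.LARGE_JOINT: CategoryGroup.MUSCULOSKELETAL,
    EventCategory.OTHER_JOINT: CategoryGroup.MUSCULOSKELETAL,
    EventCategory.IRITIS: CategoryGroup.MUSCULOSKELETAL,
    EventCategory.URETHRAL: CategoryGroup.MUSCULOSKELETAL,
    EventCategory.FATIGUE: CategoryGroup.MUSCULOSKELETAL,
    EventCategory.IBD: CategoryGroup.RELATED_DISORDER,
    EventCategory.OTHER_INFLAMMATORY_ARTHRITIS: CategoryGroup.RELATED_DISORDER,
    EventCategory.FBC: CategoryGroup.DIAGNOSTIC_TEST,
    EventCategory.ESR: CategoryGroup.DIAGNOSTIC_TEST,
    EventCategory.THYROID_FUNCTION: CategoryGroup.DIAGNOSTIC_TEST,
    EventCategory.XRAY_SPINE: CategoryGroup.DIAGNOSTIC_TEST,
    EventCategory.XRAY_PELVIS: CategoryGroup.DIAGNOSTIC_TEST,
    EventCategory.CT: CategoryGroup.DIAGNOSTIC_TEST,
    EventCategory.MRI: CategoryGroup.DIAGNOSTIC_TEST,
    EventCategory.NSAID: CategoryGroup.TREATMENT,
    EventCategory.ANALGESIC: CategoryGroup.TREATMENT,
    EventCategory.OPIOID: CategoryGroup.TREATMENT,
    EventCategory.TRICYCLIC: CategoryGroup.TREATMENT,
    EventCategory.SSRI: CategoryGroup.TREATMENT,
    EventCategory.DMARD: CategoryGroup.TREATMENT,
}

#: all category labels, in vocabulary order
CATEGORY_NAMES: tuple[str, ...] = tuple(c.value for c in EventCategory)

#: codes marking the spinal symptom/diagnosis history that qualifies a
#: symptomatic control (degenerative/mechanical spine disorders or axial pain)
SYMPTOMATIC_QUALIFYING: frozenset[str] = frozenset(
    {EventCategory.AXIAL_PAIN.value, EventCategory.OTHER_SPINE_DIAGNOSIS.value}
)

EVENT_TYPES: tuple[str, ...] = ("clinical_code", "prescription", "test")
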