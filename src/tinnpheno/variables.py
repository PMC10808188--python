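"""Variable specifications for the 64-variable questionnaire battery.

The cohort is assessed with 14 instruments yielding 64 analysis variables
(55 continuous composite/VAS scores and 9 binary items) grouped into 10
categories. Variables where a higher raw score means *less* burden
(``higher-is-better``) are reverse-coded upstream so that, after
preprocessing, higher always means higher disease burden; reversed variables
carry a ``*`` suffix on their name.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import DataValidationError

#: The fixed ten variable categories.
CATEGORIES: tuple[str, ...] = (
    "tinnitus_characteristics",
    "physical_qol",
    "pain",
    "somatic",
    "affective",
    "tinnitus_distress",
    "internal_resources",
    "perceived_stress",
    "general_qol",
    "mental_qol",
)

KINDS = ("continuous", "binary")
POLARITIES = ("higher-is-worse", "higher-is-better")


@dataclass(frozen=True)
class VariableSpec:
    """One analysis variable: its instrument, category, kind, polarity and raw range."""

    name: str
    questionnaire: str
    category: str
    kind: str  # continuous | binary
    polarity: str  # higher-is-worse | higher-is-better
    raw_min: float
    raw_max: float

    def __post_init__(self):
        if self.category not in CATEGORIES:
            raise DataValidationError(
                f"variable {self.name!r}: unknown category {self.category!r}"
            )
        if self.kind not in KINDS:
            raise DataValidationError(f"variable {self.name!r}: unknown kind {self.kind!r}")
        if self.polarity not in POLARITIES:
            raise DataValidationError(
                f"variable {self.name!r}: unknown polarity {self.polarity!r}"
            )
        if self.kind == "binary" and (self.raw_min, self.raw_max) != (0.0, 1.0):
            raise DataValidationError(
                f"variable {self.name!r}: binary variables must have bounds {{0, 1}}"
            )
        if not self.raw_min < self.raw_max:
            raise DataValidationError(
                f"variable {self.name!r}: raw_min must be < raw_max "
                f"(got {self.raw_min}, {self.raw_max})"
            )

    @property
    def reversed_name(self) -> str:
        """Name after reverse-coding (``*`` suffix convention)."""
        return self.name + "*"


def _v(name, questionnaire, category, kind, polarity, raw_max):
    return VariableSpec(name, questionnaire, category, kind, polarity, 0.0, raw_max)


def default_variable_specs() -> list[VariableSpec]:
    """The default 64-variable battery.

    3 tinnitus VAS + 8 binary localization/quality items, SF-8 quality-of-life
    scores, pain scales, somatic complaint scores, affective symptom scores
    (incl. one binary panic-syndrome item), tinnitus-distress subscales,
    internal resources, perceived stress, and general quality of life.
    """
    w, b = "higher-is-worse", "higher-is-better"
    specs = [
        # Tinnitus characteristics (11): 3 VAS + 8 binary location/noise items
        _v("tinskal_loudness", "TINSKAL", "tinnitus_characteristics", "continuous", w, 10),
        _v("tinskal_frequency", "TINSKAL", "tinnitus_characteristics", "continuous", w, 10),
        _v("tinskal_distress", "TINSKAL", "tinnitus_characteristics", "continuous", w, 10),
        _v("tlq_loc_left", "TLQ", "tinnitus_characteristics", "binary", w, 1),
        _v("tlq_loc_right", "TLQ", "tinnitus_characteristics", "binary", w, 1),
        _v("tlq_loc_both", "TLQ", "tinnitus_characteristics", "binary", w, 1),
        _v("tlq_loc_head", "TLQ", "tinnitus_characteristics", "binary", w, 1),
        _v("tlq_noise_whistling", "TLQ", "tinnitus_characteristics", "binary", w, 1),
        _v("tlq_noise_hissing", "TLQ", "tinnitus_characteristics", "binary", w, 1),
        _v("tlq_noise_ringing", "TLQ", "tinnitus_characteristics", "binary", w, 1),
        _v("tlq_noise_rustling", "TLQ", "tinnitus_characteristics", "binary", w, 1),
        # Physical quality of life (4)
        _v("sf8_general_health", "SF8", "physical_qol", "continuous", b, 100),
        _v("sf8_physical_component", "SF8", "physical_qol", "continuous", b, 100),
        _v("sf8_physical_functioning", "SF8", "physical_qol", "continuous", b, 100),
        _v("sf8_role_physical", "SF8", "physical_qol", "continuous", b, 100),
        # Experiences of pain (6)
        _v("ses_affective_pain", "SES", "pain", "continuous", w, 40),
        _v("ses_sensory_pain", "SES", "pain", "continuous", w, 30),
        _v("sf8_bodily_pain", "SF8", "pain", "continuous", b, 100),
        _v("sskal_pain_impairment", "SSKAL", "pain", "continuous", w, 10),
        _v("sskal_pain_frequency", "SSKAL", "pain", "continuous", w, 10),
        _v("sskal_pain_intensity", "SSKAL", "pain", "continuous", w, 10),
        # Somatic expressions (5)
        _v("bi_exhaustion", "BI", "somatic", "continuous", w, 4),
        _v("bi_abdominal", "BI", "somatic", "continuous", w, 4),
        _v("bi_limb_pain", "BI", "somatic", "continuous", w, 4),
        _v("bi_heart", "BI", "somatic", "continuous", w, 4),
        _v("bi_overall", "BI", "somatic", "continuous", w, 4),
        # Affective symptoms (16): 15 continuous + 1 binary
        _v("adsl_depression", "ADSL", "affective", "continuous", w, 60),
        _v("bsf_fatigue", "BSF", "affective", "continuous", w, 5),
        _v("bsf_apathy", "BSF", "affective", "continuous", w, 5),
        _v("bsf_anxious_depression", "BSF", "affective", "continuous", w, 5),
        _v("bsf_anger", "BSF", "affective", "continuous", w, 5),
        _v("bsf_positive_mindset", "BSF", "affective", "continuous", b, 5),
        _v("bsf_elevated_mood", "BSF", "affective", "continuous", b, 5),
        _v("isr_depression", "ISR", "affective", "continuous", w, 4),
        _v("isr_anxiety", "ISR", "affective", "continuous", w, 4),
        _v("isr_ocd", "ISR", "affective", "continuous", w, 4),
        _v("isr_somatoform", "ISR", "affective", "continuous", w, 4),
        _v("isr_eating", "ISR", "affective", "continuous", w, 4),
        _v("isr_additional", "ISR", "affective", "continuous", w, 4),
        _v("isr_total", "ISR", "affective", "continuous", w, 4),
        _v("phqk_depressivity", "PHQK", "affective", "continuous", w, 27),
        _v("phqk_panic", "PHQK", "affective", "binary", w, 1),
        # Tinnitus-related distress (8)
        _v("tq_emotional", "TQ", "tinnitus_distress", "continuous", w, 24),
        _v("tq_cognitive", "TQ", "tinnitus_distress", "continuous", w, 16),
        _v("tq_intrusiveness", "TQ", "tinnitus_distress", "continuous", w, 16),
        _v("tq_auditory", "TQ", "tinnitus_distress", "continuous", w, 14),
        _v("tq_sleep", "TQ", "tinnitus_distress", "continuous", w, 8),
        _v("tq_somatic", "TQ", "tinnitus_distress", "continuous", w, 6),
        _v("tq_psychological", "TQ", "tinnitus_distress", "continuous", w, 40),
        _v("tq_total", "TQ", "tinnitus_distress", "continuous", w, 84),
        # Internal resources (3)
        _v("swop_self_efficacy", "SWOP", "internal_resources", "continuous", b, 20),
        _v("swop_optimism", "SWOP", "internal_resources", "continuous", b, 8),
        _v("swop_pessimism", "SWOP", "internal_resources", "continuous", w, 8),
        # Perceived stress (5)
        _v("psq_demands", "PSQ", "perceived_stress", "continuous", w, 100),
        _v("psq_tension", "PSQ", "perceived_stress", "continuous", w, 100),
        _v("psq_worries", "PSQ", "perceived_stress", "continuous", w, 100),
        _v("psq_joy", "PSQ", "perceived_stress", "continuous", b, 100),
        _v("psq_total", "PSQ", "perceived_stress", "continuous", w, 100),
        # General quality of life (1)
        _v("acsa", "ACSA", "general_qol", "continuous", b, 10),
        # Mental quality of life (5)
        _v("sf8_mental_health", "SF8", "mental_qol", "continuous", b, 100),
        _v("sf8_role_emotional", "SF8", "mental_qol", "continuous", b, 100),
        _v("sf8_social_functioning", "SF8", "mental_qol", "continuous", b, 100),
        _v("sf8_vitality", "SF8", "mental_qol", "continuous", b, 100),
        _v("sf8_mental_component", "SF8", "mental_qol", "continuous", b, 100),
    ]
    assert len(specs) == 64
    return specs


_SPEC_COLUMNS = ["name", "questionnaire", "category", "kind", "polarity", "raw_min", "raw_max"]


def specs_to_frame(specs: Iterable[VariableSpec]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.name, s.questionnaire, s.category, s.kind, s.polarity, s.raw_min, s.raw_max)
         for s in specs],
        columns=_SPEC_COLUMNS,
    )


def write_variable_specs(specs: Iterable[VariableSpec], path: str | Path) -> None:
    specs_to_frame(specs).to_csv(path, index=False)


def read_variable_specs(path: str | Path) -> list[VariableSpec]:
    df = pd.read_csv(path)
    missing = set(_SPEC_COLUMNS) - set(df.columns)
    if missing:
        raise DataValidationError(f"variable spec file {path}: missing columns {sorted(missing)}")
    return [
        VariableSpec(
            name=str(r["name"]),
            questionnaire=str(r["questionnaire"]),
            category=str(r["category"]),
            kind=str(r["kind"]),
            polarity=str(r["polarity"]),
            raw_min=float(r["raw_min"]),
            raw_max=float(r["raw_max"]),
        )
        for _, r in df.iterrows()
    ]
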