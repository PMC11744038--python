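"""Study design of the eight public RNA-seq cohorts.

Per-cohort COVID-19 patient and control sample sizes; the platelet cohort
additionally carries the ICU/non-ICU severity split used for the severity
contrast. These sizes drive the synthetic generator's default group sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CohortDesign", "STUDY_COHORTS", "total_samples"]


@dataclass(frozen=True)
class CohortDesign:
    name: str
    n_covid: int
    n_control: int
    n_non_icu: int | None = None
    n_icu: int | None = None


STUDY_COHORTS: tuple[CohortDesign, ...] = (
    CohortDesign("platelet", n_covid=10, n_control=5, n_non_icu=6, n_icu=4),
    CohortDesign("pbmc", n_covid=31, n_control=16),
    CohortDesign("lung", n_covid=11, n_control=3),
    CohortDesign("frontal_cortex", n_covid=22, n_control=10),
    CohortDesign("ventral_midbrain", n_covid=11, n_control=3),
    CohortDesign("phuvec", n_covid=15, n_control=5),
    CohortDesign("placenta", n_covid=17, n_control=4),
    CohortDesign("hcmec", n_covid=7, n_control=7),
)


def total_samples() -> tuple[int, int]:
    """(total COVID-19 patients, total controls) across all cohorts."""
    return (
        sum(c.n_covid for c in STUDY_COHORTS),
        sum(c.n_control for c in STUDY_COHORTS),
    )


def get_cohort(name: str) -> CohortDesign:
    for c in STUDY_COHORTS:
        if c.name == name:
            return c
    raise KeyError(f"unknown cohort {name!r}")
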