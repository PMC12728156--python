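"""Reference cohort descriptors for the melanoma organoid study design this
package's defaults emulate.

These counts parameterize worked examples and the synthetic defaults: the
establishment series (semi-solid and air-liquid organotypic cultures from
metastatic melanoma surgery specimens), the clinical features of the
transcriptomic sub-cohort, and the sizes of the external ICB expression
cohorts used for signature validation.
"""
from __future__ import annotations

from .io import percent

#: organotypic-culture establishment series
ESTABLISHMENT = {
    "successful": 22,
    "attempted": 31,
    "ali_successful": 11,
    "ali_attempted": 13,
}

#: metastatic sites of the 31 surgical specimens
METASTASIS_SITES = {"lymph_node": 17, "cutaneous_subcutaneous": 11, "cns": 3}

#: clinical features of the 14-patient transcriptomic sub-cohort
TRANSCRIPTOMIC_COHORT = {
    "n_patients": 14,
    "gender": {"male": 11, "female": 3},
    "metastasis": {"lymph_node": 10, "subcutaneous": 3, "cns": 1},
}

#: external bulk-expression validation cohorts (patients with survival data)
VALIDATION_COHORTS = {"anti_pd1_combo": 69, "anti_ctla4": 40, "tcga": 349}

#: paired pre/on-treatment ICB biopsy cohort size
PAIRED_PRE_ON_PATIENTS = 42


def establishment_success_percent() -> int:
    return percent(ESTABLISHMENT["successful"], ESTABLISHMENT["attempted"])


def ali_success_percent() -> int:
    return percent(ESTABLISHMENT["ali_successful"], ESTABLISHMENT["ali_attempted"])


def total_specimens() -> int:
    return sum(METASTASIS_SITES.values())


def total_validation_patients() -> int:
    return sum(VALIDATION_COHORTS.values())
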