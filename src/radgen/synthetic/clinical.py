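"""Clinical covariate tables for synthetic multi-site cohorts.

Covariates are sampled independently per patient from site-specific
categorical marginals (only marginal frequencies are published for the
cohort this emulates, so no dependence structure is imposed).  The
``TABLE1_MARGINALS`` preset reproduces the baseline characteristics of a
642-patient advanced-NSCLC immunotherapy cohort: a 512-patient discovery
group from three academic centers and a 130-patient validation group from
a fourth.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

DISCOVERY_SITES = ("CHUM", "JGH", "IUCPQ")
VALIDATION_SITE = "CHUS"

# patient-selection flow: eligible -> imaging-window exclusion -> lesions
# that could not be delineated during annotation
COHORT_FLOW = {
    "eligible": 910,
    "excluded_no_recent_imaging": 147,
    "excluded_undelineatable_lesion": 121,
}


def apply_exclusions(n_eligible: int, exclusions: list[int] | tuple[int, ...]) -> int:
    """Sequentially remove exclusion counts from an eligible population."""
    n = int(n_eligible)
    for e in exclusions:
        if e < 0 or e > n:
            raise ValueError(f"exclusion {e} out of range for n={n}")
        n -= int(e)
    return n


def final_cohort_size() -> int:
    return apply_exclusions(
        COHORT_FLOW["eligible"],
        [
            COHORT_FLOW["excluded_no_recent_imaging"],
            COHORT_FLOW["excluded_undelineatable_lesion"],
        ],
    )


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    site_id: str
    age: float
    sex: str  # M | F
    smoking: str  # never | former | current
    ecog: str  # 0 | 1 | >=2
    stage: str  # III | IV
    histology: str  # adeno | squamous | other
    pdl1: str  # <1% | 1-49% | >=50% | missing
    first_line_ici: str  # yes | no
    treatment: str  # ICI alone | chemo-ICI
    pfs6: str  # >=6 | <6
    lesion_radius: float  # mm

    def __post_init__(self) -> None:
        if self.age <= 18:
            raise ValueError("age must exceed 18")
        if self.lesion_radius <= 0:
            raise ValueError("lesion_radius must be > 0")


_CATS = {
    "sex": ("M", "F"),
    "smoking": ("never", "former", "current"),
    "ecog": ("0", "1", ">=2"),
    "stage": ("III", "IV"),
    "histology": ("adeno", "squamous", "other"),
    "pdl1": ("<1%", "1-49%", ">=50%", "missing"),
    "first_line_ici": ("yes", "no"),
    "treatment": ("ICI alone", "chemo-ICI"),
    "pfs6": (">=6", "<6"),
}

# Discovery marginals from printed counts over n=512 (ECOG over its 497
# reported; PD-L1 missingness kept explicit: 512-437=75 unreported).
# Smoking "current or former" (466/512) is split 2:1 former:current.
_DISC = {
    "sex": {"M": 258 / 512, "F": 254 / 512},
    "smoking": {
        "never": 46 / 512,
        "former": (466 / 512) * (2 / 3),
        "current": (466 / 512) * (1 / 3),
    },
    "ecog": {"0": 137 / 497, "1": 292 / 497, ">=2": 68 / 497},
    "stage": {"III": 52 / 512, "IV": 460 / 512},
    "histology": {"adeno": 404 / 512, "squamous": 29 / 512, "other": 79 / 512},
    "pdl1": {
        "<1%": 97 / 512,
        "1-49%": 117 / 512,
        ">=50%": 223 / 512,
        "missing": 75 / 512,
    },
    "first_line_ici": {"yes": 197 / 512, "no": 315 / 512},
    "treatment": {"ICI alone": 469 / 512, "chemo-ICI": 43 / 512},
    "pfs6": {">=6": 260 / 512, "<6": 252 / 512},
    "age_mean": 68.0,
    "age_sd": 8.5,
    "lesion_radius_log_mean": np.log(12.0),
    "lesion_radius_log_sd": 0.4,
}

_VAL = {
    "sex": {"M": 69 / 130, "F": 61 / 130},
    "smoking": {
        "never": 5 / 130,
        "former": (125 / 130) * (2 / 3),
        "current": (125 / 130) * (1 / 3),
    },
    "ecog": {"0": 37 / 130, "1": 77 / 130, ">=2": 16 / 130},
    "stage": {"III": 11 / 130, "IV": 119 / 130},
    "histology": {"adeno": 89 / 130, "squamous": 13 / 130, "other": 28 / 130},
    "pdl1": {
        "<1%": 36 / 130,
        "1-49%": 34 / 130,
        ">=50%": 54 / 130,
        "missing": 6 / 130,
    },
    "first_line_ici": {"yes": 94 / 130, "no": 36 / 130},
    "treatment": {"ICI alone": 76 / 130, "chemo-ICI": 54 / 130},
    "pfs6": {">=6": 60 / 130, "<6": 70 / 130},
    "age_mean": 66.8,
    "age_sd": 9.0,
    "lesion_radius_log_mean": np.log(12.0),
    "lesion_radius_log_sd": 0.4,
}

TABLE1_MARGINALS = {
    "CHUM": _DISC,
    "JGH": _DISC,
    "IUCPQ": _DISC,
    "CHUS": _VAL,
}


def _check_marginals(marg: dict) -> None:
    for field, cats in _CATS.items():
        if field not in marg:
            raise ValueError(f"marginals missing field {field!r}")
        probs = marg[field]
        unknown = set(probs) - set(cats)
        if unknown:
            raise ValueError(f"unknown categories for {field}: {unknown}")
        total = sum(probs.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"marginals for {field} sum to {total}, not 1")


def generate_clinical_cohort(
    n_per_site: dict[str, int],
    marginals: dict[str, dict] | None = None,
    seed: int = 0,
) -> list[ClinicalRecord]:
    """Sample a clinical table, independently per patient, per-site marginals."""
    marginals = marginals if marginals is not None else TABLE1_MARGINALS
    rng = np.random.default_rng(seed)
    records: list[ClinicalRecord] = []
    for site, n in n_per_site.items():
        if site not in marginals:
            raise ValueError(f"no marginals for site {site!r}")
        marg = marginals[site]
        _check_marginals(marg)
        for i in range(n):
            row: dict[str, str] = {}
            for fld, cats in _CATS.items():
                probs = np.array([marg[fld].get(c, 0.0) for c in cats])
                row[fld] = cats[rng.choice(len(cats), p=probs / probs.sum())]
            age = float(
                np.clip(rng.normal(marg["age_mean"], marg["age_sd"]), 30.0, 95.0)
            )
            radius = float(
                np.exp(
                    rng.normal(
                        marg["lesion_radius_log_mean"], marg["lesion_radius_log_sd"]
                    )
                )
            )
            records.append(
                ClinicalRecord(
                    patient_id=f"{site}-{i:04d}",
                    site_id=site,
                    age=age,
                    lesion_radius=radius,
                    **row,
                )
            )
    return records


def records_to_frame(records: list[ClinicalRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])
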