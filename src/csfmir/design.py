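"""Cohort design: who was sampled, how often.

The study cohort is a CSF (cerebrospinal fluid) collection of 48 patients in
seven diagnosis groups — Normal, Benign, Glioblastoma, Medulloblastoma,
LungMetastasis, BreastMetastasis and Lymphoma — totalling 82 samples because
some neoplastic patients underwent repeated post-surgical lumbar punctures.
``CohortDesign`` records that structure (groups -> patients -> longitudinal
sample counts) and is the backbone every simulated dataset hangs from.
"""

from __future__ import annotations

from dataclasses import dataclass, field

GROUPS = (
    "Normal",
    "Benign",
    "Glioblastoma",
    "Medulloblastoma",
    "LungMetastasis",
    "BreastMetastasis",
    "Lymphoma",
)

#: Groups representing neoplastic disease (everything but Normal).
NEOPLASTIC_GROUPS = tuple(g for g in GROUPS if g != "Normal")

#: Derived (pseudo) group labels resolvable by :func:`csfmir.effects.resolve_group`.
METASTASIS_GROUPS = ("LungMetastasis", "BreastMetastasis")
MALIGNANT_GROUPS = ("Glioblastoma", "Medulloblastoma") + METASTASIS_GROUPS


@dataclass(frozen=True)
class Patient:
    patient_id: str
    group: str
    n_samples: int = 1

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ValueError(f"patient {self.patient_id}: n_samples must be >= 1")


@dataclass
class CohortDesign:
    """Groups, patients per group, and longitudinal samples per patient."""

    patients: list[Patient] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.patient_id for p in self.patients]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate patient ids in design")

    @property
    def groups(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.patients:
            seen.setdefault(p.group, None)
        return list(seen)

    def patients_in(self, group: str) -> list[Patient]:
        return [p for p in self.patients if p.group == group]

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    @property
    def n_samples(self) -> int:
        return sum(p.n_samples for p in self.patients)

    def sample_index(self) -> list[tuple[str, str, str]]:
        """Flat (sample_id, patient_id, group) index in deterministic order."""
        rows = []
        for p in self.patients:
            for t in range(1, p.n_samples + 1):
                rows.append((f"{p.patient_id}_s{t}", p.patient_id, p.group))
        return rows


def _expand(group: str, prefix: str, counts: list[int]) -> list[Patient]:
    return [
        Patient(f"{prefix}{i + 1:02d}", group, n) for i, n in enumerate(counts)
    ]


def build_default_design() -> CohortDesign:
    """The study cohort.

    Normal 14x1; Benign = Glioma 9x1 + Ependymoma 2x1 + Meningioma 4x1
    (15 patients, histology kept in the patient id prefix); Glioblastoma
    4 patients with 1/3/6/7 samples; Medulloblastoma 3 patients with 1/6/7;
    lung metastasis 4 patients (1,1,1,3); breast metastasis 5 patients
    (1,1,1,4,6); Lymphoma 3x1.  Sums: 48 patients (34 neoplastic),
    82 samples.
    """
    patients: list[Patient] = []
    patients += _expand("Normal", "NOR", [1] * 14)
    patients += _expand("Benign", "BEN-GLI", [1] * 9)
    patients += _expand("Benign", "BEN-EPE", [1] * 2)
    patients += _expand("Benign", "BEN-MEN", [1] * 4)
    patients += _expand("Glioblastoma", "GBM", [1, 3, 6, 7])
    patients += _expand("Medulloblastoma", "MBL", [1, 6, 7])
    patients += _expand("LungMetastasis", "LMET", [1, 1, 1, 3])
    patients += _expand("BreastMetastasis", "BMET", [1, 1, 1, 4, 6])
    patients += _expand("Lymphoma", "LYM", [1] * 3)
    return CohortDesign(patients)


def cohort_summary(design: CohortDesign) -> dict:
    """Totals: patients, neoplastic patients, samples, samples per group."""
    samples_per_group = {
        g: sum(p.n_samples for p in design.patients_in(g)) for g in design.groups
    }
    return {
        "n_patients": design.n_patients,
        "n_neoplastic_patients": sum(
            1 for p in design.patients if p.group != "Normal"
        ),
        "n_samples": design.n_samples,
        "samples_per_group": samples_per_group,
    }
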