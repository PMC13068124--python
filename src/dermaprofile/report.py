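"""Decision-support-style profile summaries.

A profile report assigns a subject to a cluster via training-derived
prototypes, lists the run's consensus drivers split into genetic vs
modifiable factors, and maps drivers to a static, editable lookup of
intervention categories (barrier support, exposure mitigation, routine
adjustment). Reports are hypothesis-supporting summaries, never diagnoses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .cohort import CohortTable
from .kmodes import ClusterModel, matching_dissimilarity, predict_labels

DISCLAIMER = (
    "Hypothesis-supporting summary derived from cohort patterns; "
    "not a medical diagnosis."
)

INTERVENTION_CATEGORIES = ("barrier support", "exposure mitigation", "routine adjustment")

#: static driver -> intervention-category lookup (editable)
INTERVENTION_LOOKUP = {
    "FLG": "barrier support",
    "AQP3": "barrier support",
    "MMP-1": "exposure mitigation",
    "MMP-3": "exposure mitigation",
    "SOD2": "exposure mitigation",
    "GPX": "exposure mitigation",
    "Low.H2O": "barrier support",
    "Is_Winter": "barrier support",
    "Scrub.Usage": "routine adjustment",
    "Exfoliation_Frequency": "routine adjustment",
    "Makeup_Frequency": "routine adjustment",
    "Camouflage_Imperfections": "routine adjustment",
    "Sleep_Quality": "routine adjustment",
    "Stress": "routine adjustment",
    "Diet_Quality": "routine adjustment",
    "Alcohol": "routine adjustment",
    "Sunbathing": "exposure mitigation",
    "Sun_Exposure": "exposure mitigation",
    "City_Living": "exposure mitigation",
    "Pollution_Exposure": "exposure mitigation",
    "Smoking": "exposure mitigation",
    "Medication": "routine adjustment",
}

MAX_DRIVERS = 10


@dataclass
class ProfileReport:
    subject_id: str
    cluster: int
    mismatch: int
    genetic_drivers: list[str] = field(default_factory=list)
    modifiable_drivers: list[str] = field(default_factory=list)
    interventions: list[str] = field(default_factory=list)
    non_diagnostic: bool = True

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "cluster": self.cluster,
            "mismatch": self.mismatch,
            "genetic_drivers": self.genetic_drivers,
            "modifiable_drivers": self.modifiable_drivers,
            "interventions": self.interventions,
            "non_diagnostic": self.non_diagnostic,
            "disclaimer": DISCLAIMER,
        }

    @classmethod
    def from_dict(cls, payload: Mapping) -> "ProfileReport":
        return cls(
            subject_id=payload["subject_id"],
            cluster=int(payload["cluster"]),
            mismatch=int(payload["mismatch"]),
            genetic_drivers=list(payload["genetic_drivers"]),
            modifiable_drivers=list(payload["modifiable_drivers"]),
            interventions=list(payload["interventions"]),
            non_diagnostic=bool(payload["non_diagnostic"]),
        )


def assign_profile(
    model: ClusterModel,
    subject_id: str,
    row: Mapping[str, int] | Sequence[int],
    consensus_drivers: Sequence[str],
    cohort: CohortTable | None = None,
) -> ProfileReport:
    """Assign one subject to its nearest prototype and attach run drivers.

    ``row`` must cover the model's features (by name if a mapping). Drivers
    are split by modality when a cohort manifest is supplied; otherwise
    membership in the known gene panel decides. At most 10 drivers are kept.
    """
    if isinstance(row, Mapping):
        try:
            vec = np.array([int(row[name]) for name in model.feature_names])
        except KeyError as exc:
            raise ValueError(f"subject row lacks model feature {exc}") from None
    else:
        vec = np.asarray(row, dtype=np.int64)
        if vec.shape != (len(model.feature_names),):
            raise ValueError("subject row length does not match the model features")
    cluster = int(predict_labels(model, vec[None, :])[0])
    mismatch = matching_dissimilarity(vec, model.modes[cluster])

    drivers = list(consensus_drivers)[:MAX_DRIVERS]
    genetic, modifiable = [], []
    for name in drivers:
        if cohort is not None:
            is_gene = cohort.spec(name).modality == "genetics"
        else:
            from .synthetic import GENES

            is_gene = name in GENES
        (genetic if is_gene else modifiable).append(name)
    interventions = sorted(
        {INTERVENTION_LOOKUP[d] for d in drivers if d in INTERVENTION_LOOKUP}
    )
    return ProfileReport(
        subject_id=subject_id,
        cluster=cluster,
        mismatch=mismatch,
        genetic_drivers=genetic,
        modifiable_drivers=modifiable,
        interventions=interventions,
    )


def render_report(report: ProfileReport, format: str = "text") -> str:
    """Deterministic serialization of a profile report (json or text)."""
    if format == "json":
        return json.dumps(report.to_dict(), sort_keys=True, indent=2)
    if format == "text":
        lines = [
            f"Profile report for subject {report.subject_id}",
            f"  Assigned cluster : {report.cluster}",
            f"  Prototype mismatch: {report.mismatch} feature(s)",
        ]
        if report.genetic_drivers or report.modifiable_drivers:
            if report.genetic_drivers:
                lines.append("  Genetic drivers  : " + ", ".join(report.genetic_drivers))
            if report.modifiable_drivers:
                lines.append(
                    "  Modifiable drivers: " + ", ".join(report.modifiable_drivers)
                )
        else:
            lines.append("  No stable drivers identified for this run.")
        if report.interventions:
            lines.append("  Intervention categories: " + ", ".join(report.interventions))
        lines.append(f"  Note: {DISCLAIMER}")
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {format!r}; use 'json' or 'text'")


def parse_report(document: str) -> ProfileReport:
    """Inverse of ``render_report(..., format='json')``."""
    return ProfileReport.from_dict(json.loads(document))
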