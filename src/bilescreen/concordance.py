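"""Genotype-phenotype concordance: predicted versus observed activities.

Both sides are reduced to (strain, activity class) records; the summary
counts, per class and per strain, the confirmed (predicted and observed),
predicted-only and observed-only entries.  Matching can run at strain level
or, when a strain-to-species map is supplied, at species level (a predicted
activity is then confirmed if any strain of the same species shows it).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .bile_chem import (LABEL_3A, LABEL_7A, LABEL_12A, LABEL_7A12A,
                        LABEL_DEHYDROX, LABEL_EPI, LABEL_OTHER)

__all__ = [
    "ALLOWED_CLASSES",
    "ConcordanceSummary",
    "map_activity_label",
    "compare",
]

ALLOWED_CLASSES = frozenset({
    "3α-HSD", "7α-HSD", "12α-HSD", "7α-dehydroxylation", "conjugation", "other",
})

_LABEL_MAP = {
    LABEL_3A: ("3α-HSD",),
    LABEL_7A: ("7α-HSD",),
    LABEL_12A: ("12α-HSD",),
    # a CA -> 7,12-dioxoLCA product evidences both dehydrogenations
    LABEL_7A12A: ("7α-HSD", "12α-HSD"),
    LABEL_DEHYDROX: ("7α-dehydroxylation",),
    LABEL_EPI: ("other",),
    LABEL_OTHER: ("other",),
}


def map_activity_label(label: str) -> tuple[str, ...]:
    """Map a transformation-graph edge label onto concordance classes."""
    try:
        return _LABEL_MAP[label]
    except KeyError:
        raise ValueError(f"unknown activity label {label!r}") from None


@dataclass
class ConcordanceSummary:
    per_class: pd.DataFrame    # class, confirmed, predicted_only, observed_only
    per_strain: pd.DataFrame   # strain_id, confirmed, predicted_only, observed_only
    n_confirmed: int
    n_predicted_only: int
    n_observed_only: int

    @property
    def n_disagreement(self) -> int:
        return self.n_predicted_only + self.n_observed_only

    def to_dict(self) -> dict:
        return {
            "confirmed": self.n_confirmed,
            "predicted_only": self.n_predicted_only,
            "observed_only": self.n_observed_only,
            "per_class": self.per_class.to_dict(orient="records"),
            "per_strain": self.per_strain.to_dict(orient="records"),
        }


def _record_set(records: pd.DataFrame, species_of: dict | None) -> set:
    out = set()
    for _, r in records.iterrows():
        cls = r["activity_class"]
        if cls not in ALLOWED_CLASSES:
            raise ValueError(f"unknown activity class label {cls!r}")
        key = species_of[r["strain_id"]] if species_of else r["strain_id"]
        out.add((key, cls))
    return out


def compare(predicted: pd.DataFrame, observed: pd.DataFrame,
            species_of: dict | None = None) -> ConcordanceSummary:
    """Set comparison of predicted and observed (strain, class) records.

    Inputs need columns ``strain_id`` and ``activity_class``.  Passing
    ``species_of`` (strain id -> species name) switches matching to species
    level.  The totals obey confirmed + observed_only = total observed and
    confirmed + predicted_only = total predicted.
    """
    pred = _record_set(predicted, species_of)
    obs = _record_set(observed, species_of)
    confirmed = pred & obs
    pred_only = pred - obs
    obs_only = obs - pred

    classes = sorted({c for _, c in pred | obs})
    per_class = pd.DataFrame([{
        "activity_class": c,
        "confirmed": sum(1 for k in confirmed if k[1] == c),
        "predicted_only": sum(1 for k in pred_only if k[1] == c),
        "observed_only": sum(1 for k in obs_only if k[1] == c),
    } for c in classes])

    strains = sorted({s for s, _ in pred | obs})
    per_strain = pd.DataFrame([{
        "strain_id": s,
        "confirmed": sum(1 for k in confirmed if k[0] == s),
        "predicted_only": sum(1 for k in pred_only if k[0] == s),
        "observed_only": sum(1 for k in obs_only if k[0] == s),
    } for s in strains])

    return ConcordanceSummary(
        per_class=per_class,
        per_strain=per_strain,
        n_confirmed=len(confirmed),
        n_predicted_only=len(pred_only),
        n_observed_only=len(obs_only),
    )
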