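"""DAS28-ESR, CDAI and EULAR response classification.

DAS28-ESR combines 28-joint tender and swollen counts, erythrocyte
sedimentation rate and a 0–100 mm general-health VAS:

    DAS28 = 0.56*sqrt(TJC28) + 0.28*sqrt(SJC28) + 0.70*ln(ESR) + 0.014*GH

CDAI is the acute-phase-reactant-free sum TJC28 + SJC28 + PtGA + PhGA on a
0–76 scale (patient/physician global assessments on 0–10). The EULAR grid
classifies the six-month response from the DAS28 improvement
(delta = baseline − month6) and the attained month-6 DAS28:
good if delta > 1.2 and attained <= 3.2; no response if delta <= 0.6, or if
delta <= 1.2 with attained > 5.1; moderate otherwise. Responders are the
good + moderate classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger(__name__)

VISITS = ("baseline", "month6")
EULAR_CLASSES = ("good", "moderate", "none")


def _check_range(name: str, value: float, lo: float, hi: float) -> None:
    if not lo <= value <= hi:
        raise ValueError(f"{name} must lie in [{lo}, {hi}]; got {value}")


@dataclass(frozen=True)
class ClinicalVisit:
    """Disease-activity components measured at one visit."""

    sample_id: str
    visit: str  # "baseline" | "month6"
    tjc28: int
    sjc28: int
    esr: float  # mm/h, >= 1 (its log enters DAS28)
    gh: float  # general health VAS, 0-100 mm
    ptga: float  # patient global assessment, 0-10
    phga: float  # physician global assessment, 0-10

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise ValueError(f"visit must be one of {VISITS}; got {self.visit!r}")
        _check_range("tjc28", self.tjc28, 0, 28)
        _check_range("sjc28", self.sjc28, 0, 28)
        if self.esr < 1:
            raise ValueError(f"esr must be >= 1 mm/h (log is taken); got {self.esr}")
        _check_range("gh", self.gh, 0, 100)
        _check_range("ptga", self.ptga, 0, 10)
        _check_range("phga", self.phga, 0, 10)


@dataclass(frozen=True)
class ResponseLabel:
    """Per-patient disease-activity summary and EULAR response class."""

    sample_id: str
    das28_baseline: float
    das28_month6: float
    delta_das28: float  # baseline - month6 (improvement positive)
    cdai_baseline: float
    cdai_month6: float
    delta_cdai: float  # baseline - month6
    eular_class: str
    is_responder: bool


def das28_esr(tjc28, sjc28, esr, gh):
    """DAS28-ESR score; strictly increasing in each component.

    Accepts scalars or numpy arrays. ESR must be >= 1 mm/h.
    """
    tjc28 = np.asarray(tjc28, dtype=float)
    sjc28 = np.asarray(sjc28, dtype=float)
    esr = np.asarray(esr, dtype=float)
    gh = np.asarray(gh, dtype=float)
    if np.any(tjc28 < 0) or np.any(tjc28 > 28) or np.any(sjc28 < 0) or np.any(sjc28 > 28):
        raise ValueError("joint counts must lie in [0, 28]")
    if np.any(esr < 1):
        raise ValueError("esr must be >= 1 mm/h (log is taken)")
    if np.any(gh < 0) or np.any(gh > 100):
        raise ValueError("gh must lie in [0, 100]")
    score = 0.56 * np.sqrt(tjc28) + 0.28 * np.sqrt(sjc28) + 0.70 * np.log(esr) + 0.014 * gh
    return float(score) if score.ndim == 0 else score


def cdai(tjc28, sjc28, ptga, phga):
    """Clinical Disease Activity Index: TJC28 + SJC28 + PtGA + PhGA (0–76)."""
    tjc28 = np.asarray(tjc28, dtype=float)
    sjc28 = np.asarray(sjc28, dtype=float)
    ptga = np.asarray(ptga, dtype=float)
    phga = np.asarray(phga, dtype=float)
    if np.any(tjc28 < 0) or np.any(tjc28 > 28) or np.any(sjc28 < 0) or np.any(sjc28 > 28):
        raise ValueError("joint counts must lie in [0, 28]")
    if np.any(ptga < 0) or np.any(ptga > 10) or np.any(phga < 0) or np.any(phga > 10):
        raise ValueError("global assessments must lie in [0, 10]")
    score = tjc28 + sjc28 + ptga + phga
    return float(score) if score.ndim == 0 else score


def eular_response_bulk(das28_baseline, das28_month6) -> np.ndarray:
    """Vectorized EULAR classification; returns an array of class labels."""
    b = np.asarray(das28_baseline, dtype=float)
    m6 = np.asarray(das28_month6, dtype=float)
    if np.any(b < 0) or np.any(m6 < 0):
        raise ValueError("DAS28 scores must be >= 0")
    delta = b - m6
    good = (delta > 1.2) & (m6 <= 3.2)
    none = (delta <= 0.6) | ((delta <= 1.2) & (m6 > 5.1))
    return np.where(good, "good", np.where(none, "none", "moderate")).astype(object)


def eular_response(das28_baseline: float, das28_month6: float) -> str:
    """EULAR response class ("good", "moderate" or "none") for one patient."""
    return str(eular_response_bulk(das28_baseline, das28_month6)[()])


def build_response_labels(
    visits: Iterable[ClinicalVisit],
) -> tuple[list[ResponseLabel], list[str]]:
    """Pair each sample's baseline and month-6 visits into a ResponseLabel.

    A sample with a duplicated visit is an error (corrupt input); a sample
    missing one of the two visits is skipped with a logged warning and
    returned in the exclusion list.
    """
    by_sample: dict[str, dict[str, ClinicalVisit]] = {}
    for v in visits:
        slot = by_sample.setdefault(v.sample_id, {})
        if v.visit in slot:
            raise ValueError(f"duplicate {v.visit} visit for sample {v.sample_id}")
        slot[v.visit] = v

    labels: list[ResponseLabel] = []
    excluded: list[str] = []
    for sid, slot in by_sample.items():
        if set(slot) != set(VISITS):
            missing = sorted(set(VISITS) - set(slot))
            logger.warning("sample %s missing visit(s) %s; skipped", sid, missing)
            excluded.append(sid)
            continue
        b, m = slot["baseline"], slot["month6"]
        das_b = das28_esr(b.tjc28, b.sjc28, b.esr, b.gh)
        das_m = das28_esr(m.tjc28, m.sjc28, m.esr, m.gh)
        cdai_b = cdai(b.tjc28, b.sjc28, b.ptga, b.phga)
        cdai_m = cdai(m.tjc28, m.sjc28, m.ptga, m.phga)
        cls = eular_response(das_b, das_m)
        labels.append(
            ResponseLabel(
                sample_id=sid,
                das28_baseline=das_b,
                das28_month6=das_m,
                delta_das28=das_b - das_m,
                cdai_baseline=cdai_b,
                cdai_month6=cdai_m,
                delta_cdai=cdai_b - cdai_m,
                eular_class=cls,
                is_responder=cls != "none",
            )
        )
    return labels, excluded


def labels_to_frame(labels: Sequence[ResponseLabel]):
    """Response labels as a pandas DataFrame indexed by sample_id."""
    import pandas as pd

    return pd.DataFrame(
        {
            "sample_id": [l.sample_id for l in labels],
            "das28_baseline": [l.das28_baseline for l in labels],
            "das28_month6": [l.das28_month6 for l in labels],
            "delta_das28": [l.delta_das28 for l in labels],
            "cdai_baseline": [l.cdai_baseline for l in labels],
            "cdai_month6": [l.cdai_month6 for l in labels],
            "delta_cdai": [l.delta_cdai for l in labels],
            "eular_class": [l.eular_class for l in labels],
            "is_responder": [l.is_responder for l in labels],
        }
    ).set_index("sample_id")


def visits_from_frame(df) -> list[ClinicalVisit]:
    """Construct ClinicalVisit records from a phenotype table.

    Expects columns sample_id, visit, tjc28, sjc28, esr, gh, ptga, phga.
    """
    required = {"sample_id", "visit", "tjc28", "sjc28", "esr", "gh", "ptga", "phga"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    return [
        ClinicalVisit(
            sample_id=str(r.sample_id),
            visit=str(r.visit),
            tjc28=int(r.tjc28),
            sjc28=int(r.sjc28),
            esr=float(r.esr),
            gh=float(r.gh),
            ptga=float(r.ptga),
            phga=float(r.phga),
        )
        for r in df.itertuples(index=False)
    ]
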