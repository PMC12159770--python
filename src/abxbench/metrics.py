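"""Basic inpatient antibiotic-use metrics.

Three quantities underlie every benchmarking comparison in this package:

* **DOT** (days of therapy): for one hospital stay, the sum over antibiotic
  agents of the number of calendar days on which that agent was administered.
  Agents given in combination are counted separately, so a day on
  vancomycin + cefepime contributes 2 DOT.
* **DASC** (days of antimicrobial spectrum coverage): DOT with each
  agent-day weighted by a per-agent spectrum score, so broad-spectrum
  therapy accumulates faster than narrow-spectrum therapy.
* **DP** (days present): patient-days of exposure, the normalising
  denominator for rates and the offset in the count models.

Spectrum scores are an external input: published score tables are
maintained elsewhere, so this module only enforces that every agent used
in a stay has a score.  A small synthetic table for tests and demos ships
with :func:`toy_spectrum_table`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgentDays",
    "SpectrumScoreTable",
    "PatientStay",
    "compute_dot",
    "compute_dasc",
    "rate_per_1000dp",
    "stay_totals",
    "toy_spectrum_table",
]


@dataclass(frozen=True)
class AgentDays:
    """Calendar days of administration of one antibiotic agent in one stay."""

    agent_id: str
    n_days: int

    def __post_init__(self) -> None:
        if self.n_days < 0:
            raise ValueError(f"n_days must be >= 0, got {self.n_days} for {self.agent_id}")


class SpectrumScoreTable:
    """Mapping from antibiotic agent to its (positive) spectrum score.

    Lookup of an unknown agent raises :class:`KeyError` naming the agent —
    a missing score is a data error, never silently treated as 1.
    """

    def __init__(self, scores: dict[str, float]):
        for agent, score in scores.items():
            if not score > 0:
                raise ValueError(f"spectrum score for {agent!r} must be > 0, got {score}")
        self._scores = dict(scores)

    def __getitem__(self, agent_id: str) -> float:
        try:
            return self._scores[agent_id]
        except KeyError:
            raise KeyError(
                f"agent {agent_id!r} has no spectrum score; add it to the score table"
            ) from None

    def __contains__(self, agent_id: str) -> bool:
        return agent_id in self._scores

    def __len__(self) -> int:
        return len(self._scores)

    def agents(self) -> list[str]:
        return sorted(self._scores)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SpectrumScoreTable":
        """Build from a two-column table (agent_id, score)."""
        return cls(dict(zip(frame.iloc[:, 0].astype(str), frame.iloc[:, 1].astype(float))))

    def to_frame(self) -> pd.DataFrame:
        agents = sorted(self._scores)
        return pd.DataFrame({"agent_id": agents, "score": [self._scores[a] for a in agents]})


@dataclass
class PatientStay:
    """One hospital stay with its covariates, exposure and antibiotic use."""

    stay_id: str
    hospital_id: str
    unit_id: str
    month: int
    age: float
    sex: int
    dp: int
    agent_days: list[AgentDays] = field(default_factory=list)
    comorbidity_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    procedure_flags: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    icu_stay: int = 0
    surgical_specialty: int = 0

    def __post_init__(self) -> None:
        if self.dp < 1:
            raise ValueError(f"stay {self.stay_id}: dp must be >= 1, got {self.dp}")
        seen: set[str] = set()
        for ad in self.agent_days:
            if ad.agent_id in seen:
                raise ValueError(f"stay {self.stay_id}: duplicate agent {ad.agent_id!r}")
            seen.add(ad.agent_id)
            if ad.n_days > self.dp:
                raise ValueError(
                    f"stay {self.stay_id}: agent {ad.agent_id!r} has {ad.n_days} days "
                    f"but the stay has only {self.dp} days present"
                )


def compute_dot(stay: PatientStay) -> int:
    """Days of therapy for one stay: sum of agent-days over all agents."""
    return int(sum(ad.n_days for ad in stay.agent_days))


def compute_dasc(stay: PatientStay, scores: SpectrumScoreTable) -> float:
    """Days of antimicrobial spectrum coverage: spectrum-weighted agent-days.

    Equals :func:`compute_dot` when every score is 1.  Raises ``KeyError``
    naming the first agent that is missing from ``scores``.
    """
    return float(sum(ad.n_days * scores[ad.agent_id] for ad in stay.agent_days))


def rate_per_1000dp(numerator: float, dp_total: int) -> float:
    """Use per 1000 days present: ``1000 * numerator / dp_total``."""
    if dp_total < 1:
        raise ValueError(f"dp_total must be >= 1, got {dp_total}")
    if numerator < 0:
        raise ValueError(f"numerator must be >= 0, got {numerator}")
    return 1000.0 * float(numerator) / float(dp_total)


def stay_totals(admin_long: pd.DataFrame, scores: SpectrumScoreTable) -> pd.DataFrame:
    """Per-stay DOT and DASC from a long administrations table.

    Parameters
    ----------
    admin_long
        Columns ``stay_id``, ``agent_id``, ``n_days`` — one row per
        (stay, agent).
    scores
        Spectrum score table covering every agent in ``admin_long``.

    Returns
    -------
    DataFrame indexed by ``stay_id`` with columns ``dot`` and ``dasc``.
    Stays absent from ``admin_long`` simply do not appear (their totals
    are zero by definition).
    """
    missing = set(admin_long["agent_id"].unique()) - set(scores.agents())
    if missing:
        raise KeyError(f"agents without spectrum score: {sorted(missing)}")
    if (admin_long["n_days"] < 0).any():
        raise ValueError("n_days must be >= 0")
    w = admin_long["agent_id"].map({a: scores[a] for a in scores.agents()})
    return pd.DataFrame(
        {
            "dot": admin_long.groupby("stay_id")["n_days"].sum(),
            "dasc": (admin_long["n_days"] * w).groupby(admin_long["stay_id"]).sum(),
        }
    )


def toy_spectrum_table() -> SpectrumScoreTable:
    """A small synthetic spectrum-score table for tests and demos.

    Scores are plausible in spread (narrow agents near 1, very broad agents
    in the teens) but are NOT any published score set.
    """
    return SpectrumScoreTable(
        {
            "penicillin": 1.0,
            "amoxicillin": 2.0,
            "ampicillin": 2.0,
            "cefazolin": 3.0,
            "ceftriaxone": 5.0,
            "cefepime": 8.0,
            "ceftazidime": 7.0,
            "ciprofloxacin": 6.0,
            "levofloxacin": 7.0,
            "azithromycin": 4.0,
            "doxycycline": 4.0,
            "metronidazole": 2.0,
            "clindamycin": 3.0,
            "vancomycin": 4.0,
            "linezolid": 4.0,
            "daptomycin": 4.0,
            "piperacillin-tazobactam": 11.0,
            "meropenem": 13.0,
            "imipenem-cilastatin": 13.0,
            "tigecycline": 16.0,
        }
    )
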