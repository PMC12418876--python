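"""Lung cancer natural history: onset, histology, stage progression, detection.

The onset hazard is a two-term model: a background term log-linear in age
plus a smoking term proportional to cumulative packyears with a log-linear
age coefficient. Tumors progress through the fixed stage sequence
IA -> IB -> II -> IIIA -> IIIB -> IV with Weibull preclinical dwell times per
stage x histology, and surface clinically through per-stage detection
hazards. Small cell tumors are parameterised with shorter dwell times
(faster progression, hence less screen-detectable preclinical time).

Tumor events are generated unconditionally on other-cause death; censoring
against the competing death happens during scenario assembly so that the
natural history is identical across screening scenarios (common random
numbers).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .population import SmokingHistory, packyears_grid, packyears

STAGES = ("IA", "IB", "II", "IIIA", "IIIB", "IV")
HISTOLOGIES = ("AD", "SQ", "ONSCLC", "SCLC")
PREONSET = "preonset"


@dataclass(frozen=True)
class StageParams:
    """Dwell-time and clinical-detection parameters for one stage x histology.

    Dwell times are Weibull (shape, scale in years); the final stage has no
    dwell (the tumor remains in stage IV until detected or the person dies).
    Detection is exponential with ``detection_hazard`` per year within the
    stage.
    """

    dwell_shape: float
    dwell_scale: float
    detection_hazard: float


@dataclass
class NaturalHistoryParams:
    onset_background_log: tuple[float, float]  # (b0, b1): exp(b0 + b1 * age)
    onset_smoking_log: tuple[float, float]  # (s0, s1): packyears * exp(s0 + s1 * age)
    histology_probs: dict[str, dict[str, float]]  # by "never"/"ever" smoker
    stage_params: dict[tuple[str, str], StageParams]
    max_age: int = 100

    def stage_cell(self, stage: str, histology: str) -> StageParams:
        try:
            return self.stage_params[(stage, histology)]
        except KeyError:
            raise ConfigurationError(
                f"missing natural-history parameters for stage {stage}, "
                f"histology {histology}"
            ) from None


@dataclass(frozen=True)
class Tumor:
    """One simulated lung tumor and its counterfactual clinical surfacing."""

    onset_age: float
    histology: str
    stage_entry_ages: tuple[float, ...]  # entry into IA, IB, II, IIIA, IIIB, IV
    clinical_detection_age: float
    stage_at_clinical_detection: str

    def __post_init__(self):
        entries = self.stage_entry_ages
        if len(entries) != len(STAGES):
            raise ValueError("stage trajectory must cover all stages")
        if any(b <= a for a, b in zip(entries, entries[1:])):
            raise ValueError("stage entry ages must be strictly increasing")
        if self.clinical_detection_age < self.onset_age:
            raise ValueError("clinical detection precedes onset")


def onset_hazard(
    history: SmokingHistory, age: float, params: NaturalHistoryParams
) -> float:
    """Annual lung cancer onset hazard at ``age`` for the given smoking history."""
    if age < 0:
        raise ValueError("age must be non-negative")
    b0, b1 = params.onset_background_log
    s0, s1 = params.onset_smoking_log
    py = packyears(history, age)
    return math.exp(b0 + b1 * age) + py * math.exp(s0 + s1 * age)


def stage_at(tumor: Tumor, age: float) -> str:
    """Stage occupied at ``age`` (``"preonset"`` before onset)."""
    if age < tumor.onset_age:
        return PREONSET
    idx = int(np.searchsorted(tumor.stage_entry_ages, age, side="right")) - 1
    return STAGES[idx]


def _categorical(probs: dict[str, float], keys: tuple[str, ...], u: float) -> str:
    total = 0.0
    for k in keys:
        total += probs[k]
        if u < total:
            return k
    return keys[-1]


def simulate_tumor(
    history: SmokingHistory,
    params: NaturalHistoryParams,
    rng: np.random.Generator | int,
) -> Tumor | None:
    """Simulate onset and full preclinical trajectory; ``None`` if no onset.

    All random draws are made in a fixed order so identical generator states
    produce identical tumors.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    e_onset = rng.exponential()
    u_hist = rng.random()
    u_dwell = rng.random(len(STAGES) - 1)
    e_detect = rng.exponential(size=len(STAGES))

    mids = np.arange(params.max_age) + 0.5
    b0, b1 = params.onset_background_log
    s0, s1 = params.onset_smoking_log
    lam = np.exp(b0 + b1 * mids) + packyears_grid(history, mids) * np.exp(
        s0 + s1 * mids
    )
    cum = np.concatenate([[0.0], np.cumsum(lam)])
    if e_onset >= cum[-1]:
        return None
    k = int(np.searchsorted(cum, e_onset, side="right")) - 1
    onset = k + (e_onset - cum[k]) / lam[k]

    status = "ever" if history.ever_smoker and onset >= history.start_age else "never"
    histology = _categorical(params.histology_probs[status], HISTOLOGIES, u_hist)

    entries = [onset]
    for i, stage in enumerate(STAGES[:-1]):
        cell = params.stage_cell(stage, histology)
        dwell = cell.dwell_scale * (-math.log1p(-u_dwell[i])) ** (1.0 / cell.dwell_shape)
        entries.append(entries[-1] + max(dwell, 1e-9))

    detection_age = math.inf
    det_stage = STAGES[-1]
    for i, stage in enumerate(STAGES):
        cell = params.stage_cell(stage, histology)
        dur = (entries[i + 1] - entries[i]) if i < len(STAGES) - 1 else math.inf
        if cell.detection_hazard > 0:
            t = e_detect[i] / cell.detection_hazard
            if t < dur:
                detection_age = entries[i] + t
                det_stage = stage
                break

    return Tumor(
        onset_age=float(onset),
        histology=histology,
        stage_entry_ages=tuple(entries),
        clinical_detection_age=float(detection_age),
        stage_at_clinical_detection=det_stage,
    )
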