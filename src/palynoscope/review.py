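"""Expert-review queue, simulated expert verification and workload budgets.

Images that volunteers validated as containing a microfossil, flagged
as disputed, or failed to agree on are routed to an expert (a project
officer, with difficult specimens escalated to a palynologist).  On
synthetic data the expert is an oracle over the ground-truth
annotations with a configurable miss rate; real review results would
enter the pipeline through the same :class:`ReviewResult` records.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .cohort import INDETERMINABLE, Specimen, TruthAnnotation
from .consensus import Category, ImageVerdict
from .geometry import Point

__all__ = [
    "ExpertDetection",
    "ReviewResult",
    "ExpertOracle",
    "build_review_queue",
    "expert_verify",
    "workload_hours",
]


@dataclass(frozen=True)
class ExpertDetection:
    """One expert-confirmed specimen occurrence in one image."""

    local: Point
    label: str  # taxon label or "indeterminable"
    escalated: bool = False


@dataclass(frozen=True)
class ReviewResult:
    image_id: str
    verified: bool
    detections: tuple[ExpertDetection, ...]
    reviewer: str  # "project_officer" | "palynologist"

    def __post_init__(self) -> None:
        if self.verified != bool(self.detections):
            raise ValueError("verified must mirror non-empty detections")


@dataclass(frozen=True)
class ExpertOracle:
    """Ground-truth-backed expert with imperfections.

    ``miss_rate`` is the probability a true specimen is overlooked;
    ``escalation_rate`` the fraction of detections the project officer
    cannot identify and escalates to the palynologist.
    """

    truth: Mapping[str, TruthAnnotation]
    specimens_by_id: Mapping[str, Specimen]
    miss_rate: float = 0.0
    escalation_rate: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0 and 0.0 <= self.escalation_rate <= 1.0):
            raise ValueError("rates must be in [0, 1]")


def build_review_queue(verdicts: Iterable[ImageVerdict]) -> list[str]:
    """Image ids needing expert review, in stable id order.

    The queue is the union of validated-fossil images, disputed images
    and no-agreement images.  Pending verdicts are an error (review
    happens after an expedition completes).
    """
    vs = list(verdicts)
    pending = [v.image_id for v in vs if v.category is Category.PENDING]
    if pending:
        raise ValueError("pending verdicts in queue build: " + ", ".join(pending[:10]))
    queue = [
        v.image_id
        for v in vs
        if v.category in (Category.AGREEMENT_FOSSIL, Category.NO_AGREEMENT) or v.disputed
    ]
    return sorted(queue)


def expert_verify(
    queue: Sequence[str],
    oracle: ExpertOracle,
    seed: int | np.random.Generator = 0,
) -> list[ReviewResult]:
    """Review the queued images against the oracle's ground truth.

    With ``miss_rate`` 0 the results equal the ground truth restricted
    to the queue.  Identifiable specimens receive their true taxon
    label, unidentifiable ones ``indeterminable``; each detection is
    independently escalated to the palynologist with probability
    ``escalation_rate``.
    """
    rng = np.random.default_rng(seed)
    out: list[ReviewResult] = []
    for image_id in queue:
        if image_id not in oracle.truth:
            raise KeyError(f"unknown image id {image_id!r}")
        ann = oracle.truth[image_id]
        dets = []
        for d in ann.detections:
            if rng.random() < oracle.miss_rate:
                continue
            sp = oracle.specimens_by_id[d.specimen_id]
            label = sp.taxon if sp.identifiable else INDETERMINABLE
            escalated = rng.random() < oracle.escalation_rate
            dets.append(ExpertDetection(d.local, label, escalated))
        reviewer = "palynologist" if any(d.escalated for d in dets) else "project_officer"
        out.append(ReviewResult(image_id, bool(dets), tuple(dets), reviewer))
    return out


def workload_hours(n_images: int, seconds_per_image: float) -> tuple[float, int]:
    """Review-time budget: (hours, hours rounded to the nearest whole).

    hours = n_images * seconds_per_image / 3600.
    """
    if n_images < 0 or seconds_per_image < 0:
        raise ValueError("inputs must be non-negative")
    hours = n_images * seconds_per_image / 3600.0
    return hours, round(hours)
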