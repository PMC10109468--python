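"""Volunteer-consensus validation of image transcriptions.

Each SEM image is shown sequentially to up to ``max_views`` distinct
volunteers, who each answer a five-question template: focus, occurrence
(microfossil present or not), count, position within the image, and the
name of the microfossil.  The image closes ("validates") at the first
moment a quorum of responses is pairwise identical on all matched
answer fields.  The verdict records the consensus category, whether a
fossil report arrived before a no-fossil validation (a *disputed*
image), and which answer fields the responses disagreed on — the raw
material of the expert-review queue and of the disagreement-reason
decomposition.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

__all__ = [
    "FOCUS_VALUES",
    "OCCURRENCE_VALUES",
    "POSITION_VALUES",
    "ANSWER_FIELDS",
    "Response",
    "Category",
    "ImageVerdict",
    "FlowReport",
    "aggregate_image",
    "disagreement_fields",
    "flow_report",
]

FOCUS_VALUES = ("in_focus", "out_of_focus")
OCCURRENCE_VALUES = ("fossil", "no_fossil")
POSITION_VALUES = ("middle", "edge", "middle_and_edge", "none")

#: The five questionnaire answer fields, in template order.
ANSWER_FIELDS = ("focus", "occurrence", "count", "position", "name")


@dataclass(frozen=True)
class Response:
    """One volunteer's completed questionnaire for one image.

    ``order_index`` is the 1-based arrival position of the response in
    the image's serving sequence.  A ``no_fossil`` occurrence forces
    count 0, position ``none`` and name ``none``.
    """

    image_id: str
    volunteer_id: str
    order_index: int
    focus: str
    occurrence: str
    count: int
    position: str
    name: str

    def __post_init__(self) -> None:
        if self.focus not in FOCUS_VALUES:
            raise ValueError(f"invalid focus answer: {self.focus!r}")
        if self.occurrence not in OCCURRENCE_VALUES:
            raise ValueError(f"invalid occurrence answer: {self.occurrence!r}")
        if self.position not in POSITION_VALUES:
            raise ValueError(f"invalid position answer: {self.position!r}")
        if self.count < 0:
            raise ValueError("count must be non-negative")
        if self.order_index < 1:
            raise ValueError("order_index is 1-based")
        if self.occurrence == "no_fossil":
            if self.count != 0 or self.position != "none" or self.name != "none":
                raise ValueError(
                    "a no_fossil response must have count 0, position 'none', name 'none'"
                )

    def answer_key(
        self, fields: Sequence[str] = ANSWER_FIELDS, count_cap: int = 10
    ) -> tuple:
        """The response's answers on ``fields``, counts binned at ``count_cap``+.

        Two responses "agree" iff their keys are equal; the drop-down's
        top bin makes all counts >= count_cap compare equal.
        """
        out = []
        for f in fields:
            v = getattr(self, f)
            if f == "count":
                v = min(v, count_cap)
            out.append(v)
        return tuple(out)


class Category(str, Enum):
    AGREEMENT_FOSSIL = "agreement_fossil"
    AGREEMENT_NO_FOSSIL = "agreement_no_fossil"
    NO_AGREEMENT = "no_agreement"
    PENDING = "pending"


@dataclass(frozen=True)
class ImageVerdict:
    """Outcome of consensus validation for one image."""

    image_id: str
    category: Category
    disputed: bool
    fossil_sublabel: str  # "pollen_or_spore" | "unknown" | "none"
    disagreement_fields: frozenset[str]
    n_responses: int

    def __post_init__(self) -> None:
        if self.disputed and self.category is not Category.AGREEMENT_NO_FOSSIL:
            raise ValueError("only no-fossil validations can be disputed")


def _sublabel(name: str) -> str:
    """Collapse an agreed name answer to the review-flow sublabel."""
    if name == "none":
        return "none"
    return "unknown" if name == "unknown" else "pollen_or_spore"


def _check_stream(responses: Sequence[Response], max_views: int) -> None:
    if len(responses) > max_views:
        raise ValueError(f"more than max_views={max_views} responses")
    seen: set[int] = set()
    prev = 0
    for r in responses:
        if r.order_index in seen:
            raise ValueError(f"duplicate order_index {r.order_index}")
        if r.order_index < prev:
            raise ValueError("responses must be sorted by order_index")
        seen.add(r.order_index)
        prev = r.order_index


def aggregate_image(
    responses: Sequence[Response],
    quorum: int = 3,
    max_views: int = 4,
    match_fields: Sequence[str] = ANSWER_FIELDS,
    count_cap: int = 10,
    order_aware_dispute: bool = True,
) -> ImageVerdict:
    """Aggregate an image's ordered responses into a verdict.

    Scanning in arrival order, the image closes at the first response
    at which ``quorum`` responses are pairwise identical on all
    ``match_fields``; the category follows the agreeing answers'
    occurrence.  A closed no-fossil image is *disputed* if at least one
    fossil report arrived before closure (``order_aware_dispute=False``
    instead flags any fossil report in the stream).  ``max_views``
    responses with no agreeing quorum give ``NO_AGREEMENT``; an
    unclosed shorter stream is ``PENDING``.
    """
    if quorum > max_views:
        raise ValueError("quorum cannot exceed max_views")
    if quorum < 1:
        raise ValueError("quorum must be >= 1")
    _check_stream(responses, max_views)
    image_id = responses[0].image_id if responses else ""

    tallies: Counter[tuple] = Counter()
    closed_at = None
    agreed_key = None
    for i, r in enumerate(responses):
        key = r.answer_key(match_fields, count_cap)
        tallies[key] += 1
        if tallies[key] >= quorum:
            closed_at, agreed_key = i, key
            break

    if closed_at is None:
        category = Category.NO_AGREEMENT if len(responses) >= max_views else Category.PENDING
        dis = (
            disagreement_fields(responses, count_cap=count_cap)
            if len(responses) >= 2
            else frozenset()
        )
        return ImageVerdict(image_id, category, False, "none", dis, len(responses))

    considered = responses[: closed_at + 1]
    agreed = dict(zip(match_fields, agreed_key))
    occurrence = agreed.get("occurrence")
    if occurrence is None:  # occurrence excluded from matching: take it from an agreeing response
        occurrence = next(
            r.occurrence
            for r in considered
            if r.answer_key(match_fields, count_cap) == agreed_key
        )
    if occurrence == "fossil":
        category = Category.AGREEMENT_FOSSIL
        name = agreed.get("name")
        if name is None:
            name = next(
                r.name
                for r in considered
                if r.answer_key(match_fields, count_cap) == agreed_key
            )
        sub = _sublabel(name)
        disputed = False
    else:
        category = Category.AGREEMENT_NO_FOSSIL
        sub = "none"
        pool = responses if not order_aware_dispute else considered
        disputed = any(r.occurrence == "fossil" for r in pool)

    # fields on which any pre-closure response dissented from the consensus
    dis = _dissent_fields(considered, agreed, match_fields, count_cap)
    return ImageVerdict(image_id, category, disputed, sub, dis, len(considered))


def _dissent_fields(
    considered: Sequence[Response],
    agreed: Mapping[str, object],
    match_fields: Sequence[str],
    count_cap: int,
) -> frozenset[str]:
    out = set()
    for r in considered:
        for f in match_fields:
            v = getattr(r, f)
            if f == "count":
                v = min(v, count_cap)
            if v != agreed[f]:
                out.add(f)
    return frozenset(out)


def disagreement_fields(
    responses: Sequence[Response],
    fields: Sequence[str] = ANSWER_FIELDS,
    count_cap: int = 10,
) -> frozenset[str]:
    """Answer fields on which not all responses agree (empty iff identical)."""
    if len(responses) < 2:
        raise ValueError("disagreement requires at least two responses")
    out = set()
    for f in fields:
        keys = {r.answer_key((f,), count_cap) for r in responses}
        if len(keys) > 1:
            out.add(f)
    return frozenset(out)


@dataclass(frozen=True)
class FlowReport:
    """Image-flow accounting of a validated expedition.

    Mirrors the review-pipeline bookkeeping: closed images split into
    agreement (fossil / no-fossil, with the fossil group subdivided by
    sublabel and the no-fossil group carrying a disputed subset) and
    no-agreement; the review queue is fossil + disputed + no-agreement.
    """

    n_images: int
    n_agreement: int
    n_agreement_no_fossil: int
    n_agreement_fossil: int
    n_fossil_pollen_spore: int
    n_fossil_unknown: int
    n_disputed: int
    n_no_agreement: int
    n_review_queue: int
    n_pending: int = 0

    def __post_init__(self) -> None:
        assert self.n_agreement == self.n_agreement_no_fossil + self.n_agreement_fossil
        assert self.n_agreement + self.n_no_agreement + self.n_pending == self.n_images
        assert self.n_disputed <= self.n_agreement_no_fossil
        assert self.n_review_queue == (
            self.n_agreement_fossil + self.n_disputed + self.n_no_agreement
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "n_images": self.n_images,
            "n_agreement": self.n_agreement,
            "n_agreement_no_fossil": self.n_agreement_no_fossil,
            "n_agreement_fossil": self.n_agreement_fossil,
            "n_fossil_pollen_spore": self.n_fossil_pollen_spore,
            "n_fossil_unknown": self.n_fossil_unknown,
            "n_disputed": self.n_disputed,
            "n_no_agreement": self.n_no_agreement,
            "n_review_queue": self.n_review_queue,
            "n_pending": self.n_pending,
        }


def flow_report(verdicts: Iterable[ImageVerdict], allow_pending: bool = False) -> FlowReport:
    """Tally verdicts into a :class:`FlowReport`.

    With ``allow_pending=False`` (final expedition reports) a PENDING
    verdict raises; otherwise pending images are tallied separately.
    """
    vs = list(verdicts)
    pending = [v for v in vs if v.category is Category.PENDING]
    if pending and not allow_pending:
        raise ValueError(
            f"{len(pending)} image(s) still pending: "
            + ", ".join(v.image_id for v in pending[:5])
        )
    n_af = sum(v.category is Category.AGREEMENT_FOSSIL for v in vs)
    n_anf = sum(v.category is Category.AGREEMENT_NO_FOSSIL for v in vs)
    n_na = sum(v.category is Category.NO_AGREEMENT for v in vs)
    n_disp = sum(v.disputed for v in vs)
    return FlowReport(
        n_images=len(vs),
        n_agreement=n_af + n_anf,
        n_agreement_no_fossil=n_anf,
        n_agreement_fossil=n_af,
        n_fossil_pollen_spore=sum(
            v.category is Category.AGREEMENT_FOSSIL and v.fossil_sublabel == "pollen_or_spore"
            for v in vs
        ),
        n_fossil_unknown=sum(
            v.category is Category.AGREEMENT_FOSSIL and v.fossil_sublabel == "unknown"
            for v in vs
        ),
        n_disputed=n_disp,
        n_no_agreement=n_na,
        n_review_queue=n_af + n_disp + n_na,
        n_pending=len(pending),
    )
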