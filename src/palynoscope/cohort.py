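"""Synthetic specimen fields and simulated volunteer transcription streams.

The generator emulates the study conditions the downstream pipeline
assumes: a planar field of palynomorphs scattered over one or more SEM
montages as a homogeneous Poisson point process at a stated density
(specimens per cm**2), per-tile ground-truth annotations that include
the duplicate appearances created by tile overlap, and up to four
sequential volunteer views per image drawn from a pool of volunteers
with imperfect detection, counting and naming and strongly
heterogeneous activity (a Pareto-tailed activity weight whose shape
makes the top decile of volunteers produce roughly 85% of
transcriptions).

All stochastic operations take explicit seeds; a single master seed
spawns per-stage substreams in the pipeline driver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .consensus import (
    ANSWER_FIELDS,
    Category,
    ImageVerdict,
    Response,
    aggregate_image,
)
from .geometry import Point, TileGrid, TileIndex, global_to_tile_local, tiles_covering

__all__ = [
    "INDETERMINABLE",
    "DEFAULT_TAXON_MIX",
    "Specimen",
    "TaxonMix",
    "VolunteerProfile",
    "TruthDetection",
    "TruthAnnotation",
    "SimulationResult",
    "make_image_id",
    "parse_image_id",
    "generate_specimens",
    "truth_annotations",
    "simulate_transcriptions",
    "default_profiles",
    "pareto_shape_for_top_share",
    "top_decile_share",
]

#: Label used for specimens that cannot be attributed to a taxon.
INDETERMINABLE = "indeterminable"


@dataclass(frozen=True)
class Specimen:
    """A ground-truth microfossil on the rock surface."""

    specimen_id: str
    montage: int
    position: Point  # montage-global, micrometres
    radius_um: float
    taxon: str
    identifiable: bool

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("radius_um must be positive")


@dataclass(frozen=True)
class TaxonMix:
    """Relative frequencies of identifiable taxa plus an indeterminable share.

    ``frequencies`` are conditional on the specimen being identifiable
    and must sum to 1; ``indeterminable_fraction`` is the marginal
    probability that a specimen cannot be attributed to any taxon.
    """

    frequencies: Mapping[str, float]
    indeterminable_fraction: float = 0.0

    def __post_init__(self) -> None:
        if not self.frequencies:
            raise ValueError("at least one taxon is required")
        if any(f < 0 for f in self.frequencies.values()):
            raise ValueError("frequencies must be non-negative")
        if not math.isclose(sum(self.frequencies.values()), 1.0, abs_tol=1e-9):
            raise ValueError("taxon frequencies must sum to 1")
        if not (0.0 <= self.indeterminable_fraction <= 1.0):
            raise ValueError("indeterminable_fraction must be in [0, 1]")

    @property
    def taxa(self) -> tuple[str, ...]:
        return tuple(self.frequencies)


#: Default mix mirroring the dominance structure of a Miocene rainforest
#: lake assemblage: southern-beech pollen dominant, then fungal spores,
#: then fern/moss spores, a tail of rarer forms, and roughly a fifth of
#: specimens too poorly preserved to attribute (83 of 383).
DEFAULT_TAXON_MIX = TaxonMix(
    frequencies={
        "Nothofagidites": 0.44,
        "fungal_spore": 0.20,
        "fern_moss_spore": 0.09,
        "Myrtaceidites": 0.08,
        "Araucariaceae": 0.07,
        "Quintinia": 0.06,
        "other_angiosperm": 0.06,
    },
    indeterminable_fraction=83.0 / 383.0,
)


@dataclass(frozen=True)
class VolunteerProfile:
    """Error model and engagement propensity of one simulated volunteer.

    ``sensitivity`` is the per-specimen detection probability;
    ``false_positive_rate`` the probability of reporting a microfossil
    in an empty image; ``name_confusion`` a row-stochastic matrix over
    taxon labels plus ``"unknown"``; ``count_error_rate`` the chance of
    mis-stating the detected count by one; ``focus_error_rate`` the
    chance of answering the focus question wrongly; ``activity_weight``
    the relative propensity to transcribe; ``skip_rate`` the chance of
    skipping a served image (producing no response).
    """

    volunteer_id: str
    sensitivity: float = 0.85
    false_positive_rate: float = 0.04
    name_confusion: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    count_error_rate: float = 0.10
    focus_error_rate: float = 0.08
    activity_weight: float = 1.0
    skip_rate: float = 0.0

    def __post_init__(self) -> None:
        for p in (
            self.sensitivity,
            self.false_positive_rate,
            self.count_error_rate,
            self.focus_error_rate,
            self.skip_rate,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if self.activity_weight <= 0:
            raise ValueError("activity_weight must be positive")
        for label, row in self.name_confusion.items():
            if not math.isclose(sum(row.values()), 1.0, abs_tol=1e-9):
                raise ValueError(f"confusion row for {label!r} must sum to 1")


@dataclass(frozen=True)
class TruthDetection:
    specimen_id: str
    local: Point  # tile-local, micrometres
    position_class: str  # "middle" | "edge"


@dataclass(frozen=True)
class TruthAnnotation:
    """Ground truth for one SEM image (tile), including overlap duplicates."""

    image_id: str
    montage: int
    tile: TileIndex
    detections: tuple[TruthDetection, ...] = ()

    @property
    def n_specimens(self) -> int:
        return len(self.detections)

    @property
    def position_answer(self) -> str:
        """The truthful answer to the position question for this image."""
        if not self.detections:
            return "none"
        classes = {d.position_class for d in self.detections}
        if classes == {"middle"}:
            return "middle"
        if classes == {"edge"}:
            return "edge"
        return "middle_and_edge"


def make_image_id(montage: int, tile: TileIndex) -> str:
    return f"m{montage}_r{tile.row:03d}_c{tile.col:03d}"


def parse_image_id(image_id: str) -> tuple[int, TileIndex]:
    m, r, c = image_id.split("_")
    return int(m[1:]), TileIndex(col=int(c[1:]), row=int(r[1:]))


def generate_specimens(
    grids: Sequence[TileGrid],
    density_per_cm2: float,
    mix: TaxonMix = DEFAULT_TAXON_MIX,
    radius_mean_um: float = 15.0,
    radius_sigma: float = 0.35,
    seed: int | np.random.Generator = 0,
) -> list[Specimen]:
    """Scatter specimens over the montages as a Poisson point process.

    The specimen count in each montage is Poisson with mean density
    times that montage's exact (unrounded) area; positions are uniform
    over the montage extent; taxa are sampled from ``mix`` and radii
    from a log-normal with the given median and log-scale sigma.
    """
    if density_per_cm2 < 0:
        raise ValueError("density_per_cm2 must be non-negative")
    rng = np.random.default_rng(seed)
    taxa = list(mix.taxa)
    probs = np.array([mix.frequencies[t] for t in taxa], dtype=float)
    probs = probs / probs.sum()
    out: list[Specimen] = []
    k = 0
    for mi, grid in enumerate(grids):
        n = rng.poisson(density_per_cm2 * grid.area_cm2)
        xs = rng.uniform(0.0, grid.width_um, n)
        ys = rng.uniform(0.0, grid.height_um, n)
        radii = rng.lognormal(math.log(radius_mean_um), radius_sigma, n)
        indet = rng.random(n) < mix.indeterminable_fraction
        picks = rng.choice(len(taxa), size=n, p=probs)
        for i in range(n):
            out.append(
                Specimen(
                    specimen_id=f"s{k:05d}",
                    montage=mi,
                    position=Point(float(xs[i]), float(ys[i])),
                    radius_um=float(radii[i]),
                    taxon=INDETERMINABLE if indet[i] else taxa[picks[i]],
                    identifiable=not bool(indet[i]),
                )
            )
            k += 1
    return out


def truth_annotations(
    specimens: Sequence[Specimen], grids: Sequence[TileGrid]
) -> dict[str, TruthAnnotation]:
    """Per-tile ground truth for every image of every montage.

    Every specimen appears in each tile whose footprint covers its
    centre, so a specimen in an overlap strip yields duplicate
    detections in the adjacent tiles.  A detection's position class is
    ``edge`` when the centre lies in an overlap band shared with a
    neighbouring tile (equivalently, when more than one tile covers
    it), ``middle`` otherwise.
    """
    dets: dict[str, list[TruthDetection]] = {}
    for sp in specimens:
        grid = grids[sp.montage]
        covering = tiles_covering(grid, sp.position)
        if not covering:
            raise ValueError(f"specimen {sp.specimen_id} outside montage extent")
        cls = "edge" if len(covering) > 1 else "middle"
        for tile in covering:
            local = global_to_tile_local(grid, tile, sp.position)
            dets.setdefault(make_image_id(sp.montage, tile), []).append(
                TruthDetection(sp.specimen_id, local, cls)
            )
    out: dict[str, TruthAnnotation] = {}
    for mi, grid in enumerate(grids):
        for tile in grid.all_tiles():
            iid = make_image_id(mi, tile)
            out[iid] = TruthAnnotation(
                iid,
                mi,
                tile,
                tuple(sorted(dets.get(iid, []), key=lambda d: d.specimen_id)),
            )
    return out


def pareto_shape_for_top_share(top_quantile: float = 0.10, share: float = 0.85) -> float:
    """Pareto tail index whose Lorenz curve gives the top ``top_quantile``
    of volunteers a ``share`` of total activity (share = q**(1 - 1/alpha))."""
    return 1.0 / (1.0 - math.log(share) / math.log(top_quantile))


def default_profiles(
    n_volunteers: int = 100,
    taxa: Sequence[str] = DEFAULT_TAXON_MIX.taxa,
    seed: int | np.random.Generator = 0,
    activity_shape: float | None = None,
    **overrides: float,
) -> list[VolunteerProfile]:
    """A volunteer pool with the default calibrated error rates and a
    heavy-tailed activity distribution.

    ``overrides`` are applied uniformly to every profile (e.g.
    ``sensitivity=1.0`` for a perfect pool).
    """
    rng = np.random.default_rng(seed)
    if activity_shape is None:
        activity_shape = pareto_shape_for_top_share()
    weights = 1.0 + rng.pareto(activity_shape, n_volunteers)
    confusion = default_confusion(taxa)
    return [
        VolunteerProfile(
            volunteer_id=f"v{i:04d}",
            name_confusion=confusion,
            activity_weight=float(weights[i]),
            **overrides,
        )
        for i in range(n_volunteers)
    ]


def default_confusion(
    taxa: Sequence[str], correct: float = 0.80, unknown: float = 0.12
) -> dict[str, dict[str, float]]:
    """Row-stochastic naming matrix: mostly correct, some 'unknown',
    the rest spread evenly over the other taxa."""
    taxa = list(taxa)
    rows: dict[str, dict[str, float]] = {}
    spread = 1.0 - correct - unknown
    for t in taxa:
        others = [u for u in taxa if u != t]
        row = {t: correct, "unknown": unknown}
        for u in others:
            row[u] = spread / len(others)
        rows[t] = row
    # indeterminable specimens are mostly called unknown
    row = {"unknown": 0.90}
    for u in taxa:
        row[u] = 0.10 / len(taxa)
    rows[INDETERMINABLE] = row
    return rows


def perfect_profiles(n_volunteers: int = 5, taxa: Sequence[str] = DEFAULT_TAXON_MIX.taxa) -> list[VolunteerProfile]:
    """Error-free volunteers (identity confusion, equal activity)."""
    identity = {t: {t: 1.0} for t in taxa}
    identity[INDETERMINABLE] = {"unknown": 1.0}
    return [
        VolunteerProfile(
            volunteer_id=f"v{i:04d}",
            sensitivity=1.0,
            false_positive_rate=0.0,
            name_confusion=identity,
            count_error_rate=0.0,
            focus_error_rate=0.0,
            activity_weight=1.0,
        )
        for i in range(n_volunteers)
    ]


def _truth_name(ann: TruthAnnotation, specimens_by_id: Mapping[str, Specimen]) -> str:
    """Deterministic truthful name answer: most common identifiable taxon,
    ties broken lexicographically; all-indeterminable images are 'unknown'."""
    taxa = [
        specimens_by_id[d.specimen_id].taxon
        for d in ann.detections
        if specimens_by_id[d.specimen_id].identifiable
    ]
    if not taxa:
        return "unknown"
    counts: dict[str, int] = {}
    for t in taxa:
        counts[t] = counts.get(t, 0) + 1
    return min(counts, key=lambda t: (-counts[t], t))


def _draw_from_row(row: Mapping[str, float], rng: np.random.Generator) -> str:
    labels = sorted(row)
    probs = np.array([row[l] for l in labels], dtype=float)
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


def _respond(
    profile: VolunteerProfile,
    ann: TruthAnnotation,
    specimens_by_id: Mapping[str, Specimen],
    order_index: int,
    rng: np.random.Generator,
) -> Response:
    focus = "in_focus" if rng.random() >= profile.focus_error_rate else "out_of_focus"
    detected = [d for d in ann.detections if rng.random() < profile.sensitivity]
    if detected:
        count = len(detected)
        if rng.random() < profile.count_error_rate:
            count = max(1, count + int(rng.choice([-1, 1])))
        classes = {d.position_class for d in detected}
        position = (
            "middle"
            if classes == {"middle"}
            else "edge"
            if classes == {"edge"}
            else "middle_and_edge"
        )
        true_name = _truth_name(
            TruthAnnotation(ann.image_id, ann.montage, ann.tile, tuple(detected)),
            specimens_by_id,
        )
        row_key = true_name if true_name in profile.name_confusion else INDETERMINABLE
        if true_name == "unknown":
            row_key = INDETERMINABLE
        name = _draw_from_row(profile.name_confusion[row_key], rng) if profile.name_confusion else true_name
        return Response(ann.image_id, profile.volunteer_id, order_index, focus, "fossil", count, position, name)
    if not ann.detections and rng.random() < profile.false_positive_rate:
        # a spurious report on an empty image: single object, arbitrary answers
        position = str(rng.choice(["middle", "edge"]))
        taxa = sorted(t for t in profile.name_confusion if t != INDETERMINABLE)
        if not taxa or rng.random() < 0.6:
            name = "unknown"
        else:
            name = str(rng.choice(taxa))
        return Response(ann.image_id, profile.volunteer_id, order_index, focus, "fossil", 1, position, name)
    return Response(ann.image_id, profile.volunteer_id, order_index, focus, "no_fossil", 0, "none", "none")


@dataclass
class SimulationResult:
    """Transcription stream plus the verdicts the serving loop closed on."""

    responses: list[Response]
    verdicts: dict[str, ImageVerdict]
    views_per_volunteer: dict[str, int]


def simulate_transcriptions(
    truth: Mapping[str, TruthAnnotation],
    specimens: Sequence[Specimen],
    profiles: Sequence[VolunteerProfile],
    quorum: int = 3,
    max_views: int = 4,
    seed: int | np.random.Generator = 0,
    match_fields: Sequence[str] = ANSWER_FIELDS,
    count_cap: int = 10,
) -> SimulationResult:
    """Serve every image sequentially to distinct volunteers until the
    consensus engine closes it or ``max_views`` is reached.

    Volunteers are sampled per image with probability proportional to
    their activity weight, without replacement within an image.  Skips
    produce no response and do not count toward the quorum (but the
    skipping volunteer is not served the same image again).
    """
    if not profiles:
        raise ValueError("at least one volunteer profile is required")
    if quorum > max_views:
        raise ValueError("quorum cannot exceed max_views")
    rng = np.random.default_rng(seed)
    specimens_by_id = {s.specimen_id: s for s in specimens}
    weights = np.array([p.activity_weight for p in profiles], dtype=float)

    responses: list[Response] = []
    verdicts: dict[str, ImageVerdict] = {}
    views: dict[str, int] = {p.volunteer_id: 0 for p in profiles}

    for image_id in sorted(truth):
        ann = truth[image_id]
        available = np.ones(len(profiles), dtype=bool)
        stream: list[Response] = []
        verdict = aggregate_image(stream, quorum, max_views, match_fields, count_cap)
        while verdict.category is Category.PENDING and available.any():
            w = np.where(available, weights, 0.0)
            vi = int(rng.choice(len(profiles), p=w / w.sum()))
            available[vi] = False
            profile = profiles[vi]
            if profile.skip_rate and rng.random() < profile.skip_rate:
                continue
            stream.append(_respond(profile, ann, specimens_by_id, len(stream) + 1, rng))
            views[profile.volunteer_id] += 1
            verdict = aggregate_image(stream, quorum, max_views, match_fields, count_cap)
        if not stream:
            verdict = ImageVerdict(image_id, Category.PENDING, False, "none", frozenset(), 0)
        responses.extend(stream)
        verdicts[image_id] = verdict

    return SimulationResult(responses, verdicts, views)


def top_decile_share(views_per_volunteer: Mapping[str, int]) -> float:
    """Fraction of all transcriptions contributed by the most active 10%
    of volunteers (rounded up to at least one volunteer)."""
    counts = sorted(views_per_volunteer.values(), reverse=True)
    total = sum(counts)
    if total == 0:
        return 0.0
    k = max(1, math.ceil(0.10 * len(counts)))
    return sum(counts[:k]) / total
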