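"""Reading and writing transcription exports and report artefacts.

Transcription files are delimited text, one row per volunteer view of
one image.  Because export layouts vary, ingestion is adapter-based: a
:class:`TranscriptionSchema` maps file headers onto the questionnaire
fields and normalises answer vocabularies.  Rows that fail validation
are quarantined with a reason, never silently dropped.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .cohort import Specimen
from .consensus import FlowReport, ImageVerdict, Response
from .geometry import Point

__all__ = [
    "TranscriptionSchema",
    "SYNTHETIC_SCHEMA",
    "DIGIVOL_SCHEMA",
    "QuarantinedRow",
    "read_transcriptions",
    "write_transcriptions",
    "write_ground_truth",
    "read_ground_truth",
    "write_verdicts",
    "write_flow_report",
    "write_json_report",
]


@dataclass(frozen=True)
class TranscriptionSchema:
    """Column mapping from a delimited export onto Response fields.

    ``columns`` maps each Response field (image_id, volunteer_id, and
    the five answers; ``order`` optional) to the file's header for it.
    ``value_maps`` normalises raw cell values (case-insensitive) into
    the canonical answer vocabulary.  When no order column is mapped,
    arrival order within an image is taken from file order.
    """

    columns: Mapping[str, str]
    delimiter: str = ","
    encoding: str = "utf-8"
    value_maps: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    REQUIRED = ("image_id", "volunteer_id", "focus", "occurrence", "count", "position", "name")

    def __post_init__(self) -> None:
        missing = [f for f in self.REQUIRED if f not in self.columns]
        if missing:
            raise ValueError(f"schema missing mapped field(s): {', '.join(missing)}")


SYNTHETIC_SCHEMA = TranscriptionSchema(
    columns={
        "image_id": "image_id",
        "volunteer_id": "volunteer_id",
        "order": "order_index",
        "focus": "focus",
        "occurrence": "occurrence",
        "count": "count",
        "position": "position",
        "name": "name",
    }
)

#: Best-guess mapping for DigiVol questionnaire exports; real exports
#: should ship their own mapping file (see TranscriptionSchema).
DIGIVOL_SCHEMA = TranscriptionSchema(
    columns={
        "image_id": "externalIdentifier",
        "volunteer_id": "transcriberID",
        "focus": "isTheImageOutOfFocus",
        "occurrence": "areThereAnyMicrofossilsInThisImage",
        "count": "howManyMicrofossilsArePresent",
        "position": "whereIsTheMicrofossil",
        "name": "whatTypeOfMicrofossilIsPresent",
    },
    value_maps={
        "focus": {"in focus": "in_focus", "out of focus": "out_of_focus"},
        "occurrence": {
            "with a microfossil": "fossil",
            "without a microfossil": "no_fossil",
            "yes": "fossil",
            "no": "no_fossil",
        },
        "position": {"middle and edge": "middle_and_edge", "both": "middle_and_edge"},
        "name": {"pollen or spores": "pollen_or_spore"},
    },
)


@dataclass(frozen=True)
class QuarantinedRow:
    row_number: int  # 1-based data-row number in the file
    reason: str
    raw: Mapping[str, object]


def _normalise(field_name: str, value: object, schema: TranscriptionSchema) -> str:
    s = str(value).strip()
    vmap = schema.value_maps.get(field_name, {})
    return vmap.get(s.lower(), s)


def read_transcriptions(
    path: str | Path, schema: TranscriptionSchema = SYNTHETIC_SCHEMA
) -> tuple[dict[str, list[Response]], list[QuarantinedRow]]:
    """Parse a transcription export into per-image ordered Response lists.

    Responses are ordered by the mapped order column when present,
    otherwise by file order within each image.  Invalid rows are
    returned as :class:`QuarantinedRow` records.  A mapped column
    missing from the file raises an error naming the field.
    """
    df = pd.read_csv(path, sep=schema.delimiter, encoding=schema.encoding, dtype=str)
    for fname in schema.REQUIRED:
        if schema.columns[fname] not in df.columns:
            raise ValueError(
                f"input file is missing the {fname!r} column ({schema.columns[fname]!r})"
            )
    grouped: dict[str, list[Response]] = {}
    quarantined: list[QuarantinedRow] = []
    counters: dict[str, int] = {}
    order_col = schema.columns.get("order")
    if order_col is not None and order_col not in df.columns:
        order_col = None  # fall back to file order
    for i, row in enumerate(df.to_dict("records"), start=1):
        try:
            image_id = str(row[schema.columns["image_id"]]).strip()
            if order_col is not None:
                order = int(str(row[order_col]).strip())
            else:
                order = counters.get(image_id, 0) + 1
            resp = Response(
                image_id=image_id,
                volunteer_id=str(row[schema.columns["volunteer_id"]]).strip(),
                order_index=order,
                focus=_normalise("focus", row[schema.columns["focus"]], schema),
                occurrence=_normalise("occurrence", row[schema.columns["occurrence"]], schema),
                count=int(str(row[schema.columns["count"]]).strip()),
                position=_normalise("position", row[schema.columns["position"]], schema),
                name=_normalise("name", row[schema.columns["name"]], schema),
            )
        except (ValueError, KeyError, TypeError) as exc:
            quarantined.append(QuarantinedRow(i, str(exc), row))
            continue
        counters[resp.image_id] = counters.get(resp.image_id, 0) + 1
        grouped.setdefault(resp.image_id, []).append(resp)
    for image_id in grouped:
        grouped[image_id].sort(key=lambda r: r.order_index)
    return grouped, quarantined


def write_transcriptions(
    responses: Sequence[Response],
    path: str | Path,
    schema: TranscriptionSchema = SYNTHETIC_SCHEMA,
) -> None:
    cols = schema.columns
    records = []
    for r in responses:
        rec = {
            cols["image_id"]: r.image_id,
            cols["volunteer_id"]: r.volunteer_id,
            cols["focus"]: r.focus,
            cols["occurrence"]: r.occurrence,
            cols["count"]: r.count,
            cols["position"]: r.position,
            cols["name"]: r.name,
        }
        if "order" in cols:
            rec[cols["order"]] = r.order_index
        records.append(rec)
    pd.DataFrame.from_records(records).to_csv(path, sep=schema.delimiter, index=False)


GROUND_TRUTH_COLUMNS = (
    "specimen_id",
    "montage",
    "x_um",
    "y_um",
    "radius_um",
    "taxon",
    "identifiable",
)


def write_ground_truth(specimens: Sequence[Specimen], path: str | Path) -> None:
    """Sidecar file with one row per generated specimen, for evaluation."""
    pd.DataFrame.from_records(
        [
            {
                "specimen_id": s.specimen_id,
                "montage": s.montage,
                "x_um": s.position.x_um,
                "y_um": s.position.y_um,
                "radius_um": s.radius_um,
                "taxon": s.taxon,
                "identifiable": s.identifiable,
            }
            for s in specimens
        ],
        columns=list(GROUND_TRUTH_COLUMNS),
    ).to_csv(path, index=False)


def read_ground_truth(path: str | Path) -> list[Specimen]:
    df = pd.read_csv(path)
    return [
        Specimen(
            specimen_id=str(r.specimen_id),
            montage=int(r.montage),
            position=Point(float(r.x_um), float(r.y_um)),
            radius_um=float(r.radius_um),
            taxon=str(r.taxon),
            identifiable=bool(r.identifiable),
        )
        for r in df.itertuples(index=False)
    ]


def write_verdicts(verdicts: Sequence[ImageVerdict], path: str | Path) -> None:
    pd.DataFrame.from_records(
        [
            {
                "image_id": v.image_id,
                "category": v.category.value,
                "disputed": v.disputed,
                "fossil_sublabel": v.fossil_sublabel,
                "disagreement_fields": "|".join(sorted(v.disagreement_fields)),
                "n_responses": v.n_responses,
            }
            for v in verdicts
        ]
    ).to_csv(path, index=False)


def write_flow_report(flow: FlowReport, path: str | Path, seed: int | None = None) -> None:
    write_json_report(flow.as_dict(), path, seed=seed)


def write_json_report(payload: Mapping, path: str | Path, seed: int | None = None) -> None:
    """Write a JSON report with a deterministic layout and seed header."""
    doc = {"master_seed": seed, **payload} if seed is not None else dict(payload)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
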