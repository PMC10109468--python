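"""End-to-end pipeline orchestration.

Simulation mode runs the full study workflow: generate a specimen
field, simulate volunteer transcription, validate by consensus, build
and review the expert queue, and compute the overlap-deduplicated
census with a performance audit against the generated ground truth.
File mode ingests a transcription export and runs the consensus and
flow/queue/workload stages (expert review and census require review
records or ground truth, which an export alone does not carry).

All randomness derives from one master seed via spawned substreams,
recorded in every JSON report header; the same seed gives
byte-identical reports.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import census as census_mod
from . import cohort, consensus, io, review
from .config import PipelineConfig
from .geometry import dataset_totals

__all__ = ["PipelineResult", "run_pipeline", "review_results_to_detections"]

log = logging.getLogger("palynoscope")


@dataclass
class PipelineResult:
    config: PipelineConfig
    flow: consensus.FlowReport
    verdicts: dict[str, consensus.ImageVerdict]
    responses: list[consensus.Response]
    queue: list[str]
    workload: Mapping[str, float]
    review_results: list[review.ReviewResult] | None = None
    census: census_mod.CensusTable | None = None
    performance: census_mod.PerformanceReport | None = None
    specimens: list[cohort.Specimen] | None = None
    views_per_volunteer: dict[str, int] | None = None


def review_results_to_detections(
    results: Sequence[review.ReviewResult],
) -> list[census_mod.Detection]:
    """Flatten expert review results into census detections."""
    out = []
    for r in results:
        montage, tile = cohort.parse_image_id(r.image_id)
        for d in r.detections:
            out.append(
                census_mod.Detection(r.image_id, montage, tile, d.local, d.label, "expert")
            )
    return out


def _stage(name: str):
    log.info("stage: %s", name)
    return time.perf_counter()


def run_pipeline(
    config: PipelineConfig,
    input_source: str | Path = "simulate",
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Execute the pipeline; optionally write all report artefacts.

    ``input_source`` is either the literal string ``"simulate"`` or the
    path of a transcription export readable with the synthetic schema
    (use :func:`palynoscope.io.read_transcriptions` directly for custom
    layouts).
    """
    grids = config.montage.grids()
    cc = config.consensus
    seed_seq = np.random.SeedSequence(config.master_seed)
    s_spec, s_trans, s_expert = (int(s.generate_state(1)[0] % (2**31)) for s in seed_seq.spawn(3))

    simulate = str(input_source) == "simulate"
    specimens = None
    truth = None
    views = None
    if simulate:
        t0 = _stage("simulate")
        sim = config.simulation
        specimens = cohort.generate_specimens(
            grids,
            sim.density_per_cm2,
            sim.taxon_mix,
            radius_mean_um=sim.radius_mean_um,
            seed=s_spec,
        )
        truth = cohort.truth_annotations(specimens, grids)
        profiles = cohort.default_profiles(
            sim.n_volunteers,
            taxa=sim.taxon_mix.taxa,
            seed=s_spec,
            sensitivity=sim.sensitivity,
            false_positive_rate=sim.false_positive_rate,
            count_error_rate=sim.count_error_rate,
            focus_error_rate=sim.focus_error_rate,
            skip_rate=sim.skip_rate,
        )
        simres = cohort.simulate_transcriptions(
            truth,
            specimens,
            profiles,
            quorum=cc.quorum,
            max_views=cc.max_views,
            seed=s_trans,
            match_fields=cc.match_fields,
            count_cap=cc.count_cap,
        )
        responses = simres.responses
        grouped: dict[str, list[consensus.Response]] = {}
        for r in responses:
            grouped.setdefault(r.image_id, []).append(r)
        views = simres.views_per_volunteer
        log.info("simulated %d responses in %.1fs", len(responses), time.perf_counter() - t0)
    else:
        _stage("ingest")
        grouped, quarantined = io.read_transcriptions(input_source)
        if quarantined:
            log.warning("%d rows quarantined on ingest", len(quarantined))
        responses = [r for rs in grouped.values() for r in rs]

    _stage("consensus")
    verdicts = {
        image_id: consensus.aggregate_image(
            rs, cc.quorum, cc.max_views, cc.match_fields, cc.count_cap, cc.order_aware_dispute
        )
        for image_id, rs in sorted(grouped.items())
    }
    flow = consensus.flow_report(verdicts.values(), allow_pending=not simulate)

    _stage("review")
    closed = [v for v in verdicts.values() if v.category is not consensus.Category.PENDING]
    queue = review.build_review_queue(closed)
    totals = dataset_totals(grids)
    hours_all, _ = review.workload_hours(flow.n_images, config.review.seconds_per_image)
    hours_queue, hours_queue_r = review.workload_hours(len(queue), config.review.seconds_per_image)
    workload = {
        "seconds_per_image": config.review.seconds_per_image,
        "review_hours_full_dataset": hours_all,
        "review_hours_queue": hours_queue,
        "review_hours_queue_rounded": hours_queue_r,
    }

    review_results = census_table = performance = None
    if simulate:
        oracle = review.ExpertOracle(
            truth,
            {s.specimen_id: s for s in specimens},
            miss_rate=config.review.miss_rate,
            escalation_rate=config.review.escalation_rate,
        )
        review_results = review.expert_verify(queue, oracle, seed=s_expert)
        _stage("census")
        detections = review_results_to_detections(review_results)
        clusters = census_mod.deduplicate_detections(detections, grids, config.census.epsilon_um)
        census_table = census_mod.census_table(clusters, totals.total_area_cm2_exact)
        performance = census_mod.detection_performance(specimens, clusters, config.census.epsilon_um)

    result = PipelineResult(
        config=config,
        flow=flow,
        verdicts=verdicts,
        responses=responses,
        queue=queue,
        workload=workload,
        review_results=review_results,
        census=census_table,
        performance=performance,
        specimens=specimens,
        views_per_volunteer=views,
    )
    if out_dir is not None:
        write_reports(result, out_dir)
    return result


def write_reports(result: PipelineResult, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = result.config.master_seed
    io.write_transcriptions(result.responses, out / "transcriptions.csv")
    io.write_verdicts(sorted(result.verdicts.values(), key=lambda v: v.image_id), out / "verdicts.csv")
    io.write_flow_report(result.flow, out / "flow_report.json", seed=seed)
    io.write_json_report(
        {"queue": result.queue, "workload": dict(result.workload)},
        out / "review_queue.json",
        seed=seed,
    )
    if result.specimens is not None:
        io.write_ground_truth(result.specimens, out / "ground_truth.csv")
    if result.census is not None:
        io.write_json_report(
            {
                "rows": result.census.as_records(),
                "n_unique": result.census.n_unique,
                "n_identifiable": result.census.n_identifiable,
                "n_indeterminable": result.census.n_indeterminable,
                "total_area_cm2": result.census.total_area_cm2,
            },
            out / "census.json",
            seed=seed,
        )
    if result.performance is not None:
        p = result.performance
        io.write_json_report(
            {
                "recall": p.recall,
                "n_truth": p.n_truth,
                "n_matched": p.n_matched,
                "missed_specimen_ids": list(p.missed_specimen_ids),
                "n_false_clusters": p.n_false_clusters,
            },
            out / "performance.json",
            seed=seed,
        )
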