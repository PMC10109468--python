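#!/usr/bin/env python
"""Consensus validation of the simulated survey and the image flow.

Aggregates the simulated transcription stream (scratch/survey/, created
by 02_simulate_survey.py; re-simulated here if absent) into per-image
verdicts, reports the flow accounting — agreement (fossil / no-fossil),
disputed, no-agreement, review queue — and decomposes the reasons for
no-agreement by questionnaire field (count, occurrence, name, position,
focus).  Writes results/03_flow.json and a bar chart of the
decomposition under scratch/.
"""

import argparse
import json
from collections import Counter
from pathlib import Path

from palynoscope.config import default_config
from palynoscope.consensus import Category, aggregate_image, flow_report
from palynoscope.io import read_transcriptions
from palynoscope.pipeline import run_pipeline

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    cfg = default_config(master_seed=args.seed)
    stream = ROOT / "scratch" / "survey" / "transcriptions.csv"
    if stream.exists():
        grouped, quarantined = read_transcriptions(stream)
        if quarantined:
            print(f"warning: {len(quarantined)} rows quarantined")
        cc = cfg.consensus
        verdicts = {
            iid: aggregate_image(rs, cc.quorum, cc.max_views, cc.match_fields, cc.count_cap)
            for iid, rs in grouped.items()
        }
    else:
        print("no saved stream found; re-simulating")
        verdicts = run_pipeline(cfg).verdicts

    flow = flow_report(verdicts.values())
    n = flow.n_images
    print(f"images                : {n}")
    print(f"agreement             : {flow.n_agreement} "
          f"({flow.n_agreement_no_fossil} no-fossil / {flow.n_agreement_fossil} fossil)")
    print(f"  fossil sublabels    : {flow.n_fossil_pollen_spore} pollen-or-spore, "
          f"{flow.n_fossil_unknown} unknown")
    print(f"disputed              : {flow.n_disputed} ({100 * flow.n_disputed / n:.1f}%)")
    print(f"no agreement          : {flow.n_no_agreement} ({100 * flow.n_no_agreement / n:.1f}%)")
    print(f"review queue          : {flow.n_review_queue} ({100 * flow.n_review_queue / n:.1f}%)")

    reasons = Counter()
    for v in verdicts.values():
        if v.category is Category.NO_AGREEMENT:
            for f in v.disagreement_fields:
                reasons[f] += 1
    print("no-agreement reasons  :",
          ", ".join(f"{f}={c}" for f, c in reasons.most_common()))

    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "03_flow.json").write_text(
        json.dumps({**flow.as_dict(), "no_agreement_reasons": dict(reasons)}, indent=2) + "\n"
    )

    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fields, counts = zip(*reasons.most_common()) if reasons else ((), ())
        fig, ax = plt.subplots(figsize=(5, 3))
        ax.bar(fields, counts, color="#4c72b0")
        ax.set_ylabel("no-agreement images")
        ax.set_title("Disagreement reasons among no-agreement images")
        fig.tight_layout()
        scratch = ROOT / "scratch"
        scratch.mkdir(exist_ok=True)
        fig.savefig(scratch / "03_disagreement_reasons.png", dpi=150)
        print(f"figure -> {scratch / '03_disagreement_reasons.png'}")
    except ImportError:
        print("matplotlib unavailable; skipping figure")


if __name__ == "__main__":
    main()
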