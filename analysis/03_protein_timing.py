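#!/usr/bin/env python
"""Relative protein timing against the AFM anchors.

Simulates a cohort of single-closure clathrin events, measures the
appearance / peak / disappearance of each trace relative to invagination
start and pit closure, and writes the cohort summary to
results/timing_summary.csv.  Expected behaviour of the recovered means:
appearance is unbiased (threshold-crossing and scan-lag shifts cancel),
while the peak and disappearance carry the ~ -5 s half-frame sampling
bias plus the uncorrected AFM<->CLSM lag — the same physics as the
instrument.
"""

import os

import pandas as pd

from hsafm_cme.config import preset_config
from hsafm_cme.lifecycle import (ChannelAbsentError, detect_event_times,
                                 relative_timing, timing_summary)
from hsafm_cme.generate import generate_dataset
from hsafm_cme.pipeline import match_tracks_to_truth, run_analyze
from hsafm_cme.studies import IN_FIELD_MOBILITY, _derive_seed

OUT = os.path.join(os.path.dirname(__file__), "..", "results")


def main(n_target: int = 35, seed: int = 21) -> None:
    events = []
    k = 0
    while len(events) < n_target and k < 4 * n_target:
        cfg = preset_config("untreated", n_frames=70, n_events=2,
                            channels=("clathrin",),
                            mobility_cm2_s=dict(IN_FIELD_MOBILITY),
                            seed=_derive_seed(seed, k))
        k += 1
        bundle = generate_dataset(cfg)
        result = run_analyze(bundle)
        matched = match_tracks_to_truth(result.tracks, bundle.truth)
        for tr in result.tracks:
            if tr.track_id not in matched or len(tr.detections) < 2 or tr.gaps:
                continue
            if tr.closure_frame(cfg.n_frames) is None:
                continue
            t_inv, t_clo = detect_event_times(tr, cfg.n_frames,
                                              cfg.frame_interval_s)
            trace = result.traces.get(tr.track_id, {}).get("clathrin")
            if trace is None:
                continue
            try:
                events.append(relative_timing(trace, t_inv, t_clo))
            except ChannelAbsentError:
                continue
    summary = timing_summary(events)
    os.makedirs(OUT, exist_ok=True)
    summary.to_csv(os.path.join(OUT, "timing_summary.csv"), index=False)
    with pd.option_context("display.width", 120):
        print(summary.round(1).to_string(index=False))
    print(f"\nn = {len(events)} clathrin traces; generator means: appearance "
          "34 s before invagination, peak 3 s after closure, disappearance "
          "39 s after closure.")


if __name__ == "__main__":
    main()
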