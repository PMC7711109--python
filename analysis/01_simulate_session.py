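#!/usr/bin/env python
"""Simulate one subject's session and write it out in standard formats.

Builds the six-block internal-attention design (72 s per condition per
block, trials of 16-50 s each preceded by a 2 s instruction), renders the
labeled task time series and the 600-TR meditation period from sparse
state patterns, and writes NIfTI + events TSV + truth sidecar under
results/session_example/. Prints the design arithmetic: 432 labeled TRs
per condition, 2160 total, 600 meditation TRs.
"""
from pathlib import Path

import attnstates as a
from attnstates.synth import attach_ratings, sticky_chain, write_synthetic_session

OUT = Path(__file__).resolve().parent.parent / "results" / "session_example"
SEED = 0

design = a.build_ia_design(seed=SEED)
design = attach_ratings(design, seed=SEED)
patterns = a.make_state_patterns(n_voxels=2000, seed=SEED)
ts, design = a.simulate_ia_session(patterns, design, noise_sd=1.0, seed=SEED + 1)
samples = a.extract_labeled_samples(ts, design)
med_ts, truth = a.simulate_meditation_session(
    patterns, sticky_chain((0.5, 0.3, 0.2), 0.8), noise_sd=1.0, seed=SEED + 2
)

paths = write_synthetic_session(
    OUT,
    ts,
    design,
    truth=truth,
    params={"seed": SEED, "n_voxels": 2000, "noise_sd": 1.0},
)

per_cond = {c: int((samples.labels == c).sum()) for c in a.CONDITIONS}
print(f"task series: {ts.n_trs} TRs x {ts.n_voxels} voxels")
print(f"labeled samples per condition: {per_cond} (total {samples.n_samples})")
print(f"meditation period: {med_ts.n_trs} TRs")
print(f"written: {sorted(paths)} -> {OUT}")
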