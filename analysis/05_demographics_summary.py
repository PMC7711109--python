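#!/usr/bin/env python
"""Summarize the study cohort's demographics with dual reporting.

Counts and one-decimal percentages per standardized axis, plus the
derived diversity composites (sexual-minority, racial-minority,
multi-racial, Bachelor's-or-higher shares). Writes
results/demographics_summary.json.
"""
import json
from pathlib import Path

import attnstates as a
from attnstates.demographics import study_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "demographics_summary.json"

summary = a.summarize_demographics(study_cohort())
OUT.parent.mkdir(parents=True, exist_ok=True)
OUT.write_text(json.dumps(summary, indent=2, sort_keys=True))

print(f"n = {summary['n']}")
for name, comp in summary["composites"].items():
    print(f"{name}: {comp['percent']}% ({comp['n']}/{summary['n']})")
print(f"written: {OUT}")
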