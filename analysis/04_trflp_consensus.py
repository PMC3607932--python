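#!/usr/bin/env python
"""Run the T-RFLP pipeline on the simulated peak tables: filter, replicate
quality gate, Dunbar-style normalization, moving-average alignment and
replicate consensus. Reports QC outcomes and checks recovery against the
simulated ground-truth abundance weights.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from sludge_archaea.trflp import run_pipeline, write_consensus_table

OUT = Path("results")
SYN = OUT / "synthetic"

consensi, qc = run_pipeline(SYN / "peak_table.csv")
write_consensus_table(consensi, OUT / "consensus_profiles.csv")
(OUT / "trflp_qc.json").write_text(json.dumps(qc, indent=2) + "\n")

removed = [f for pair in qc["removed_fraction"].values() for f in pair]
print(f"{qc['n_samples']} sample x enzyme groups -> {len(consensi)} consensus "
      f"profiles; {len(qc['rejected'])} rejected, "
      f"{len(qc['empty_consensus'])} empty")
print(f"fluorescence removed by normalization: "
      f"{100 * np.mean(removed):.1f} +- {100 * np.std(removed):.1f}% "
      f"(minor, as expected)")

# recovery check against ground truth, per enzyme, averaged over dates
truth = pd.read_csv(SYN / "true_weights.csv", index_col="date")
errors = []
for cons in consensi:
    w = np.sort(truth.loc[cons.sample_id].to_numpy())[::-1]
    ab = np.sort([b[3] for b in cons.bins])[::-1]
    k = min(len(w), len(ab))
    errors.append(np.abs(ab[:k] - w[:k]).max())
print(f"max |consensus abundance - true weight| over "
      f"{len(errors)} profiles: {max(errors):.3f} "
      f"(noise sd 0.05, sub-floor peaks undetectable)")
print("wrote consensus_profiles.csv, trflp_qc.json")
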