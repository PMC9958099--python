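"""Step 2 — preprocessing report.

Reads each study fixture, applies turn-pattern trial exclusion and pooled
scaled-MAD outlier flagging, and writes per-study summaries:
  results/<study>/exclusion_report.tsv
  results/<study>/outlier_summary.tsv  (flag counts per pair x task)

Run after 01_simulate.py:  python analysis/02_preprocess.py
"""

from pathlib import Path

import numpy as np
import pandas as pd

from turntap import io as tio
from turntap import preprocess as pp

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    for study in ("study1", "study2"):
        out = ROOT / "results" / study
        dataset = tio.read_fixture(out / "dataset.tsv")
        kept, report = pp.exclude_trials(dataset)
        report.to_csv(out / "exclusion_report.tsv", sep="\t", index=False)
        series = pp.flag_outliers([pp.compute_itis(t.events, t.meta) for t in kept])
        rows = []
        for s in series:
            rows.append({"pair_id": s.meta.pair_id, "task": s.meta.task,
                         "n_itis": len(s.itis_ms),
                         "n_flagged": int(np.sum(s.outlier_mask))})
        summary = (pd.DataFrame(rows)
                   .groupby(["pair_id", "task"], as_index=False).sum())
        summary.to_csv(out / "outlier_summary.tsv", sep="\t", index=False)
        frac = summary["n_flagged"].sum() / summary["n_itis"].sum()
        print(f"{study}: kept {len(kept)}/{len(dataset)} trials, "
              f"{frac:.2%} of intervals flagged as outliers")


if __name__ == "__main__":
    main()
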