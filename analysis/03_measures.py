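"""Step 3 — dependent measures.

Computes per-trial accuracy, CV, and lag-1/2/4 autocorrelations, aggregates
them to pair x task x block means, and builds the ITI-contrast profiles.
Writes per study:
  results/<study>/measures.tsv
  results/<study>/contrast_profile_<task>.tsv

Run after 02_preprocess.py:  python analysis/03_measures.py
"""

from pathlib import Path

from turntap import io as tio
from turntap.cli import analyze_dataset

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    for study in ("study1", "study2"):
        out = ROOT / "results" / study
        dataset = tio.read_fixture(out / "dataset.tsv")
        between = "predictability" if study == "study1" else None
        outputs = analyze_dataset(dataset, between=between)
        outputs["measures"].to_csv(out / "measures.tsv", sep="\t", index=False)
        for task, profile in outputs["profiles"].items():
            profile.reported().to_csv(out / f"contrast_profile_{task}.tsv",
                                      sep="\t", index=False)
        means = (outputs["measures"]
                 .groupby(["measure", "task"])["value"].mean().unstack())
        print(f"== {study}: grand means by task ==")
        print(means.round(4).to_string(), "\n")


if __name__ == "__main__":
    main()
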