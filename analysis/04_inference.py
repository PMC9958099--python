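"""Step 4 — inference.

Runs the full mixed-ANOVA pipeline (Type-III SS, Greenhouse-Geisser
correction, generalized eta squared), linear block contrasts, the
contrast-of-contrasts, Tukey pairwise comparisons, and within-subject CIs.
Writes all tables under results/<study>/ and prints the text report.

Run after 01_simulate.py:  python analysis/04_inference.py
"""

from pathlib import Path

from turntap import io as tio
from turntap.cli import analyze_dataset, format_report, write_outputs

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    for study in ("study1", "study2"):
        out = ROOT / "results" / study
        dataset = tio.read_fixture(out / "dataset.tsv")
        between = "predictability" if study == "study1" else None
        outputs = analyze_dataset(dataset, between=between)
        write_outputs(outputs, out)
        print(f"########## {study} ##########")
        print(format_report(outputs))


if __name__ == "__main__":
    main()
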