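"""Step 1 — generate the synthetic experiments.

Writes one fixture dataset per study profile under results/:
  results/study1/dataset.tsv   A-B turn taking, Predictable/Random split
  results/study2/dataset.tsv   A-A-B-B turn taking, Random sequences only

Run: python analysis/01_simulate.py [--seed N]
"""

import argparse
from pathlib import Path

from turntap.cli import config_for_study, run_simulation

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()
    for study in ("study1", "study2"):
        cfg = config_for_study(study, seed=args.seed)
        fixture = run_simulation(cfg, ROOT / "results" / study)
        print(f"{study}: {cfg.n_pairs} pairs, pattern {cfg.turn_pattern} -> {fixture}")


if __name__ == "__main__":
    main()
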