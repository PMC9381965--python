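"""Segment every subject and tabulate per-subject asymmetry indices.

Thin driver: regenerates the same cohort as 01 (deterministic in the
seed), measures it and writes one row per subject per modality.
"""

import argparse
import importlib
from pathlib import Path

from hodasym.cohort import iter_cohort
from hodasym.pipeline import analyze_measurements, measure_subject, subjects_frame

driver01 = importlib.import_module("01_simulate_cohort")


def main() -> None:
    p = argparse.ArgumentParser(description=__doc__)
    p.add_argument("--seed", type=int, default=0)
    p.add_argument("--out-dir", type=Path, default=Path("results"))
    args = p.parse_args()

    spec = driver01.default_spec(args.seed)
    measurements = [measure_subject(s) for s in iter_cohort(spec)]
    analysis = analyze_measurements(measurements)
    df = subjects_frame(analysis)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    out = args.out_dir / "subject_asymmetry.csv"
    df.to_csv(out, index=False)
    print(f"wrote {out} ({len(df)} rows)")
    print(df.groupby(["role", "modality"]).diff_percent.mean().round(2))


if __name__ == "__main__":
    main()
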