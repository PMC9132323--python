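#!/usr/bin/env python
"""Train the compact CNN on the cue-conflict datasets and report
four-condition accuracy.

Default scale is a quick sweep (500 training images, 32x32 rasters, one
seed per dataset, ~2 min/dataset); ``--full`` uses the complete 2000-image
datasets at 64x64 with several seeds, which takes correspondingly longer.
Writes results/cnn/report_<experiment>_<variant>.json and a combined CSV.

Expected picture (mirroring the published CNN rows): high Both accuracy,
Non-shape at or above Shape on the a-variants, and Conflict at or below
chance — the network leans on the non-shape cue, and almost exclusively so
when that cue is the more predictive one (b-variants).
"""

import argparse
from pathlib import Path

from shapebias import evaluation as ev
from shapebias.cnn import harness

OUT = Path("results/cnn")
DATASETS = [
    ("exp1", "a"), ("exp1", "b"), ("exp2", "a"), ("exp2", "b"),
    ("exp3", "a"), ("exp3", "b"), ("exp4", "a"), ("exp4", "b"),
    ("exp5_patch", "noshape"), ("exp5_segment", "noshape"),
    ("exp5_size", "noshape"), ("exp5_colour", "noshape"),
]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--full", action="store_true",
                        help="2000 images at 64x64 with 3 seeds per dataset")
    parser.add_argument("--seeds", type=int, default=None)
    parser.add_argument("--datasets", nargs="*", default=None,
                        help="subset like exp1_a exp2_b")
    args = parser.parse_args()

    if args.full:
        config = harness.desk_config()
        n_train, n_test, n_seeds = 2000, 500, args.seeds or 3
    else:
        config = harness.desk_config(input_size=32, max_epochs=40)
        n_train, n_test, n_seeds = 500, 100, args.seeds or 1

    wanted = DATASETS if not args.datasets else [
        tuple(d.rsplit("_", 1)) for d in args.datasets]
    OUT.mkdir(parents=True, exist_ok=True)

    all_reports = []
    for experiment, variant in wanted:
        report = harness.run_experiment(
            experiment, variant, config, n_seeds=n_seeds,
            n_train=n_train, n_test_per_condition=n_test, dataset_seed=0)
        report.to_json(OUT / f"report_{experiment}_{variant}.json")
        all_reports.extend(report.reports)
        agg = report.aggregate()
        desc = ", ".join(f"{c}={v['mean']:.2f}" for c, v in agg.items())
        train_acc = sum(report.train_accuracy) / len(report.train_accuracy)
        print(f"{experiment}_{variant}: train={train_acc:.3f}  {desc}")

    paths = ev.make_report(all_reports, OUT, plots=True)
    print(f"\nwrote {', '.join(str(p) for p in sorted(paths.values()))}")


if __name__ == "__main__":
    main()
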