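"""Shared configuration for the numbered analysis drivers.

One RunConfig, one seed: every stage reads and writes results/pipeline_run
so the scripts can be run in order (01 -> 04) or individually after their
inputs exist.  The release is the desk-scale schedule (100 particles/day
for 10 days); the IBM numerics are the production values (120-s step,
122-day drift, 6-hourly snapshots).
"""

import argparse
from pathlib import Path

from urchindrift.pipeline import RunConfig

RESULTS = Path(__file__).resolve().parent.parent / "results" / "pipeline_run"


def default_config(seed: int | None = None) -> RunConfig:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out-dir", default=str(RESULTS))
    args, _ = parser.parse_known_args()
    return RunConfig(
        out_dir=args.out_dir,
        seed=seed if seed is not None else args.seed,
        particles_per_day=100,
        n_release_days=10,
        catch_n_records=8000,
    )
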