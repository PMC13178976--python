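"""Replicated coverage study for the synthetic-recovery pipeline.

Runs the full simulate -> aggregate -> impute -> fit recovery multiple
times with distinct seeds and reports, per replicate and aggregated, the
share of generating parameter values inside their 95% credible intervals
and the minimum correct-sign pd.  This is the long-running companion to
the single-replicate check in the test suite; schedule it, don't run it
per commit (20 replicates take a couple of hours on one CPU).

Usage:  python scripts/coverage_study.py --seed 1 --replicates 20 \
            --out results/coverage_study.json
"""

from __future__ import annotations

import argparse
import json
import logging
import warnings
from pathlib import Path

import numpy as np


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, required=True)
    parser.add_argument("--replicates", type=int, default=20)
    parser.add_argument("--out", type=str, required=True)
    args = parser.parse_args()

    warnings.filterwarnings("ignore")
    logging.disable(logging.WARNING)

    from teamdynam.pipeline import run_synthetic_recovery

    rng = np.random.default_rng(args.seed)
    replicates = []
    for r in range(args.replicates):
        seed = int(rng.integers(2**31 - 1))
        res = run_synthetic_recovery(seed=seed)
        replicates.append(
            {
                "seed": seed,
                "min_sign_pd": res["min_sign_pd"],
                "coverage": res["coverage"],
                "sign_pds": res["sign_pds"],
            }
        )
        print(
            f"replicate {r}: min_sign_pd={res['min_sign_pd']:.3f} "
            f"coverage={res['coverage']:.3f}",
            flush=True,
        )
    coverages = [r["coverage"] for r in replicates]
    summary = {
        "replicates": replicates,
        "mean_coverage": float(np.mean(coverages)),
        "share_sign_recovered": float(
            np.mean([r["min_sign_pd"] >= 0.95 for r in replicates])
        ),
    }
    out = Path(args.out)
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(json.dumps(summary, indent=2))
    print(json.dumps({k: v for k, v in summary.items() if k != "replicates"}))


if __name__ == "__main__":
    main()
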