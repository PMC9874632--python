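"""Run the full-scale reference protocol.

100,000 training-pool segments (75,000 train / 25,000 validation),
33 epochs on the full 1,225,606-parameter network, evaluated on 10,000
independently generated segments.  This takes on the order of days on a
single CPU core with the pure-NumPy training engine; use ``--scale`` to
run a proportional fraction (the pipeline layout is identical at any
scale).

    python scripts/full_protocol.py --seed 1 --scale 1.0 --out-dir results/full
"""

import argparse
import json
import sys
import time
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from nmrmultiplet import NetworkConfig, SimulationConfig, run_pipeline  # noqa: E402


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--scale", type=float, default=1.0)
    ap.add_argument("--out-dir", default="results/full_protocol")
    args = ap.parse_args()

    t0 = time.time()
    report = run_pipeline(
        config=SimulationConfig(),
        network=NetworkConfig(),  # full architecture, no pooling
        scale=args.scale,
        seed=args.seed,
        out_dir=args.out_dir,
        log=lambda m: print(m, file=sys.stderr, flush=True),
    )
    print(
        json.dumps(
            {
                "overall_accuracy_percent": 100 * report["overall_accuracy"],
                "macro_precision_percent": 100 * report["macro_precision"],
                "macro_recall_percent": 100 * report["macro_recall"],
                "macro_f1_percent": 100 * report["macro_f1"],
                "map50_percent": 100 * report["objectwise"]["0.5"]["map"],
                "map75_percent": 100 * report["objectwise"]["0.75"]["map"],
                "wall_seconds": time.time() - t0,
            },
            indent=2,
        )
    )
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
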