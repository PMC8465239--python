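#!/usr/bin/env python
"""Production-scale drivers: the full 30rc box at 200,000 steps.

These are the study-condition runs (81,000 beads: 600 single-tail +
600 double-tail lipids with 3-bead heads and 10-bead tails at rho=3)
under zero, weak (W=6) and strong (W=1) shear, plus the tail-length
phase-diagram sweep.  They take many core-hours; run them detached and
analyze the dumps afterwards with `dpdlipid analyze`.

Examples:

    # one production run per shear condition
    python scripts/long_run.py membrane --shear 0 --out runs/zero
    python scripts/long_run.py membrane --shear 6 --out runs/weak
    python scripts/long_run.py membrane --shear 1 --out runs/strong

    # the NT1 x NT2 in {2..10} phase diagram at weak shear
    python scripts/long_run.py sweep --shear 6 --out runs/diagram_weak
"""

from __future__ import annotations

import argparse
from pathlib import Path

from dpdlipid.cli import cmd_simulate, cmd_sweep


def _write_config(path: Path, swap_interval: int, sweep: bool) -> None:
    import dpdlipid as d

    cfg = d.RunConfig(swap_interval=swap_interval)
    if sweep:
        # reduced per-cell scale; still far beyond the test suite's sizes
        cfg = cfg.replace(box_lengths=(15.0, 15.0, 15.0), n_lipids_1=150,
                          n_lipids_2=150, total_steps=50_000)
    cfg.to_toml(path)
    if sweep:
        with open(path, "a") as fh:
            fh.write("\n[sweep]\n"
                     "nt1 = [2, 4, 6, 8, 10]\n"
                     "nt2 = [2, 4, 6, 8, 10]\n"
                     "seeds = [0, 1, 2]\n"
                     "steps = 50000\n")


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("mode", choices=("membrane", "sweep"))
    ap.add_argument("--shear", type=int, default=0,
                    help="swap interval W (0 = no shear; 6 weak, 1 strong)")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", required=True)
    args = ap.parse_args()

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    config_path = out / "config.toml"
    _write_config(config_path, args.shear, args.mode == "sweep")

    ns = argparse.Namespace(config=str(config_path), set=[], out=str(out))
    if args.mode == "membrane":
        ns.steps = None
        ns.seed = args.seed
        ns.init = "random"
        return cmd_simulate(ns)
    return cmd_sweep(ns)


if __name__ == "__main__":
    raise SystemExit(main())
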