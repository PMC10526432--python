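#!/usr/bin/env python
"""Generate the synthetic two-group resting-state EEG cohort.

The cohort carries the group structure the downstream stages look for:
group B (the DD-like group) has elevated alpha1/beta oscillator
amplitude, a more irregular beta band, and band-specific phase-coupling
differences in both directions. Desk-scale conditions (10 + 10 subjects,
60 s recordings) keep the full pipeline runnable in minutes; pass
--full for the 38 + 34 x 600 s protocol.

Writes results/cohort/ (one TSV matrix per subject + manifest).
"""
import argparse
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from eegdiff.io import save_cohort
from eegdiff.synth import default_cohort_config, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path,
                    default=Path(__file__).resolve().parents[1] / "results" / "cohort")
    ap.add_argument("--full", action="store_true",
                    help="full-scale protocol: 38+34 subjects, 600 s")
    args = ap.parse_args()

    cfg = default_cohort_config(seed=args.seed)
    if not args.full:
        cfg.n_group_a, cfg.n_group_b, cfg.duration = 10, 10, 60.0
    cfg.validate()
    recs = generate_cohort(cfg)
    manifest = save_cohort(recs, args.out)
    sizes = cfg.group_sizes()
    print(f"wrote {len(recs)} recordings "
          f"({sizes[cfg.group_names[0]]} {cfg.group_names[0]}, "
          f"{sizes[cfg.group_names[1]]} {cfg.group_names[1]}; "
          f"{cfg.duration:.0f} s at {cfg.fs:.0f} Hz, 16 channels)")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
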