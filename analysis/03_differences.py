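#!/usr/bin/env python
"""Two-group difference maps and differential brain networks.

Runs the per-feature one-way ANOVA (p < 0.05) on band power and fuzzy
entropy per (band, channel), and on the phase-lag index per (band,
channel pair); builds the per-band differential network with signed
edge counts (reported as B-higher/A-higher ratios) and the per-band
share of all significant connections.

Both statistical units are reported: 'epoch' (every segment is an
observation — large n, within-subject correlation ignored) and
'subject' (per-subject means — conservative and leakage-free).

Reads results/features.csv; writes results/stats/.
"""
import argparse
import json
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from eegdiff.io import load_feature_table
from eegdiff.plots import plot_difference_map, plot_network
from eegdiff.stats_networks import (diff_results_frame, difference_map,
                                    differential_network,
                                    key_connection_share)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path,
                    default=ROOT / "results" / "features.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results" / "stats")
    ap.add_argument("--alpha", type=float, default=0.05)
    args = ap.parse_args()

    table = load_feature_table(args.features)
    groups = list(pd.unique(table["group"]))
    args.out.mkdir(parents=True, exist_ok=True)

    for unit in ("epoch", "subject"):
        print(f"\n=== unit = {unit} ===")
        for family in ("PSD", "FE"):
            res = difference_map(table, family, alpha=args.alpha, unit=unit)
            diff_results_frame(res).to_csv(
                args.out / f"diff_{family.lower()}_{unit}.csv", index=False)
            per_band = {}
            for r in res:
                if r.significant:
                    per_band.setdefault(r.band, []).append(r)
            for band, rs in sorted(per_band.items()):
                higher = {r.direction for r in rs}
                print(f"  {family} {band}: {len(rs)}/16 channels differ "
                      f"(higher in {', '.join(sorted(higher))})")
            plot_difference_map(res, args.out / f"map_{family.lower()}_{unit}.png",
                                title=f"{family} ({unit} level)")

        nets = differential_network(table, alpha=args.alpha, unit=unit)
        ratios = {b: n.ratio for b, n in nets.items()}
        print(f"  PLI edge ratios ({groups[1]}-higher/{groups[0]}-higher): "
              f"{ratios}")
        summary = {"alpha": args.alpha, "unit": unit, "ratios": ratios}
        if any(n.n_edges for n in nets.values()):
            shares = key_connection_share(nets)
            summary["band_shares_pct"] = {b: round(100 * s, 1)
                                          for b, s in shares.items()}
            print(f"  share of significant connections per band: "
                  f"{summary['band_shares_pct']}")
        for band, net in nets.items():
            pd.DataFrame(list(net.edges),
                         columns=["pair", "direction", "p_value"]).to_csv(
                args.out / f"network_{band}_{unit}.csv", index=False)
            plot_network(net, args.out / f"network_{band}_{unit}.png",
                         groups=tuple(groups))
        (args.out / f"summary_{unit}.json").write_text(
            json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
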