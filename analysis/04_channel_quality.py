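#!/usr/bin/env python
"""Channel quality validation on synthetic grids.

Two analyses mirroring the session-level quality checks: (i) outlier-score
flagging of simulated bad contacts over several seeds, and (ii) zero-lag
R^2 of channel pairs versus inter-electrode distance, separately along and
across the muscle fibers, on clean monopolar grids.

Outputs: results/outlier_validation.json, results/correlation_profile.csv.
"""

import argparse
import csv
import json
from pathlib import Path

import numpy as np

from hdsemg.channel_qc import (
    correlation_vs_distance,
    eligible_channels,
    outlier_scores,
)
from hdsemg.grid_preprocess import channels_to_grid, derive_differential, split_grids
from hdsemg.movement_labels import default_table
from hdsemg.synthetic_session import (
    LatencyModel,
    SourceModel,
    bad_differential_channels,
    make_bad_channel_mask,
    make_protocol,
    simulate_emg,
    simulate_forces,
)

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-seeds", type=int, default=5)
    args = parser.parse_args()

    table = default_table()
    protocol = make_protocol(8, 1, 4.0, 4.0)
    elig = eligible_channels()

    hits = total = false_pos = clean_total = 0
    for k in range(args.n_seeds):
        seed = args.seed + k
        mask = make_bad_channel_mask(2, seed=seed)
        _, gt = simulate_forces(protocol, table, LatencyModel(), seed=seed,
                                line_noise_amplitude=0.05, bad_channel_mask=mask)
        emg = simulate_emg(protocol, table, SourceModel(), gt, seed=seed + 1000)
        session = split_grids(derive_differential(emg))
        summary, _, _ = outlier_scores(session.extensors, session.flexors)
        affected = [i for i in bad_differential_channels(mask) if elig[i]]
        hits += sum(summary.scores[i] > 0 for i in affected)
        total += len(affected)
        clean = [i for i in range(128) if elig[i] and i not in affected]
        false_pos += sum(summary.scores[i] > 0 for i in clean)
        clean_total += len(clean)
    print(f"bad-contact channels flagged: {hits}/{total} "
          f"({100 * hits / total:.0f} %)")
    print(f"clean channels flagged: {false_pos}/{clean_total} "
          f"({100 * false_pos / clean_total:.2f} %)")

    # correlation structure on one clean session, flexor grid
    _, gt = simulate_forces(protocol, table, LatencyModel(), seed=args.seed)
    emg = simulate_emg(protocol, table, SourceModel(), gt, seed=args.seed + 77)
    grid = channels_to_grid(emg[:, 64:])
    profiles = {ax: correlation_vs_distance(grid, ax) for ax in ("along", "across")}
    for ax, prof in profiles.items():
        pretty = ", ".join(f"{v:.3f}" for v in prof.mean_r2)
        print(f"mean R^2 {ax} fibers, distances 1-7: {pretty}")

    (ROOT / "results").mkdir(exist_ok=True)
    with open(ROOT / "results" / "outlier_validation.json", "w") as fh:
        json.dump({
            "n_seeds": int(args.n_seeds),
            "bad_channels_flagged": int(hits),
            "bad_channels_total": int(total),
            "clean_channels_flagged": int(false_pos),
            "clean_channels_total": int(clean_total),
        }, fh, indent=2)
    with open(ROOT / "results" / "correlation_profile.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["axis", "distance", "mean_r2", "p25_r2", "p75_r2", "n_pairs"])
        for ax, prof in profiles.items():
            for i, d in enumerate(prof.distances):
                w.writerow([ax, d, f"{prof.mean_r2[i]:.5f}",
                            f"{prof.p25_r2[i]:.5f}", f"{prof.p75_r2[i]:.5f}",
                            prof.n_pairs[i]])
    print("wrote results/outlier_validation.json and results/correlation_profile.csv")


if __name__ == "__main__":
    main()
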