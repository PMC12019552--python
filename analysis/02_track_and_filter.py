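#!/usr/bin/env python
"""Link the simulated localizations into tracks and apply the 7-step filter.

Consumes results/01_simulate/localizations.csv (run 01 first, or pass
--locs), links with 3-frame gap closing, keeps tracks of at least seven
steps, and writes tracks + metadata under results/02_tracks/.
"""

import argparse
from pathlib import Path

from nanospt import io
from nanospt.detect_link import LinkConfig, filter_tracks, link_tracks

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--locs", type=Path,
                    default=ROOT / "results/01_simulate/localizations.csv")
    ap.add_argument("--out", type=Path, default=ROOT / "results/02_tracks")
    args = ap.parse_args()

    locs = io.read_localizations(args.locs)
    cfg = LinkConfig(max_disp_um=0.3, max_gap=3)
    tracks = link_tracks(locs, cfg)
    kept = filter_tracks(tracks, min_steps=7)
    args.out.mkdir(parents=True, exist_ok=True)
    io.write_tracks(kept, args.out / "tracks.csv",
                    args.out / "tracks_meta.json")
    n_gapped = sum(1 for t in kept if t.gap_frames)
    print(f"linked {len(locs)} localizations into {len(tracks)} tracks; "
          f"{len(kept)} have >= 7 steps ({n_gapped} bridged blink gaps)")
    print(f"wrote {args.out}/tracks.csv")


if __name__ == "__main__":
    main()
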