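#!/usr/bin/env python
"""Generate the study's synthetic inputs: two toy genomes with planted
orthologs/decoys/intron shifts, and stage-structured two-species count
matrices with known truth. Everything downstream reads from results/sim/."""

import argparse
from pathlib import Path

from orthostage import make_fixture_suite


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/sim"))
    args = ap.parse_args()

    paths = make_fixture_suite(args.out, seed=args.seed)
    print(f"Simulated inputs written under {args.out} (seed {args.seed}):")
    for key, p in sorted(paths.items()):
        print(f"  {key}: {p}")


if __name__ == "__main__":
    main()
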