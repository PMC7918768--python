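#!/usr/bin/env python
"""Probe the central mechanism: same mean fat fraction, different pattern.

Generates pairs of phantoms with matched mean PDFF (within 0.2 pp) — one
with homogeneous voxel noise, one with thin high-PDFF streaks — and
compares GLCM contrast and global variance.  If texture features are to add
information beyond mean PDFF, they must separate these pairs; the mean, by
construction, cannot.  Writes results/separability.csv.
"""

import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from muscletex.pipeline import PipelineConfig, extract_features_single
from muscletex.synthetic import PhantomSpec, generate_phantom

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--pairs", type=int, default=50)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

cfg = PipelineConfig()
rows = []
for i in range(args.pairs):
    sp = PhantomSpec(mean_pdff_pct=5.0, noise_sd_pct=1.0, pattern="streaks",
                     seed=args.seed * 100_000 + i)
    hp = dataclasses.replace(sp, pattern="homogeneous",
                             seed=args.seed * 100_000 + 50_000 + i)
    vs, ms = generate_phantom(sp)
    vh, mh = generate_phantom(hp)
    fs = extract_features_single(vs, ms, cfg)
    fh = extract_features_single(vh, mh, cfg)
    rows.append(
        {
            "pair": i,
            "mean_streak": fs["pdff"],
            "mean_homog": fh["pdff"],
            "contrast_streak": fs["contrast"],
            "contrast_homog": fh["contrast"],
            "varglob_streak": fs["variance_global"],
            "varglob_homog": fh["variance_global"],
        }
    )

df = pd.DataFrame(rows)
args.out.mkdir(parents=True, exist_ok=True)
df.to_csv(args.out / "separability.csv", index=False)

wins_c = (df["contrast_streak"] > df["contrast_homog"]).mean()
wins_v = (df["varglob_streak"] > df["varglob_homog"]).mean()
print(f"{args.pairs} mean-matched pairs "
      f"(max |mean diff| = {(df['mean_streak'] - df['mean_homog']).abs().max():.3f} pp)")
print(f"  streak contrast higher:        {100 * wins_c:.0f}%")
print(f"  streak global variance higher: {100 * wins_v:.0f}%")
print(f"  median contrast ratio streak/homog: "
      f"{(df['contrast_streak'] / df['contrast_homog']).median():.2f}")
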