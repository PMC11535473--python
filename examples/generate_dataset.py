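"""Generate the four-condition galactose-feed dataset.

Runs the synthetic generator (two replicate flasks per condition, realistic
sampling cadences, 5% CV noise, channel-specific missingness) and prints how
much of each channel survives — mirroring the incompleteness a real campaign
produces.
"""

from chosoft.synthetic import generate_dataset

observed, truth = generate_dataset(seed=7)

print(f"{len(observed.df)} scheduled observations over "
      f"{observed.df['condition'].nunique()} conditions x "
      f"{observed.df['replicate'].nunique()} replicates\n")
print(f"{'channel':>12} {'cells':>6} {'missing':>8}")
for name, grp in observed.df.groupby("channel"):
    print(f"{name:>12} {len(grp):6d} {grp['value'].isna().mean():8.0%}")

print("\nTiter and UDP-GlcNAc are the sparsest channels; the soft sensors "
      "must cope with exactly this pattern. 'truth' holds the noiseless "
      "ground-truth values for every scheduled cell.")
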