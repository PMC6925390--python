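"""Generate a ground-truthed synthetic dataset.

Creates a small world (8 subjects, 10 days) with a moderate text effect
size, writes the four dataset files, and prints the true state counts.
Every post's true state comes from the same tiredness model the
labeling pipeline applies, so the pair can be checked end to end.
"""

from collections import Counter

from somnotext import WorldConfig, generate_world, world_to_files

config = WorldConfig(n_subjects=8, n_days=10, effect_size=0.4, gap_prob=0.1, seed=42)
world = generate_world(config)
paths = world_to_files(world, "scratch/example_world")

print(f"posts: {len(world.posts)}")
print("true states:", dict(Counter(world.truth.values())))
print("files:", ", ".join(str(p) for p in paths.values()))
print(
    "\n'deprived' posts draw their words from a reduced vocabulary mixture "
    "(effect size 0.4); 'excluded' marks posts inside forced >28-h sensor gaps."
)
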