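"""Train the GRU classifier on a synthetic world and report test AUC.

Runs the full chain at desk scale — generate, label, train CBOW word
vectors, build the (posts x kappa x dim+3) tensor, then three seeded
81/9/10 split/train/test cycles — and prints the per-seed AUCs.
Takes on the order of a minute on one CPU.
"""

from somnotext import (
    EmbeddingConfig,
    TrainConfig,
    WorldConfig,
    build_tensor,
    generate_world,
    label_posts,
    repeated_evaluation,
    train_embeddings,
)

world = generate_world(
    WorldConfig(n_subjects=20, n_days=21, effect_size=0.8,
                deprived_vocab_fraction=0.5, seed=1)
)
rows = [lp for lp in label_posts(world.posts, world.trajectories)
        if lp.drop_reason == "none"]
emb = train_embeddings(world.corpus, EmbeddingConfig(dim=32, seed=1))
tensor = build_tensor(rows, emb)
print(f"{len(rows)} labeled posts, kappa={tensor.spec.kappa}, "
      f"xi={tensor.spec.xi}, vocabulary={len(emb)}")

result = repeated_evaluation(
    tensor, TrainConfig(hidden_units=32, epochs=10), seeds=[1, 2, 3]
)
print("per-seed test AUCs:", [round(a, 3) for a in result.per_seed_aucs])
print(f"mean AUC {result.mean_auc:.3f} (SD {result.sd_auc:.3f})")
print(
    "\nAUC is the probability a random deprived post outranks a random "
    "sufficient one; 0.5 is chance. At this strong text effect size the "
    "classifier separates the states well."
)
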