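"""End-to-end orchestration: synthesize, label, train/evaluate.

These functions are the library face of the command-line interface; each
reads/writes the package's standard file formats and returns its main
result so they are equally usable from Python.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, replace
from pathlib import Path

from . import classifier as clf
from .embeddings import EmbeddingConfig, train_embeddings
from .features import build_tensor, load_lexicon, preprocess
from .io_ingest import (
    read_labeled_posts,
    read_posts,
    read_sleep_csv,
    write_labeled_posts,
)
from .labeling import DROP_NONE, LabeledPost, label_posts
from .synthetic import WorldConfig, generate_world, world_to_files
from .tiredness import TirednessParams, build_trajectory, write_trajectory_csv
from .timeutil import parse_ts

logger = logging.getLogger(__name__)


def run_synthesize(config: WorldConfig, out_dir: str | Path) -> dict[str, Path]:
    """Generate a synthetic world and write its dataset directory."""
    world = generate_world(config)
    return world_to_files(world, out_dir)


def run_label(
    sleep_path: str | Path,
    posts_path: str | Path,
    out_dir: str | Path,
    params: TirednessParams = TirednessParams(),
) -> list[LabeledPost]:
    """Ingest sleep + posts, build trajectories, label, and write
    ``labeled.csv`` and ``trajectory.csv`` into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schedules = read_sleep_csv(sleep_path)
    posts = read_posts(posts_path)
    trajectories = {sid: build_trajectory(s, params) for sid, s in schedules.items()}
    labeled = label_posts(posts, trajectories, params)
    write_labeled_posts(out / "labeled.csv", labeled)
    write_trajectory_csv(out / "trajectory.csv", trajectories)
    return labeled


def _labeled_rows_with_text(labeled_path, posts_path) -> list[LabeledPost]:
    """Join the labeled CSV back to post text; keep non-dropped rows."""
    from .io_ingest import Post

    df = read_labeled_posts(labeled_path)
    text_by_id = {p.post_id: p.text for p in read_posts(posts_path)}
    rows: list[LabeledPost] = []
    for rec in df.itertuples(index=False):
        if rec.drop_reason != DROP_NONE:
            continue
        text = text_by_id.get(rec.post_id)
        if text is None:
            raise ValueError(f"post {rec.post_id!r} in labeled CSV missing from posts file")
        rows.append(
            LabeledPost(
                Post(rec.post_id, rec.subject_id, parse_ts(rec.timestamp), text),
                float(rec.tl),
                rec.label,
            )
        )
    return rows


def read_corpus(path: str | Path) -> list[list[str]]:
    """One sentence per line; lines are run through :func:`preprocess`."""
    with open(path, encoding="utf-8") as fh:
        sents = [preprocess(line) for line in fh if line.strip()]
    return [s for s in sents if s]


def run_train_eval(
    labeled_path: str | Path,
    posts_path: str | Path,
    corpus_path: str | Path,
    out_dir: str | Path,
    emb_config: EmbeddingConfig = EmbeddingConfig(),
    train_config: clf.TrainConfig = clf.TrainConfig(),
    seeds: list[int] | None = None,
    lexicon_path: str | Path | None = None,
) -> dict:
    """Embeddings -> tensor -> repeated seeded evaluation.

    Writes ``metrics.json``, ``embedding.txt`` (word2vec text format) and
    a model checkpoint ``model.npz`` (trained at the first seed) into
    ``out_dir``; returns the metrics dict.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if seeds is None:
        seeds = [train_config.seed + i for i in range(train_config.n_runs)]
    rows = _labeled_rows_with_text(labeled_path, posts_path)
    if not rows:
        raise ValueError("no labeled (non-dropped) posts to train on")
    labels = {lp.label for lp in rows}
    if len(labels) < 2:
        raise ValueError(f"labeled data has a single class: {labels}")

    emb = train_embeddings(read_corpus(corpus_path), emb_config)
    emb.save(out / "embedding.txt")
    lex = load_lexicon(lexicon_path)
    tensor = build_tensor(rows, emb, lex)
    logger.info(
        "tensor: %d posts, kappa=%d, xi=%d, vocabulary=%d",
        len(tensor), tensor.spec.kappa, tensor.spec.xi, len(emb),
    )

    result = clf.repeated_evaluation(tensor, train_config, seeds)

    ckpt_cfg = replace(train_config, seed=seeds[0])
    train, val, test = clf.split_dataset(tensor, ckpt_cfg)
    model = clf.train_model(train, val, ckpt_cfg)
    model.save(out / "model.npz")

    metrics = {
        "per_seed_aucs": result.per_seed_aucs,
        "mean_auc": result.mean_auc,
        "sd_auc": result.sd_auc,
        "n_train": len(train),
        "n_val": len(val),
        "n_test": len(test),
        "kappa": tensor.spec.kappa,
        "xi": tensor.spec.xi,
        "vocabulary_size": len(emb),
        "seeds": list(seeds),
        "config": {
            "embedding": asdict(emb_config),
            "train": asdict(train_config),
        },
    }
    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2)
    return metrics
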