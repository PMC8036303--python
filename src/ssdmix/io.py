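"""Delimited-text and JSON I/O for bags, labels, models and kernel matrices."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .ssd import FeatureBag, SSDMixture

__all__ = [
    "write_bags_tsv",
    "read_bags_tsv",
    "write_labels_tsv",
    "read_labels_tsv",
    "save_model_json",
    "load_model_json",
    "write_kernel_tsv",
    "read_kernel_tsv",
]


def write_bags_tsv(bags, path: str | Path) -> None:
    """Bags as TSV: image_id column, then one column per feature coordinate."""
    frames = []
    for bag in bags:
        df = pd.DataFrame(bag.vectors, columns=[f"f{d}" for d in range(bag.dim)])
        df.insert(0, "image_id", bag.image_id)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_bags_tsv(path: str | Path) -> list[FeatureBag]:
    df = pd.read_csv(path, sep="\t")
    if "image_id" not in df.columns:
        raise ValueError("bags file must have an image_id column")
    feat_cols = [c for c in df.columns if c != "image_id"]
    return [
        FeatureBag(str(image_id), group[feat_cols].to_numpy(dtype=float))
        for image_id, group in df.groupby("image_id", sort=False)
    ]


def write_labels_tsv(labels: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"image_id": list(labels), "label": list(labels.values())}
    ).to_csv(path, sep="\t", index=False)


def read_labels_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["image_id"], df["label"]))


def save_model_json(model: SSDMixture, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model_json(path: str | Path) -> SSDMixture:
    return SSDMixture.from_dict(json.loads(Path(path).read_text()))


def write_kernel_tsv(gram: np.ndarray, image_ids, path: str | Path) -> None:
    pd.DataFrame(gram, index=list(image_ids), columns=list(image_ids)).to_csv(
        path, sep="\t", index_label="image_id"
    )


def read_kernel_tsv(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col="image_id")
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]
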