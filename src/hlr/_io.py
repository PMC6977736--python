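"""CSV / manifest plumbing shared by the command-line interface."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import ClusterInstance, SyntheticConfig, TrainingSet


def sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path, command: str, params: dict, inputs=()) -> None:
    """Record a run: command, full parameter snapshot, input checksums.

    Deliberately no timestamps or hostnames — identical runs must produce
    byte-identical manifests.
    """
    from . import __version__
    doc = {
        "command": command,
        "version": __version__,
        "params": params,
        "inputs": {str(p): sha256(p) for p in inputs},
    }
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def read_matrix_csv(path, delimiter: str = ",", header: str | bool = "auto",
                    label_col: str | int | None = None):
    """Read a numeric sample matrix from CSV/TSV.

    ``header='auto'`` sniffs the first line: if every token parses as a
    float the file is taken to be headerless.  ``label_col`` names (or
    indexes) a column of ground-truth labels to strip off and return
    separately.

    Returns ``(X, labels_or_None)``.
    """
    path = Path(path)
    if header == "auto":
        first = path.open().readline()
        tokens = [t for t in first.strip().split(delimiter) if t != ""]
        header = not _all_floats(tokens)
    df = pd.read_csv(path, sep=delimiter, header=0 if header else None)
    labels = None
    if label_col is not None:
        if isinstance(label_col, int) or (isinstance(label_col, str)
                                          and label_col not in df.columns):
            label_col = df.columns[int(label_col)]
        labels = df.pop(label_col).to_numpy()
    X = df.to_numpy(dtype=float)
    return X, labels


def _all_floats(tokens) -> bool:
    if not tokens:
        return False
    for t in tokens:
        try:
            float(t)
        except ValueError:
            return False
    return True


# ---------------------------------------------------------------- datasets

def save_training_set(ts: TrainingSet, outdir) -> None:
    """Write a training set as points.csv + labels.csv + manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dim = ts.instances[0].points.shape[1]
    cols = [f"x{j}" for j in range(dim)]
    frames = []
    for i, inst in enumerate(ts.instances):
        df = pd.DataFrame(inst.points, columns=cols)
        df.insert(0, "instance", i)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(outdir / "points.csv", index=False)
    pd.DataFrame({"instance": np.arange(len(ts)),
                  "n_clusters": ts.labels}).to_csv(outdir / "labels.csv", index=False)
    meta = {
        "config": ts.config.to_dict() if ts.config else None,
        "K": len(ts),
        "sizes": [list(inst.sizes) for inst in ts.instances],
    }
    (outdir / "dataset.json").write_text(json.dumps(meta, indent=2) + "\n")


def load_training_set(datadir) -> TrainingSet:
    datadir = Path(datadir)
    points = pd.read_csv(datadir / "points.csv")
    labels = pd.read_csv(datadir / "labels.csv")
    meta = json.loads((datadir / "dataset.json").read_text())
    config = SyntheticConfig(**{**meta["config"],
                                "k_range": tuple(meta["config"]["k_range"]),
                                "size_range": tuple(meta["config"]["size_range"]),
                                "centroid_interval": tuple(meta["config"]["centroid_interval"]),
                                "sigma_range": tuple(meta["config"]["sigma_range"])}) \
        if meta.get("config") else None
    instances = []
    for i, row in labels.iterrows():
        X = points.loc[points["instance"] == row["instance"]] \
            .drop(columns="instance").to_numpy(dtype=float)
        sizes = meta["sizes"][i] if meta.get("sizes") else [X.shape[0]]
        if sum(sizes) != X.shape[0] or len(sizes) != row["n_clusters"]:
            sizes = None
        instances.append(ClusterInstance(
            points=X, n_clusters=int(row["n_clusters"]),
            sizes=tuple(sizes) if sizes else _fallback_sizes(int(row["n_clusters"]),
                                                             X.shape[0])))
    return TrainingSet(instances=instances,
                       labels=labels["n_clusters"].to_numpy(dtype=int),
                       config=config)


def _fallback_sizes(k: int, M: int) -> tuple[int, ...]:
    base = [M // k] * k
    for i in range(M - sum(base)):
        base[i] += 1
    return tuple(base)
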