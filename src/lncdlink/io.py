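"""Plain-text readers and writers for the pipeline's artifacts.

Everything is TSV or simple structured text: association and ontology edge
lists, labelled similarity matrices with a sidecar role file, walk corpora
(one whitespace-separated walk per line), embeddings in word2vec text
format, and metrics/prediction tables.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .similarity import SimilarityMatrix

__all__ = [
    "save_matrix",
    "load_matrix",
    "save_pairs",
    "save_predictions",
]


def save_matrix(sim: SimilarityMatrix, path) -> None:
    """Write a similarity matrix as TSV with headers plus a `.meta` sidecar."""
    path = Path(path)
    sim.to_frame().to_csv(path, sep="\t")
    meta = {"role": sim.role, "n": len(sim.ids)}
    path.with_suffix(path.suffix + ".meta").write_text(yaml.safe_dump(meta))


def load_matrix(path) -> SimilarityMatrix:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = path.with_suffix(path.suffix + ".meta")
    if not meta_path.exists():
        raise FileNotFoundError(f"missing sidecar metadata {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    return SimilarityMatrix(df.to_numpy(dtype=float),
                            [str(c) for c in df.columns], meta["role"])


def save_pairs(pairs, path, header=("lncRNA_id", "disease_id")) -> None:
    """Write (lncRNA, disease) pairs as a two-column TSV without header."""
    with open(path, "w") as fh:
        for l, d in pairs:
            fh.write(f"{l}\t{d}\n")


def save_predictions(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
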