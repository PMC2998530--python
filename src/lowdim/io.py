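"""Tab-separated file formats.

Expression matrices travel as TSV with a header row and an id column.  The
microarray convention puts probes/genes in rows, so that is the default read
orientation; matrices are normalized to samples-in-rows internally.
Embeddings round-trip at full double precision (17 significant digits).
"""
from __future__ import annotations

import ast
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .types import Embedding, ExpressionMatrix, ValidationError

ORIENTATIONS = ("genes_in_rows", "samples_in_rows")


def read_expression(path, orientation: str = "genes_in_rows") -> ExpressionMatrix:
    """Read a TSV expression table and normalize to samples-in-rows.

    The first row is a header of ids, the first column holds the other axis'
    ids.  Ragged rows, non-numeric cells and duplicate ids are rejected with
    line-numbered messages.
    """
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"orientation must be one of {ORIENTATIONS}")
    path = Path(path)
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                header_ids = line.rstrip("\n").split("\t")[1:]
                break
        else:
            raise ValidationError(f"{path.name}: empty file")
    dup = {h for h in header_ids if header_ids.count(h) > 1}
    if dup:
        raise ValidationError(f"{path.name}: duplicate ids in header: {sorted(dup)}")
    raw = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str, comment="#")
    n_cols = raw.shape[1]
    values = np.empty(raw.shape, dtype=float)
    for r in range(raw.shape[0]):
        row = raw.iloc[r]
        if row.isna().any():
            raise ValidationError(
                f"{path.name}: ragged or incomplete row at line {r + 2} (id {raw.index[r]!r})"
            )
        for c in range(n_cols):
            try:
                values[r, c] = float(row.iloc[c])
            except (TypeError, ValueError):
                raise ValidationError(
                    f"{path.name}: non-numeric cell at line {r + 2}, column {c + 2} "
                    f"(value {row.iloc[c]!r})"
                ) from None
    row_ids = [str(i) for i in raw.index]
    col_ids = [str(c) for c in raw.columns]
    if orientation == "genes_in_rows":
        return ExpressionMatrix(values.T, sample_ids=col_ids, feature_ids=row_ids)
    return ExpressionMatrix(values, sample_ids=row_ids, feature_ids=col_ids)


def write_expression(X: ExpressionMatrix, path, orientation: str = "genes_in_rows") -> None:
    if orientation not in ORIENTATIONS:
        raise ValidationError(f"orientation must be one of {ORIENTATIONS}")
    if orientation == "genes_in_rows":
        df = pd.DataFrame(X.values.T, index=X.feature_ids, columns=X.sample_ids)
        df.index.name = "feature_id"
    else:
        df = pd.DataFrame(X.values, index=X.sample_ids, columns=X.feature_ids)
        df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.17g")


def read_labels(path) -> dict:
    """Read a two-column TSV (sample id, class) without a header."""
    path = Path(path)
    labels = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValidationError(
                    f"{path.name}: expected two tab-separated columns at line {lineno}"
                )
            sid, cls = parts
            if sid in labels:
                raise ValidationError(f"{path.name}: duplicate sample id {sid!r} at line {lineno}")
            labels[sid] = cls
    if not labels:
        raise ValidationError(f"{path.name}: no labels found")
    return labels


def attach_labels(X: ExpressionMatrix, labels: dict, require_binary: bool = True) -> ExpressionMatrix:
    """Validate a label mapping against a matrix and encode classes as 0/1.

    Benchmark-style commands require exactly two classes; embedding-only
    workflows may carry any labels (they are unused).
    """
    unknown = sorted(set(labels) - set(X.sample_ids))
    if unknown:
        raise ValidationError(f"labels refer to unknown sample ids: {unknown}")
    classes = sorted(set(labels.values()))
    if require_binary:
        if len(classes) != 2:
            raise ValidationError(
                f"benchmark commands require exactly 2 classes, got {len(classes)}: {classes}"
            )
        encoded = {sid: classes.index(c) for sid, c in labels.items()}
    else:
        encoded = {sid: (classes.index(c) if c not in (0, 1, "0", "1") else int(c)) for sid, c in labels.items()}
    return ExpressionMatrix(X.values, list(X.sample_ids), list(X.feature_ids), encoded)


def write_embedding(emb: Embedding, path, seed=None) -> None:
    """Write an embedding TSV with a provenance comment header."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# method: {emb.method}\n")
        fh.write(f"# params: {dict(emb.params)!r}\n")
        fh.write(f"# seed: {seed}\n")
        fh.write(f"# lowdim version: {__version__}\n")
        if emb.dropped_ids:
            fh.write(f"# dropped (disconnected): {list(emb.dropped_ids)!r}\n")
        cols = "\t".join(f"dim{j + 1}" for j in range(emb.d))
        fh.write(f"sample_id\t{cols}\n")
        for sid, row in zip(emb.sample_ids, emb.coords):
            vals = "\t".join(f"{v:.17g}" for v in row)
            fh.write(f"{sid}\t{vals}\n")


def read_embedding(path) -> Embedding:
    path = Path(path)
    meta = {"method": "PCA", "params": {}, "dropped": ()}
    rows, sids = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("# method:"):
                meta["method"] = line.split(":", 1)[1].strip()
            elif line.startswith("# params:"):
                meta["params"] = ast.literal_eval(line.split(":", 1)[1].strip())
            elif line.startswith("# dropped"):
                meta["dropped"] = tuple(ast.literal_eval(line.split(":", 1)[1].strip()))
            elif line.startswith("#") or line.startswith("sample_id\t"):
                continue
            elif line:
                parts = line.split("\t")
                sids.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
    coords = np.asarray(rows, dtype=float)
    params = dict(meta["params"])
    params["d"] = coords.shape[1]
    return Embedding(coords, meta["method"], params, sids, meta["dropped"])


def parse_config(path) -> dict:
    """Parse a plain-text ``key = value[,value...]`` configuration file."""
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValidationError(f"config line {lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            items = [v.strip() for v in value.split(",") if v.strip()]
            parsed = []
            for v in items:
                try:
                    parsed.append(int(v))
                except ValueError:
                    try:
                        parsed.append(float(v))
                    except ValueError:
                        parsed.append(v)
            out[key] = parsed if len(parsed) > 1 else parsed[0]
    return out
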