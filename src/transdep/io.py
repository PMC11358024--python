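"""Readers and writers for the pipeline's plain-text interchange formats.

All matrices travel as TSV with a leading ``gene`` column and sample IDs in
the header; floats are written in their shortest round-trip representation
so files are byte-stable and diffable.  Models serialize to a single TSV
with a JSON header line, survival/metadata/design/count tables are plain
TSV, reads are standard 4-line FASTQ.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (EssentialityMap, ExpressionMatrix, FormatError,
                         GeneModel, ModelSet)

MODEL_FORMAT_VERSION = 1


def _fmt(x) -> str:
    """Shortest round-trip decimal representation."""
    if isinstance(x, (float, np.floating)):
        return repr(float(x))
    return str(x)


def _frame_to_tsv(df: pd.DataFrame, path, index_label: str) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\t".join([index_label, *map(str, df.columns)]) + "\n")
        for label, row in zip(df.index, df.to_numpy()):
            fh.write("\t".join([str(label), *(_fmt(v) for v in row)]) + "\n")


def read_matrix(path, kind: str = "real"):
    """Load a genes x samples TSV.

    kind = 'real' returns a plain DataFrame of floats, 'binary' validates a
    0/1 matrix, 'expression' / 'essentiality' wrap in the typed container.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={0: str},
                     float_precision="round_trip")
    if df.columns[0] != "gene":
        raise FormatError(f"{path}: first column must be 'gene', got {df.columns[0]!r}")
    df = df.set_index("gene")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated gene row(s): {dup[:5]}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicated sample column(s): {dup[:5]}")
    try:
        vals = df.astype(float)
    except ValueError as e:
        raise FormatError(f"{path}: non-numeric cell ({e})") from None
    if vals.isna().to_numpy().any():
        gene = vals.index[vals.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value in gene row {gene!r}")
    if kind == "binary":
        arr = vals.to_numpy()
        bad = ~np.isin(arr, (0.0, 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise FormatError(
                f"{path}: non-binary value {arr[i, j]!r} at gene={vals.index[i]!r}, "
                f"sample={vals.columns[j]!r}"
            )
        return vals.astype(int)
    if kind == "expression":
        return ExpressionMatrix(vals)
    if kind == "essentiality":
        return EssentialityMap(vals)
    if kind == "real":
        return vals
    raise ValueError(f"unknown kind {kind!r}")


def write_matrix(obj, path) -> None:
    df = obj.values if isinstance(obj, (ExpressionMatrix, EssentialityMap)) else obj
    _frame_to_tsv(df, path, "gene")


def read_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str},
                     float_precision="round_trip")
    if "sample" not in df.columns:
        raise FormatError(f"{path}: metadata needs a 'sample' column")
    df = df.set_index("sample")
    if df.index.has_duplicates:
        raise FormatError(f"{path}: duplicated sample in metadata")
    return df


def write_metadata(meta: pd.DataFrame, path) -> None:
    _frame_to_tsv(meta, path, "sample")


def read_survival(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str},
                     float_precision="round_trip").set_index("sample")
    for col in ("time", "event"):
        if col not in df.columns:
            raise FormatError(f"{path}: survival table needs a {col!r} column")
    if (df["time"] <= 0).any():
        raise FormatError(f"{path}: nonpositive survival time")
    if not df["event"].isin((0, 1)).all():
        raise FormatError(f"{path}: event must be 0/1")
    return df


def write_survival(surv: pd.DataFrame, path) -> None:
    _frame_to_tsv(surv, path, "sample")


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"construct_id": str}).set_index("construct_id")
    vals = df.astype(float)
    if (vals < 0).to_numpy().any() or not np.allclose(vals, vals.round()):
        raise FormatError(f"{path}: counts must be nonnegative integers")
    return vals.astype(int)


def write_counts(counts: pd.DataFrame, path) -> None:
    _frame_to_tsv(counts, path, "construct_id")


def write_fastq(records, path) -> None:
    """records: iterable of (read_id, sequence); quality is constant 'I'."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def read_fastq(path):
    """Yield (read_id, sequence) from a 4-line FASTQ."""
    from Bio import SeqIO

    for rec in SeqIO.parse(str(path), "fastq"):
        yield rec.id, str(rec.seq)


# ---------------------------------------------------------------- models ---

def serialize_models(mset: ModelSet, path) -> None:
    """Single TSV: JSON header line, model table, then long-format coefficients."""
    path = Path(path)
    with open(path, "w") as fh:
        header = {"format": "transdep-models", "version": MODEL_FORMAT_VERSION,
                  "provenance": mset.provenance}
        fh.write("#" + json.dumps(header, sort_keys=True) + "\n")
        fh.write("gene\tmode\talpha\tlambda\tintercept\tcv_r\tp\tq\tpass\t"
                 "n_features\tself_rank\tflag\n")
        for m in sorted(mset.models, key=lambda m: (m.mode, m.gene)):
            fh.write("\t".join([
                m.gene, m.mode, _fmt(m.alpha), _fmt(m.lam), _fmt(m.intercept),
                _fmt(m.cv_r), _fmt(m.p), _fmt(m.q), str(int(m.passed)),
                str(m.n_features), "" if m.self_rank is None else str(m.self_rank),
                m.flag,
            ]) + "\n")
        fh.write("#coefficients\n")
        fh.write("gene\tmode\tfeature\tcoefficient\tfeature_mean\tfeature_sd\n")
        for m in sorted(mset.models, key=lambda m: (m.mode, m.gene)):
            for feat in m.coef.index:
                fh.write("\t".join([
                    m.gene, m.mode, str(feat), _fmt(m.coef[feat]),
                    _fmt(m.feature_mean[feat]), _fmt(m.feature_sd[feat]),
                ]) + "\n")


def deserialize_models(path) -> ModelSet:
    path = Path(path)
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or not lines[0].startswith("#{"):
        raise FormatError(f"{path}: missing model header")
    header = json.loads(lines[0][1:])
    if header.get("version") != MODEL_FORMAT_VERSION:
        raise FormatError(
            f"{path}: model format version {header.get('version')} != "
            f"{MODEL_FORMAT_VERSION}"
        )
    split = lines.index("#coefficients")
    model_rows = [l.split("\t") for l in lines[2:split]]
    coef_cols = lines[split + 1].split("\t")
    coef_rows = [l.split("\t") for l in lines[split + 2:]]
    coefs: dict[tuple, list] = {}
    for row in coef_rows:
        d = dict(zip(coef_cols, row))
        coefs.setdefault((d["gene"], d["mode"]), []).append(
            (d["feature"], float(d["coefficient"]),
             float(d["feature_mean"]), float(d["feature_sd"]))
        )
    models = []
    cols = lines[1].split("\t")
    for row in model_rows:
        d = dict(zip(cols, row))
        entries = coefs.get((d["gene"], d["mode"]), [])
        feats = [e[0] for e in entries]
        models.append(GeneModel(
            gene=d["gene"], mode=d["mode"], alpha=float(d["alpha"]),
            lam=float(d["lambda"]), intercept=float(d["intercept"]),
            coef=pd.Series([e[1] for e in entries], index=feats, dtype=float),
            feature_mean=pd.Series([e[2] for e in entries], index=feats, dtype=float),
            feature_sd=pd.Series([e[3] for e in entries], index=feats, dtype=float),
            cv_r=float(d["cv_r"]), p=float(d["p"]), q=float(d["q"]),
            passed=bool(int(d["pass"])),
            self_rank=None if d["self_rank"] == "" else int(d["self_rank"]),
            flag=d["flag"],
        ))
    return ModelSet(models, provenance=header.get("provenance", {}))


def write_truth(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=1, sort_keys=True)
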