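"""Readers, writers and filtering for count tables.

Count tables are taxa-by-samples: first column taxon ids, header row sample
ids (the dominant microbiome convention).  Classic BIOM-format JSON (v1,
sparse or dense) is also accepted.  Taxon filtering never redefines the
depth covariate: sequencing depth is always the column sum of the
*unfiltered* matrix.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .normalize import NormalizedMatrix
from .zinb import CountMatrix

__all__ = ["read_counts", "write_counts", "write_normalized", "filter_taxa"]


def _frame_to_matrix(df: pd.DataFrame, path) -> CountMatrix:
    taxon_ids = [str(t) for t in df.index]
    sample_ids = [str(s) for s in df.columns]
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float)) | (values.astype(float) != np.floor(values.astype(float)))
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise ValueError(
            f"{path}: non-integer entry at taxon {taxon_ids[i]!r}, sample {sample_ids[j]!r}")
    values = values.astype(np.int64)
    neg = values < 0
    if neg.any():
        i, j = np.argwhere(neg)[0]
        raise ValueError(
            f"{path}: negative count at taxon {taxon_ids[i]!r}, sample {sample_ids[j]!r}")
    return CountMatrix(counts=values, taxon_ids=taxon_ids, sample_ids=sample_ids)


def _read_biom_json(path) -> CountMatrix:
    with open(path) as fh:
        doc = json.load(fh)
    for key in ("rows", "columns", "data", "matrix_type", "shape"):
        if key not in doc:
            raise ValueError(f"{path}: not classic BIOM JSON (missing {key!r})")
    p, n = doc["shape"]
    counts = np.zeros((p, n), dtype=np.int64)
    if doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            counts[int(i), int(j)] = int(v)
    elif doc["matrix_type"] == "dense":
        counts[:] = np.asarray(doc["data"], dtype=np.int64)
    else:
        raise ValueError(f"{path}: unknown matrix_type {doc['matrix_type']!r}")
    taxon_ids = [str(r["id"]) for r in doc["rows"]]
    sample_ids = [str(c["id"]) for c in doc["columns"]]
    return CountMatrix(counts=counts, taxon_ids=taxon_ids, sample_ids=sample_ids)


def read_counts(path, fmt: str | None = None,
                orientation: str = "taxa-by-samples") -> CountMatrix:
    """Read a count table; ``fmt`` in {tsv, csv, biom-json} (inferred from suffix).

    ``orientation="samples-by-taxa"`` transposes tables whose rows are samples.
    """
    if orientation not in ("taxa-by-samples", "samples-by-taxa"):
        raise ValueError(f"unknown orientation {orientation!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = {".tsv": "tsv", ".txt": "tsv", ".csv": "csv",
               ".biom": "biom-json", ".json": "biom-json"}.get(path.suffix.lower(), "tsv")
    if fmt == "biom-json":
        return _read_biom_json(path)
    sep = "\t" if fmt == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, index_col=0)
    except Exception as exc:
        raise ValueError(f"{path}: could not parse as {fmt}: {exc}") from exc
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate taxon id {dup!r}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    if orientation == "samples-by-taxa":
        df = df.T
    return _frame_to_matrix(df, path)


def write_counts(path, counts: CountMatrix) -> None:
    pd.DataFrame(counts.counts, index=counts.taxon_ids,
                 columns=counts.sample_ids).to_csv(path, sep="\t")


def write_normalized(path, norm: NormalizedMatrix, metadata: dict | None = None) -> None:
    """Write the residual matrix as TSV plus a JSON metadata sidecar."""
    path = Path(path)
    pd.DataFrame(norm.values, index=norm.taxon_ids,
                 columns=norm.sample_ids).to_csv(path, sep="\t")
    meta = {"seed": norm.seed}
    meta.update(metadata or {})
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2, default=str))


def read_normalized(path) -> NormalizedMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    meta_path = Path(path).with_suffix(Path(path).suffix + ".meta.json")
    seed = None
    if meta_path.exists():
        seed = json.loads(meta_path.read_text()).get("seed")
    return NormalizedMatrix(values=df.to_numpy(dtype=float),
                            taxon_ids=[str(t) for t in df.index],
                            sample_ids=[str(s) for s in df.columns], seed=seed)


def filter_taxa(counts: CountMatrix, min_nonzero_samples: int = 10):
    """Drop taxa with nonzero counts in <= ``min_nonzero_samples`` samples.

    The retention rule is strict ("more than"): a taxon nonzero in exactly
    ``min_nonzero_samples`` samples is dropped.  Returns the filtered matrix,
    the dropped taxon ids, and the log-depth vector of the *unfiltered*
    matrix to use as the model covariate.
    """
    nonzero = (counts.counts > 0).sum(axis=1)
    keep = nonzero > min_nonzero_samples
    if not keep.any():
        raise ValueError("no taxa pass the prevalence filter")
    dropped = [t for t, k in zip(counts.taxon_ids, keep) if not k]
    x = np.log(counts.counts.sum(axis=0).astype(float))
    kept = CountMatrix(counts=counts.counts[keep],
                       taxon_ids=[t for t, k in zip(counts.taxon_ids, keep) if k],
                       sample_ids=list(counts.sample_ids))
    return kept, dropped, x
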