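"""Readers and writers for the pipeline's on-disk formats.

Formats: 10x-style Matrix-Market triple (``matrix.mtx[.gz]`` +
``features.tsv[.gz]`` + ``barcodes.tsv[.gz]``), annotation TSV
(``cell_id``, ``line``, ``group``, ``cluster``), GMT gene-set collections,
plain-text TF lists, and TSV result tables with a reproducibility header.
All readers reject malformed input rather than coercing it.
"""

from __future__ import annotations

import gzip
import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import GeneMatrix
from .errors import FormatError


def _find(dir_path: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = dir_path / name
        if p.exists():
            return p
    raise FormatError(f"missing file {stem}[.gz] in {dir_path}")


def _open_text(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "r")


def _read_lines(path: Path) -> list[str]:
    with _open_text(path) as fh:
        return [line.rstrip("\n") for line in fh if line.strip() != ""]


def _dedupe(names: list[str]) -> list[str]:
    """Disambiguate duplicates deterministically: suffix .1, .2 in file order."""
    seen: dict[str, int] = {}
    out = []
    for name in names:
        if name in seen:
            seen[name] += 1
            out.append(f"{name}.{seen[name]}")
        else:
            seen[name] = 0
            out.append(name)
    return out


def read_matrix(dir_path, integer: bool = True) -> GeneMatrix:
    """Read a 10x-style Matrix-Market triple from ``dir_path``.

    ``features.tsv`` may have one column (gene name) or 10x's id/name/type
    columns, in which case the second column is used. Duplicate names are
    suffixed ``.1``, ``.2``, ... in file order. With ``integer=True``
    (counts) non-integer values are a format error.
    """
    dir_path = Path(dir_path)
    mtx_path = _find(dir_path, "matrix.mtx")
    feat_path = _find(dir_path, "features.tsv")
    bc_path = _find(dir_path, "barcodes.tsv")

    try:
        if mtx_path.suffix == ".gz":
            with gzip.open(mtx_path, "rb") as fh:
                M = scipy.io.mmread(_io.BytesIO(fh.read()))
        else:
            M = scipy.io.mmread(mtx_path)
    except Exception as exc:  # noqa: BLE001 - re-raise with the file name
        raise FormatError(f"cannot parse {mtx_path}: {exc}") from exc
    M = sp.csr_matrix(M)

    if integer:
        if not np.allclose(M.data, np.round(M.data)):
            raise FormatError(f"{mtx_path} contains non-integer values for a count matrix")
        if (M.data < 0).any():
            raise FormatError(f"{mtx_path} contains negative counts")
        M = M.astype(np.int64)

    feat_rows = [line.split("\t") for line in _read_lines(feat_path)]
    genes = [row[1] if len(row) >= 2 else row[0] for row in feat_rows]
    barcodes = [line.split("\t")[0] for line in _read_lines(bc_path)]
    if M.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"{mtx_path}: matrix is {M.shape} but {feat_path.name} lists "
            f"{len(genes)} genes and {bc_path.name} lists {len(barcodes)} barcodes"
        )
    return GeneMatrix(M, pd.Index(_dedupe(genes)), pd.Index(_dedupe(barcodes)))


def write_matrix(dir_path, mat: GeneMatrix) -> None:
    """Write a Matrix-Market triple (plain text) into ``dir_path``."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    X = sp.coo_matrix(mat.X)
    is_int = np.issubdtype(X.dtype, np.integer)
    scipy.io.mmwrite(
        dir_path / "matrix.mtx", X, field="integer" if is_int else "real"
    )
    with open(dir_path / "features.tsv", "w") as fh:
        for g in mat.genes:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(dir_path / "barcodes.tsv", "w") as fh:
        for b in mat.cells:
            fh.write(f"{b}\n")


def read_annotation(path) -> pd.DataFrame:
    """Read the per-cell annotation TSV (cell_id, line, group, cluster)."""
    path = Path(path)
    ann = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "line": str, "group": str})
    required = {"cell_id", "line", "group", "cluster"}
    missing = required - set(ann.columns)
    if missing:
        raise FormatError(f"{path}: missing annotation columns {sorted(missing)}")
    if ann["cell_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate cell_id values")
    return ann


def write_annotation(path, ann: pd.DataFrame) -> None:
    ann.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT file: name <tab> description <tab> member genes...

    Members are de-duplicated preserving order; an empty set or a line
    with fewer than three fields is a format error naming the line.
    """
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member"
                )
            name = fields[0]
            members = list(dict.fromkeys(g for g in fields[2:] if g != ""))
            if not members:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = members
    if not sets:
        raise FormatError(f"{path}: no gene set found")
    return sets


def write_gmt(path, sets: dict[str, list[str]], description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *members]) + "\n")


def read_gene_list(path) -> list[str]:
    """One gene symbol per line; blank lines ignored, order preserved."""
    path = Path(path)
    genes = list(dict.fromkeys(_read_lines(path)))
    if not genes:
        raise FormatError(f"{path}: empty gene list")
    return genes


def write_table(path, df: pd.DataFrame, header_meta: dict | None = None) -> None:
    """Write a result TSV with ``# key=value`` reproducibility header lines."""
    with open(path, "w") as fh:
        for key, value in (header_meta or {}).items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
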