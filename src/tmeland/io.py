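"""On-disk formats: Space Ranger-dialect count trios, signature files, results.

Count matrices travel as the Matrix Market trio (``matrix.mtx`` genes ×
barcodes, ``features.tsv``, ``barcodes.tsv``) next to a
``tissue_positions.csv``; both the header-bearing and the 6-column legacy
header-less position dialects are accepted.  In memory counts are a dense
spots × genes :class:`pandas.DataFrame` — sections at desk scale are a few
thousand spots by a few thousand genes.

All readers raise :class:`IOFormatError` on malformed input; there are no
partial silent loads.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from tmeland.config import ConfigError, Signature, SignatureSet
from tmeland.grid import SpotGrid

logger = logging.getLogger("tmeland")

_POSITION_COLUMNS = [
    "barcode",
    "in_tissue",
    "array_row",
    "array_col",
    "pxl_row_in_fullres",
    "pxl_col_in_fullres",
]


class IOFormatError(ValueError):
    """Raised when an on-disk artifact violates its format contract."""


def _dedup_genes(names: list[str]) -> list[str]:
    """Deterministic suffix rule for duplicate gene identifiers: the second
    occurrence of NAME becomes NAME.1, the third NAME.2, and so on."""
    seen: dict[str, int] = {}
    out = []
    for n in names:
        k = seen.get(n, 0)
        out.append(n if k == 0 else f"{n}.{k}")
        seen[n] = k + 1
    return out


def read_counts(path: str | Path, pitch_px: float = 100.0) -> tuple[SpotGrid, pd.DataFrame]:
    """Read a Space Ranger-dialect directory into (SpotGrid, counts).

    Expects ``matrix.mtx``, ``features.tsv``, ``barcodes.tsv`` and
    ``tissue_positions.csv`` (or ``tissue_positions_list.csv``).  The
    returned count matrix is spots × genes, row order aligned with the
    SpotGrid.  An optional ``clusters.csv`` (barcode, cluster) attaches
    cluster labels.
    """
    d = Path(path)
    if not d.is_dir():
        raise IOFormatError(f"not a directory: {d}")
    mtx = d / "matrix.mtx"
    feats = d / "features.tsv"
    bcs = d / "barcodes.tsv"
    for f in (mtx, feats, bcs):
        if not f.exists():
            raise IOFormatError(f"missing required file: {f}")
    pos_file = None
    for cand in ("tissue_positions.csv", "tissue_positions_list.csv"):
        if (d / cand).exists():
            pos_file = d / cand
            break
    if pos_file is None:
        raise IOFormatError(f"missing tissue_positions.csv in {d}")

    m = scipy.io.mmread(mtx)  # genes × barcodes
    m = scipy.sparse.csr_matrix(m)
    features = pd.read_csv(feats, sep="\t", header=None)
    barcodes = pd.read_csv(bcs, sep="\t", header=None)[0].astype(str).tolist()
    gene_ids = _dedup_genes(features[0].astype(str).tolist())
    if m.shape != (len(gene_ids), len(barcodes)):
        raise IOFormatError(
            f"matrix shape {m.shape} does not match {len(gene_ids)} features × "
            f"{len(barcodes)} barcodes"
        )

    positions = _read_positions(pos_file)
    pos_set = set(positions.index)
    bc_set = set(barcodes)
    missing = sorted(bc_set - pos_set)
    if missing:
        raise IOFormatError(
            f"{len(missing)} matrix barcodes absent from tissue positions, "
            f"e.g. {missing[:5]}"
        )
    positions = positions.loc[barcodes]

    counts = pd.DataFrame(
        m.T.toarray(), index=pd.Index(barcodes, name="barcode"), columns=gene_ids
    )
    table = pd.DataFrame(
        {
            "array_row": positions["array_row"].to_numpy(int),
            "array_col": positions["array_col"].to_numpy(int),
            "pixel_x": positions["pxl_col_in_fullres"].to_numpy(float),
            "pixel_y": positions["pxl_row_in_fullres"].to_numpy(float),
            "in_tissue": positions["in_tissue"].to_numpy(int).astype(bool),
        },
        index=counts.index,
    )
    cl_file = d / "clusters.csv"
    if cl_file.exists():
        cl = pd.read_csv(cl_file, index_col=0)
        table["cluster"] = cl.iloc[:, 0].reindex(table.index)
    return SpotGrid(table, pitch_px=pitch_px), counts


def _read_positions(path: Path) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline().strip()
    has_header = "barcode" in first.lower()
    df = pd.read_csv(
        path,
        header=0 if has_header else None,
        names=None if has_header else _POSITION_COLUMNS,
    )
    if has_header:
        df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _POSITION_COLUMNS if c not in df.columns]
    if missing:
        raise IOFormatError(f"tissue positions file missing columns {missing}")
    df = df.set_index(df["barcode"].astype(str)).drop(columns=["barcode"])
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise IOFormatError(f"duplicate barcodes in tissue positions: {dups[:5]}")
    return df


def write_counts(path: str | Path, grid: SpotGrid, counts: pd.DataFrame) -> None:
    """Write the Space Ranger-dialect trio plus tissue_positions.csv."""
    d = Path(path)
    d.mkdir(parents=True, exist_ok=True)
    if not counts.index.equals(grid.spot_ids):
        raise IOFormatError("count matrix rows do not match SpotGrid spot ids")
    mat = scipy.sparse.csc_matrix(counts.to_numpy().T)  # genes × barcodes
    scipy.io.mmwrite(d / "matrix.mtx", mat, field="integer")
    pd.DataFrame(
        {"id": counts.columns, "name": counts.columns, "type": "Gene Expression"}
    ).to_csv(d / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(counts.index).to_csv(d / "barcodes.tsv", sep="\t", header=False, index=False)
    t = grid.table
    pos = pd.DataFrame(
        {
            "barcode": t.index,
            "in_tissue": t["in_tissue"].astype(int).to_numpy(),
            "array_row": t["array_row"].to_numpy(),
            "array_col": t["array_col"].to_numpy(),
            "pxl_row_in_fullres": t["pixel_y"].to_numpy(),
            "pxl_col_in_fullres": t["pixel_x"].to_numpy(),
        }
    )
    pos.to_csv(d / "tissue_positions.csv", index=False)
    if "cluster" in t.columns:
        t[["cluster"]].to_csv(d / "clusters.csv")


def read_signatures(path: str | Path) -> SignatureSet:
    """Read a signature set from JSON or two-column TSV.

    JSON maps signature name to either a gene list or an object with
    ``genes`` / ``category`` / ``tag`` keys.  The TSV dialect has one
    ``signature<TAB>gene`` pair per line.  Genes unknown to any particular
    count matrix are retained here — intersection happens at scoring time.
    """
    p = Path(path)
    if not p.exists():
        raise IOFormatError(f"no such signature file: {p}")
    text = p.read_text()
    if p.suffix.lower() == ".json" or text.lstrip().startswith("{"):
        try:
            d = json.loads(text)
        except json.JSONDecodeError as e:
            raise IOFormatError(f"malformed signature JSON: {e}") from e
        try:
            return SignatureSet.from_dict(d)
        except ConfigError as e:
            raise IOFormatError(str(e)) from e
    # TSV dialect
    sigs: dict[str, list[str]] = {}
    for ln, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise IOFormatError(f"{p}:{ln}: expected 'signature<TAB>gene'")
        sigs.setdefault(parts[0], []).append(parts[1])
    try:
        return SignatureSet(Signature(n, tuple(g), tag=n) for n, g in sigs.items())
    except ConfigError as e:
        raise IOFormatError(str(e)) from e


def write_signatures(path: str | Path, sigs: SignatureSet) -> None:
    Path(path).write_text(json.dumps(sigs.to_dict(), indent=2))


def write_results(tables: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write named result tables as CSV under out_dir; returns paths."""
    d = Path(out_dir)
    d.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in tables.items():
        f = d / f"{name}.csv"
        df.to_csv(f)
        written.append(f)
    return written
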