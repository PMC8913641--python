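"""Reading and writing biomass tables and inferred networks.

The raw input of the whole pipeline is a wide-format delimited table:
taxa in columns, one sampling event per row, biomass in mg/l, with a
few leading metadata columns (sample id, reservoir, date, site and —
optionally — a turbidity reading in NTU and/or a preassigned turbidity
class).  Inferred networks are written as plain-text edge lists,
GraphML or SIF so they can be re-rendered in external graph viewers.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "BiomassMatrix",
    "TurbidityClassSpec",
    "BiomassFormatError",
    "BiomassValidationError",
    "METADATA_COLUMNS",
    "TURBIDITY_CLASSES",
    "read_biomass_table",
    "write_biomass_table",
    "assign_classes",
    "write_network",
    "read_network",
    "NETWORK_FORMATS",
]

#: Leading columns recognised as per-sample metadata; everything else is a taxon.
METADATA_COLUMNS = (
    "sample_id",
    "reservoir",
    "date",
    "site",
    "turbidity_class",
    "turbidity_ntu",
)

TURBIDITY_CLASSES = ("HT", "MT", "LT")


class BiomassFormatError(ValueError):
    """The file does not conform to the wide biomass-table format."""


class BiomassValidationError(ValueError):
    """The table parsed but violates a biomass-matrix invariant."""


@dataclass(frozen=True)
class TurbidityClassSpec:
    """Turbidity class boundaries in Nephelometric Turbidity Units.

    High turbidity (HT) is strictly above ``ht_min``; low turbidity (LT)
    strictly below ``lt_max``; moderate turbidity (MT) is the closed
    interval [``lt_max``, ``ht_min``], so the boundary readings 15 and
    25 NTU both fall in MT.
    """

    lt_max: float = 15.0
    ht_min: float = 25.0

    def __post_init__(self) -> None:
        if not (0 < self.lt_max <= self.ht_min):
            raise ValueError(
                f"class boundaries must satisfy 0 < lt_max <= ht_min, "
                f"got lt_max={self.lt_max}, ht_min={self.ht_min}"
            )

    def classify(self, ntu: float) -> str:
        if ntu < 0 or not np.isfinite(ntu):
            raise ValueError(f"turbidity must be a finite non-negative NTU value, got {ntu}")
        if ntu > self.ht_min:
            return "HT"
        if ntu < self.lt_max:
            return "LT"
        return "MT"


@dataclass
class BiomassMatrix:
    """Samples x taxa biomass table with per-sample metadata.

    ``values`` holds biomass in mg/l (non-negative; NaN = missing),
    indexed by sample id with one column per taxon.  ``samples`` holds
    the metadata, indexed identically.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(index=self.values.index)
        self.validate()

    # -- invariants -------------------------------------------------
    def validate(self) -> None:
        normalized = [" ".join(str(t).split()) for t in self.values.columns]
        if any(not t for t in normalized):
            raise BiomassValidationError("taxon names must be non-empty")
        if len(set(normalized)) != len(normalized):
            dupes = sorted({t for t in normalized if normalized.count(t) > 1})
            raise BiomassValidationError(f"duplicate taxon names after whitespace normalization: {dupes}")
        if not self.values.index.equals(self.samples.index):
            raise BiomassValidationError("values and samples must share the same sample index")
        if not self.values.index.is_unique:
            raise BiomassValidationError("sample_id values must be unique")
        arr = self.values.to_numpy(dtype=float)
        neg = np.argwhere(arr < 0)
        if neg.size:
            cells = [
                f"(sample={self.values.index[i]}, taxon={self.values.columns[j]}, value={arr[i, j]})"
                for i, j in neg[:20]
            ]
            raise BiomassValidationError(f"negative biomass values: {', '.join(cells)}")

    # -- conveniences -----------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset(self, sample_ids: Iterable[str]) -> "BiomassMatrix":
        idx = list(sample_ids)
        return BiomassMatrix(self.values.loc[idx].copy(), self.samples.loc[idx].copy())

    def split_by_class(self) -> dict[str, "BiomassMatrix"]:
        """Partition samples by their turbidity class label."""
        if "turbidity_class" not in self.samples.columns:
            raise BiomassValidationError("samples carry no turbidity_class column; run assign_classes first")
        out: dict[str, BiomassMatrix] = {}
        for cls in TURBIDITY_CLASSES:
            ids = self.samples.index[self.samples["turbidity_class"] == cls]
            if len(ids):
                out[cls] = self.subset(ids)
        return out


# ---------------------------------------------------------------------------
# Biomass table reading / writing
# ---------------------------------------------------------------------------

def read_biomass_table(
    path: str | Path,
    *,
    delimiter: str = ",",
    decimal: str = ".",
) -> BiomassMatrix:
    """Read a wide biomass table.

    The first header row names the columns; columns named in
    :data:`METADATA_COLUMNS` are treated as per-sample metadata and the
    rest as taxa.  Empty cells become missing values (NaN), never zero.
    ``decimal=","`` accepts European decimal-comma numbers.
    """
    import csv

    with open(path, newline="") as fh:
        header = next(csv.reader(fh, delimiter=delimiter))
    header = [" ".join(str(c).split()) for c in header]
    if len(set(header)) != len(header):
        dupes = sorted({c for c in header if header.count(c) > 1})
        raise BiomassFormatError(f"{path}: duplicate taxon names: {dupes}")

    df = pd.read_csv(path, sep=delimiter, dtype=str, keep_default_na=False, skipinitialspace=True)
    df.columns = header

    meta_cols = [c for c in df.columns if c in METADATA_COLUMNS]
    taxa_cols = [c for c in df.columns if c not in METADATA_COLUMNS]
    if not taxa_cols:
        raise BiomassFormatError(f"{path}: no taxon columns found (metadata columns: {meta_cols})")

    if "sample_id" in df.columns:
        index = df["sample_id"].astype(str)
    else:
        index = pd.Index([f"s{i + 1:04d}" for i in range(len(df))], name="sample_id")
    values = pd.DataFrame(index=pd.Index(index, name="sample_id"))

    def _parse(cell: str, row: int, col: str) -> float:
        cell = cell.strip()
        if cell == "" or cell.upper() in {"NA", "NAN"}:
            return np.nan
        txt = cell.replace("−", "-")  # unicode minus
        if decimal == ",":
            txt = txt.replace(",", ".")
        try:
            return float(txt)
        except ValueError:
            raise BiomassFormatError(
                f"{path}: unparseable number {cell!r} at row {row + 2}, column {col!r}"
            ) from None

    for col in taxa_cols:
        values[col] = [_parse(v, i, col) for i, v in enumerate(df[col])]

    meta = pd.DataFrame(index=values.index)
    for col in meta_cols:
        if col == "sample_id":
            continue
        if col == "turbidity_ntu":
            meta[col] = [_parse(v, i, col) for i, v in enumerate(df[col])]
        else:
            meta[col] = [v.strip() if v.strip() else None for v in df[col]]
    return BiomassMatrix(values, meta)


def write_biomass_table(
    m: BiomassMatrix,
    path: str | Path,
    *,
    delimiter: str = ",",
    decimal: str = ".",
) -> None:
    """Write a biomass matrix in the same wide format :func:`read_biomass_table` reads."""
    out = pd.DataFrame(index=m.values.index)
    for col in m.samples.columns:
        out[col] = m.samples[col]
    for col in m.values.columns:
        out[col] = m.values[col]
    out.index.name = "sample_id"
    out.to_csv(path, sep=delimiter, decimal=decimal)


def assign_classes(m: BiomassMatrix, spec: TurbidityClassSpec | None = None) -> BiomassMatrix:
    """Label every sample HT/MT/LT from its NTU reading.

    Samples with a preassigned class keep it; all others must carry a
    ``turbidity_ntu`` value.  Returns a new matrix; the input is untouched.
    """
    spec = spec or TurbidityClassSpec()
    meta = m.samples.copy()
    if "turbidity_class" not in meta.columns:
        meta["turbidity_class"] = None
    classes = []
    for sid, row in meta.iterrows():
        cls = row.get("turbidity_class")
        if cls in TURBIDITY_CLASSES:
            classes.append(cls)
            continue
        ntu = row.get("turbidity_ntu")
        if ntu is None or (isinstance(ntu, float) and np.isnan(ntu)):
            raise BiomassValidationError(
                f"sample {sid!r} has neither a turbidity_ntu value nor a preassigned class"
            )
        classes.append(spec.classify(float(ntu)))
    meta["turbidity_class"] = classes
    return BiomassMatrix(m.values.copy(), meta)


# ---------------------------------------------------------------------------
# Network export / import
# ---------------------------------------------------------------------------

NETWORK_FORMATS = ("edgelist", "graphml", "sif")

_EDGELIST_COLUMNS = ["source", "target", "r", "sign", "weight"]


def write_network(net: nx.Graph, path: str | Path, format: str = "edgelist") -> None:
    """Write a signed correlation network.

    ``edgelist`` is a tab-separated table with columns source, target,
    r, sign, weight; ``graphml`` carries the same edge attributes typed;
    ``sif`` uses the interaction labels ``pos``/``neg``.
    """
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unsupported network format {format!r}; supported: {', '.join(NETWORK_FORMATS)}")
    path = Path(path)
    if fmt == "edgelist":
        rows = [
            {
                "source": u,
                "target": v,
                "r": d.get("r"),
                "sign": d.get("sign"),
                "weight": d.get("weight"),
            }
            for u, v, d in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1])))
        ]
        pd.DataFrame(rows, columns=_EDGELIST_COLUMNS).to_csv(path, sep="\t", index=False)
    elif fmt == "graphml":
        g = nx.Graph()
        g.add_nodes_from((str(n), {k: _graphml_safe(v) for k, v in d.items()}) for n, d in net.nodes(data=True))
        g.add_edges_from(
            (str(u), str(v), {k: _graphml_safe(val) for k, val in d.items()})
            for u, v, d in net.edges(data=True)
        )
        nx.write_graphml(g, path)
    else:  # sif
        lines = []
        for u, v, d in sorted(net.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            label = "pos" if d.get("sign", "+") == "+" else "neg"
            lines.append(f"{u}\t{label}\t{v}")
        for n in sorted(nx.isolates(net)):
            lines.append(str(n))
        path.write_text("\n".join(lines) + ("\n" if lines else ""))


def _graphml_safe(v):
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, np.bool_):
        return bool(v)
    return v


def read_network(path: str | Path, format: str = "edgelist") -> nx.Graph:
    """Read a network written by :func:`write_network`."""
    fmt = format.lower()
    if fmt not in NETWORK_FORMATS:
        raise ValueError(f"unsupported network format {format!r}; supported: {', '.join(NETWORK_FORMATS)}")
    path = Path(path)
    if fmt == "graphml":
        return nx.read_graphml(path)
    g = nx.Graph()
    if fmt == "edgelist":
        df = pd.read_csv(path, sep="\t")
        for _, row in df.iterrows():
            g.add_edge(
                str(row["source"]),
                str(row["target"]),
                r=float(row["r"]),
                sign=str(row["sign"]),
                weight=float(row["weight"]),
            )
        return g
    # sif
    for line in path.read_text().splitlines():
        parts = line.split("\t")
        if len(parts) == 1 and parts[0]:
            g.add_node(parts[0])
        elif len(parts) >= 3:
            u, label, v = parts[0], parts[1], parts[2]
            g.add_edge(u, v, sign="+" if label == "pos" else "-")
    return g
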