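"""Reading and writing signal matrices, networks, and result tables.

Matrices are exchanged as TSV (first row = variable names, first column =
sample/region identifiers); gzip is handled transparently by pandas based on
the file extension. Networks are exchanged as edge-list TSV or GraphML.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALE_TAGS = ("raw", "normalized", "rank")

#: Fixed window length (bp) used to normalize non-mRNA count columns.
DEFAULT_REGION_LENGTH = 4000


@dataclass
class SignalMatrix:
    """A samples x variables real-valued matrix with named axes.

    Parameters
    ----------
    values : ndarray of shape (n_samples, p_variables)
    sample_ids : sequence of row identifiers
    variable_names : sequence of unique column names
    scale_tag : one of ``{"raw", "normalized", "rank"}``
    """

    values: np.ndarray
    sample_ids: list[str]
    variable_names: list[str]
    scale_tag: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.variable_names = [str(v) for v in self.variable_names]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n, p = self.values.shape
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.variable_names) != p:
            raise ValueError(f"{len(self.variable_names)} variable names for {p} columns")
        if len(set(self.variable_names)) != p:
            raise ValueError("variable names must be unique")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("signal matrix contains non-finite values")
        if self.scale_tag not in SCALE_TAGS:
            raise ValueError(f"scale_tag must be one of {SCALE_TAGS}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variable_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.variable_names)


@dataclass(frozen=True)
class RegionAnnotation:
    """Length annotation for one matrix row (genomic region / transcript)."""

    region_id: str
    length_bp: int

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValueError(f"length_bp must be positive, got {self.length_bp}")


def load_signal_matrix(path: str | Path, drop_missing: bool = False) -> SignalMatrix:
    """Load a TSV signal matrix (header row = variable names, col 0 = ids).

    Rows containing missing or non-numeric cells are dropped (and counted in
    the log) when ``drop_missing`` is set; otherwise they are fatal.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        cols = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(cols)) != len(cols):
        dupes = sorted({c for c in cols if cols.count(c) > 1})
        raise ValueError(f"duplicate variable names in header: {dupes}")

    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df = df.apply(pd.to_numeric, errors="coerce")
    bad = df.isna().any(axis=1)
    if bad.any():
        if not drop_missing:
            raise ValueError(
                f"{int(bad.sum())} rows contain missing/non-numeric values "
                "(pass drop_missing=True to drop them)"
            )
        logger.info("dropping %d rows with missing values", int(bad.sum()))
        df = df.loc[~bad]
    sm = SignalMatrix(
        values=df.to_numpy(dtype=float),
        sample_ids=[str(i) for i in df.index],
        variable_names=[str(c) for c in df.columns],
        scale_tag="raw",
    )
    logger.info("loaded %d samples x %d variables from %s", sm.n_samples, sm.n_variables, path)
    return sm


def save_signal_matrix(sm: SignalMatrix, path: str | Path) -> None:
    """Write a signal matrix as TSV; full float precision round-trips."""
    sm.to_frame().to_csv(Path(path), sep="\t", float_format="%.17g")


def normalize_counts(
    raw: SignalMatrix,
    lengths: Sequence[RegionAnnotation] | None = None,
    mrna_columns: Sequence[str] = (),
    region_length: int = DEFAULT_REGION_LENGTH,
) -> SignalMatrix:
    """Convert raw read counts to reads-per-bp.

    Non-mRNA columns are divided by the fixed ``region_length``; columns named
    in ``mrna_columns`` are divided by the per-row transcript length given in
    ``lengths`` (one :class:`RegionAnnotation` per sample row, same order).
    """
    if raw.scale_tag != "raw":
        raise ValueError(f"expected scale_tag 'raw', got '{raw.scale_tag}'")
    mrna_columns = list(mrna_columns)
    unknown = set(mrna_columns) - set(raw.variable_names)
    if unknown:
        raise ValueError(f"mRNA columns not in matrix: {sorted(unknown)}")
    out = raw.values / float(region_length)
    if mrna_columns:
        if lengths is None:
            raise ValueError("per-row lengths are required for mRNA columns")
        if len(lengths) != raw.n_samples:
            raise ValueError(
                f"need one length per sample row: got {len(lengths)} for {raw.n_samples} rows"
            )
        by_id = {ann.region_id: ann.length_bp for ann in lengths}
        missing = [s for s in raw.sample_ids if s not in by_id]
        if missing:
            raise ValueError(f"missing transcript length for rows: {missing[:5]}...")
        lvec = np.array([by_id[s] for s in raw.sample_ids], dtype=float)
        for name in mrna_columns:
            j = raw.variable_names.index(name)
            out[:, j] = raw.values[:, j] / lvec
    return SignalMatrix(out, raw.sample_ids, raw.variable_names, scale_tag="normalized")


# ---------------------------------------------------------------------------
# network exchange


@dataclass
class Network:
    """A lightweight signed weighted undirected network.

    ``edges`` maps a sorted variable-name pair to an attribute dict with keys
    ``weight`` (signed partial correlation), and optionally ``q_value``,
    ``support_count`` and ``provenance``.
    """

    variables: list[str]
    edges: dict[tuple[str, str], dict] = field(default_factory=dict)

    def add_edge(self, a: str, b: str, **attrs) -> None:
        if a == b:
            raise ValueError("self-loops are not allowed")
        self.edges[tuple(sorted((a, b)))] = dict(attrs)


EDGE_COLUMNS = ["var_a", "var_b", "partial_correlation", "q_value", "support_count", "provenance"]


def save_edge_list(net: Network, path: str | Path) -> None:
    rows = []
    for (a, b), attrs in sorted(net.edges.items()):
        rows.append(
            {
                "var_a": a,
                "var_b": b,
                "partial_correlation": attrs.get("weight", np.nan),
                "q_value": attrs.get("q_value", np.nan),
                "support_count": attrs.get("support_count", ""),
                "provenance": attrs.get("provenance", ""),
            }
        )
    pd.DataFrame(rows, columns=EDGE_COLUMNS).to_csv(
        Path(path), sep="\t", index=False, float_format="%.17g"
    )


def load_edge_list(path: str | Path, variables: Sequence[str] | None = None) -> Network:
    df = pd.read_csv(Path(path), sep="\t")
    names = set()
    net = Network(variables=[], edges={})
    for _, row in df.iterrows():
        a, b = str(row["var_a"]), str(row["var_b"])
        names.update((a, b))
        net.add_edge(
            a,
            b,
            weight=float(row["partial_correlation"]),
            q_value=float(row["q_value"]) if pd.notna(row.get("q_value")) else None,
            support_count=int(row["support_count"]) if pd.notna(row.get("support_count")) else None,
            provenance=str(row["provenance"]) if pd.notna(row.get("provenance")) else "",
        )
    net.variables = sorted(names) if variables is None else list(variables)
    return net


def save_graphml(net: Network, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(net.variables)
    for (a, b), attrs in net.edges.items():
        clean = {k: v for k, v in attrs.items() if v is not None}
        g.add_edge(a, b, **clean)
    nx.write_graphml(g, str(path))


def load_network(path: str | Path) -> Network:
    """Load a network from GraphML or edge-list TSV, by extension."""
    path = Path(path)
    if path.suffix.lower() == ".graphml":
        g = nx.read_graphml(str(path))
        net = Network(variables=sorted(g.nodes()), edges={})
        for a, b, attrs in g.edges(data=True):
            net.add_edge(str(a), str(b), **attrs)
        return net
    return load_edge_list(path)
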