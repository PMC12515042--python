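"""Readers and writers for count tables, metadata tables, and networks.

Count tables are taxa x samples matrices of nonnegative integers, exchanged
either as TSV (first column = taxon id, remaining columns = sample ids) or
as BIOM v1 JSON (dense or sparse).  Site and environment tables are TSV with
a header row.  Co-occurrence networks travel as a TSV edge list plus a
sibling ``*_nodes.tsv`` table (so isolated nodes and module labels survive
the round trip) or as GraphML.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Malformed input table or graph file."""


# ---------------------------------------------------------------------------
# count tables


def _validate_count_frame(df: pd.DataFrame, source: str) -> pd.DataFrame:
    if df.index.duplicated().any():
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise FormatError(f"{source}: duplicated taxon ids {dupes}")
    if df.columns.duplicated().any():
        dupes = sorted(df.columns[df.columns.duplicated()].unique())
        raise FormatError(f"{source}: duplicated sample ids {dupes}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() | (numeric < 0) | (numeric % 1 != 0)
        if bad.any():
            taxon = df.index[bad.to_numpy()][0]
            raise FormatError(
                f"{source}: non-count value {df.loc[taxon, col]!r} "
                f"at taxon {taxon!r}, sample {col!r}"
            )
    return df.astype(np.int64)


def read_count_table(path: str | Path, format: str | None = None) -> pd.DataFrame:
    """Read a taxa x samples count table from TSV or BIOM v1 JSON."""
    path = Path(path)
    if format is None:
        format = "biom-json" if path.suffix in {".biom", ".json"} else "tsv"
    if format == "tsv":
        # check the raw header: read_csv silently mangles duplicate columns
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        fields = header.split("\t")[1:]
        dupes = sorted({f for f in fields if fields.count(f) > 1})
        if dupes:
            raise FormatError(f"{path}: duplicated sample ids {dupes}")
        try:
            df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
        except pd.errors.EmptyDataError:
            raise FormatError(f"{path}: empty count table") from None
        if df.shape[1] == 0:
            raise FormatError(f"{path}: count table has no sample columns")
        df.index = df.index.astype(str)
        return _validate_count_frame(df, str(path))
    if format == "biom-json":
        payload = json.loads(path.read_text())
        taxa = [r["id"] for r in payload["rows"]]
        samples = [c["id"] for c in payload["columns"]]
        shape = tuple(payload["shape"])
        mat = np.zeros(shape, dtype=np.int64)
        if payload.get("matrix_type") == "dense":
            mat[:] = np.asarray(payload["data"])
        else:
            for i, j, v in payload["data"]:
                mat[int(i), int(j)] = v
        df = pd.DataFrame(mat, index=pd.Index(taxa, dtype=str), columns=samples)
        return _validate_count_frame(df, str(path))
    raise ValueError(f"unknown count-table format {format!r}")


def write_count_table(
    counts: pd.DataFrame, path: str | Path, format: str | None = None
) -> Path:
    path = Path(path)
    if format is None:
        format = "biom-json" if path.suffix in {".biom", ".json"} else "tsv"
    if format == "tsv":
        counts.to_csv(path, sep="\t", index_label="taxon_id")
    elif format == "biom-json":
        rows, cols = np.nonzero(counts.to_numpy())
        payload = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "cwpsoil",
            "matrix_type": "sparse",
            "matrix_element_type": "int",
            "shape": list(counts.shape),
            "rows": [{"id": str(t), "metadata": None} for t in counts.index],
            "columns": [{"id": str(s), "metadata": None} for s in counts.columns],
            "data": [
                [int(i), int(j), int(counts.iat[i, j])] for i, j in zip(rows, cols)
            ],
        }
        path.write_text(json.dumps(payload))
    else:
        raise ValueError(f"unknown count-table format {format!r}")
    return path


# ---------------------------------------------------------------------------
# site and environment tables


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Site metadata: site_id, cwp_species, latitude, longitude[, ecoregion]."""
    df = pd.read_csv(path, sep="\t", dtype={"site_id": str, "cwp_species": str})
    required = {"site_id", "cwp_species", "latitude", "longitude"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: site table missing columns {sorted(missing)}")
    if df["site_id"].duplicated().any():
        raise FormatError(f"{path}: duplicated site ids")
    if not df["latitude"].between(-90, 90).all():
        raise FormatError(f"{path}: latitude outside [-90, 90]")
    if not df["longitude"].between(-180, 180).all():
        raise FormatError(f"{path}: longitude outside [-180, 180]")
    return df.set_index("site_id")


def write_site_table(sites: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    sites.to_csv(path, sep="\t", index_label="site_id")
    return path


def read_env_table(path: str | Path) -> pd.DataFrame:
    """Per-site numeric edaphoclimatic table; NaN cells allowed pre-imputation."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.duplicated().any():
        raise FormatError(f"{path}: duplicated site ids in environment table")
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        raise FormatError(f"{path}: non-numeric environment columns {non_numeric}")
    return df


def write_env_table(env: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    env.to_csv(path, sep="\t", index_label="site_id")
    return path


# ---------------------------------------------------------------------------
# networks


def _nodes_path(path: Path) -> Path:
    return path.with_name(path.stem + "_nodes.tsv")


def write_network(net, path: str | Path, format: str = "edge-list-tsv") -> Path:
    """Serialize a co-occurrence network (see :mod:`cwpsoil.network`).

    The edge-list format writes the edges to ``path`` and a companion
    ``*_nodes.tsv`` carrying every node with its module label and main-module
    flag, so the pair round-trips losslessly through :func:`read_network`.
    """
    path = Path(path)
    edge_cols = ["taxon_a", "taxon_b", "n_a", "n_b", "j_obs", "p_value"]
    if format == "edge-list-tsv":
        net.edges.loc[:, edge_cols].to_csv(path, sep="\t", index=False)
        nodes = pd.DataFrame(
            {
                "taxon": list(net.nodes),
                "module": [net.membership.get(t) for t in net.nodes],
            }
        )
        nodes["main"] = [
            bool(m is not None and m in net.main_modules) for m in nodes["module"]
        ]
        nodes.to_csv(_nodes_path(path), sep="\t", index=False)
    elif format == "graphml":
        g = nx.Graph(kingdom=net.kingdom or "", modularity=float(net.modularity or 0.0))
        for t in net.nodes:
            m = net.membership.get(t)
            g.add_node(
                str(t),
                module=-1 if m is None else int(m),
                main=bool(m is not None and m in net.main_modules),
            )
        for row in net.edges.itertuples(index=False):
            g.add_edge(
                str(row.taxon_a),
                str(row.taxon_b),
                n_a=int(row.n_a),
                n_b=int(row.n_b),
                j_obs=int(row.j_obs),
                p_value=float(row.p_value),
            )
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return path


def read_network(path: str | Path, format: str = "edge-list-tsv"):
    from .network import CooccurrenceNetwork

    path = Path(path)
    if format == "edge-list-tsv":
        edges = pd.read_csv(
            path, sep="\t", dtype={"taxon_a": str, "taxon_b": str}
        )
        nodes = pd.read_csv(_nodes_path(path), sep="\t", dtype={"taxon": str})
        membership = {}
        main: set[int] = set()
        for row in nodes.itertuples(index=False):
            if pd.notna(row.module):
                membership[row.taxon] = int(row.module)
                if bool(row.main):
                    main.add(int(row.module))
        return CooccurrenceNetwork(
            nodes=list(nodes["taxon"]),
            edges=edges,
            membership=membership,
            main_modules=main,
        )
    if format == "graphml":
        g = nx.read_graphml(path)
        membership = {
            n: int(d["module"]) for n, d in g.nodes(data=True) if int(d["module"]) >= 0
        }
        main = {
            int(d["module"])
            for _, d in g.nodes(data=True)
            if d.get("main") and int(d["module"]) >= 0
        }
        edges = pd.DataFrame(
            [
                {
                    "taxon_a": a,
                    "taxon_b": b,
                    "n_a": int(d["n_a"]),
                    "n_b": int(d["n_b"]),
                    "j_obs": int(d["j_obs"]),
                    "p_value": float(d["p_value"]),
                }
                for a, b, d in g.edges(data=True)
            ],
            columns=["taxon_a", "taxon_b", "n_a", "n_b", "j_obs", "p_value"],
        )
        return CooccurrenceNetwork(
            nodes=list(g.nodes),
            edges=edges,
            membership=membership,
            main_modules=main,
            kingdom=g.graph.get("kingdom") or None,
            modularity=g.graph.get("modularity"),
        )
    raise ValueError(f"unknown network format {format!r}")
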