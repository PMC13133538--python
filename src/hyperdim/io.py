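"""File round-tripping: response tables with metadata, correlation
matrices, specs and network exports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import ItemResponseMatrix


def write_response_csv(
    data: ItemResponseMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    data.values.to_csv(path)
    meta = {
        "category_counts": {str(k): int(v) for k, v in data.category_counts.items()},
    }
    if data.scale_provenance is not None:
        meta["scale_provenance"] = {
            str(k): v for k, v in data.scale_provenance.items()
        }
    Path(metadata_path).write_text(json.dumps(meta, indent=2))


def read_response_csv(path: str | Path, metadata_path: str | Path) -> ItemResponseMatrix:
    """Read a persons x items CSV (header = item ids, blank cells = missing)
    validated against the metadata's category counts."""
    meta = json.loads(Path(metadata_path).read_text())
    counts = pd.Series(meta["category_counts"]).astype(int)
    df = pd.read_csv(path, index_col=0)
    df.columns = df.columns.astype(str)
    extra = [c for c in df.columns if c not in counts.index]
    if extra:
        raise ValueError(f"items missing from metadata: {extra}")
    prov = None
    if "scale_provenance" in meta:
        prov = pd.Series(meta["scale_provenance"]).reindex(df.columns)
    return ItemResponseMatrix(df, counts.loc[df.columns], prov)


def write_correlation_csv(R: pd.DataFrame, path: str | Path) -> None:
    R.to_csv(path)


def read_correlation_csv(path: str | Path) -> pd.DataFrame:
    R = pd.read_csv(path, index_col=0)
    R.columns = R.columns.astype(str)
    R.index = R.index.astype(str)
    if list(R.index) != list(R.columns):
        raise ValueError("correlation CSV must be square with matching labels")
    return R


def write_network(network, edge_csv: str | Path, graphml: str | Path | None = None) -> None:
    network.edge_list.to_csv(edge_csv, index=False)
    if graphml is not None:
        import networkx as nx

        nx.write_graphml(network.to_graph(), graphml)


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Series):
        return o.to_dict()
    if isinstance(o, pd.DataFrame):
        return o.to_dict()
    raise TypeError(f"not JSON serializable: {type(o)}")
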