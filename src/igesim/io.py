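"""Plain-text file formats for the simulation artifacts.

All files are comma-separated with a header row:

pedigree:   animal,sire,dam,role,herd         (0 = unknown parent / no herd)
truth:      animal,a_D,a_I,e_D,e_I            (environmental columns cows only)
edges:      herd,source,target,f_true,f_analysis,directed  (undirected dyads
            written once with source < target)
phenotypes: cow,herd,y                        (readable without the truth files)
ebv:        animal,role,aD_hat,aI_hat
"""

from __future__ import annotations

import pandas as pd

from .network import ContactNetwork

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "write_truth",
    "read_truth",
    "write_edges",
    "read_edges",
    "write_phenotypes",
    "read_phenotypes",
    "write_ebv",
]


def write_pedigree(pedigree: pd.DataFrame, path) -> None:
    pedigree.to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    ped = pd.read_csv(path)
    for col in ("animal", "sire", "dam", "herd"):
        ped[col] = ped[col].astype(int)
    return ped


def write_truth(bvs: pd.DataFrame, env: pd.DataFrame, path) -> None:
    merged = bvs[["animal", "a_D", "a_I"]].merge(
        env[["animal", "e_D", "e_I"]], on="animal", how="left"
    )
    merged.to_csv(path, index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_edges(network: ContactNetwork, path) -> None:
    edges = network.edges.copy()
    if not network.directed:
        lo = edges[["source", "target"]].min(axis=1)
        hi = edges[["source", "target"]].max(axis=1)
        edges["source"], edges["target"] = lo, hi
    edges["directed"] = int(network.directed)
    edges.to_csv(path, index=False)


def read_edges(path, cow_herd: pd.Series | None = None) -> ContactNetwork:
    """Load an edge-list file; ``cow_herd`` (cow id -> herd) covers cows with
    no contacts, otherwise the herd membership is inferred from the edges."""
    edges = pd.read_csv(path)
    directed = bool(edges["directed"].iloc[0]) if len(edges) else False
    edges = edges.drop(columns=["directed"])
    if cow_herd is None:
        both = pd.concat(
            [
                edges[["source", "herd"]].rename(columns={"source": "cow"}),
                edges[["target", "herd"]].rename(columns={"target": "cow"}),
            ]
        ).drop_duplicates("cow")
        cow_herd = pd.Series(
            both["herd"].to_numpy(), index=both["cow"].to_numpy()
        ).sort_index()
    return ContactNetwork(directed=directed, edges=edges, cow_herd=cow_herd)


def write_phenotypes(phenos: pd.DataFrame, path) -> None:
    phenos[["cow", "herd", "y"]].to_csv(path, index=False)


def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ebv(ebv: pd.DataFrame, pedigree: pd.DataFrame, path) -> None:
    out = ebv.merge(pedigree[["animal", "role"]], on="animal", how="left")
    out[["animal", "role", "aD_hat", "aI_hat"]].to_csv(path, index=False)
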