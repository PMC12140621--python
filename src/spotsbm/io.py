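"""Readers and writers for the formats the workflow touches.

Expression: MatrixMarket (.mtx) with barcode/feature TSV companions, or a
dense CSV/TSV (spots x genes, header row, first column = spot id).
Coordinates: the Visium tissue-positions CSV dialect or a generic
(id, x, y) CSV.  Graphs travel as per-layer edge lists (TSV, 0-based node
indices, i < j); labels as (spot_id, label) CSV with 1-based labels.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread

from . import __version__
from .preprocess import ExpressionMatrix, MultiLayerGraph, SpatialCoords
from .sbm import PosteriorSamples
from .simulate import SimulationTruth
from .summaries import ACCSummary

__all__ = [
    "read_expression",
    "read_coords",
    "read_labels",
    "write_labels",
    "write_edge_list",
    "read_edge_list",
    "write_graph",
    "read_graph",
    "write_chains",
    "read_chains",
    "write_summary",
    "write_simulation",
    "write_manifest",
]

_VISIUM_COLS = ["barcode", "in_tissue", "array_row", "array_col", "pxl_row", "pxl_col"]


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read spots x genes expression from .mtx (+ barcodes/features TSV in
    the same directory) or a dense CSV/TSV with an id column."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if path.suffix == ".mtx":
        mat = sp.csr_matrix(mmread(path))
        barcodes = _companion(path, ("barcodes.tsv", "barcodes.txt"))
        features = _companion(path, ("features.tsv", "genes.tsv", "features.txt"))
        spot_ids = barcodes[0].astype(str).tolist()
        gene_ids = features[0].astype(str).tolist()
        counts = np.asarray(mat.todense(), dtype=float)
        if counts.shape == (len(gene_ids), len(spot_ids)) and counts.shape[0] != counts.shape[1]:
            counts = counts.T  # genes x spots orientation, as 10x writes it
        return ExpressionMatrix(counts=counts, spot_ids=spot_ids, gene_ids=gene_ids)
    sep = "\t" if path.suffix in (".tsv", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    return ExpressionMatrix(
        counts=df.to_numpy(dtype=float),
        spot_ids=df.index.astype(str).tolist(),
        gene_ids=df.columns.astype(str).tolist(),
    )


def _companion(mtx_path: Path, names: tuple[str, ...]) -> pd.DataFrame:
    for name in names:
        cand = mtx_path.with_name(name)
        if cand.exists():
            return pd.read_csv(cand, sep="\t", header=None)
    raise FileNotFoundError(
        f"no companion file ({'/'.join(names)}) next to {mtx_path}"
    )


def read_coords(path: str | Path) -> SpatialCoords:
    """Read spatial coordinates from a Visium tissue-positions CSV (pixel
    columns used) or a generic (id, x, y) CSV."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"coordinates file not found: {path}")
    df = pd.read_csv(path)
    if df.shape[1] == 6:
        # historical Visium exports carry no header row
        if not any(c.lower().startswith("barcode") for c in df.columns.astype(str)):
            df = pd.read_csv(path, header=None)
        df.columns = _VISIUM_COLS
        df = df[df["in_tissue"].astype(int) == 1]
        xy = df[["pxl_col", "pxl_row"]].to_numpy(dtype=float)
        return SpatialCoords(xy=xy, spot_ids=df["barcode"].astype(str).tolist())
    if df.shape[1] == 3:
        ids = df.iloc[:, 0].astype(str).tolist()
        return SpatialCoords(xy=df.iloc[:, 1:3].to_numpy(dtype=float), spot_ids=ids)
    raise ValueError(
        f"{path}: expected a 6-column Visium table or 3-column (id, x, y) table, "
        f"got {df.shape[1]} columns"
    )


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"labels file not found: {path}")
    df = pd.read_csv(path)
    ids = df.iloc[:, 0].astype(str).tolist()
    labels = df.iloc[:, 1].to_numpy(dtype=np.int64)
    return ids, labels


def write_labels(path: str | Path, spot_ids: list[str], labels: np.ndarray) -> None:
    """Labels are written 1-based, matching community numbering 1..K."""
    pd.DataFrame({"spot_id": spot_ids, "label": np.asarray(labels, dtype=np.int64)}).to_csv(
        path, index=False
    )


def write_edge_list(path: str | Path, layer: sp.spmatrix, layer_index: int) -> None:
    """One TSV per layer: node_i, node_j, layer with 0-based indices, i < j."""
    coo = sp.coo_matrix(sp.triu(layer, k=1))
    df = pd.DataFrame({"node_i": coo.row, "node_j": coo.col, "layer": layer_index})
    df.sort_values(["node_i", "node_j"]).to_csv(path, sep="\t", index=False)


def read_edge_list(path: str | Path, n_nodes: int) -> sp.csr_matrix:
    """Read one layer; rejects self-loops, duplicates and i >= j rows
    rather than silently repairing them."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"edge list not found: {path}")
    df = pd.read_csv(path, sep="\t")
    i = df["node_i"].to_numpy(dtype=np.int64)
    j = df["node_j"].to_numpy(dtype=np.int64)
    if np.any(i == j):
        bad = int(np.flatnonzero(i == j)[0]) + 2
        raise ValueError(f"{path}: self-loop at line {bad}")
    if np.any(i > j):
        bad = int(np.flatnonzero(i > j)[0]) + 2
        raise ValueError(f"{path}: edge with node_i > node_j at line {bad} "
                         "(edges must be stored once with i < j)")
    if np.any((i < 0) | (j >= n_nodes)):
        raise ValueError(f"{path}: node index outside [0, {n_nodes})")
    if pd.DataFrame({"i": i, "j": j}).duplicated().any():
        raise ValueError(f"{path}: duplicate edges present")
    a = sp.coo_matrix((np.ones(i.size, dtype=np.int8), (i, j)), shape=(n_nodes, n_nodes))
    a = a.tocsr()
    return (a + a.T).astype(np.int8)


def write_graph(outdir: str | Path, graph: MultiLayerGraph) -> list[Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for idx, layer in enumerate(graph.layers, start=1):
        p = outdir / f"layer{idx}_edges.tsv"
        write_edge_list(p, layer, idx)
        paths.append(p)
    with open(outdir / "nodes.json", "w") as fh:
        json.dump({"n_spots": graph.n_spots, "spot_ids": graph.spot_ids}, fh)
    return paths


def read_graph(outdir: str | Path) -> MultiLayerGraph:
    outdir = Path(outdir)
    with open(outdir / "nodes.json") as fh:
        meta = json.load(fh)
    n = meta["n_spots"]
    layers = []
    idx = 1
    while (outdir / f"layer{idx}_edges.tsv").exists():
        layers.append(read_edge_list(outdir / f"layer{idx}_edges.tsv", n))
        idx += 1
    if not layers:
        raise FileNotFoundError(f"no layer*_edges.tsv files in {outdir}")
    return MultiLayerGraph(layers=layers, spot_ids=[str(s) for s in meta["spot_ids"]])


def write_chains(path: str | Path, samples: PosteriorSamples, config: dict | None = None) -> None:
    """Compressed columnar chain export plus a JSON config sidecar."""
    path = Path(path)
    np.savez_compressed(
        path,
        z_chain=samples.z_chain.astype(np.int16),
        pi_chain=samples.pi_chain,
        theta_chain=samples.theta_chain,
        log_post=samples.log_post,
        log_post_full=samples.log_post_full,
    )
    sidecar = {
        "K": samples.K,
        "burn": samples.burn,
        "seed": samples.seed,
        "n_stored": samples.n_stored,
        "version": __version__,
    }
    sidecar.update(config or {})
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_chains(path: str | Path) -> PosteriorSamples:
    path = Path(path)
    data = np.load(path if path.suffix == ".npz" else path.with_suffix(".npz"))
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return PosteriorSamples(
        z_chain=data["z_chain"], pi_chain=data["pi_chain"],
        theta_chain=data["theta_chain"], log_post=data["log_post"],
        burn=meta["burn"], seed=meta["seed"], K=meta["K"],
        log_post_full=data["log_post_full"],
    )


def write_summary(path: str | Path, summary: ACCSummary) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(summary.to_dict(), fh, indent=2)
    summary.to_frame().to_csv(path.with_suffix(".csv"), index=False)


def write_simulation(outdir: str | Path, truth: SimulationTruth) -> None:
    """Round-trippable export: coordinates, true labels, Theta, edge lists
    and a config JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ids = truth.coords.spot_ids
    pd.DataFrame(
        {"spot_id": ids, "x": truth.coords.xy[:, 0], "y": truth.coords.xy[:, 1]}
    ).to_csv(outdir / "coords.csv", index=False)
    write_labels(outdir / "true_labels.csv", ids, truth.z_true)
    pd.DataFrame(truth.theta_true).to_csv(outdir / "theta_true.csv", index=False, header=False)
    write_graph(outdir, truth.graph)
    with open(outdir / "config.json", "w") as fh:
        json.dump(
            {
                "setting": truth.setting_id,
                "seed": truth.seed,
                "n_spots": truth.coords.n_spots,
                "R": truth.R,
                "params": {str(k): v for k, v in truth.params.items()},
                "version": __version__,
            },
            fh,
            indent=2,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(outdir: str | Path, config: dict, artifacts: list[Path]) -> Path:
    """Run manifest: configuration, package version and content hashes of
    every written artifact, enabling bit-exact re-runs."""
    outdir = Path(outdir)
    manifest = {
        "config": config,
        "version": __version__,
        "artifacts": {str(p.name): _sha256(Path(p)) for p in artifacts if Path(p).exists()},
    }
    path = outdir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path
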