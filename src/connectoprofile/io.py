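"""Reading, validation and export of connectomes, node tables and cohorts.

A connectome is stored as an N x N delimited text matrix with no header;
edge weights are non-negative reals (typically SIFT2-filtered streamline
counts). Region metadata (label, hemisphere, centroid coordinates in mm)
lives in a separate node-table CSV. A cohort manifest (YAML or JSON) ties
together one patient matrix, the control matrices and optional per-subject
total intracranial volumes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import CohortError, DimensionError, FormatError, SymmetryError

#: relative tolerance below which asymmetry is treated as round-off and averaged away
SYMMETRY_RTOL = 1e-6

VALID_HEMISPHERES = {"left", "right", "midline"}

NODE_TABLE_COLUMNS = ["index", "label", "hemisphere", "x", "y", "z"]


@dataclass
class NodeTable:
    """Region metadata: labels, hemispheres and centroid coordinates (mm)."""

    labels: list[str]
    hemispheres: list[str]
    coords: np.ndarray  # (N, 3), mm

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.labels)
        if self.coords.shape != (n, 3):
            raise FormatError(
                f"coordinate array has shape {self.coords.shape}, expected ({n}, 3)"
            )
        if len(self.hemispheres) != n:
            raise FormatError("hemisphere column length does not match labels")
        if len(set(self.labels)) != n:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate node labels: {dupes}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("node coordinates must be finite (no missing values)")
        bad = set(self.hemispheres) - VALID_HEMISPHERES
        if bad:
            raise ValueError(f"unknown hemisphere values: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @property
    def n_nodes(self) -> int:
        return len(self.labels)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(len(self.labels)),
                "label": self.labels,
                "hemisphere": self.hemispheres,
                "x": self.coords[:, 0],
                "y": self.coords[:, 1],
                "z": self.coords[:, 2],
            }
        )


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric weighted adjacency matrix.

    ``weights[i, j]`` is the connection weight between regions i and j
    (zero means no edge); the diagonal is zero. ``icv`` is the subject's
    total intracranial volume in mm^3, if known.
    """

    weights: np.ndarray
    subject_id: str = ""
    icv: float | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        w = self.weights
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise FormatError(f"connectivity matrix must be square, got shape {w.shape}")
        if not np.all(np.isfinite(w)):
            raise ValueError("connectivity matrix contains non-finite entries")
        if np.any(w < 0):
            raise ValueError("connectivity matrix contains negative weights")
        if not np.array_equal(w, w.T):
            raise SymmetryError("connectivity matrix is not exactly symmetric after ingestion")
        if np.any(np.diag(w) != 0):
            raise ValueError("connectivity matrix diagonal must be zero")
        if self.icv is not None and not self.icv > 0:
            raise ValueError("icv must be positive (mm^3)")

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class Cohort:
    """A patient plus the healthy-control reference group."""

    controls: list[ConnectivityMatrix]
    patient: ConnectivityMatrix
    node_table: NodeTable
    name: str = "cohort"

    def __post_init__(self) -> None:
        if len(self.controls) < 2:
            raise CohortError(
                f"need at least 2 controls for an edgewise SD, got {len(self.controls)}"
            )
        n = self.node_table.n_nodes
        for m in [self.patient, *self.controls]:
            if m.n_nodes != n:
                raise DimensionError(
                    f"subject '{m.subject_id}' has {m.n_nodes} nodes, node table has {n}"
                )
        control_ids = [c.subject_id for c in self.controls]
        if len(set(control_ids)) != len(control_ids):
            raise CohortError("control subject ids are not unique")
        if self.patient.subject_id in control_ids:
            raise CohortError(
                f"patient id '{self.patient.subject_id}' also appears among controls"
            )

    @property
    def n_nodes(self) -> int:
        return self.node_table.n_nodes

    @property
    def n_controls(self) -> int:
        return len(self.controls)


def _sniff_delimiter(path: Path) -> str | None:
    """Guess comma vs tab vs whitespace from the first non-empty line."""
    with open(path) as fh:
        for line in fh:
            if line.strip():
                if "," in line:
                    return ","
                if "\t" in line:
                    return "\t"
                return None  # np.loadtxt default: any whitespace
    raise FormatError(f"{path}: file is empty")


def read_matrix(
    path: str | Path,
    delimiter: str = "auto",
    subject_id: str | None = None,
    icv: float | None = None,
) -> ConnectivityMatrix:
    """Read a square weighted connectivity matrix from delimited text.

    The matrix is validated (square, finite, non-negative), its diagonal is
    forced to zero, and numerical asymmetry up to ``max|A - A.T| / max(A) <=
    1e-6`` is repaired by averaging ``(A + A.T) / 2``; larger asymmetry
    raises :class:`~connectoprofile.errors.SymmetryError`. Fully
    disconnected nodes (zero rows) are accepted with a warning since
    anatomically disconnected regions legitimately stay in the matrix.
    """
    path = Path(path)
    delim = _sniff_delimiter(path) if delimiter == "auto" else delimiter
    try:
        arr = np.loadtxt(path, delimiter=delim, ndmin=2)
    except ValueError as exc:
        raise FormatError(f"{path}: could not parse numeric matrix ({exc})") from exc
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise FormatError(f"{path}: matrix must be square, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{path}: matrix contains non-finite entries")
    if np.any(arr < 0):
        raise ValueError(f"{path}: matrix contains negative weights")
    asym = np.max(np.abs(arr - arr.T))
    scale = arr.max()
    if asym > 0:
        if scale == 0 or asym / scale > SYMMETRY_RTOL:
            raise SymmetryError(
                f"{path}: asymmetry {asym:.3g} exceeds relative tolerance {SYMMETRY_RTOL}"
            )
        arr = (arr + arr.T) / 2.0
    np.fill_diagonal(arr, 0.0)
    strengths = arr.sum(axis=1)
    if np.any(strengths == 0):
        warnings.warn(
            f"{path}: {int(np.sum(strengths == 0))} fully disconnected node(s)",
            stacklevel=2,
        )
    return ConnectivityMatrix(
        weights=arr,
        subject_id=subject_id if subject_id is not None else path.stem,
        icv=icv,
    )


def write_matrix(m: ConnectivityMatrix, path: str | Path, delimiter: str = ",") -> None:
    """Write a connectivity matrix as delimited text at 12 significant digits."""
    np.savetxt(path, m.weights, delimiter=delimiter, fmt="%.12g")


def read_node_table(path: str | Path) -> NodeTable:
    """Read a node table CSV with header ``index,label,hemisphere,x,y,z``.

    Indices must be contiguous 0..N-1, labels unique, coordinates complete
    (navigation efficiency needs centroid geometry for every region).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in NODE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: node table missing columns {missing}")
    df = df.sort_values("index").reset_index(drop=True)
    if not np.array_equal(df["index"].to_numpy(), np.arange(len(df))):
        raise ValueError(f"{path}: node indices must be contiguous 0..N-1")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float)
    if np.any(~np.isfinite(coords)):
        raise ValueError(f"{path}: node table has missing/non-finite coordinates")
    return NodeTable(
        labels=[str(l) for l in df["label"]],
        hemispheres=[str(h) for h in df["hemisphere"]],
        coords=coords,
    )


def write_node_table(nodes: NodeTable, path: str | Path) -> None:
    nodes.to_dataframe().to_csv(path, index=False)


def load_cohort(manifest: str | Path) -> Cohort:
    """Load a cohort from a YAML/JSON manifest.

    Manifest keys: ``node_table`` (path), ``controls`` (list of paths),
    ``patient`` (path), optional ``icv`` ({subject_id: mm^3}). Relative
    paths resolve against the manifest's directory.
    """
    manifest = Path(manifest)
    with open(manifest) as fh:
        spec = yaml.safe_load(fh)
    if not isinstance(spec, dict):
        raise FormatError(f"{manifest}: manifest must be a mapping")
    for key in ("node_table", "controls", "patient"):
        if key not in spec:
            raise FormatError(f"{manifest}: manifest missing key '{key}'")
    base = manifest.parent
    icv_map = spec.get("icv") or {}

    def _resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    nodes = read_node_table(_resolve(spec["node_table"]))
    controls = []
    for p in spec["controls"]:
        path = _resolve(p)
        controls.append(read_matrix(path, icv=icv_map.get(path.stem)))
    if len(controls) < 2:
        raise CohortError(f"{manifest}: need at least 2 control matrices")
    patient_path = _resolve(spec["patient"])
    patient = read_matrix(patient_path, icv=icv_map.get(patient_path.stem))
    return Cohort(
        controls=controls,
        patient=patient,
        node_table=nodes,
        name=spec.get("name", manifest.stem),
    )


def write_manifest(
    path: str | Path,
    node_table: str,
    controls: list[str],
    patient: str,
    icv: dict[str, float] | None = None,
    name: str | None = None,
) -> None:
    spec: dict = {"node_table": node_table, "controls": controls, "patient": patient}
    if icv:
        spec["icv"] = {k: float(v) for k, v in icv.items()}
    if name:
        spec["name"] = name
    with open(path, "w") as fh:
        yaml.safe_dump(spec, fh, sort_keys=False)


def export_edge_csv(
    path: str | Path,
    nodes: NodeTable,
    weights: np.ndarray,
    z: np.ndarray,
    p: np.ndarray,
    q: np.ndarray,
    significant: np.ndarray,
) -> None:
    """Write the upper-triangle edge list with deviation statistics.

    Columns: node_i_label, node_j_label, weight, z, p, q, significant.
    NaN z/p/q marks edges excluded from testing (zero control variance).
    """
    iu, ju = np.triu_indices(len(nodes), k=1)
    df = pd.DataFrame(
        {
            "node_i_label": [nodes.labels[i] for i in iu],
            "node_j_label": [nodes.labels[j] for j in ju],
            "weight": weights[iu, ju],
            "z": z[iu, ju],
            "p": p[iu, ju],
            "q": q[iu, ju],
            "significant": significant[iu, ju],
        }
    )
    df.to_csv(path, index=False, float_format="%.12g")


def export_node_csv(
    path: str | Path,
    nodes: NodeTable,
    strength: np.ndarray,
    strength_z: np.ndarray,
    betweenness: np.ndarray,
    is_hub: np.ndarray,
) -> None:
    """Write the per-node table: strength, strength z, betweenness, hub flag."""
    pd.DataFrame(
        {
            "label": nodes.labels,
            "strength": strength,
            "strength_z": strength_z,
            "betweenness": betweenness,
            "is_hub": is_hub,
        }
    ).to_csv(path, index=False, float_format="%.12g")


def write_json(path: str | Path, payload: dict) -> None:
    """Deterministic JSON export (sorted keys, repr-stable floats)."""
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
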