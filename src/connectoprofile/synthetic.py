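"""Synthetic connectome cohorts with known ground truth.

Real structural connectomes are streamline-count matrices over atlas
regions; their dominant statistical features, for the purposes of this
package, are (a) edge weights that decay with inter-regional distance,
(b) right-skewed positive weights, (c) multiplicative between-subject
variability with a roughly constant coefficient of variation, and (d)
bilateral mirror symmetry of the region geometry. The generator emulates
exactly these: node centroids sampled in a brain-sized ellipsoid with
left/right mirror pairs, a distance-decay weight template thresholded to
a target density, per-subject lognormal multiplicative noise, and focal
"lesions" that attenuate (or sever) every edge incident to chosen nodes,
returning the altered-edge mask as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigError
from .io import (
    ConnectivityMatrix,
    NodeTable,
    write_json,
    write_manifest,
    write_matrix,
    write_node_table,
)

#: brain-sized ellipsoid semi-axes (x = left-right, y = ant-post, z = inf-sup), mm
ELLIPSOID_SEMI_AXES = (65.0, 85.0, 60.0)


@dataclass
class SyntheticConfig:
    """Generator settings for one synthetic cohort.

    Defaults emulate the study conditions of a single-patient normative
    comparison: 84 atlas regions, 12 healthy controls, multiplicative
    subject noise with CV 0.15. ``base_weight`` sets the streamline-count
    scale of the strongest (shortest) connections and ``decay_scale`` the
    exponential distance decay of edge weight; ``density`` is the
    fraction of node pairs kept as edges (strongest retained).
    """

    n_nodes: int = 84
    n_controls: int = 12
    base_weight: float = 2000.0
    decay_scale: float = 35.0
    density: float = 0.6
    subject_noise_cv: float = 0.15
    icv_mean: float = 1.5e6  # mm^3
    icv_cv: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ConfigError("need at least 3 nodes")
        if not 0 < self.density <= 1:
            raise ConfigError("density must be in (0, 1]")
        if self.subject_noise_cv < 0:
            raise ConfigError("subject_noise_cv must be non-negative")
        if self.base_weight <= 0 or self.decay_scale <= 0:
            raise ConfigError("base_weight and decay_scale must be positive")


@dataclass
class LesionSpec:
    """Edges incident to ``target_nodes`` are multiplied by ``attenuation``
    (or zeroed when ``severed``)."""

    target_nodes: list[int]
    attenuation: float = 0.3
    severed: bool = False

    def __post_init__(self) -> None:
        if not self.target_nodes:
            raise ValueError("lesion needs at least one target node")
        if not 0 <= self.attenuation <= 1:
            raise ValueError("attenuation must lie in [0, 1]")


def _sample_geometry(cfg: SyntheticConfig, rng: np.random.Generator) -> NodeTable:
    """Mirror-symmetric node centroids inside a brain-sized ellipsoid."""
    n_pairs, odd = divmod(cfg.n_nodes, 2)
    a, b, c = ELLIPSOID_SEMI_AXES
    pts = []
    while len(pts) < n_pairs:
        cand = rng.uniform(-1, 1, size=3)
        # keep right-hemisphere half (x > 0.08 leaves a midline gap)
        if cand[0] > 0.08 and (cand**2).sum() <= 1.0:
            pts.append(cand * [a, b, c])
    right = np.array(pts)
    left = right * [-1, 1, 1]
    coords = [left, right]
    hemis = ["left"] * n_pairs + ["right"] * n_pairs
    labels = [f"region{k:02d}_L" for k in range(n_pairs)] + [
        f"region{k:02d}_R" for k in range(n_pairs)
    ]
    if odd:
        mid = rng.uniform(-1, 1, size=3) * [0.0, b, c]
        coords.append(mid[None, :])
        hemis.append("midline")
        labels.append("region_mid")
    return NodeTable(labels=labels, hemispheres=hemis, coords=np.vstack(coords))


def generate_template(cfg: SyntheticConfig) -> tuple[ConnectivityMatrix, NodeTable]:
    """Distance-decay weight template thresholded to the target density.

    w_ij = base_weight * exp(-d_ij / decay_scale) for the retained
    (strongest, i.e. shortest-distance) fraction of node pairs; fully
    deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    nodes = _sample_geometry(cfg, rng)
    diff = nodes.coords[:, None, :] - nodes.coords[None, :, :]
    dist = np.sqrt((diff**2).sum(axis=-1))
    w = cfg.base_weight * np.exp(-dist / cfg.decay_scale)
    np.fill_diagonal(w, 0.0)
    n = cfg.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = iu.size
    n_keep = int(round(cfg.density * n_pairs))
    if n_keep < 1:
        raise ConfigError("density too low: no edges retained")
    vals = w[iu, ju]
    keep = np.argsort(vals)[::-1][:n_keep]
    out = np.zeros_like(w)
    out[iu[keep], ju[keep]] = vals[keep]
    out = out + out.T
    return ConnectivityMatrix(weights=out, subject_id="template"), nodes


def _noisy_copy(
    template: np.ndarray, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Template with symmetric per-edge lognormal noise (median 1, given CV)."""
    n = template.shape[0]
    if cv == 0:
        return template.copy()
    sigma = np.sqrt(np.log1p(cv**2))
    iu, ju = np.triu_indices(n, k=1)
    noise = np.ones((n, n))
    factors = rng.lognormal(mean=0.0, sigma=sigma, size=iu.size)
    noise[iu, ju] = factors
    noise[ju, iu] = factors
    return template * noise


def generate_cohort(
    template: ConnectivityMatrix,
    cfg: SyntheticConfig,
    rng: np.random.Generator | None = None,
    n_subjects: int | None = None,
    id_prefix: str = "control",
) -> list[ConnectivityMatrix]:
    """Independent noisy realisations of the template, with sampled ICVs."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    n_subjects = n_subjects if n_subjects is not None else cfg.n_controls
    out = []
    for k in range(n_subjects):
        w = _noisy_copy(template.weights, cfg.subject_noise_cv, rng)
        icv = float(rng.normal(cfg.icv_mean, cfg.icv_cv * cfg.icv_mean))
        out.append(
            ConnectivityMatrix(weights=w, subject_id=f"{id_prefix}{k:02d}", icv=max(icv, 1.0))
        )
    return out


def inject_lesion(
    subject: ConnectivityMatrix, spec: LesionSpec
) -> tuple[ConnectivityMatrix, np.ndarray]:
    """Attenuate (or sever) all edges incident to the target nodes.

    Returns the lesioned matrix and a boolean mask marking exactly the
    edges that actually changed (nonzero weight incident to a target);
    the mask is the ground truth for deviation-recovery experiments.
    """
    n = subject.n_nodes
    targets = np.asarray(spec.target_nodes, dtype=int)
    if np.any(targets < 0) or np.any(targets >= n):
        raise ValueError("lesion target node out of range")
    factor = 0.0 if spec.severed else spec.attenuation
    w = subject.weights.copy()
    incident = np.zeros((n, n), dtype=bool)
    incident[targets, :] = True
    incident[:, targets] = True
    np.fill_diagonal(incident, False)
    mask = incident & (w > 0) & (factor != 1.0)
    w[incident] *= factor
    return (
        ConnectivityMatrix(weights=w, subject_id=subject.subject_id + "_lesioned",
                           icv=subject.icv),
        mask,
    )


def generate_study(
    cfg: SyntheticConfig,
    lesion: LesionSpec | None = None,
) -> dict:
    """One full in-memory study: controls, patient, node table, ground truth.

    The patient is an extra draw from the control-generating distribution;
    if ``lesion`` is given it is applied to that draw and the altered-edge
    mask is returned under ``"lesion_mask"``.
    """
    template, nodes = generate_template(cfg)
    rng = np.random.default_rng(cfg.seed + 1)
    controls = generate_cohort(template, cfg, rng=rng)
    patient = generate_cohort(template, cfg, rng=rng, n_subjects=1, id_prefix="patient")[0]
    patient.subject_id = "patient"
    mask = np.zeros((cfg.n_nodes, cfg.n_nodes), dtype=bool)
    if lesion is not None:
        patient, mask = inject_lesion(patient, lesion)
        patient.subject_id = "patient"
    return {
        "template": template,
        "nodes": nodes,
        "controls": controls,
        "patient": patient,
        "lesion_mask": mask,
        "config": cfg,
        "lesion": lesion,
    }


def write_study(study: dict, outdir: str | Path) -> Path:
    """Write a ready-to-run dataset: matrices, node table, manifest, truth.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    nodes: NodeTable = study["nodes"]
    write_node_table(nodes, outdir / "nodes.csv")
    icv = {}
    control_files = []
    for c in study["controls"]:
        fname = f"{c.subject_id}.csv"
        write_matrix(c, outdir / fname)
        control_files.append(fname)
        if c.icv is not None:
            icv[c.subject_id] = c.icv
    patient = study["patient"]
    write_matrix(patient, outdir / "patient.csv")
    if patient.icv is not None:
        icv["patient"] = patient.icv
    manifest = outdir / "cohort.yaml"
    write_manifest(
        manifest,
        node_table="nodes.csv",
        controls=control_files,
        patient="patient.csv",
        icv=icv,
        name="synthetic",
    )
    mask = study["lesion_mask"]
    iu, ju = np.triu_indices(mask.shape[0], k=1)
    truth = {
        "lesioned_edges": [
            [int(i), int(j)] for i, j in zip(iu[mask[iu, ju]], ju[mask[iu, ju]])
        ],
        "target_nodes": list(map(int, study["lesion"].target_nodes))
        if study["lesion"]
        else [],
        "seed": study["config"].seed,
    }
    write_json(outdir / "ground_truth.json", truth)
    return manifest


def preset_config(name: str, seed: int = 0) -> SyntheticConfig:
    """Named presets: ``default84`` (study-scale) and ``tiny10`` (test-scale)."""
    if name == "default84":
        return SyntheticConfig(seed=seed)
    if name == "tiny10":
        return SyntheticConfig(n_nodes=10, n_controls=6, density=0.8, seed=seed)
    raise ConfigError(f"unknown preset '{name}'")
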