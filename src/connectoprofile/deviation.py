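"""Regional deviation mapping: edge/node z-scores, FDR, hubs.

Each patient edge weight T_ij is converted to a z-score against the
control cohort, z_ij = (T_ij - mu_ij) / sigma_ij, with mu/sigma the
per-edge control mean and sample SD. Two-sided p-values use the standard
normal reference; Benjamini-Hochberg FDR is applied over the unique
(upper-triangle) edges with nonzero control variance. Node strengths are
z-scored the same way. Negative z means the connection is weaker in the
patient than in controls, positive means stronger. Hubs are the top
fraction (default 10%) of nodes by betweenness centrality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special
from statsmodels.stats.multitest import multipletests

from .errors import CohortError, DimensionError
from .io import ConnectivityMatrix
from .metrics import node_strengths

SIGN_WEAKER = "weaker"
SIGN_STRONGER = "stronger"


@dataclass
class CohortEdgeStats:
    """Per-edge control mean and sample SD (ddof=1)."""

    mu: np.ndarray
    sigma: np.ndarray
    n_controls: int


@dataclass
class HubSet:
    """The top-fraction betweenness nodes with their centrality values."""

    hubs: list[tuple[int, float]]
    fraction: float = 0.10

    @property
    def indices(self) -> set[int]:
        return {i for i, _ in self.hubs}


@dataclass
class DeviationResult:
    """Edge and node deviation maps for one patient."""

    z_edges: np.ndarray
    p_edges: np.ndarray
    q_edges: np.ndarray
    significant_edges: list[tuple[int, int, float, float, float, str]]
    excluded_edges: list[tuple[int, int, str]]
    z_nodes: np.ndarray
    p_nodes: np.ndarray
    q_nodes: np.ndarray
    significant_nodes: list[tuple[int, float, float, float, str]]
    excluded_nodes: list[tuple[int, str]]
    n_edges_tested: int = 0
    fdr_q: float = 0.05

    @property
    def n_significant_weaker(self) -> int:
        return sum(1 for e in self.significant_edges if e[5] == SIGN_WEAKER)

    @property
    def n_significant_stronger(self) -> int:
        return sum(1 for e in self.significant_edges if e[5] == SIGN_STRONGER)


def cohort_edge_stats(controls: list[ConnectivityMatrix]) -> CohortEdgeStats:
    """Per-edge sample mean and SD across the control cohort."""
    if len(controls) < 2:
        raise CohortError("edgewise SD needs at least 2 controls")
    n = controls[0].n_nodes
    for c in controls:
        if c.n_nodes != n:
            raise DimensionError("control matrices differ in dimension")
    stack = np.stack([c.weights for c in controls])
    return CohortEdgeStats(
        mu=stack.mean(axis=0),
        sigma=stack.std(axis=0, ddof=1),
        n_controls=len(controls),
    )


def edge_z_matrix(
    patient: ConnectivityMatrix, stats: CohortEdgeStats
) -> tuple[np.ndarray, list[tuple[int, int, str]]]:
    """z_ij = (T_ij - mu_ij) / sigma_ij; zero-variance edges handled separately.

    Where sigma_ij = 0 and the patient matches the control mean, z = 0;
    where sigma_ij = 0 but the patient differs, the edge carries no
    parametric information and is excluded (z = NaN, reason
    "zero-variance"). Returns the symmetric z matrix and the excluded
    upper-triangle edge list.
    """
    t = patient.weights
    if t.shape != stats.mu.shape:
        raise DimensionError(
            f"patient matrix {t.shape} does not match cohort stats {stats.mu.shape}"
        )
    mu, sigma = stats.mu, stats.sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma > 0, (t - mu) / np.where(sigma > 0, sigma, 1.0), 0.0)
    degenerate = (sigma == 0) & (t != mu)
    z[degenerate] = np.nan
    np.fill_diagonal(z, 0.0)
    iu, ju = np.triu_indices(t.shape[0], k=1)
    excl = degenerate[iu, ju]
    excluded = [
        (int(i), int(j), "zero-variance") for i, j in zip(iu[excl], ju[excl])
    ]
    return z, excluded


def z_to_p_two_sided(z: float | np.ndarray) -> float | np.ndarray:
    """Two-sided standard-normal p-value, p = 2 Phi(-|z|).

    Computed through the complementary error function so the far tail is
    accurate (no catastrophic 1 - CDF cancellation); e.g. z = -3.41 gives
    p = 6.50e-04 and z = -9.62 gives p ~ 6.6e-22.
    """
    z = np.asarray(z, dtype=float)
    p = special.erfc(np.abs(z) / np.sqrt(2.0))
    return float(p) if p.ndim == 0 else p


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up over one test family.

    Returns (adjusted q-values, rejection mask). Adjusted values follow
    the usual monotone definition q_(k) = min_{j>=k} m p_(j) / j capped
    at 1; rejections are all p_(k) with p_(k) <= k q / m for the largest
    such k.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    reject, q_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return q_adj, reject


def node_strength_z(
    patient: ConnectivityMatrix,
    controls: list[ConnectivityMatrix],
    fdr_q: float = 0.05,
    correct: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list, list]:
    """Per-node strength z-scores with (optional) BH-FDR over the node family.

    Returns (z, p, q, significant, excluded): ``significant`` lists
    (index, z, p, q, sign) tuples, ``excluded`` lists (index, reason) for
    zero-variance nodes.
    """
    if len(controls) < 2:
        raise CohortError("node z needs at least 2 controls")
    s_pat = node_strengths(patient.weights)
    s_ctl = np.stack([node_strengths(c.weights) for c in controls])
    mu = s_ctl.mean(axis=0)
    sd = s_ctl.std(axis=0, ddof=1)
    n = s_pat.size
    z = np.full(n, np.nan)
    ok = sd > 0
    z[ok] = (s_pat[ok] - mu[ok]) / sd[ok]
    z[(~ok) & (s_pat == mu)] = 0.0
    excluded = [(int(i), "zero-variance") for i in np.nonzero(np.isnan(z))[0]]
    tested = np.nonzero(~np.isnan(z))[0]
    p = np.full(n, np.nan)
    qv = np.full(n, np.nan)
    rejected = np.zeros(n, dtype=bool)
    if tested.size:
        p[tested] = z_to_p_two_sided(z[tested])
        if correct:
            q_adj, rej = bh_fdr(p[tested], q=fdr_q)
            qv[tested] = q_adj
            rejected[tested] = rej
        else:
            qv[tested] = p[tested]
            rejected[tested] = p[tested] <= fdr_q
    significant = [
        (int(i), float(z[i]), float(p[i]), float(qv[i]),
         SIGN_WEAKER if z[i] < 0 else SIGN_STRONGER)
        for i in np.nonzero(rejected)[0]
    ]
    return z, p, qv, significant, excluded


def detect_hubs(
    bc: np.ndarray,
    fraction: float = 0.10,
    strengths: np.ndarray | None = None,
) -> HubSet:
    """Top-fraction betweenness nodes; k = round-half-up(fraction * N).

    On 84 nodes the default 10% rule selects 8 hubs. Ties at the
    threshold are broken by higher strength (when given), then lower node
    index, so the selection is deterministic.
    """
    bc = np.asarray(bc, dtype=float)
    n = bc.size
    k = min(int(np.floor(fraction * n + 0.5)), n)
    if k <= 0:
        return HubSet(hubs=[], fraction=fraction)
    s = np.asarray(strengths, dtype=float) if strengths is not None else np.zeros(n)
    order = sorted(range(n), key=lambda i: (-bc[i], -s[i], i))
    chosen = order[:k]
    return HubSet(hubs=[(int(i), float(bc[i])) for i in chosen], fraction=fraction)


def hub_alterations(patient_hubs: HubSet, reference_hubs: HubSet) -> dict[str, list[int]]:
    """Hubs gained (patient-only) and lost (reference-only)."""
    pat = patient_hubs.indices
    ref = reference_hubs.indices
    return {"gained": sorted(pat - ref), "lost": sorted(ref - pat)}


def compute_deviation(
    patient: ConnectivityMatrix,
    controls: list[ConnectivityMatrix],
    fdr_q: float = 0.05,
    correct_nodes: bool = True,
) -> DeviationResult:
    """Full edge + node deviation analysis for one patient.

    The edge test family is the upper-triangle off-diagonal edges with
    nonzero control variance; BH-FDR runs once over that family.
    """
    stats = cohort_edge_stats(controls)
    z, excluded_edges = edge_z_matrix(patient, stats)
    n = z.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    zu = z[iu, ju]
    tested = ~np.isnan(zu)
    p_edges = np.full_like(z, np.nan)
    q_edges = np.full_like(z, np.nan)
    rej_mat = np.zeros_like(z, dtype=bool)
    significant = []
    if np.any(tested):
        p_vals = z_to_p_two_sided(zu[tested])
        q_adj, rej = bh_fdr(p_vals, q=fdr_q)
        ti, tj = iu[tested], ju[tested]
        p_edges[ti, tj] = p_vals
        p_edges[tj, ti] = p_vals
        q_edges[ti, tj] = q_adj
        q_edges[tj, ti] = q_adj
        rej_mat[ti[rej], tj[rej]] = True
        rej_mat[tj[rej], ti[rej]] = True
        for i, j, zv, pv, qv in zip(ti[rej], tj[rej], zu[tested][rej], p_vals[rej], q_adj[rej]):
            sign = SIGN_WEAKER if zv < 0 else SIGN_STRONGER
            significant.append((int(i), int(j), float(zv), float(pv), float(qv), sign))
    np.fill_diagonal(p_edges, np.nan)
    np.fill_diagonal(q_edges, np.nan)
    zn, pn, qn, sig_nodes, excl_nodes = node_strength_z(
        patient, controls, fdr_q=fdr_q, correct=correct_nodes
    )
    return DeviationResult(
        z_edges=z,
        p_edges=p_edges,
        q_edges=q_edges,
        significant_edges=significant,
        excluded_edges=excluded_edges,
        z_nodes=zn,
        p_nodes=pn,
        q_nodes=qn,
        significant_nodes=sig_nodes,
        excluded_nodes=excl_nodes,
        n_edges_tested=int(np.sum(tested)),
        fdr_q=fdr_q,
    )
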