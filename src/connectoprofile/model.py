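"""Normative connectome model: fit a control reference, profile a patient.

:class:`ConnectomeNormativeModel` is built from a :class:`~connectoprofile.io.Cohort`
(or a manifest file); :meth:`~ConnectomeNormativeModel.fit` estimates the
normative reference — per-metric control bands and per-edge mean/SD — and
evaluates the patient against it, returning a
:class:`NormativeProfileResults` that carries the eight-metric profile
with its categories, the edge/node deviation maps with FDR decisions,
and the hub comparison, with ``summary()``, ``plot_profile()`` and
``save()`` for reporting.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as cio
from .deviation import (
    DeviationResult,
    HubSet,
    compute_deviation,
    detect_hubs,
    hub_alterations,
)
from .errors import ConfigError
from .io import Cohort, ConnectivityMatrix
from .metrics import (
    METRIC_NAMES,
    MetricProfile,
    NullModelConfig,
    betweenness_centrality,
    compute_metric_profile,
    node_strengths,
    remap_weights_to_lengths,
)
from .profile import (
    ProfileReport,
    ReferenceBand,
    build_profile_report,
    reference_band,
    render_graphme,
    transform_for_display,
)


def _subject_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-subject null-model seeds derived from one base seed."""
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


class ConnectomeNormativeModel:
    """Single-patient normative comparison against a healthy-control cohort.

    Parameters
    ----------
    cohort
        Patient, controls and node table (see :func:`connectoprofile.io.load_cohort`).
    null_config
        Degree-preserving rewiring null-model settings for the normalised
        clustering coefficient (default: 100 nulls, 10 swaps per edge).
    icv_mode
        Head-size correction applied to display metrics: ``'none'``,
        ``'divide'`` (metric / ICV) or ``'multiply'``.
    ci_method
        Control band construction: ``'t_mean'`` (95% CI of the mean,
        default), ``'normal_mean'``, or ``'prediction'`` (95% prediction
        interval for a new individual).
    fdr_q
        Benjamini-Hochberg level for edge and node deviation tests.
    hub_fraction
        Fraction of top-betweenness nodes flagged as hubs (default 0.10).
    reference_hubs
        ``'group_average'`` computes reference hubs on the control
        group-average connectome; ``'consensus'`` ranks nodes by how often
        they are hubs in individual controls.
    correct_nodes
        Whether node-strength tests are FDR-corrected over the node family.
    """

    def __init__(
        self,
        cohort: Cohort,
        null_config: NullModelConfig | None = None,
        icv_mode: str = "none",
        ci_method: str = "t_mean",
        fdr_q: float = 0.05,
        hub_fraction: float = 0.10,
        reference_hubs: str = "group_average",
        correct_nodes: bool = True,
        navigation_length: str = "reciprocal",
    ):
        if icv_mode not in ("none", "divide", "multiply"):
            raise ConfigError(f"unknown icv_mode '{icv_mode}'")
        if reference_hubs not in ("group_average", "consensus"):
            raise ConfigError(f"unknown reference_hubs mode '{reference_hubs}'")
        if not 0 < fdr_q < 1:
            raise ConfigError("fdr_q must lie in (0, 1)")
        if not 0 < hub_fraction <= 1:
            raise ConfigError("hub_fraction must lie in (0, 1]")
        if icv_mode != "none":
            missing = [
                m.subject_id
                for m in [cohort.patient, *cohort.controls]
                if m.icv is None
            ]
            if missing:
                raise ConfigError(
                    f"icv_mode='{icv_mode}' but subjects lack ICV: {missing}"
                )
        self.cohort = cohort
        self.null_config = null_config or NullModelConfig()
        self.icv_mode = icv_mode
        self.ci_method = ci_method
        self.fdr_q = fdr_q
        self.hub_fraction = hub_fraction
        self.reference_hubs = reference_hubs
        self.correct_nodes = correct_nodes
        self.navigation_length = navigation_length

    @classmethod
    def from_manifest(cls, manifest: str | Path, **kwargs) -> "ConnectomeNormativeModel":
        """Build the model straight from a cohort manifest file."""
        return cls(cio.load_cohort(manifest), **kwargs)

    def _profile(self, m: ConnectivityMatrix, seed: int) -> MetricProfile:
        cfg = NullModelConfig(
            n_nulls=self.null_config.n_nulls,
            rewires_per_edge=self.null_config.rewires_per_edge,
            seed=seed,
        )
        return compute_metric_profile(
            m, self.cohort.node_table, cfg, navigation_length=self.navigation_length
        )

    def _reference_hub_set(
        self, control_profiles: list[MetricProfile]
    ) -> HubSet:
        if self.reference_hubs == "group_average":
            avg = np.mean([c.weights for c in self.cohort.controls], axis=0)
            bc = betweenness_centrality(remap_weights_to_lengths(avg))
            return detect_hubs(bc, self.hub_fraction, strengths=node_strengths(avg))
        # consensus: rank nodes by hub frequency across controls, break ties
        # by mean betweenness then index
        n = self.cohort.n_nodes
        freq = np.zeros(n)
        mean_bc = np.zeros(n)
        for prof in control_profiles:
            hs = detect_hubs(prof.betweenness_vec, self.hub_fraction, prof.strength_vec)
            for i in hs.indices:
                freq[i] += 1
            mean_bc += prof.betweenness_vec / len(control_profiles)
        k = len(detect_hubs(mean_bc, self.hub_fraction).hubs)
        order = sorted(range(n), key=lambda i: (-freq[i], -mean_bc[i], i))
        return HubSet(
            hubs=[(int(i), float(mean_bc[i])) for i in order[:k]],
            fraction=self.hub_fraction,
        )

    def fit(self, seed: int = 0) -> "NormativeProfileResults":
        """Estimate the normative reference and evaluate the patient.

        ``seed`` drives every stochastic component (the rewiring null
        models); repeated fits with the same seed are bit-identical.
        """
        cohort = self.cohort
        seeds = _subject_seeds(seed, cohort.n_controls + 1)
        control_profiles = [
            self._profile(c, s) for c, s in zip(cohort.controls, seeds[:-1])
        ]
        patient_profile = self._profile(cohort.patient, seeds[-1])
        control_display = [
            transform_for_display(p, icv=c.icv, icv_mode=self.icv_mode)
            for p, c in zip(control_profiles, cohort.controls)
        ]
        band = reference_band(control_display, ci_method=self.ci_method)
        report = build_profile_report(
            patient_profile, band, icv=cohort.patient.icv, icv_mode=self.icv_mode
        )
        deviation = compute_deviation(
            cohort.patient,
            cohort.controls,
            fdr_q=self.fdr_q,
            correct_nodes=self.correct_nodes,
        )
        patient_hubs = detect_hubs(
            patient_profile.betweenness_vec,
            self.hub_fraction,
            strengths=patient_profile.strength_vec,
        )
        ref_hubs = self._reference_hub_set(control_profiles)
        return NormativeProfileResults(
            model=self,
            seed=seed,
            control_profiles=control_profiles,
            patient_profile=patient_profile,
            band=band,
            report=report,
            deviation=deviation,
            patient_hubs=patient_hubs,
            reference_hubs=ref_hubs,
        )


@dataclass
class NormativeProfileResults:
    """Fitted normative comparison for one patient."""

    model: ConnectomeNormativeModel
    seed: int
    control_profiles: list[MetricProfile]
    patient_profile: MetricProfile
    band: ReferenceBand
    report: ProfileReport
    deviation: DeviationResult
    patient_hubs: HubSet
    reference_hubs: HubSet

    @property
    def hub_changes(self) -> dict[str, list[int]]:
        return hub_alterations(self.patient_hubs, self.reference_hubs)

    def summary(self) -> str:
        """Human-readable report: profile categories, deviations, hubs."""
        labels = self.model.cohort.node_table.labels
        lines = []
        pid = self.patient_profile.subject_id
        lines.append(f"Normative connectome profile — patient '{pid}'")
        lines.append(
            f"  controls: n={len(self.control_profiles)}, "
            f"band: {self.band.ci_method}, icv_mode: {self.model.icv_mode}"
        )
        lines.append("")
        lines.append(f"  {'metric':<24}{'raw':>12}{'displayed':>14}"
                     f"{'band low':>12}{'band high':>12}  category")
        for name in METRIC_NAMES:
            lines.append(
                f"  {name:<24}{self.report.raw[name]:>12.5g}"
                f"{self.report.displayed[name]:>14.5g}"
                f"{self.band.ci_low[name]:>12.5g}{self.band.ci_high[name]:>12.5g}"
                f"  {self.report.category[name]}"
            )
        dev = self.deviation
        lines.append("")
        lines.append(
            f"  edges tested: {dev.n_edges_tested} "
            f"(excluded: {len(dev.excluded_edges)}); "
            f"significant at q<={dev.fdr_q:g}: "
            f"{dev.n_significant_weaker} weaker, "
            f"{dev.n_significant_stronger} stronger"
        )
        sig_nodes = [
            f"{labels[i]} (z={z:+.2f})" for i, z, _, _, _ in dev.significant_nodes
        ]
        lines.append(
            "  significant node strengths: "
            + (", ".join(sig_nodes) if sig_nodes else "none")
        )
        changes = self.hub_changes
        gained = ", ".join(labels[i] for i in changes["gained"]) or "none"
        lost = ", ".join(labels[i] for i in changes["lost"]) or "none"
        lines.append(f"  hubs gained: {gained}")
        lines.append(f"  hubs lost:   {lost}")
        return "\n".join(lines)

    def to_json_dict(self) -> dict:
        """All numeric outputs as a JSON-serialisable dict."""
        labels = self.model.cohort.node_table.labels
        dev = self.deviation
        metrics = {
            name: {
                "raw": self.report.raw[name],
                "displayed": self.report.displayed[name],
                "band": [self.band.ci_low[name], self.band.ci_high[name]],
                "control_mean": self.band.mean[name],
                "category": self.report.category[name],
            }
            for name in METRIC_NAMES
        }
        changes = self.hub_changes
        return {
            "subject": self.patient_profile.subject_id,
            "seed": self.seed,
            "metrics": metrics,
            "deviation": {
                "n_edges_tested": dev.n_edges_tested,
                "n_excluded_edges": len(dev.excluded_edges),
                "n_significant_weaker": dev.n_significant_weaker,
                "n_significant_stronger": dev.n_significant_stronger,
                "significant_edges": [
                    {
                        "node_i": labels[i],
                        "node_j": labels[j],
                        "z": z,
                        "p": p,
                        "q": q,
                        "sign": sign,
                    }
                    for i, j, z, p, q, sign in dev.significant_edges
                ],
                "significant_nodes": [
                    {"node": labels[i], "z": z, "p": p, "q": q, "sign": sign}
                    for i, z, p, q, sign in dev.significant_nodes
                ],
            },
            "hubs": {
                "patient": [[labels[i], bc] for i, bc in self.patient_hubs.hubs],
                "reference": [[labels[i], bc] for i, bc in self.reference_hubs.hubs],
                "gained": [labels[i] for i in changes["gained"]],
                "lost": [labels[i] for i in changes["lost"]],
            },
        }

    def run_log(self) -> dict:
        """Every parameter and seed of the run, for auditability."""
        m = self.model
        return {
            "seed": self.seed,
            "n_controls": len(self.control_profiles),
            "n_nodes": m.cohort.n_nodes,
            "icv_mode": m.icv_mode,
            "ci_method": m.ci_method,
            "fdr_q": m.fdr_q,
            "hub_fraction": m.hub_fraction,
            "reference_hubs": m.reference_hubs,
            "correct_nodes": m.correct_nodes,
            "navigation_length": m.navigation_length,
            "null_model": {
                "n_nulls": m.null_config.n_nulls,
                "rewires_per_edge": m.null_config.rewires_per_edge,
            },
            "subject_null_seeds": {
                p.subject_id: p.seed
                for p in [*self.control_profiles, self.patient_profile]
            },
        }

    def plot_profile(self, out: str | Path) -> None:
        """Render the GraphMe radar plot to ``out`` (format by extension)."""
        render_graphme(self.report, self.band, str(out))

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write the full output bundle; returns the paths written."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nodes = self.model.cohort.node_table
        dev = self.deviation
        sig = np.zeros_like(dev.z_edges, dtype=bool)
        for i, j, *_ in dev.significant_edges:
            sig[i, j] = sig[j, i] = True
        paths = {
            "report": outdir / "report.json",
            "edges": outdir / "edges.csv",
            "nodes": outdir / "nodes.csv",
            "plot": outdir / "graphme.svg",
            "log": outdir / "run_log.json",
        }
        cio.write_json(paths["report"], self.to_json_dict())
        cio.export_edge_csv(
            paths["edges"], nodes, self.model.cohort.patient.weights,
            dev.z_edges, dev.p_edges, dev.q_edges, sig,
        )
        hub_mask = np.zeros(len(nodes), dtype=bool)
        for i in self.patient_hubs.indices:
            hub_mask[i] = True
        cio.export_node_csv(
            paths["nodes"], nodes,
            self.patient_profile.strength_vec, dev.z_nodes,
            self.patient_profile.betweenness_vec, hub_mask,
        )
        self.plot_profile(paths["plot"])
        cio.write_json(paths["log"], self.run_log())
        return paths
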