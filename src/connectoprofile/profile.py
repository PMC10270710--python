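"""GraphMe radar profiles: display transform, reference band, categorisation.

A patient's eight graph metrics are compared against a healthy-control
band. Three metrics for which higher raw values mean worse network
structure (characteristic path length, normalised clustering, mean
betweenness) are inverted (1/x) so that on the radar plot higher is
always better; an optional head-size correction then scales every metric
by the subject's total intracranial volume (ICV). Each metric is
categorised as *normal* (inside the control 95% interval, boundaries
inclusive), *supra-normal* (above) or *infra-normal* (below).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy import stats

from .errors import ConfigError, MetricUndefinedError
from .metrics import METRIC_NAMES, MetricProfile

#: metrics whose raw value is "lower is better" and get inverted for display
INVERTED_METRICS = ("char_path_length", "normalized_clustering", "betweenness")

CATEGORY_NORMAL = "normal"
CATEGORY_SUPRA = "supra-normal"
CATEGORY_INFRA = "infra-normal"

#: human-readable axis labels for the radar plot
AXIS_LABELS = {
    "strength": "Strength",
    "global_efficiency": "Global\nefficiency",
    "char_path_length": "1 / Char. path\nlength",
    "navigation_efficiency": "Navigation\nefficiency",
    "local_efficiency": "Local\nefficiency",
    "clustering": "Clustering",
    "normalized_clustering": "1 / Normalized\nclustering",
    "betweenness": "1 / Betweenness",
}


@dataclass
class ReferenceBand:
    """Per-metric control mean and 95% interval on the display scale."""

    mean: dict[str, float]
    ci_low: dict[str, float]
    ci_high: dict[str, float]
    n_controls: int
    ci_method: str = "t_mean"


@dataclass
class ProfileReport:
    """Patient display values with their band categories."""

    subject_id: str
    raw: dict[str, float]
    displayed: dict[str, float]
    category: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "subject": self.subject_id,
            "metrics": {
                name: {
                    "raw": self.raw[name],
                    "displayed": self.displayed[name],
                    "category": self.category[name],
                }
                for name in METRIC_NAMES
            },
        }


def transform_for_display(
    profile: MetricProfile | dict[str, float],
    icv: float | None = None,
    icv_mode: str = "none",
) -> dict[str, float]:
    """Invert the lower-is-better metrics and apply the ICV correction.

    ``icv_mode='divide'`` divides every metric by ICV (the conventional
    head-size correction), ``'multiply'`` multiplies by ICV, ``'none'``
    leaves values as they are. Inversion happens before the ICV scaling.
    With ``icv_mode='none'`` the transform is an involution on the three
    inverted metrics.
    """
    values = profile.values() if isinstance(profile, MetricProfile) else dict(profile)
    out: dict[str, float] = {}
    for name, v in values.items():
        if name in INVERTED_METRICS:
            if v == 0:
                raise MetricUndefinedError(f"cannot invert zero-valued metric '{name}'")
            v = 1.0 / v
        out[name] = float(v)
    if icv_mode == "none":
        return out
    if icv_mode not in ("divide", "multiply"):
        raise ConfigError(f"unknown icv_mode '{icv_mode}'")
    if icv is None:
        raise ConfigError(f"icv_mode='{icv_mode}' requires a subject ICV")
    factor = 1.0 / icv if icv_mode == "divide" else icv
    return {name: v * factor for name, v in out.items()}


def reference_band(
    control_values: list[dict[str, float]],
    ci_method: str = "t_mean",
) -> ReferenceBand:
    """Control mean and 95% interval per metric, from display-scale values.

    ``t_mean``: mean +/- t_{0.975, n-1} * sd / sqrt(n) (CI of the mean);
    ``normal_mean``: mean +/- 1.96 * sd / sqrt(n);
    ``prediction``: mean +/- t_{0.975, n-1} * sd * sqrt(1 + 1/n), the
    interval a new healthy individual falls in with 95% probability —
    statistically the appropriate band for classifying a single subject.
    Zero-variance metrics collapse the band to the mean, with a warning.
    """
    if len(control_values) < 2:
        raise ConfigError("reference band needs at least 2 control profiles")
    if ci_method not in ("t_mean", "normal_mean", "prediction"):
        raise ConfigError(f"unknown ci_method '{ci_method}'")
    n = len(control_values)
    mean: dict[str, float] = {}
    lo: dict[str, float] = {}
    hi: dict[str, float] = {}
    for name in METRIC_NAMES:
        vals = np.array([cv[name] for cv in control_values], dtype=float)
        mu = float(vals.mean())
        sd = float(vals.std(ddof=1))
        if sd == 0:
            warnings.warn(f"zero control variance for '{name}'; band collapses to mean")
            half = 0.0
        elif ci_method == "t_mean":
            half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        elif ci_method == "normal_mean":
            half = stats.norm.ppf(0.975) * sd / np.sqrt(n)
        elif ci_method == "prediction":
            half = stats.t.ppf(0.975, n - 1) * sd * np.sqrt(1 + 1.0 / n)
        else:
            raise ConfigError(f"unknown ci_method '{ci_method}'")
        mean[name], lo[name], hi[name] = mu, mu - half, mu + half
    return ReferenceBand(mean=mean, ci_low=lo, ci_high=hi, n_controls=n, ci_method=ci_method)


def categorize_metric(value: float, ci_low: float, ci_high: float) -> str:
    """normal inside [ci_low, ci_high] (inclusive), infra below, supra above."""
    if value < ci_low:
        return CATEGORY_INFRA
    if value > ci_high:
        return CATEGORY_SUPRA
    return CATEGORY_NORMAL


def build_profile_report(
    patient: MetricProfile,
    band: ReferenceBand,
    icv: float | None = None,
    icv_mode: str = "none",
) -> ProfileReport:
    """Transform the patient profile and categorise each metric against the band."""
    displayed = transform_for_display(patient, icv=icv, icv_mode=icv_mode)
    category = {
        name: categorize_metric(displayed[name], band.ci_low[name], band.ci_high[name])
        for name in METRIC_NAMES
    }
    return ProfileReport(
        subject_id=patient.subject_id,
        raw=patient.values(),
        displayed=displayed,
        category=category,
    )


def render_graphme(report: ProfileReport, band: ReferenceBand, out: str) -> None:
    """Radar plot: patient polygon (red) over the control mean (dark blue)
    and shaded 95% band (light blue), one axis per metric.

    Each axis is scaled independently to the span of the band and the
    patient value so every metric is readable regardless of units. Output
    format (SVG/PNG/...) follows the file extension.
    """
    names = METRIC_NAMES
    k = len(names)
    angles = np.linspace(0, 2 * np.pi, k, endpoint=False)

    def _scale(name: str, value: float) -> float:
        candidates = [
            band.ci_low[name],
            band.ci_high[name],
            band.mean[name],
            report.displayed[name],
        ]
        vmin, vmax = min(candidates), max(candidates)
        span = vmax - vmin
        if span == 0:
            return 0.6
        pad = 0.25 * span
        return 0.1 + 0.8 * (value - (vmin - pad)) / (span + 2 * pad)

    def _close(vals: list[float]) -> np.ndarray:
        return np.array(vals + vals[:1])

    ang = np.append(angles, angles[0])
    lo = _close([_scale(n, band.ci_low[n]) for n in names])
    hi = _close([_scale(n, band.ci_high[n]) for n in names])
    mid = _close([_scale(n, band.mean[n]) for n in names])
    pat = _close([_scale(n, report.displayed[n]) for n in names])

    fig, ax = plt.subplots(figsize=(6.5, 6.5), subplot_kw={"projection": "polar"})
    ax.set_theta_offset(np.pi / 2)
    ax.set_theta_direction(-1)
    ax.fill_between(ang, lo, hi, color="#7fb3d5", alpha=0.45, label="control 95% band")
    ax.plot(ang, mid, color="#1a2e57", lw=2, label="control mean")
    ax.plot(ang, pat, color="#c0392b", lw=2, label=report.subject_id or "patient")
    ax.set_xticks(angles)
    ax.set_xticklabels([AXIS_LABELS[n] for n in names], fontsize=8)
    ax.set_yticklabels([])
    ax.set_ylim(0, 1.05)
    ax.legend(loc="upper right", bbox_to_anchor=(1.25, 1.1), fontsize=8)
    fig.tight_layout()
    fig.savefig(out)
    plt.close(fig)
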