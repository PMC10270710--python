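"""Monte-Carlo validation experiments for the deviation pipeline.

These run the edgewise z-score / FDR analysis on synthetic cohorts with
known ground truth: a specificity experiment (unlesioned patients should
yield almost no FDR rejections) and a recovery experiment (attenuated
edges of lesioned nodes should be flagged as significantly weaker with
high sensitivity and precision).
"""

from __future__ import annotations

import numpy as np

from .deviation import SIGN_WEAKER, compute_deviation
from .synthetic import LesionSpec, SyntheticConfig, generate_cohort, generate_template


def _fresh_cohort(cfg: SyntheticConfig, seed: int):
    cfg = SyntheticConfig(
        n_nodes=cfg.n_nodes,
        n_controls=cfg.n_controls,
        base_weight=cfg.base_weight,
        decay_scale=cfg.decay_scale,
        density=cfg.density,
        subject_noise_cv=cfg.subject_noise_cv,
        seed=seed,
    )
    template, nodes = generate_template(cfg)
    rng = np.random.default_rng(seed + 1)
    controls = generate_cohort(template, cfg, rng=rng)
    patient = generate_cohort(template, cfg, rng=rng, n_subjects=1, id_prefix="patient")[0]
    return template, nodes, controls, patient, rng


def null_fdr_fractions(
    n_replicates: int = 200,
    seed: int = 0,
    cfg: SyntheticConfig | None = None,
    fdr_q: float = 0.05,
) -> np.ndarray:
    """Fraction of tested edges FDR-rejected for unlesioned patients.

    Each replicate draws a fresh control cohort and an extra patient from
    the same generating distribution, so every rejection is a false
    positive. Returns the per-replicate rejected fractions.
    """
    cfg = cfg or SyntheticConfig()
    base = np.random.default_rng(seed).integers(0, 2**31 - 10_000, size=n_replicates)
    fractions = np.empty(n_replicates)
    for r in range(n_replicates):
        _, _, controls, patient, _ = _fresh_cohort(cfg, int(base[r]))
        res = compute_deviation(patient, controls, fdr_q=fdr_q)
        fractions[r] = len(res.significant_edges) / max(res.n_edges_tested, 1)
    return fractions


def lesion_recovery_rates(
    n_seeds: int = 100,
    seed: int = 0,
    cfg: SyntheticConfig | None = None,
    n_target_nodes: int = 4,
    attenuation: float = 0.3,
    fdr_q: float = 0.05,
) -> tuple[np.ndarray, np.ndarray]:
    """Sensitivity and precision of significant-weaker-edge recovery.

    Each run lesions ``n_target_nodes`` randomly chosen nodes of a fresh
    patient (all incident edges multiplied by ``attenuation``) and scores
    the FDR-significant weaker edges against the ground-truth altered-edge
    mask. Returns (per-run sensitivity, per-run precision).
    """
    cfg = cfg or SyntheticConfig()
    base = np.random.default_rng(seed + 1).integers(0, 2**31 - 10_000, size=n_seeds)
    sens = np.empty(n_seeds)
    prec = np.empty(n_seeds)
    for r in range(n_seeds):
        _, _, controls, patient, rng = _fresh_cohort(cfg, int(base[r]))
        targets = rng.choice(cfg.n_nodes, size=n_target_nodes, replace=False)
        from .synthetic import inject_lesion

        lesioned, mask = inject_lesion(
            patient, LesionSpec(target_nodes=[int(t) for t in targets],
                                attenuation=attenuation)
        )
        res = compute_deviation(lesioned, controls, fdr_q=fdr_q)
        truth = {
            (i, j)
            for i, j in zip(*np.nonzero(np.triu(mask, k=1)))
        }
        found = {
            (i, j)
            for i, j, z, p, q, sign in res.significant_edges
            if sign == SIGN_WEAKER
        }
        hit = len(truth & found)
        sens[r] = hit / len(truth) if truth else 1.0
        prec[r] = hit / len(found) if found else 1.0
    return sens, prec
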