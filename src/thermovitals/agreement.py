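"""Study-level agreement statistics between estimates and references.

Bland-Altman limits are reported as empirical 5th/95th percentiles of
the paired differences (estimate minus reference), not Gaussian
+/-1.96 SD limits.  Group means of MAE are unweighted across groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["AgreementReport", "bland_altman", "mae_by_group"]


@dataclass
class AgreementReport:
    mean_difference: float
    percentile_5: float
    percentile_95: float
    mae: float
    n: int
    differences: np.ndarray = field(repr=False, default=None)
    pair_means: np.ndarray = field(repr=False, default=None)


def bland_altman(estimates: Sequence[float], references: Sequence[float]) -> AgreementReport:
    """Paired-difference agreement summary (differences = est - ref)."""
    est = np.asarray(estimates, dtype=np.float64)
    ref = np.asarray(references, dtype=np.float64)
    if est.shape != ref.shape:
        raise ValueError(f"length mismatch: {est.shape} vs {ref.shape}")
    if est.size < 2:
        raise ValueError("need at least 2 paired points")
    diff = est - ref
    p5, p95 = np.percentile(diff, [5.0, 95.0])
    return AgreementReport(
        mean_difference=float(diff.mean()),
        percentile_5=float(p5),
        percentile_95=float(p95),
        mae=float(np.abs(diff).mean()),
        n=int(est.size),
        differences=diff,
        pair_means=(est + ref) / 2.0,
    )


def mae_by_group(
    estimates: Sequence[float],
    references: Sequence[float],
    group_ids: Sequence,
) -> tuple[dict, float]:
    """Per-group MAE plus the unweighted mean across groups."""
    est = np.asarray(estimates, dtype=np.float64)
    ref = np.asarray(references, dtype=np.float64)
    groups = np.asarray(group_ids)
    if not (len(est) == len(ref) == len(groups)):
        raise ValueError("estimates, references and group_ids must align")
    if len(est) == 0:
        raise ValueError("no paired points")
    per_group: dict = {}
    for g in dict.fromkeys(groups.tolist()):  # preserves first-seen order
        mask = groups == g
        per_group[g] = float(np.abs(est[mask] - ref[mask]).mean())
    return per_group, float(np.mean(list(per_group.values())))


def plot_bland_altman(report: AgreementReport, path: str) -> None:
    """Optional difference-vs-mean scatter saved to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(report.pair_means, report.differences, s=12, alpha=0.7)
    for y, style, label in (
        (report.mean_difference, "-", "mean"),
        (report.percentile_5, "--", "5th pct"),
        (report.percentile_95, "--", "95th pct"),
    ):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
        ax.annotate(f"{label}: {y:.2f}", (0.99, y), xycoords=("axes fraction", "data"),
                    ha="right", va="bottom", fontsize=8)
    ax.set_xlabel("pair mean")
    ax.set_ylabel("estimate - reference")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
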