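"""Bland-Altman agreement between inferred and ground-truth volumes.

For paired volume series the differences d_i = estimate_i - reference_i are
summarized by their mean (bias), sample standard deviation, limits of
agreement (mean +/- 1.96 SD), the standard error of the mean difference
(SD/sqrt(n)) and a coefficient of variation expressing SD(d) as a
percentage of the grand mean of the paired means.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["AgreementReport", "bland_altman", "plot_bland_altman"]


@dataclass(frozen=True)
class AgreementReport:
    n: int
    mean_difference: float  # mL, estimate - reference
    sd_differences: float  # mL, sample SD (ddof=1)
    limits_of_agreement: tuple[float, float]  # mean -/+ 1.96 SD
    se_of_mean_difference: float  # mL, SD / sqrt(n)
    cv_percent: float  # 100 * SD(d) / mean of paired means

    def __post_init__(self) -> None:
        lo, hi = self.limits_of_agreement
        if not lo <= self.mean_difference <= hi:
            raise ValueError("mean difference must lie within the limits of agreement")
        if self.cv_percent < 0:
            raise ValueError("cv_percent must be >= 0")

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_difference_ml": self.mean_difference,
            "sd_differences_ml": self.sd_differences,
            "loa_lower_ml": self.limits_of_agreement[0],
            "loa_upper_ml": self.limits_of_agreement[1],
            "se_of_mean_difference_ml": self.se_of_mean_difference,
            "cv_percent": self.cv_percent,
        }


def bland_altman(reference, estimate) -> AgreementReport:
    """Bland-Altman statistics for paired volume series (mL)."""
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape or ref.ndim != 1:
        raise ValueError("reference and estimate must be equal-length 1-D sequences")
    n = len(ref)
    if n < 2:
        raise ValueError("need at least two pairs")
    d = est - ref
    mean_d = float(d.mean())
    sd = float(d.std(ddof=1))
    grand_mean = float(((ref + est) / 2.0).mean())
    cv = 100.0 * sd / abs(grand_mean) if grand_mean != 0 else 0.0
    return AgreementReport(
        n=n,
        mean_difference=mean_d,
        sd_differences=sd,
        limits_of_agreement=(mean_d - 1.96 * sd, mean_d + 1.96 * sd),
        se_of_mean_difference=float(sd / np.sqrt(n)),
        cv_percent=float(cv),
    )


def plot_bland_altman(report: AgreementReport, reference, estimate,
                      path: Path | str) -> Path:
    """Scatter of differences against paired means with bias/LoA lines."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    means = (ref + est) / 2.0
    diffs = est - ref

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(means, diffs, s=24, color="tab:blue", zorder=3)
    ax.axhline(report.mean_difference, color="k", lw=1.2, label="mean")
    for lim in report.limits_of_agreement:
        ax.axhline(lim, color="k", lw=1.0, ls="--")
    ax.set_xlabel("mean of reference and estimate (mL)")
    ax.set_ylabel("estimate - reference (mL)")
    ax.set_title("Bland-Altman agreement")
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return path
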