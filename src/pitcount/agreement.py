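"""Method-comparison statistics for manual vs automated %PIT counts.

Bland–Altman agreement (bias, 1.96·SD limits of agreement, confidence
intervals via the classical sd·√(3/n) approximation for the LOAs), the
stratified acceptance rule used for %PIT method comparison (overall LOAs
within ±5 percentage points; within ±1.5 for samples whose manual %PIT is
below 5%), observer-consensus maps, the paired t-test and Pearson
correlation.  Differences are fixed as automated − manual, so a positive
bias means the automated count reads higher.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PairedMeasurements",
    "BAResult",
    "AcceptanceSpec",
    "AcceptanceVerdict",
    "ConsensusMap",
    "bland_altman",
    "check_loa_acceptance",
    "consensus_map",
    "paired_t_test",
    "pearson_r",
    "ba_plot",
]

_Z_LOA = 1.96


@dataclass
class PairedMeasurements:
    """Manual and automated %PIT for the same samples."""

    sample_ids: list[str]
    manual: np.ndarray
    automated: np.ndarray

    def __post_init__(self) -> None:
        self.manual = np.asarray(self.manual, dtype=np.float64)
        self.automated = np.asarray(self.automated, dtype=np.float64)
        self.sample_ids = [str(s) for s in self.sample_ids]
        n = len(self.sample_ids)
        if self.manual.shape != (n,) or self.automated.shape != (n,):
            raise ValueError("sample_ids, manual and automated must have equal length")
        if n < 2:
            raise ValueError("at least 2 paired measurements are required")
        if not (np.all(np.isfinite(self.manual)) and np.all(np.isfinite(self.automated))):
            raise ValueError("paired measurements must be finite (no missing values)")

    def __len__(self) -> int:
        return len(self.sample_ids)

    def subset_low(self, threshold: float = 5.0) -> "PairedMeasurements":
        """Pairs whose *manual* %PIT is below the threshold (the low
        stratum of the acceptance rule)."""
        keep = self.manual < threshold
        if keep.sum() < 2:
            raise ValueError(
                f"fewer than 2 pairs with manual %PIT < {threshold:g}"
            )
        return PairedMeasurements(
            [s for s, k in zip(self.sample_ids, keep) if k],
            self.manual[keep],
            self.automated[keep],
        )


@dataclass
class BAResult:
    """Bland–Altman summary of automated − manual differences."""

    n: int
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    bias_ci: tuple[float, float]
    loa_lower_ci: tuple[float, float]
    loa_upper_ci: tuple[float, float]
    differences: np.ndarray = field(repr=False)
    means: np.ndarray = field(repr=False)
    n_outside_loa: int = 0


def bland_altman(pairs: PairedMeasurements) -> BAResult:
    """Bias, limits of agreement and their confidence intervals.

    LOAs are bias ± 1.96·sd of the paired differences (sample sd, n−1).
    The bias CI uses t(n−1) with standard error sd/√n; each LOA CI uses
    the classical approximation sd·√(3/n) with t(n−1).  Zero variance
    yields degenerate width-0 intervals, not an error.
    """
    d = pairs.automated - pairs.manual
    n = d.size
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    loa_lo = bias - _Z_LOA * sd
    loa_hi = bias + _Z_LOA * sd
    tcrit = float(stats.t.ppf(0.975, n - 1))
    se_bias = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(3.0 / n)
    outside = int(np.sum((d < loa_lo) | (d > loa_hi)))
    return BAResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_lower=loa_lo,
        loa_upper=loa_hi,
        bias_ci=(bias - tcrit * se_bias, bias + tcrit * se_bias),
        loa_lower_ci=(loa_lo - tcrit * se_loa, loa_lo + tcrit * se_loa),
        loa_upper_ci=(loa_hi - tcrit * se_loa, loa_hi + tcrit * se_loa),
        differences=d,
        means=(pairs.automated + pairs.manual) / 2.0,
        n_outside_loa=outside,
    )


@dataclass(frozen=True)
class AcceptanceSpec:
    """Stratified LOA acceptance bounds (percentage points)."""

    overall_bound: float = 5.0
    low_bound: float = 1.5
    low_stratum_below: float = 5.0

    def __post_init__(self) -> None:
        if self.overall_bound <= 0 or self.low_bound <= 0:
            raise ValueError("acceptance bounds must be positive")

    def bound_for(self, stratum: str) -> float:
        if stratum == "overall":
            return self.overall_bound
        if stratum == "low":
            return self.low_bound
        raise ValueError(f"unknown stratum {stratum!r}; use 'overall' or 'low'")


@dataclass
class AcceptanceVerdict:
    stratum: str
    bound: float
    max_abs_loa: float
    passed: bool
    margin: float  # bound − max_abs_loa; negative when failed


def check_loa_acceptance(
    ba: BAResult, spec: AcceptanceSpec | None = None, stratum: str = "overall"
) -> AcceptanceVerdict:
    """Pass iff both LOAs lie within the stratum's bound.

    The caller is responsible for computing ``ba`` on the matching
    stratum (subset pairs with manual %PIT < 5 for ``stratum="low"``).
    """
    if spec is None:
        spec = AcceptanceSpec()
    bound = spec.bound_for(stratum)
    worst = max(abs(ba.loa_upper), abs(ba.loa_lower))
    return AcceptanceVerdict(stratum, bound, worst, worst <= bound, bound - worst)


@dataclass
class ConsensusMap:
    """Per-pixel count of observers annotating each pixel (0..k)."""

    counts: np.ndarray
    n_observers: int

    def summary(self) -> dict[int, int]:
        """Pixel count at each consensus level 0..k."""
        return {
            level: int(np.sum(self.counts == level))
            for level in range(self.n_observers + 1)
        }


def consensus_map(masks: list[np.ndarray]) -> ConsensusMap:
    """Sum binary annotation masks from k observers per pixel."""
    if len(masks) < 2:
        raise ValueError("at least 2 observer masks are required")
    arrs = [np.asarray(m, dtype=bool) for m in masks]
    shape = arrs[0].shape
    for i, m in enumerate(arrs[1:], start=2):
        if m.shape != shape:
            raise ValueError(
                f"geometry mismatch: mask 1 is {shape}, mask {i} is {m.shape}"
            )
    total = np.sum([m.astype(np.int32) for m in arrs], axis=0)
    return ConsensusMap(total, len(arrs))


def paired_t_test(pairs: PairedMeasurements) -> tuple[float, float]:
    """Two-sided paired t-test of automated vs manual counts.

    t = mean(d) / (sd(d)/√n), df = n−1.  Zero variance of the
    differences is degenerate and raises.
    """
    d = pairs.automated - pairs.manual
    n = d.size
    sd = float(np.std(d, ddof=1))
    if sd == 0.0:
        raise ValueError(
            "paired t-test is degenerate: the differences have zero variance"
        )
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), n - 1))
    return t, p


def pearson_r(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with a two-sided p-value via the
    t = r·√((n−2)/(1−r²)) transform, df = n−2."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D with equal length")
    n = x.size
    if n < 3:
        raise ValueError("at least 3 points are required")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: correlation is undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    r = float(np.dot(xc, yc) / np.sqrt(np.dot(xc, xc) * np.dot(yc, yc)))
    r = min(1.0, max(-1.0, r))
    if 1.0 - r * r <= 0.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = float(2.0 * stats.t.sf(abs(t), n - 2))
    return r, p


def ba_plot(ba: BAResult, path=None, title: str = "Bland–Altman agreement"):
    """Mean-vs-difference plot with bias and LOA bands; saves to ``path``
    when given, returns the figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(ba.means, ba.differences, s=18, color="k", zorder=3)
    ax.axhline(ba.bias, color="tab:blue", label=f"bias {ba.bias:.2f}%")
    ax.axhspan(*ba.bias_ci, color="tab:blue", alpha=0.15)
    ax.axhline(ba.loa_upper, color="tab:green", ls="--", label=f"upper LOA {ba.loa_upper:.2f}%")
    ax.axhspan(*ba.loa_upper_ci, color="tab:green", alpha=0.15)
    ax.axhline(ba.loa_lower, color="tab:red", ls="--", label=f"lower LOA {ba.loa_lower:.2f}%")
    ax.axhspan(*ba.loa_lower_ci, color="tab:red", alpha=0.15)
    ax.set_xlabel("mean of manual and automated %PIT")
    ax.set_ylabel("automated − manual %PIT")
    ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
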