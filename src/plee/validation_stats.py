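"""Method-comparison statistics: Pearson correlation and Bland–Altman.

Used to compare P_Lee values extracted by script against an independent
determination of the same quantity (e.g. a clinician reading representative
end-expiratory values off the pressure-time curve).  Correlation answers
whether the two methods move together; Bland–Altman agreement (bias =
mean difference, limits of agreement = bias ± 1.96 SD of the differences)
answers whether they can be used interchangeably.

Differences are oriented as (method A - method B); by convention A is the
manual reference and B the scripted extraction, so a positive bias means
the manual reading runs higher.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ValidationError


class CorrelationUndefinedError(ValidationError):
    """One series has zero variance, so r is undefined.

    Bland–Altman agreement is still well defined and is carried on the
    exception (`bias`, `sd_diff`) for callers that want it.
    """

    def __init__(self, message: str, bias: float, sd_diff: float):
        super().__init__(f"{message} (bias {bias:.3g}, SD of differences {sd_diff:.3g})")
        self.bias = bias
        self.sd_diff = sd_diff


@dataclass(frozen=True)
class ComparisonResult:
    """Agreement between two methods measuring the same quantity."""

    n_pairs: int
    pearson_r: float
    ci_low: float
    ci_high: float
    bias: float
    sd_diff: float

    @property
    def loa_low(self) -> float:
        """Lower 95% limit of agreement, bias - 1.96 SD."""
        return self.bias - 1.96 * self.sd_diff

    @property
    def loa_high(self) -> float:
        """Upper 95% limit of agreement, bias + 1.96 SD."""
        return self.bias + 1.96 * self.sd_diff

    def summary(self) -> str:
        return (
            f"n = {self.n_pairs}\n"
            f"Pearson r = {self.pearson_r:.2f} "
            f"(95% CI {self.ci_low:.2f} to {self.ci_high:.2f})\n"
            f"bias = {self.bias:.2f} cmH2O (SD {self.sd_diff:.2f})\n"
            f"limits of agreement: {self.loa_low:.2f} to {self.loa_high:.2f} cmH2O"
        )


def _fisher_ci(r: float, n: int, conf: float) -> tuple[float, float]:
    """Confidence interval for a correlation via the Fisher z-transform."""
    from scipy import stats

    if n <= 3:
        return (-1.0, 1.0)
    if abs(r) >= 1.0:  # atanh diverges; the interval degenerates to the point
        return (r, r)
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zcrit = float(stats.norm.ppf(0.5 + conf / 2.0))
    return (math.tanh(z - zcrit * se), math.tanh(z + zcrit * se))


def compare_methods(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    conf: float = 0.95,
) -> ComparisonResult:
    """Pearson correlation (with Fisher-z CI) and Bland–Altman agreement.

    ``x`` is method A (reference/manual), ``y`` method B (scripted):
    differences are x - y.  The SD of differences uses the n-1 denominator;
    the limits of agreement use the conventional exact 1.96 multiplier.
    Raises :class:`CorrelationUndefinedError` when either series is
    constant (agreement numbers travel on the exception).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and the same length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")

    diff = x - y
    bias = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))

    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise CorrelationUndefinedError(
            "correlation undefined: a series has zero variance", bias, sd_diff
        )
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    ci_low, ci_high = _fisher_ci(r, n, conf)
    return ComparisonResult(
        n_pairs=n, pearson_r=r, ci_low=ci_low, ci_high=ci_high,
        bias=bias, sd_diff=sd_diff,
    )


def plot_comparison(
    result: ComparisonResult,
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    out_dir: str | Path,
    label_a: str = "method A",
    label_b: str = "method B",
) -> tuple[Path, Path]:
    """Write the correlation and Bland–Altman plots as PNG files.

    The correlation plot shows the pairs with the identity line; the
    Bland–Altman plot shows difference against pair mean with horizontal
    lines at the bias and both limits of agreement.  Returns the two paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(y, x, color="tab:blue")
    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax.plot(lims, lims, "k--", lw=1, label="identity")
    ax.set_xlabel(f"{label_b} (cmH2O)")
    ax.set_ylabel(f"{label_a} (cmH2O)")
    ax.set_title(f"r = {result.pearson_r:.2f} "
                 f"(95% CI {result.ci_low:.2f}-{result.ci_high:.2f})")
    ax.legend()
    corr_path = out_dir / "correlation.png"
    fig.tight_layout()
    fig.savefig(corr_path, dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    means = (x + y) / 2.0
    diffs = x - y
    ax.scatter(means, diffs, color="tab:blue")
    ax.axhline(result.bias, color="k", lw=1)
    ax.axhline(result.loa_low, color="k", lw=1, ls="--")
    ax.axhline(result.loa_high, color="k", lw=1, ls="--")
    ax.set_xlabel(f"mean of {label_a} and {label_b} (cmH2O)")
    ax.set_ylabel(f"{label_a} - {label_b} (cmH2O)")
    ax.set_title(
        f"bias {result.bias:.2f}, LoA {result.loa_low:.2f} to {result.loa_high:.2f}"
    )
    ba_path = out_dir / "bland_altman.png"
    fig.tight_layout()
    fig.savefig(ba_path, dpi=120)
    plt.close(fig)
    return corr_path, ba_path
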