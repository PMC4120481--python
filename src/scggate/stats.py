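"""Agreement and correlation statistics for validating the gating signals.

Pearson product-moment correlation for matched interval series, Bland-Altman
bias and 95 % limits of agreement (bias +/- 1.96 * sample sd of the paired
differences), and ordinary least-squares fits (e.g. cardiac-cycle percentage
against heart rate).  Statistics operate on matched pairs; mismatched lengths
are an error, never silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

#: Two-sided normal quantile for 95 % limits of agreement.
LOA_FACTOR = 1.96


@dataclass
class AgreementResult:
    """Bland-Altman style agreement summary for n matched pairs."""

    r: float
    bias: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self) -> None:
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("limits of agreement must bracket the bias")


def _paired(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch between paired lists")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    return x, y


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x, y = _paired(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    return float(sps.pearsonr(x, y).statistic)


def bland_altman(a, b) -> AgreementResult:
    """Bland-Altman agreement between two measurements of the same quantity.

    ``d = a - b``; bias is ``mean(d)`` and the 95 % limits of agreement are
    ``bias +/- 1.96 * sd(d)`` with the sample sd (ddof=1).  The Pearson r of
    the raw pairs is included (NaN when either side is constant).
    """
    a, b = _paired(a, b)
    d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    try:
        r = pearson_r(a, b)
    except ValueError:
        r = float("nan")
    return AgreementResult(r=r, bias=bias,
                           loa_low=bias - LOA_FACTOR * sd,
                           loa_high=bias + LOA_FACTOR * sd,
                           n=int(a.size))


def linear_fit(x, y) -> tuple[float, float, float]:
    """Ordinary least-squares line: returns ``(slope, intercept, r)``."""
    x, y = _paired(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: fit undefined")
    res = sps.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


def bland_altman_plot(a, b, path, title: str = "Bland-Altman") -> AgreementResult:
    """Write a Bland-Altman scatter (mean vs difference) with bias/LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    res = bland_altman(a, b)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, a - b, s=12, alpha=0.7)
    for yv, style in ((res.bias, "-"), (res.loa_low, "--"), (res.loa_high, "--")):
        ax.axhline(yv, color="crimson", linestyle=style, linewidth=1)
    ax.set_xlabel("mean of pair")
    ax.set_ylabel("difference (a - b)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return res
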