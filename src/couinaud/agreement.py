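"""Agreement statistics: Dice overlap and Bland-Altman limits of agreement.

Two segmentations of the same liver are compared with the Dice score
2|A∩B| / (|A| + |B|).  Paired scalar measurements (volumes, medians)
are compared with Bland-Altman analysis: the bias is the mean paired
difference, and the 95% limits of agreement (LOA) are bias +/- 1.96
standard deviations of the differences (sample SD, n-1 denominator).
Percent-mode differences are normalised by the pair mean,
100 * (a - b) / ((a + b) / 2), the standard choice for measurements
whose variability scales with their magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DiceResult",
    "AgreementResult",
    "dice",
    "bland_altman",
    "simulate_recovery",
    "plot_bland_altman",
]

LOA_MULTIPLIER = 1.96


@dataclass
class DiceResult:
    dice: float
    intersection_voxels: int
    size_a: int
    size_b: int


@dataclass
class AgreementResult:
    """Bias and 95% limits of agreement of paired differences."""

    n: int
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    mode: str

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "mode": self.mode,
            "loa_multiplier": LOA_MULTIPLIER,
        }


def _foreground(obj, segment: int | None) -> np.ndarray:
    grid = np.asarray(obj.grid if hasattr(obj, "grid") else obj)
    if segment is None:
        return grid > 0
    return grid == segment


def dice(a, b, segment: int | None = None) -> DiceResult:
    """Dice overlap of two masks or of one segment of two labelmaps.

    Both inputs must share grid shape and affine.  With ``segment``
    given, the comparison is restricted to voxels carrying that code.
    """
    if hasattr(a, "affine") and hasattr(b, "affine"):
        if a.grid.shape != b.grid.shape:
            raise ValueError(
                f"grid shape mismatch: {a.grid.shape} vs {b.grid.shape}"
            )
        if not np.allclose(a.affine, b.affine, atol=1e-6):
            raise ValueError("affine mismatch between the two inputs")
    fa = _foreground(a, segment)
    fb = _foreground(b, segment)
    if fa.shape != fb.shape:
        raise ValueError(f"grid shape mismatch: {fa.shape} vs {fb.shape}")
    size_a = int(fa.sum())
    size_b = int(fb.sum())
    if size_a + size_b == 0:
        raise ValueError("both inputs empty: Dice undefined")
    inter = int(np.count_nonzero(fa & fb))
    return DiceResult(
        dice=2.0 * inter / (size_a + size_b),
        intersection_voxels=inter,
        size_a=size_a,
        size_b=size_b,
    )


def bland_altman(pairs, mode: str = "absolute") -> AgreementResult:
    """Bias and 95% LOA of paired measurements.

    ``pairs`` is a sequence of (a, b) or an (n, 2) array.  Differences
    are a - b (absolute mode) or 100 * (a - b) / pair mean (percent
    mode); LOA = bias +/- 1.96 * sample SD.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) sequence")
    n = arr.shape[0]
    if n < 3:
        raise ValueError(f"need at least 3 pairs, got {n}")
    if mode not in ("absolute", "percent"):
        raise ValueError(f"mode must be 'absolute' or 'percent', got {mode!r}")
    a, b = arr[:, 0], arr[:, 1]
    if mode == "percent":
        means = (a + b) / 2.0
        if np.any(means == 0):
            raise ValueError("zero pair mean: percent difference undefined")
        d = 100.0 * (a - b) / means
    else:
        d = a - b
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return AgreementResult(
        n=n,
        bias=bias,
        sd_diff=sd,
        loa_low=bias - LOA_MULTIPLIER * sd,
        loa_high=bias + LOA_MULTIPLIER * sd,
        mode=mode,
    )


def simulate_recovery(bias_pct: float, sd_pct: float, n: int, seed: int,
                      reps: int = 1, true_value: float = 1500.0) -> dict:
    """Recovery check for the Bland-Altman estimator under a known model.

    Each rep draws n paired measurements where the second reading is the
    first scaled by 1 - (bias_pct + eps)/100 with eps ~ Normal(0, sd_pct)
    — the same generative model as the phantom pairs simulator — then
    runs percent-mode Bland-Altman.  Returns the distribution of the
    recovered bias and LOA endpoints alongside the analytic truth
    (bias_pct, bias_pct +/- 1.96 * sd_pct).
    """
    if sd_pct < 0:
        raise ValueError("sd_pct must be non-negative")
    if n < 3:
        raise ValueError("need n >= 3")
    if reps < 1:
        raise ValueError("need reps >= 1")
    from .phantom import simulate_pairs  # local import: avoid cycle

    biases = np.empty(reps)
    loa_lo = np.empty(reps)
    loa_hi = np.empty(reps)
    rng = np.random.default_rng(seed)
    truths = np.full(n, float(true_value))
    for r in range(reps):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        table = simulate_pairs(truths, bias_pct, sd_pct, n, seed=sub_seed)
        res = bland_altman(table[["value_a", "value_b"]].to_numpy(),
                           mode="percent")
        biases[r] = res.bias
        loa_lo[r] = res.loa_low
        loa_hi[r] = res.loa_high
    return {
        "reps": reps,
        "n": n,
        "true_bias": float(bias_pct),
        "true_loa_low": float(bias_pct - LOA_MULTIPLIER * sd_pct),
        "true_loa_high": float(bias_pct + LOA_MULTIPLIER * sd_pct),
        "bias_mean": float(biases.mean()),
        "bias_sd": float(biases.std(ddof=1)) if reps > 1 else 0.0,
        "loa_low_mean": float(loa_lo.mean()),
        "loa_high_mean": float(loa_hi.mean()),
        "biases": biases,
        "loa_lows": loa_lo,
        "loa_highs": loa_hi,
    }


def plot_bland_altman(pairs, result: AgreementResult, out_path=None,
                      guide_pct: float = 10.0):
    """Mean-vs-difference plot with bias, LOA and +/-10% guide lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(pairs, dtype=float)
    a, b = arr[:, 0], arr[:, 1]
    means = (a + b) / 2.0
    if result.mode == "percent":
        diffs = 100.0 * (a - b) / means
        ylabel = "difference (% of pair mean)"
    else:
        diffs = a - b
        ylabel = "difference"
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=18, color="tab:blue", zorder=3)
    ax.axhline(result.bias, linestyle="--", color="black",
               label=f"bias = {result.bias:.2f}")
    for loa in (result.loa_low, result.loa_high):
        ax.axhline(loa, linestyle=":", color="black")
    if result.mode == "percent" and guide_pct:
        for g in (-guide_pct, guide_pct):
            ax.axhline(g, linestyle=":", color="green", alpha=0.7)
    ax.set_xlabel("pair mean")
    ax.set_ylabel(ylabel)
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, dpi=120)
        plt.close(fig)
        return None
    return fig
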