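"""Evaluation utilities: histogram similarity, agreement metrics, noise, maps.

The Bhattacharyya coefficient (BC) measures the similarity of two radius
histograms; because the package's VSDs are max-normalized rather than
probability vectors, both inputs are renormalized to unit sum inside the
computation, which keeps BC in [0, 1] with BC(p, p) = 1.

Signal-to-noise is defined on the amplitude scale,
snr_db = 20·log10(RMS(signal)/σ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def _as_hist(p) -> np.ndarray:
    arr = np.asarray(getattr(p, "values", p), dtype=float)
    if arr.size == 0 or not arr.any():
        raise ValueError("histogram must be nonempty with positive mass")
    if (arr < 0).any():
        raise ValueError("histogram bins must be non-negative")
    return arr / arr.sum()


def bhattacharyya(p, q) -> float:
    """Σ √(pᵢ·qᵢ) after renormalizing both histograms to unit sum; in [0, 1]."""
    return float(np.sqrt(_as_hist(p) * _as_hist(q)).sum())


def mre(true: np.ndarray, pred: np.ndarray) -> float:
    """Mean residual error in percent: 100 · mean(|predᵢ − trueᵢ| / trueᵢ)."""
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape:
        raise ValueError("true and pred must have equal length")
    if (t == 0).any():
        raise ValueError("mre: true values must be nonzero")
    return float(100.0 * np.mean(np.abs(p - t) / np.abs(t)))


def bland_altman(true: np.ndarray, pred: np.ndarray):
    """Agreement summary: mean difference, ±1.96·SD limits, % within limits.

    Differences are ``true − pred``.  Returns
    ``(mean_diff, (lower, upper), pct_within)``; degenerate zero-SD limits
    are flagged with a warning.
    """
    t = np.asarray(true, dtype=float)
    p = np.asarray(pred, dtype=float)
    if t.shape != p.shape or t.size < 3:
        raise ValueError("bland_altman requires equal-length inputs with n >= 3")
    d = t - p
    mean_diff = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = mean_diff - 1.96 * sd, mean_diff + 1.96 * sd
    if sd == 0:
        import warnings

        warnings.warn("bland_altman: zero-SD differences, degenerate limits")
    pct_within = float(100.0 * np.mean((d >= lower) & (d <= upper)))
    return mean_diff, (lower, upper), pct_within


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; requires n ≥ 3 and nonzero variances."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.shape != y.shape:
        raise ValueError("pearson requires equal-length inputs with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson: zero-variance input")
    return float(np.corrcoef(x, y)[0, 1])


def add_noise(curve: np.ndarray, snr_db: float, seed: int = 0) -> np.ndarray:
    """Additive white Gaussian noise at an amplitude-scale SNR (dB).

    σ = RMS(curve)·10^(−snr_db/20); each curve in a batch uses its own RMS.
    """
    arr = np.asarray(curve, dtype=float)
    rng = np.random.default_rng(seed)
    rms = np.sqrt(np.mean(arr**2, axis=-1, keepdims=True))
    sigma = rms * 10.0 ** (-snr_db / 20.0)
    return arr + rng.normal(0.0, 1.0, size=arr.shape) * sigma


@dataclass
class ParametricMap:
    """Per-tile scalar broadcast to every voxel of its tile."""

    values: np.ndarray
    tile_size: int

    @property
    def tile_values(self) -> np.ndarray:
        """Recover the per-tile scalars (lossless inverse of stitching)."""
        t = self.tile_size
        nx, ny, nz = (s // t for s in self.values.shape)
        return self.values[::t, ::t, ::t][:nx, :ny, :nz]


def stitch_map(volume_shape, tile_values: np.ndarray, tile_size: int = 123) -> ParametricMap:
    """Broadcast per-tile scalars back onto the full-resolution grid.

    ``tile_values`` must have shape ``floor(volume_shape / tile_size)``; edge
    remainders smaller than a full tile are dropped, so the output shape is
    the largest tile-aligned box inside ``volume_shape``.
    """
    tiles = tuple(s // tile_size for s in volume_shape)
    vals = np.asarray(tile_values, dtype=float)
    if vals.shape != tiles:
        raise ValueError(f"tile_values shape {vals.shape} != expected tiling {tiles}")
    full = np.repeat(np.repeat(np.repeat(vals, tile_size, 0), tile_size, 1), tile_size, 2)
    return ParametricMap(full, tile_size)


@dataclass
class MetricsReport:
    """Descriptive agreement metrics for a set of volumes of interest."""

    pearson_r: float
    mre_percent: float
    bc_mean: float
    bc_sd: float
    bland_altman: dict
    n: int
    per_voi: "object" = None  # optional DataFrame of per-record values

    def to_dict(self) -> dict:
        out = {
            "pearson_r": self.pearson_r,
            "mre_percent": self.mre_percent,
            "bc_mean": self.bc_mean,
            "bc_sd": self.bc_sd,
            "n": self.n,
        }
        out.update({f"bland_altman_{k}": v for k, v in self.bland_altman.items()})
        return out


def evaluate_predictions(
    true_cbv: np.ndarray,
    pred_cbv: np.ndarray,
    true_vsd: np.ndarray,
    pred_vsd: np.ndarray,
) -> MetricsReport:
    """Standard report: CBV correlation/MRE/Bland-Altman plus VSD similarity."""
    bc = np.array(
        [bhattacharyya(t, p) for t, p in zip(np.atleast_2d(true_vsd), np.atleast_2d(pred_vsd))]
    )
    mean_diff, (lo, hi), pct = bland_altman(true_cbv, pred_cbv)
    return MetricsReport(
        pearson_r=pearson(true_cbv, pred_cbv),
        mre_percent=mre(true_cbv, pred_cbv),
        bc_mean=float(bc.mean()),
        bc_sd=float(bc.std(ddof=1)) if bc.size > 1 else 0.0,
        bland_altman={"mean_diff": mean_diff, "lower": lo, "upper": hi, "pct_within": pct},
        n=len(np.asarray(true_cbv)),
    )


def correlation_plot(true, pred, path: str, label: str = "CBV") -> None:
    """Scatter of true vs predicted values with the identity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(true, pred, s=4, alpha=0.4)
    lim = [min(np.min(true), np.min(pred)), max(np.max(true), np.max(pred))]
    ax.plot(lim, lim, "k--", lw=1)
    ax.set_xlabel(f"true {label}")
    ax.set_ylabel(f"predicted {label}")
    ax.set_title(f"r = {pearson(true, pred):.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(true, pred, path: str, label: str = "CBV") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = np.asarray(true, float)
    p = np.asarray(pred, float)
    mean_diff, (lo, hi), _ = bland_altman(t, p)
    fig, ax = plt.subplots(figsize=(4.5, 3.5))
    ax.scatter((t + p) / 2, t - p, s=4, alpha=0.4)
    for y, style in ((mean_diff, "-"), (lo, "--"), (hi, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel(f"mean {label}")
    ax.set_ylabel(f"difference (true − predicted)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
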