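"""Comparator methods: dictionary matching and analytical vessel size indices.

Dictionary matching is the classical vascular-fingerprinting estimator: a
query ratio curve is compared against every training curve by coefficient of
determination R², and the labels of the best-matching entry are returned.

The vessel size index (VSI) comes in two analytical forms: the MRI form,
built from the contrast-induced relaxation-rate changes ΔR2*/ΔR2, the
apparent diffusion coefficient and the susceptibility shift,

    VSI_MRI = 0.425 · (ADC / (γ·Δχ·B0))^{1/2} · (ΔR2*/ΔR2)^{3/2},

and the histology form, the −3/2 power mean of the radius distribution f(R)
(here the VSD renormalized to unit sum),

    VSI_Histo = [ Σ f_i · R_i^{−2/3} ]^{−3/2}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .gesfide import GAMMA_RAD_S_T
from .morphometry import VSDHistogram


@dataclass
class Dictionary:
    """Signal dictionary with paired CBV and VSD labels."""

    entries: np.ndarray  # (M, 18)
    cbv_labels: np.ndarray  # (M,)
    vsd_labels: np.ndarray  # (M, 40)

    def __post_init__(self):
        self.entries = np.asarray(self.entries, dtype=float)
        if len(self.entries) < 1:
            raise ValueError("dictionary must contain at least one entry")
        if len(self.cbv_labels) != len(self.entries) or len(self.vsd_labels) != len(self.entries):
            raise ValueError("labels must pair one-to-one with entries")


def dictionary_match(query: np.ndarray, dictionary: Dictionary):
    """Labels of the dictionary entry with the highest R² against the query.

    R² = 1 − SS_res/SS_tot with SS_tot taken about the query mean; ties break
    toward the lowest entry index.  A zero-variance query makes R² undefined,
    in which case the match falls back to minimum sum-of-squares distance.
    Returns ``(cbv, vsd, best_r2)``.
    """
    q = np.asarray(query, dtype=float)
    resid = ((dictionary.entries - q) ** 2).sum(axis=1)
    ss_tot = float(((q - q.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("dictionary_match: zero-variance query; using least-squares distance")
        best = int(np.argmin(resid))
        best_r2 = float("nan")
    else:
        r2 = 1.0 - resid / ss_tot
        best = int(np.argmax(r2))
        best_r2 = float(r2[best])
    return (
        float(dictionary.cbv_labels[best]),
        np.asarray(dictionary.vsd_labels[best]),
        best_r2,
    )


def dictionary_match_batch(queries: np.ndarray, dictionary: Dictionary):
    """Vectorized :func:`dictionary_match` over an (N, 18) query matrix."""
    q = np.asarray(queries, dtype=float)
    resid = ((q[:, None, :] - dictionary.entries[None, :, :]) ** 2).sum(axis=2)
    ss_tot = ((q - q.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - resid / ss_tot[:, None]
    best = np.where(ss_tot > 0, np.argmax(r2, axis=1), np.argmin(resid, axis=1))
    return (
        dictionary.cbv_labels[best],
        dictionary.vsd_labels[best],
        r2[np.arange(len(q)), best],
    )


@dataclass
class VsiParams:
    """Physical constants of the VSI_MRI formula.

    ``adc_um2_ms`` is the apparent diffusion coefficient in µm²/ms; ``gamma``
    the gyromagnetic ratio in rad·s⁻¹·T⁻¹; ``b0`` Tesla; ``delta_chi``
    dimensionless.
    """

    adc_um2_ms: float = 1.0
    gamma: float = GAMMA_RAD_S_T
    b0: float = 3.0
    delta_chi: float = 1e-6

    def __post_init__(self):
        for name in ("adc_um2_ms", "gamma", "b0", "delta_chi"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def vsi_mri(dr2_star: float, dr2: float, params: VsiParams | None = None) -> float:
    """VSI_MRI in µm; NaN where ΔR2 is non-positive (undefined, flagged voxel).

    All terms are converted to SI internally (ADC µm²/ms → m²/s), so the
    square-root factor carries metres and the result is reported in µm.
    """
    params = params or VsiParams()
    dr2_star = np.asarray(dr2_star, dtype=float)
    dr2 = np.asarray(dr2, dtype=float)
    adc_m2_s = params.adc_um2_ms * 1e-9
    scale_m = 0.425 * np.sqrt(adc_m2_s / (params.gamma * params.delta_chi * params.b0))
    with np.errstate(divide="ignore", invalid="ignore"):
        out = scale_m * 1e6 * np.where(dr2 > 0, (dr2_star / dr2) ** 1.5, np.nan)
    return float(out) if out.ndim == 0 else out


def vsi_from_distribution(radii: np.ndarray, weights: np.ndarray) -> float:
    """[Σ fᵢ·Rᵢ^{−2/3}]^{−3/2} for a discrete radius distribution (µm).

    ``weights`` are renormalized to unit sum, matching the unit-integral
    constraint of the underlying radius-density formulation.
    """
    w = np.asarray(weights, dtype=float)
    r = np.asarray(radii, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("vsi_from_distribution: all-zero weights")
    f = w / total
    return float((f @ r ** (-2.0 / 3.0)) ** (-1.5))


def vsi_histo(vsd: VSDHistogram) -> float:
    """VSI_Histo in µm from the VSD, renormalized internally to unit sum."""
    if not vsd.values.any():
        raise ValueError("vsi_histo: all-zero VSD")
    return vsi_from_distribution(vsd.bin_centers, vsd.values)
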