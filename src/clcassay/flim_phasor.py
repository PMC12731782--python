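"""Phasor FLIM-FRET analysis.

Fit-free lifetime estimation: each pixel's photon-count decay histogram is
mapped to its first-harmonic Fourier coordinates

    G = sum_k c_k cos(w t_k) / sum_k c_k,
    S = sum_k c_k sin(w t_k) / sum_k c_k,       w = 2 pi f,

with f the pulse repetition frequency and t_k the bin centres. A pure
monoexponential decay of lifetime tau lies on the universal semicircle at
G = 1/(1+(w tau)^2), S = w tau/(1+(w tau)^2). The predominant pixel cluster
is located by Gaussian fitting of the (G, S) density map, the lifetime is
read off as tau = S/(2 pi f G), and FRET efficiency follows from donor
lifetime quenching, E = 1 - tau_DA/tau_D.

No instrument-response deconvolution is applied (fit-free approach); bin
centres are the time coordinate convention throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DecayStack",
    "PhasorPoint",
    "PhasorCluster",
    "FretResult",
    "phasor_transform",
    "phasor_coordinates",
    "cluster_fit",
    "lifetime_from_phasor",
    "fret_efficiency",
    "roi_lifetime",
]


@dataclass
class DecayStack:
    """Per-pixel photon-count decay histograms.

    ``counts`` has shape (rows, cols, n_bins); integer photon counts for
    measured/Poisson data, floats for noise-free synthetic decays. Bin
    centres span one excitation period 1/rep_rate.
    """

    counts: np.ndarray
    bin_centers_ns: np.ndarray
    rep_rate_mhz: float
    region_masks: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.bin_centers_ns = np.asarray(self.bin_centers_ns, dtype=float)
        if self.counts.ndim != 3:
            raise ValueError("counts must be (rows, cols, n_bins)")
        if self.counts.shape[2] != self.bin_centers_ns.size:
            raise ValueError("bin_centers_ns length must equal n_bins")
        if np.any(self.counts < 0):
            raise ValueError("photon counts must be nonnegative")
        if self.rep_rate_mhz <= 0:
            raise ValueError("rep_rate_mhz must be positive")
        if self.bin_centers_ns.max() > self.period_ns:
            raise ValueError("bin centres exceed the excitation period")

    @property
    def period_ns(self) -> float:
        return 1e3 / self.rep_rate_mhz

    @property
    def n_bins(self) -> int:
        return self.counts.shape[2]


@dataclass(frozen=True)
class PhasorPoint:
    g: float
    s: float
    total_photons: float


@dataclass
class PhasorCluster:
    centroid_g: float
    centroid_s: float
    sigma_g: float
    sigma_s: float
    n_pixels: int
    roi: str = ""
    gaussian_converged: bool = True


@dataclass(frozen=True)
class FretResult:
    tau_d_ns: float
    tau_da_ns: float
    efficiency: float
    lifetime_lengthened: bool = False


def _angular_frequency(rep_rate_mhz: float) -> float:
    """omega in rad/ns for a repetition rate in MHz."""
    return 2.0 * np.pi * rep_rate_mhz * 1e-3


def phasor_coordinates(tau_ns: float | np.ndarray, rep_rate_mhz: float):
    """Universal-semicircle coordinates of a monoexponential lifetime."""
    wt = _angular_frequency(rep_rate_mhz) * np.asarray(tau_ns, dtype=float)
    denom = 1.0 + wt**2
    return 1.0 / denom, wt / denom


def phasor_transform(
    stack: DecayStack,
    roi: np.ndarray | str | None = None,
    *,
    min_photons: float = 20.0,
):
    """First-harmonic phasor of every ROI pixel, plus the pooled phasor.

    Returns ``(g, s, total, pooled)`` where ``g``/``s``/``total`` are images
    with NaN outside the ROI or below the photon floor, and ``pooled`` is
    the :class:`PhasorPoint` of the summed ROI decay. Pixels with too few
    photons are masked rather than propagated as NaN into the pooled value.
    """
    if isinstance(roi, str):
        try:
            mask = stack.region_masks[roi]
        except KeyError:
            raise KeyError(f"unknown ROI {roi!r}") from None
    elif roi is None:
        mask = np.ones(stack.counts.shape[:2], dtype=bool)
    else:
        mask = np.asarray(roi, dtype=bool)
    if not mask.any():
        raise ValueError("ROI is empty")

    w = _angular_frequency(stack.rep_rate_mhz)
    cosw = np.cos(w * stack.bin_centers_ns)
    sinw = np.sin(w * stack.bin_centers_ns)
    counts = stack.counts.astype(float)
    total = counts.sum(axis=2)
    ok = mask & (total >= min_photons) & (total > 0)

    g = np.full(total.shape, np.nan)
    s = np.full(total.shape, np.nan)
    tot = np.full(total.shape, np.nan)
    if ok.any():
        sel = counts[ok]
        g[ok] = sel @ cosw / total[ok]
        s[ok] = sel @ sinw / total[ok]
        tot[ok] = total[ok]

    pooled_counts = counts[mask & (total > 0)].sum(axis=0)
    pooled_total = pooled_counts.sum()
    if pooled_total <= 0:
        raise ValueError("ROI contains no photons")
    pooled = PhasorPoint(
        g=float(pooled_counts @ cosw / pooled_total),
        s=float(pooled_counts @ sinw / pooled_total),
        total_photons=float(pooled_total),
    )
    return g, s, tot, pooled


def _gauss2d(coords, amp, g0, s0, sg, ss):
    gg, ss_ = coords
    return amp * np.exp(-0.5 * (((gg - g0) / sg) ** 2 + ((ss_ - s0) / ss) ** 2))


def cluster_fit(
    g: np.ndarray,
    s: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    bin_width: float = 0.005,
    window_sigmas: float = 5.0,
    min_points: int = 50,
    roi: str = "",
) -> PhasorCluster:
    """Locate the predominant pixel cluster in the (G, S) density map.

    The phasor points are histogrammed at fixed ``bin_width``, the modal
    bin is found, a moment estimate of the local cloud is taken within
    ``window_sigmas`` standard deviations of the mode, and a 2-D Gaussian
    is fitted to the windowed histogram. Falls back to the weighted
    centroid (flagged) if the fit cannot converge; degenerate single-bin
    clouds return the centroid directly.
    """
    g = np.asarray(g, dtype=float).ravel()
    s = np.asarray(s, dtype=float).ravel()
    ok = np.isfinite(g) & np.isfinite(s)
    g, s = g[ok], s[ok]
    if weights is not None:
        weights = np.asarray(weights, dtype=float).ravel()[ok]
    if g.size < min_points:
        raise ValueError(f"need at least {min_points} phasor points, got {g.size}")

    spread_g = g.max() - g.min()
    spread_s = s.max() - s.min()
    if spread_g < bin_width and spread_s < bin_width:
        # all points effectively coincide
        wsum = weights if weights is not None else np.ones_like(g)
        cg = float(np.average(g, weights=wsum))
        cs = float(np.average(s, weights=wsum))
        return PhasorCluster(cg, cs, 0.0, 0.0, g.size, roi, True)

    g_edges = np.arange(g.min() - bin_width, g.max() + 2 * bin_width, bin_width)
    s_edges = np.arange(s.min() - bin_width, s.max() + 2 * bin_width, bin_width)
    hist, g_edges, s_edges = np.histogram2d(g, s, bins=[g_edges, s_edges], weights=weights)
    ig, is_ = np.unravel_index(np.argmax(hist), hist.shape)
    mode_g = 0.5 * (g_edges[ig] + g_edges[ig + 1])
    mode_s = 0.5 * (s_edges[is_] + s_edges[is_ + 1])

    # moment estimate near the mode to size the fit window
    d2 = (g - mode_g) ** 2 + (s - mode_s) ** 2
    local = d2 <= (10 * bin_width) ** 2
    if local.sum() < 5:
        local = np.ones_like(g, dtype=bool)
    sg0 = max(float(g[local].std()), bin_width)
    ss0 = max(float(s[local].std()), bin_width)

    win = (np.abs(g - mode_g) <= window_sigmas * sg0) & (np.abs(s - mode_s) <= window_sigmas * ss0)
    gw, sw = g[win], s[win]
    ww = weights[win] if weights is not None else None
    hist_w, ge, se = np.histogram2d(
        gw,
        sw,
        bins=[
            np.arange(gw.min() - bin_width, gw.max() + 2 * bin_width, bin_width),
            np.arange(sw.min() - bin_width, sw.max() + 2 * bin_width, bin_width),
        ],
        weights=ww,
    )
    gc = 0.5 * (ge[:-1] + ge[1:])
    sc = 0.5 * (se[:-1] + se[1:])
    GG, SS = np.meshgrid(gc, sc, indexing="ij")
    z = hist_w.ravel()
    try:
        popt, _ = curve_fit(
            _gauss2d,
            (GG.ravel(), SS.ravel()),
            z,
            p0=[z.max(), mode_g, mode_s, sg0, ss0],
            maxfev=5000,
        )
        _, g0, s0, sgf, ssf = popt
        converged = True
    except (RuntimeError, ValueError):
        wsum = ww if ww is not None else np.ones_like(gw)
        g0 = float(np.average(gw, weights=wsum))
        s0 = float(np.average(sw, weights=wsum))
        sgf, ssf = sg0, ss0
        converged = False
    return PhasorCluster(float(g0), float(s0), abs(float(sgf)), abs(float(ssf)), int(win.sum()), roi, converged)


def lifetime_from_phasor(point, rep_rate_mhz: float) -> float:
    """Phase lifetime tau = S / (2 pi f G) in ns, f in cycles/ns."""
    if isinstance(point, PhasorCluster):
        g, s = point.centroid_g, point.centroid_s
    elif isinstance(point, PhasorPoint):
        g, s = point.g, point.s
    else:
        g, s = point
    if g <= 0:
        raise ValueError("lifetime undefined for G <= 0")
    f_per_ns = rep_rate_mhz * 1e-3
    return float(s / (2.0 * np.pi * f_per_ns * g))


def fret_efficiency(tau_d_ns: float, tau_da_ns: float) -> FretResult:
    """FRET efficiency from donor lifetime quenching: E = 1 - tau_DA/tau_D.

    Negative efficiencies (lifetime lengthening) are allowed but flagged.
    """
    if tau_d_ns <= 0:
        raise ValueError("donor lifetime must be positive")
    e = 1.0 - tau_da_ns / tau_d_ns
    return FretResult(float(tau_d_ns), float(tau_da_ns), float(e), lifetime_lengthened=e < 0)


def roi_lifetime(
    stack: DecayStack,
    roi: np.ndarray | str | None = None,
    *,
    min_photons: float = 20.0,
    bin_width: float = 0.005,
) -> tuple[PhasorCluster, float]:
    """Convenience pipeline: phasor transform -> cluster fit -> lifetime.

    Returns the fitted cluster and its lifetime in ns.
    """
    g, s, tot, _ = phasor_transform(stack, roi, min_photons=min_photons)
    finite = np.isfinite(g)
    cluster = cluster_fit(
        g[finite], s[finite], tot[finite], bin_width=bin_width,
        roi=roi if isinstance(roi, str) else "",
    )
    return cluster, lifetime_from_phasor(cluster, stack.rep_rate_mhz)
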