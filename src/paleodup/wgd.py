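"""Ks-distribution peak fitting and molecular-clock dating of WGD events.

Paralog Ks distributions are right-skewed, so Gaussian mixtures are fitted
on log-Ks with BIC model selection; component means are reported back on
the Ks scale. Dating uses the standard molecular clock T = Ks / (2 r) with
r the synonymous substitution rate per site per year (7.54e-9 for
Caryophyllales).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.mixture import GaussianMixture

from .kaks import KaKsResult
from .synteny import SyntenyBlock

__all__ = [
    "KsPeakModel",
    "ClockParams",
    "WGDEvent",
    "CARYOPHYLLALES_RATE",
    "anchor_ks_distribution",
    "fit_ks_peaks",
    "date_wgd",
    "estimate_rate",
]

#: Synonymous substitutions per site per year reported for Caryophyllales.
CARYOPHYLLALES_RATE = 7.54e-9

_SD_FLOOR = 1e-3


@dataclass
class KsPeakModel:
    """A Gaussian mixture over log-Ks, reported on the Ks scale."""

    n_components: int
    means: list[float]  # Ks units (exp of log-space means), ascending
    sds: list[float]  # log-space standard deviations, matching order
    weights: list[float]
    bic: float
    ks_range_used: tuple[float, float]


@dataclass(frozen=True)
class ClockParams:
    """Synonymous substitution rate r per site per year."""

    r: float

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("rate r must be positive")


@dataclass
class WGDEvent:
    """A dated whole-genome duplication."""

    ks_mode: float
    age_mya: float
    rate_used: ClockParams
    label: str = ""


def anchor_ks_distribution(
    blocks: list[SyntenyBlock],
    kaks: dict[tuple[str, str], KaKsResult],
    ks_cap: float = 3.0,
) -> list[float]:
    """Collect anchor-pair Ks values from syntenic blocks.

    Saturated pairs and values outside (0, ks_cap] are excluded. Each
    block's ``median_ks`` (over its own valid anchors, pre-cap) is stored
    back on the block as a side effect.
    """
    out: list[float] = []
    for b in blocks:
        block_ks = []
        for a in b.anchors:
            res = kaks.get((a.gene_a, a.gene_b)) or kaks.get((a.gene_b, a.gene_a))
            if res is None:
                raise KeyError(f"no Ka/Ks result for anchor {a.gene_a}/{a.gene_b}")
            if res.saturated or math.isnan(res.Ks):
                continue
            block_ks.append(res.Ks)
            if 0.0 < res.Ks <= ks_cap:
                out.append(res.Ks)
        b.median_ks = float(np.median(block_ks)) if block_ks else None
    return out


def _count_density_modes(gm: GaussianMixture, log_ks: np.ndarray) -> int:
    """Local maxima of the fitted mixture density over the data range."""
    lo, hi = float(log_ks.min()), float(log_ks.max())
    pad = 0.05 * (hi - lo) + 1e-6
    grid = np.linspace(lo - pad, hi + pad, 2000).reshape(-1, 1)
    dens = gm.score_samples(grid)
    d = np.diff(dens)
    return int(((d[:-1] > 0) & (d[1:] <= 0)).sum())


def fit_ks_peaks(
    ks_values: list[float],
    max_components: int = 4,
    seed: int = 0,
    n_init: int = 10,
) -> KsPeakModel:
    """Fit 1..max_components Gaussian mixtures on log-Ks; select by BIC
    among models whose components correspond to distinct density modes.

    EM happily splits one skewed peak into two heavily overlapping
    components; such a model says nothing extra about WGD events, so a
    candidate with fewer density modes than components is discarded before
    BIC comparison (the 1-component model is always a valid candidate).
    """
    ks = np.asarray([k for k in ks_values if k > 0], dtype=float)
    if len(ks) < 50:
        raise ValueError(
            f"need >= 50 positive Ks values to fit a mixture (got {len(ks)}); "
            "consider a KDE mode estimate instead"
        )
    log_ks = np.log(ks).reshape(-1, 1)
    ks_range = (float(ks.min()), float(ks.max()))
    if np.ptp(log_ks) == 0.0:
        # degenerate: all values identical
        return KsPeakModel(
            n_components=1,
            means=[float(ks[0])],
            sds=[_SD_FLOOR],
            weights=[1.0],
            bic=float("nan"),
            ks_range_used=ks_range,
        )
    best: GaussianMixture | None = None
    best_bic = math.inf
    for k in range(1, max_components + 1):
        gm = GaussianMixture(
            n_components=k,
            covariance_type="full",
            n_init=n_init,
            random_state=seed,
            reg_covar=1e-6,
        ).fit(log_ks)
        if k > 1 and _count_density_modes(gm, log_ks) < k:
            continue  # overlapping components: not k distinct peaks
        bic = gm.bic(log_ks)
        if bic < best_bic:
            best_bic = bic
            best = gm
    assert best is not None
    mu = best.means_.ravel()
    sd = np.sqrt(best.covariances_.reshape(-1))
    w = best.weights_.ravel()
    order = np.argsort(mu)
    return KsPeakModel(
        n_components=best.n_components,
        means=[float(np.exp(m)) for m in mu[order]],
        sds=[max(float(s), _SD_FLOOR) for s in sd[order]],
        weights=[float(x) for x in w[order]],
        bic=float(best_bic),
        ks_range_used=ks_range,
    )


def date_wgd(ks_mode: float, clock: ClockParams, label: str = "") -> WGDEvent:
    """Date a WGD from its Ks mode: T = Ks / (2 r), in million years."""
    if ks_mode <= 0:
        raise ValueError("ks_mode must be positive")
    age_mya = ks_mode / (2.0 * clock.r) / 1e6
    return WGDEvent(ks_mode=ks_mode, age_mya=age_mya, rate_used=clock, label=label)


def estimate_rate(ortholog_ks_peak: float, calibration_age_mya: float) -> ClockParams:
    """Calibrate r from an ortholog Ks peak and a known divergence age."""
    if ortholog_ks_peak <= 0 or calibration_age_mya <= 0:
        raise ValueError("ks peak and calibration age must be positive")
    return ClockParams(r=ortholog_ks_peak / (2.0 * calibration_age_mya * 1e6))
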