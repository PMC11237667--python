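"""Paralog Ks distributions and WGD peak detection.

After a whole-genome duplication, surviving paralog pairs accumulate
synonymous substitutions in parallel, so the distribution of pairwise Ks
over paralog pairs shows a peak per duplication event.  Here Ks values are
computed with NG86 + Jukes-Cantor (:func:`cilipop.codons.ks_ka_pair`),
filtered to an informative window, and peaks are called by fitting Gaussian
mixtures in log-Ks space with BIC model selection (Ks is positive and
right-skewed, so components are log-normal on the natural scale).
A kernel-density mode finder is provided as a cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import argrelmax
from scipy.stats import gaussian_kde
from sklearn.mixture import GaussianMixture

from .codons import GeneticCode, ks_ka_pair
from .io import SequenceRecord


@dataclass
class KsDistribution:
    """Ks values retained in (ks_min, ks_max], with filter bookkeeping."""

    values: np.ndarray
    ks_min: float
    ks_max: float
    n_input: int
    n_filtered_low: int = 0
    n_filtered_high: int = 0
    n_saturated: int = 0
    n_malformed: int = 0

    @property
    def n_retained(self) -> int:
        return len(self.values)


@dataclass
class KsMixtureFit:
    """Best-BIC Gaussian mixture on log Ks."""

    k: int
    weights: list[float]
    log_means: list[float]
    log_sds: list[float]
    log_likelihood: float
    bic: float
    bic_by_k: dict[int, float]
    seed: int
    n_restarts: int
    n_values: int


@dataclass
class PeakCall:
    """Retained mixture components as WGD-peak candidates."""

    modes: list[float]          # exp(log-mean), ascending
    weights: list[float]
    n_peaks: int
    min_weight: float
    dropped_weights: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------

def ks_for_pairs(
    pairs: list[tuple[SequenceRecord, SequenceRecord]],
    code: GeneticCode,
    ks_min: float = 0.01,
    ks_max: float = 5.0,
) -> tuple[KsDistribution, pd.DataFrame]:
    """Ks per paralog pair, filtered to the informative window.

    Values <= ks_min (allelic or assembly-duplicate artifacts) and > ks_max
    or saturated (p_s >= 3/4) are excluded with counts; malformed pairs
    (length mismatch, not a codon multiple) are skipped and counted.
    Returns the filtered distribution plus a per-pair table.
    """
    values: list[float] = []
    rows = []
    low = high = sat = bad = 0
    for rec_a, rec_b in pairs:
        pair_id = f"{rec_a.id}|{rec_b.id}"
        try:
            div = ks_ka_pair(rec_a.seq, rec_b.seq, code)
        except ValueError as exc:
            bad += 1
            rows.append({"pair_id": pair_id, "ks": np.nan, "ka": np.nan,
                         "status": f"malformed: {exc}"})
            continue
        ka = np.nan if div.ka is None else div.ka
        if div.saturated_s:
            sat += 1
            rows.append({"pair_id": pair_id, "ks": np.nan, "ka": ka,
                         "status": "saturated"})
            continue
        ks = div.ks
        if ks <= ks_min:
            low += 1
            status = "filtered_low"
        elif ks > ks_max:
            high += 1
            status = "filtered_high"
        else:
            values.append(ks)
            status = "retained"
        rows.append({"pair_id": pair_id, "ks": ks, "ka": ka, "status": status})
    dist = KsDistribution(
        values=np.array(values), ks_min=ks_min, ks_max=ks_max,
        n_input=len(pairs), n_filtered_low=low, n_filtered_high=high,
        n_saturated=sat, n_malformed=bad,
    )
    return dist, pd.DataFrame(rows)


def ks_distribution_from_values(
    ks: np.ndarray, ks_min: float = 0.01, ks_max: float = 5.0
) -> KsDistribution:
    """Filter a raw Ks array into a KsDistribution (no sequence step)."""
    ks = np.asarray(ks, dtype=float)
    finite = np.isfinite(ks)
    low = int((ks[finite] <= ks_min).sum())
    high = int((ks[finite] > ks_max).sum())
    keep = ks[finite & (ks > ks_min) & (ks <= ks_max)]
    return KsDistribution(
        values=keep, ks_min=ks_min, ks_max=ks_max, n_input=len(ks),
        n_filtered_low=low, n_filtered_high=high,
        n_saturated=int((~finite).sum()),
    )


def fit_ks_mixture(
    dist: KsDistribution,
    k_range: range | list[int] = range(1, 5),
    n_restarts: int = 10,
    seed: int = 0,
) -> KsMixtureFit:
    """EM Gaussian mixtures on log Ks; component count picked by BIC.

    Each k in ``k_range`` is fitted with ``n_restarts`` seeded
    initializations; the minimum-BIC model wins.  Deterministic given the
    seed.  Requires >= 50 retained values (below that a density plot is the
    honest output, not a mixture fit).
    """
    if dist.n_retained < 50:
        raise ValueError(
            f"only {dist.n_retained} Ks values; need >= 50 for a mixture fit "
            "(consider a density-only summary)"
        )
    x = np.log(dist.values).reshape(-1, 1)
    best = None
    bic_by_k: dict[int, float] = {}
    for k in k_range:
        gm = GaussianMixture(
            n_components=k, covariance_type="full",
            n_init=n_restarts, random_state=seed, max_iter=500,
        ).fit(x)
        bic = float(gm.bic(x))
        bic_by_k[k] = bic
        if best is None or bic < best[0]:
            best = (bic, k, gm)
    bic, k, gm = best
    order = np.argsort(gm.means_.ravel())
    return KsMixtureFit(
        k=k,
        weights=[float(gm.weights_[i]) for i in order],
        log_means=[float(gm.means_.ravel()[i]) for i in order],
        log_sds=[float(math.sqrt(gm.covariances_[i].ravel()[0])) for i in order],
        log_likelihood=float(gm.score(x) * len(x)),
        bic=bic, bic_by_k=bic_by_k, seed=seed,
        n_restarts=n_restarts, n_values=dist.n_retained,
    )


def call_wgd_peaks(fit: KsMixtureFit, min_weight: float = 0.1) -> PeakCall:
    """Components with weight >= min_weight, as Ks-scale peak modes.

    The retained peak count is the WGD-event proxy (e.g. two peaks vs one
    peak distinguishes a twice- from a once-duplicated genome).
    """
    kept = [(math.exp(m), w) for m, w in zip(fit.log_means, fit.weights)
            if w >= min_weight]
    dropped = [w for w in fit.weights if w < min_weight]
    kept.sort()
    return PeakCall(
        modes=[m for m, _ in kept],
        weights=[w for _, w in kept],
        n_peaks=len(kept),
        min_weight=min_weight,
        dropped_weights=dropped,
    )


def kde_modes(
    dist: KsDistribution, bw_method: float | str = "scott", grid: int = 512
) -> list[float]:
    """Kernel-density local maxima of log Ks, on the Ks scale.

    Cross-check for the mixture-based peak call; mode positions depend on
    the bandwidth, so this is advisory.
    """
    x = np.log(dist.values)
    kde = gaussian_kde(x, bw_method=bw_method)
    grid_x = np.linspace(x.min() - 0.5, x.max() + 0.5, grid)
    dens = kde(grid_x)
    peaks = argrelmax(dens)[0]
    return [float(math.exp(grid_x[i])) for i in peaks]


def fit_summary_frame(fit: KsMixtureFit) -> pd.DataFrame:
    return pd.DataFrame({
        "component": range(1, fit.k + 1),
        "weight": fit.weights,
        "log_mean": fit.log_means,
        "log_sd": fit.log_sds,
        "mode_ks": [math.exp(m) for m in fit.log_means],
    })
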