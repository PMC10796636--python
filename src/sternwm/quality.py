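"""Waveform features and spike-sorting quality metrics.

Each spike is embedded in a clustering feature space of energy (sum of
squared samples), signed peak amplitude, total area under the waveform
(sum of absolute samples), and the first five principal components of
the energy-normalized waveforms — eight coordinates in total.  PCA is
computed within channel, i.e. on all spikes recorded on an electrode
pooled across the units sorted there.

Isolation distance of a cluster of n spikes is the squared Mahalanobis
distance — under the cluster's own mean and covariance — of the n-th
closest non-member spike on the same electrode; it is undefined when
fewer non-member spikes than cluster members exist.  The projection
test separates two same-electrode clusters along the line joining their
means, in units of the pooled SD of the projected points.  SNR is the
mean-waveform amplitude (at the peak, or averaged over samples) divided
by the residual noise SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .model import AnalysisConfig, SessionRecord
from .spikes import cv2_score, isi_metrics, session_mean_rate

N_FEATURES = 8
N_PCS = 5


@dataclass
class FeatureMatrix:
    """Per-spike features (n_spikes x 8) plus the retained PCA basis."""

    features: np.ndarray  # columns: energy, peak, area, pc1..pc5
    pca_basis: np.ndarray  # n_samples x 5, orthonormal columns
    explained_variance: np.ndarray  # length 5, non-increasing
    degenerate: np.ndarray  # boolean flags for all-zero waveforms

    column_names = ("energy", "peak_amplitude", "total_area",
                    "pc1", "pc2", "pc3", "pc4", "pc5")


def waveform_features(waveforms: np.ndarray) -> FeatureMatrix:
    """Embed waveforms (n_spikes x n_samples, all one electrode) in the
    sorting-quality clustering feature space."""
    W = np.asarray(waveforms, dtype=float)
    if W.ndim != 2:
        raise ValueError("waveforms must be a 2-D matrix")
    n, m = W.shape
    if n < 6:
        raise ValueError("PCA needs at least 6 spikes")
    energy = np.sum(W ** 2, axis=1)
    peak_idx = np.argmax(np.abs(W), axis=1)
    peak = W[np.arange(n), peak_idx]
    area = np.sum(np.abs(W), axis=1)

    degenerate = energy == 0.0
    norm = np.where(degenerate, 1.0, np.sqrt(energy))
    X = W / norm[:, None]
    X[degenerate] = 0.0
    Xc = X - X.mean(axis=0)
    # SVD of the centered, energy-normalized waveforms
    _u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    basis = vt[:N_PCS].T  # n_samples x 5
    scores = Xc @ basis
    explained = (s[:N_PCS] ** 2) / (n - 1)

    feats = np.column_stack([energy, peak, area, scores])
    return FeatureMatrix(features=feats, pca_basis=basis,
                         explained_variance=explained, degenerate=degenerate)


def isolation_distance(cluster: np.ndarray, noise: np.ndarray
                       ) -> Optional[float]:
    """Squared Mahalanobis radius containing as many noise points as the
    cluster has members; ``None`` when undefined (too few noise points
    or a singular cluster covariance)."""
    cluster = np.asarray(cluster, dtype=float)
    noise = np.asarray(noise, dtype=float)
    n, d = cluster.shape
    if n < d + 1:
        return None
    if noise.shape[0] < n:
        return None
    mu = cluster.mean(axis=0)
    cov = np.cov(cluster, rowvar=False)
    try:
        cov_inv = np.linalg.inv(cov)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov_inv)):
        return None
    diff = noise - mu
    d2 = np.einsum("ij,jk,ik->i", diff, cov_inv, diff)
    d2_sorted = np.sort(d2)
    return float(d2_sorted[n - 1])


def projection_distance(cluster_a: np.ndarray, cluster_b: np.ndarray) -> float:
    """Separation of two clusters along the line joining their means,
    in units of the pooled SD of the projected points.  Coincident means
    give 0 by convention."""
    A = np.asarray(cluster_a, dtype=float)
    B = np.asarray(cluster_b, dtype=float)
    if A.size == 0 or B.size == 0:
        raise ValueError("both clusters must be non-empty")
    mu_a = A.mean(axis=0)
    mu_b = B.mean(axis=0)
    direction = mu_b - mu_a
    norm = np.linalg.norm(direction)
    if norm == 0:
        return 0.0
    u = direction / norm
    pa = A @ u
    pb = B @ u
    na, nb = pa.size, pb.size
    if na + nb < 3:
        return float("inf")
    var_pool = (np.sum((pa - pa.mean()) ** 2) + np.sum((pb - pb.mean()) ** 2)) \
        / (na + nb - 2)
    if var_pool == 0:
        return float("inf")
    return float(abs(pb.mean() - pa.mean()) / np.sqrt(var_pool))


def snr_metrics(waveforms: np.ndarray) -> dict:
    """Peak and mean signal-to-noise ratio of a unit's waveforms.

    Noise SD is the SD of the residuals (waveform minus mean waveform)
    pooled over all samples and spikes.
    """
    W = np.asarray(waveforms, dtype=float)
    if W.ndim != 2 or W.shape[0] < 2:
        raise ValueError("need at least 2 waveforms")
    mean_wf = W.mean(axis=0)
    resid = W - mean_wf
    noise_sd = float(resid.std(ddof=1))
    if noise_sd == 0:
        return {"snr_peak": float("nan"), "snr_mean": float("nan"),
                "noise_sd": 0.0}
    return {"snr_peak": float(np.max(np.abs(mean_wf)) / noise_sd),
            "snr_mean": float(np.mean(np.abs(mean_wf)) / noise_sd),
            "noise_sd": noise_sd}


@dataclass
class UnitQualityMetrics:
    unit_id: int
    electrode_id: int
    n_spikes: int
    pct_isi_below: float
    mean_rate_hz: float
    cv2: float
    snr_peak: float
    snr_mean: float
    isolation_distance: Optional[float]
    pairwise_projection_distances: list[tuple[int, float]] = field(default_factory=list)


def unit_quality_metrics(session: SessionRecord,
                         config: AnalysisConfig | None = None
                         ) -> list[UnitQualityMetrics]:
    """All sorting-quality metrics for every unit of a session.

    The noise set of a unit is every same-electrode spike assigned to
    another cluster; units alone on their electrode have undefined
    isolation distance and no projection distances.
    """
    cfg = config or AnalysisConfig()
    by_electrode: dict[int, list] = {}
    for u in session.units:
        by_electrode.setdefault(u.electrode_id, []).append(u)

    feats: dict[int, np.ndarray] = {}
    for eid, units in by_electrode.items():
        with_wf = [u for u in units if u.waveforms is not None and u.n_spikes > 0]
        pooled = [u.waveforms for u in with_wf]
        if pooled and sum(w.shape[0] for w in pooled) >= 6:
            fm = waveform_features(np.concatenate(pooled, axis=0))
            start = 0
            for u in with_wf:
                feats[u.unit_id] = fm.features[start:start + u.n_spikes]
                start += u.n_spikes

    out: list[UnitQualityMetrics] = []
    for u in session.units:
        isi = isi_metrics(u.spike_times, cfg.isi_violation_threshold)
        snr = {"snr_peak": float("nan"), "snr_mean": float("nan")}
        if u.waveforms is not None and u.n_spikes >= 2:
            snr = snr_metrics(u.waveforms)
        iso = None
        proj: list[tuple[int, float]] = []
        if u.unit_id in feats:
            others = [o for o in by_electrode[u.electrode_id]
                      if o.unit_id != u.unit_id and o.unit_id in feats]
            if others:
                noise = np.concatenate([feats[o.unit_id] for o in others])
                iso = isolation_distance(feats[u.unit_id], noise)
                proj = [(o.unit_id,
                         projection_distance(feats[u.unit_id], feats[o.unit_id]))
                        for o in others]
        out.append(UnitQualityMetrics(
            unit_id=u.unit_id, electrode_id=u.electrode_id,
            n_spikes=u.n_spikes, pct_isi_below=isi["pct_below"],
            mean_rate_hz=session_mean_rate(u, session),
            cv2=cv2_score(u.spike_times),
            snr_peak=snr["snr_peak"], snr_mean=snr["snr_mean"],
            isolation_distance=iso,
            pairwise_projection_distances=proj))
    return out


def quality_frame(metrics: list[UnitQualityMetrics]) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append(dict(
            unit_id=m.unit_id, electrode_id=m.electrode_id,
            n_spikes=m.n_spikes, pct_isi_below=m.pct_isi_below,
            mean_rate_hz=m.mean_rate_hz, cv2=m.cv2, snr_peak=m.snr_peak,
            snr_mean=m.snr_mean,
            isolation_distance=(np.nan if m.isolation_distance is None
                                else m.isolation_distance),
            mean_projection_distance=(
                np.nan if not m.pairwise_projection_distances
                else float(np.mean([d for _o, d in m.pairwise_projection_distances]))),
        ))
    return pd.DataFrame(rows)
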