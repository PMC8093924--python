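"""Study-level grouping of source components by weighted k-means.

Independent components from all subjects are clustered on a joint
feature space built from four blocks: equivalent-dipole location
(3 dims, weight 10), event-related potential (reduced to 4 dims,
weight 1), ERSP (4 dims, weight 1) and scalp map (6 dims, weight 1).
Non-spatial blocks are reduced by principal components fit across all
ICs pooled over both groups; every block is centered and scaled to unit
total variance before its weight is applied, so the dipole block carries
100x the variance of each unit-weight block.

Clusters must contain at least 70% of unique subjects to be retained for
the spectral-power analysis; a subject with several ICs in one cluster
counts once toward that fraction, and those ICs are averaged within
subject before any group statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "IcRecord",
    "FeatureMatrix",
    "ClusterSolution",
    "build_feature_matrix",
    "kmeans_cluster",
    "retain_by_subject_coverage",
    "cluster_centroid",
    "subject_cluster_means",
    "ic_records_from_epochs",
    "BLOCK_SPEC",
]

#: block name -> (reduced dimension, weight)
BLOCK_SPEC = {"dipole": (3, 10.0), "erp": (4, 1.0), "ersp": (4, 1.0), "scalp": (6, 1.0)}


@dataclass
class IcRecord:
    """Raw per-IC features before reduction."""

    subject_id: str
    ic_index: int
    dipole_xyz: np.ndarray  # (3,) MNI mm
    erp: np.ndarray  # any length >= 4
    ersp: np.ndarray  # any length >= 4
    scalp: np.ndarray  # any length >= 6


@dataclass
class FeatureMatrix:
    """Stacked, reduced, standardized and weighted IC features.

    ``X`` is (n_ics, 17); ``blocks`` maps block name to its column slice;
    ``dipoles`` keeps the raw (unweighted) dipole coordinates for
    centroid reporting.
    """

    X: np.ndarray
    ids: pd.DataFrame  # columns subject_id, ic_index
    blocks: dict
    dipoles: np.ndarray


def build_feature_matrix(records: list[IcRecord]) -> FeatureMatrix:
    """Assemble the weighted clustering features from per-IC records.

    Each non-spatial block is PCA-reduced to its configured dimension
    (components fit on all ICs pooled), then every block is centered,
    scaled to unit total variance, and multiplied by its weight.
    """
    if not any(records):
        raise ValueError("no IC records")
    for rec in records:
        if rec.dipole_xyz is None or len(np.atleast_1d(rec.dipole_xyz)) != 3:
            raise ValueError(f"missing dipole for {rec.subject_id}/{rec.ic_index}")

    raw = {
        "dipole": np.array([np.asarray(r.dipole_xyz, float) for r in records]),
        "erp": np.array([np.asarray(r.erp, float) for r in records]),
        "ersp": np.array([np.asarray(r.ersp, float) for r in records]),
        "scalp": np.array([np.asarray(r.scalp, float) for r in records]),
    }

    cols = []
    blocks = {}
    start = 0
    for name, (dim, weight) in BLOCK_SPEC.items():
        B = raw[name]
        if B.shape[1] < dim:
            raise ValueError(f"block {name} needs at least {dim} input dims")
        if name != "dipole" and B.shape[1] > dim:
            B = PCA(n_components=dim, svd_solver="full").fit_transform(B)
        B = B - B.mean(axis=0)
        total_var = B.var(axis=0).sum()
        if total_var <= 0:
            raise ValueError(f"degenerate (zero-variance) block {name}")
        B = B / np.sqrt(total_var) * weight
        cols.append(B)
        blocks[name] = slice(start, start + dim)
        start += dim

    X = np.hstack(cols)
    ids = pd.DataFrame(
        {"subject_id": [r.subject_id for r in records],
         "ic_index": [r.ic_index for r in records]}
    )
    return FeatureMatrix(X=X, ids=ids, blocks=blocks, dipoles=raw["dipole"])


@dataclass
class ClusterSolution:
    """k-means assignment of ICs plus retention bookkeeping.

    ``assignment`` has one row per IC with columns subject_id, ic_index,
    cluster.  ``unique_subject_fraction`` and ``retained`` are filled by
    :func:`retain_by_subject_coverage`.
    """

    k: int
    assignment: pd.DataFrame
    dipoles: np.ndarray
    wcss: float
    unique_subject_fraction: np.ndarray | None = None
    retained: np.ndarray | None = None

    def members(self, cluster: int) -> np.ndarray:
        return np.flatnonzero(self.assignment["cluster"].to_numpy() == cluster)

    def to_tsv(self, path) -> None:
        df = self.assignment.copy()
        if self.retained is not None:
            df["retained"] = self.retained[df["cluster"].to_numpy()]
        df.to_csv(path, sep="\t", index=False)


def kmeans_cluster(
    features: FeatureMatrix, k: int = 12, seed: int = 0, n_restarts: int = 50
) -> ClusterSolution:
    """Best-of-``n_restarts`` k-means (k-means++ seeding) on the features.

    Deterministic for a given seed; the restart with the lowest
    within-cluster sum of squares wins.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if features.X.shape[0] < k:
        raise ValueError("fewer ICs than clusters")
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    lab = km.fit_predict(features.X)
    assignment = features.ids.copy()
    assignment["cluster"] = lab
    return ClusterSolution(
        k=k, assignment=assignment, dipoles=features.dipoles, wcss=float(km.inertia_)
    )


def retain_by_subject_coverage(
    sol: ClusterSolution, n_subjects: int, threshold: float = 0.70
) -> ClusterSolution:
    """Retention rule: keep clusters covering >= threshold of subjects.

    The fraction is distinct subjects in the cluster over the total
    subject count (a subject with several ICs in one cluster counts
    once); retention uses >= (a cluster at exactly the threshold stays).
    """
    if n_subjects <= 0:
        raise ValueError("n_subjects must be positive")
    frac = np.zeros(sol.k)
    for c in range(sol.k):
        m = sol.assignment["cluster"] == c
        frac[c] = sol.assignment.loc[m, "subject_id"].nunique() / n_subjects
    return replace(sol, unique_subject_fraction=frac, retained=frac >= threshold)


def cluster_centroid(sol: ClusterSolution, cluster: int) -> tuple[np.ndarray, np.ndarray]:
    """Unweighted mean and per-axis SD of member dipole coordinates (mm)."""
    if cluster not in set(sol.assignment["cluster"]):
        raise ValueError(f"unknown cluster id {cluster}")
    d = sol.dipoles[sol.members(cluster)]
    sd = d.std(axis=0, ddof=0) if len(d) > 1 else np.zeros(3)
    return d.mean(axis=0), sd


def subject_cluster_means(
    sol: ClusterSolution, values: np.ndarray, cluster: int
) -> pd.DataFrame:
    """Average a per-IC quantity within subject for one cluster.

    ``values`` is (n_ics, ...) aligned with the assignment rows; subjects
    with several ICs in the cluster contribute one averaged row, so group
    statistics never double-count a subject.
    """
    idx = sol.members(cluster)
    sub = sol.assignment.iloc[idx]
    vals = np.asarray(values)[idx]
    out = []
    for sid, grp in sub.groupby("subject_id", sort=True):
        pos = [sub.index.get_loc(i) for i in grp.index]
        out.append((sid, vals[pos].mean(axis=0)))
    df = pd.DataFrame({"subject_id": [o[0] for o in out]})
    df["value"] = [o[1] for o in out]
    return df


# ---------------------------------------------------------------------------
# feature extraction from epochs
# ---------------------------------------------------------------------------

#: virtual sensor directions for the synthetic scalp-map proxy
_SCALP_DIRS = None


def _scalp_positions(n: int = 20, radius: float = 110.0) -> np.ndarray:
    """Fixed quasi-uniform positions on an upper-hemisphere cap (mm)."""
    global _SCALP_DIRS
    if _SCALP_DIRS is None or len(_SCALP_DIRS) != n:
        i = np.arange(n) + 0.5
        phi = np.arccos(i / n)  # upper hemisphere
        theta = np.pi * (1 + 5**0.5) * i
        _SCALP_DIRS = np.stack(
            [
                radius * np.sin(phi) * np.cos(theta),
                radius * np.sin(phi) * np.sin(theta) - 18.0,
                radius * np.cos(phi) + 18.0,
            ],
            axis=1,
        )
    return _SCALP_DIRS


def ic_records_from_epochs(
    epochs_list: list,
    band_window_spec=None,
    erp_points: int = 32,
) -> list[IcRecord]:
    """Summarize every subject's ICs into clustering features.

    ERP: the trial-averaged waveform from stimulus onset to +600 ms,
    resampled to ``erp_points`` samples.  ERSP: band x window mean dB
    values (the spectral features the statistics stage uses).  Scalp map:
    a synthetic inverse-square projection of the dipole onto fixed
    virtual sensors — a geometry proxy used because the simulator has no
    forward model.
    """
    from . import ersp as ersp_mod

    spec = band_window_spec or ersp_mod.BandWindowSpec()
    sensors = _scalp_positions()
    records = []
    for ep in epochs_list:
        times = ep.times_ms
        erp_sel = (times >= 0) & (times <= 600)
        for k in range(ep.n_sources):
            erp_wave = ep.activations[k].mean(axis=1)[erp_sel]
            xp = np.linspace(0, 1, erp_wave.size)
            erp_feat = np.interp(np.linspace(0, 1, erp_points), xp, erp_wave)

            tf = ersp_mod.compute_ersp(ep, k)
            tf = ersp_mod.baseline_normalize(tf)
            ersp_feat = np.array(
                [
                    ersp_mod.band_window_mean(tf, band, win)
                    for band in spec.bands.values()
                    for win in spec.windows.values()
                ]
            )

            d2 = ((sensors - ep.dipole_mni[k]) ** 2).sum(axis=1)
            scalp_feat = 1.0 / np.maximum(d2, 100.0)
            scalp_feat = scalp_feat / np.linalg.norm(scalp_feat)

            records.append(
                IcRecord(
                    subject_id=ep.subject_id,
                    ic_index=k,
                    dipole_xyz=ep.dipole_mni[k],
                    erp=erp_feat,
                    ersp=ersp_feat,
                    scalp=scalp_feat,
                )
            )
    return records
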