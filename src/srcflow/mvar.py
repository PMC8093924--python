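"""Sliding-window MVAR fits (Vieira-Morf) and renormalized PDC.

The effective-connectivity stage models the K retained IC activations as
a multivariate autoregressive (MVAR) process

    x(t) = sum_{r=1..p} A_r x(t-r) + e(t),   e ~ N(0, Sigma)

fit within 1-second sliding windows pooled across trials with the
Vieira-Morf algorithm (multichannel Burg lattice with geometric-mean
reflection normalization, stable by construction).  Directed influence
j -> i at normalized frequency phi = f/fs is quantified by renormalized
partial directed coherence (rPDC):

    Abar_ij(phi) = -sum_r a_ij(r) exp(-i 2 pi phi r)
    Q = (Re Abar_ij, Im Abar_ij)^T
    rPDC_{j->i}(phi) = Q^T V^{-1}(phi) Q

where V is the 2x2 covariance of Q induced by the estimator covariance of
the coefficients a_ij(1..p).  The renormalization makes rPDC non-negative
and invariant to channel scaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .synthio import SourceEpochs

__all__ = [
    "DataRatio",
    "MvarWindowModel",
    "IcConnectivityTensor",
    "select_top_ics",
    "check_data_ratio",
    "fit_mvar_window",
    "rpdc",
    "log_freq_grid",
    "sliding_connectivity",
]


# ---------------------------------------------------------------------------
# IC selection and the data-ratio rule
# ---------------------------------------------------------------------------


def select_top_ics(epochs: SourceEpochs, k_keep: int = 10) -> SourceEpochs:
    """Restrict a subject to the top ``k_keep`` ICs by explained variance.

    ``variance_rank`` 1 is the highest-variance IC.  If the subject has
    fewer than ``k_keep`` ICs, all are kept.  Sources are reordered by
    rank so downstream indexing is variance-ordered.
    """
    order = np.argsort(epochs.variance_rank)
    keep = order[: min(k_keep, epochs.n_sources)]
    return SourceEpochs(
        subject_id=epochs.subject_id,
        activations=epochs.activations[keep],
        fs=epochs.fs,
        dipole_mni=epochs.dipole_mni[keep],
        variance_rank=epochs.variance_rank[keep],
        epoch_window=epochs.epoch_window,
        trial_ref=epochs.trial_ref,
    )


@dataclass(frozen=True)
class DataRatio:
    """Result of the MVAR data-sufficiency rule (K^2 p + 1)/(Ns Nt) <= 0.1."""

    ratio: float
    admissible: bool
    max_p: int


def check_data_ratio(K: int, p: int, n_samples: int, n_trials: int) -> DataRatio:
    """Parameters-to-data ratio rule for MVAR fitting.

    ratio = (K^2 p + 1) / (Ns Nt); the fit is admissible when the ratio is
    at most 0.1.  ``max_p`` is the largest admissible model order for the
    given K, Ns, Nt (0 when even p = 1 is inadmissible).  Comparisons are
    done in exact integer arithmetic.
    """
    if min(K, p, n_samples, n_trials) <= 0:
        raise ValueError("all counts must be positive")
    num = K * K * p + 1
    den = n_samples * n_trials
    admissible = 10 * num <= den
    max_p = (den - 10) // (10 * K * K)
    return DataRatio(ratio=num / den, admissible=bool(admissible), max_p=int(max_p))


# ---------------------------------------------------------------------------
# Vieira-Morf estimator
# ---------------------------------------------------------------------------


@dataclass
class MvarWindowModel:
    """MVAR(p) fit for one sliding-window position.

    ``coeffs[r-1]`` is A_r in x(t) = sum_r A_r x(t-r) + e.  The estimator
    covariance of row-i coefficients against source j is assembled from
    ``resid_cov[i, i]`` and the (j, j) lag-block of
    ``regressor_cov_inv`` divided by ``n_eff``.
    """

    coeffs: np.ndarray  # (p, K, K)
    resid_cov: np.ndarray  # (K, K)
    regressor_cov_inv: np.ndarray  # (K p, K p), lag-major blocks
    n_eff: int
    window_center_ms: float | None = None

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_sources(self) -> int:
        return self.coeffs.shape[1]

    def coefficient_covariance(self, i: int, j: int) -> np.ndarray:
        """p x p covariance of the estimated a_ij(1..p)."""
        p, K = self.order, self.n_sources
        idx = j + K * np.arange(p)
        block = self.regressor_cov_inv[np.ix_(idx, idx)]
        return self.resid_cov[i, i] * block / self.n_eff


def fit_mvar_window(data: np.ndarray, p: int) -> MvarWindowModel:
    """Fit an MVAR(p) to one window by the Vieira-Morf lattice recursion.

    ``data`` has shape (K, Ns, Nt): channels x samples x trials, already
    mean-removed per channel and trial.  Forward/backward prediction
    errors are pooled across trials; reflection coefficients use the
    normalized (geometric-mean) partial correlation, which keeps the fit
    stable by construction.  Residual covariance comes from the final
    forward residuals.
    """
    x = np.asarray(data, dtype=float)
    if x.ndim == 2:
        x = x[:, :, None]
    K, Ns, Nt = x.shape
    if p < 1 or p >= Ns:
        raise ValueError("model order must satisfy 1 <= p < n_samples")

    f = x.copy()
    b = x.copy()
    # error-filter coefficients: x(t) + sum_k Afil[k] x(t-k) = e(t)
    Afil: list[np.ndarray] = []
    Bfil: list[np.ndarray] = []

    for m in range(1, p + 1):
        F = f[:, m:, :].reshape(K, -1)
        Bm = b[:, m - 1 : Ns - 1, :].reshape(K, -1)
        Rff = F @ F.T
        Rbb = Bm @ Bm.T
        Rfb = F @ Bm.T
        try:
            Sf = np.linalg.cholesky(Rff)
            Sb = np.linalg.cholesky(Rbb)
        except np.linalg.LinAlgError as exc:  # rank-deficient window
            raise np.linalg.LinAlgError(
                f"singular prediction-error covariance at order {m}; "
                "input window is rank deficient"
            ) from exc
        Sf_inv = np.linalg.inv(Sf)
        Sb_inv = np.linalg.inv(Sb)
        rho = Sf_inv @ Rfb @ Sb_inv.T
        Amm = -Sf @ rho @ Sb_inv
        Bmm = -Sb @ rho.T @ Sf_inv

        f_new = f.copy()
        b_new = b.copy()
        seg_f = f[:, m:, :]
        seg_b = b[:, m - 1 : Ns - 1, :]
        f_new[:, m:, :] = seg_f + np.einsum("kl,lst->kst", Amm, seg_b)
        b_new[:, m:, :] = seg_b + np.einsum("kl,lst->kst", Bmm, seg_f)
        f, b = f_new, b_new

        A_next = [Afil[k] + Amm @ Bfil[m - 2 - k] for k in range(m - 1)]
        B_next = [Bfil[k] + Bmm @ Afil[m - 2 - k] for k in range(m - 1)]
        Afil = A_next + [Amm]
        Bfil = B_next + [Bmm]

    n_eff = (Ns - p) * Nt
    Ffin = f[:, p:, :].reshape(K, -1)
    resid_cov = Ffin @ Ffin.T / n_eff
    coeffs = -np.stack(Afil)  # AR convention: x(t) = sum A_r x(t-r) + e

    # regressor covariance from the same windowed data (lag-major stacking)
    Z = np.empty((K * p, (Ns - p) * Nt))
    for r in range(1, p + 1):
        Z[(r - 1) * K : r * K] = x[:, p - r : Ns - r, :].reshape(K, -1)
    R = Z @ Z.T / n_eff
    try:
        R_inv = np.linalg.inv(R)
    except np.linalg.LinAlgError:
        R_inv = np.linalg.pinv(R)
    return MvarWindowModel(
        coeffs=coeffs, resid_cov=resid_cov, regressor_cov_inv=R_inv, n_eff=n_eff
    )


# ---------------------------------------------------------------------------
# renormalized partial directed coherence
# ---------------------------------------------------------------------------


def rpdc(model: MvarWindowModel, freqs: np.ndarray, fs: float) -> np.ndarray:
    """rPDC for every ordered source pair at the given frequencies.

    Returns an array indexed ``[leader j, follower i, frequency]`` holding
    rPDC_{j->i}; the diagonal (self-influence) is NaN.  A numerically
    singular 2x2 covariance V is ridge-regularized by 1e-12 of its trace.
    """
    freqs = np.asarray(freqs, dtype=float)
    p, K = model.order, model.n_sources
    phi = freqs / fs
    r = np.arange(1, p + 1)
    # T(phi): rows (-cos 2 pi phi r) and (sin 2 pi phi r)
    ang = 2.0 * np.pi * phi[:, None] * r[None, :]
    Tmat = np.stack([-np.cos(ang), np.sin(ang)], axis=1)  # (F, 2, p)

    out = np.full((K, K, freqs.size), np.nan)
    for i in range(K):
        for j in range(K):
            if i == j:
                continue
            a = model.coeffs[:, i, j]
            C = model.coefficient_covariance(i, j)
            Q = Tmat @ a  # (F, 2)
            V = np.einsum("fap,pq,fbq->fab", Tmat, C, Tmat)  # (F, 2, 2)
            det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] * V[:, 1, 0]
            bad = det <= np.finfo(float).tiny
            if np.any(bad):
                eps = 1e-12 * np.trace(V, axis1=1, axis2=2)
                V = V.copy()
                V[bad, 0, 0] += eps[bad]
                V[bad, 1, 1] += eps[bad]
                det = V[:, 0, 0] * V[:, 1, 1] - V[:, 0, 1] * V[:, 1, 0]
            # Q^T V^{-1} Q with analytic 2x2 inverse
            q0, q1 = Q[:, 0], Q[:, 1]
            num = (
                V[:, 1, 1] * q0 * q0 - 2.0 * V[:, 0, 1] * q0 * q1 + V[:, 0, 0] * q1 * q1
            )
            out[j, i] = num / det
    return out


def log_freq_grid(n: int = 30, lo: float = 2.0, hi: float = 49.0) -> np.ndarray:
    """Log-equally-spaced frequency grid, endpoints included."""
    return np.logspace(np.log10(lo), np.log10(hi), n)


# ---------------------------------------------------------------------------
# sliding-window connectivity
# ---------------------------------------------------------------------------


@dataclass
class IcConnectivityTensor:
    """Per-subject rPDC over IC pairs, frequencies and window positions.

    ``values[j, i, f, t]`` is rPDC leader j -> follower i at frequency
    ``freqs[f]`` and window center ``times[t]`` (ms relative to stimulus).
    The diagonal is NaN.  ``dipole_mni`` carries the per-IC dipole used
    for ROI projection.
    """

    values: np.ndarray  # (K, K, F, T)
    freqs: np.ndarray
    times: np.ndarray
    subject_id: str
    dipole_mni: np.ndarray | None = None


def sliding_connectivity(
    epochs: SourceEpochs,
    window_ms: float = 1000.0,
    step_ms: float = 20.0,
    freqs: np.ndarray | None = None,
    order: int | None = None,
) -> IcConnectivityTensor:
    """Sliding-window Vieira-Morf + rPDC over a whole epoch set.

    Window positions start at the epoch onset and advance by ``step_ms``;
    the count is (T_epoch - window) / step with the final endpoint
    dropped, so 4-s epochs with a 1-s window and 20-ms steps give 150
    positions.  Each window is mean-removed per channel and trial before
    fitting.  ``order`` defaults to the largest admissible order under
    the data-ratio rule; an explicit inadmissible order raises.
    """
    if freqs is None:
        freqs = log_freq_grid()
    K = epochs.n_sources
    fs = epochs.fs
    n_win_samples = int(round(window_ms * fs / 1000.0))
    epoch_ms = epochs.n_samples * 1000.0 / fs
    # position count in ms arithmetic, final endpoint dropped
    n_positions = int((epoch_ms - window_ms) / step_ms)
    if n_positions < 1:
        raise ValueError("epoch shorter than one window")
    starts = np.round(np.arange(n_positions) * step_ms * fs / 1000.0).astype(int)
    if np.max(freqs) > fs / 2:
        raise ValueError("frequency grid exceeds Nyquist")

    ratio0 = check_data_ratio(K, 1, n_win_samples, epochs.n_trials)
    if order is None:
        order = ratio0.max_p
        if order < 1:
            raise ValueError("no admissible model order for this data size")
    else:
        dr = check_data_ratio(K, order, n_win_samples, epochs.n_trials)
        if not dr.admissible:
            raise ValueError(
                f"order {order} inadmissible: ratio {dr.ratio:.4f} > 0.1 "
                f"(max admissible order {dr.max_p})"
            )

    t0 = epochs.epoch_window[0]
    times = t0 + np.arange(n_positions) * step_ms + window_ms / 2.0

    values = np.empty((K, K, len(freqs), n_positions))
    X = epochs.activations
    for w in range(n_positions):
        sl = X[:, starts[w] : starts[w] + n_win_samples, :]
        sl = sl - sl.mean(axis=1, keepdims=True)
        model = fit_mvar_window(sl, order)
        model.window_center_ms = float(times[w])
        values[:, :, :, w] = rpdc(model, freqs, fs)

    return IcConnectivityTensor(
        values=values,
        freqs=np.asarray(freqs, dtype=float),
        times=times,
        subject_id=epochs.subject_id,
        dipole_mni=epochs.dipole_mni,
    )
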