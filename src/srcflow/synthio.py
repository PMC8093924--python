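"""Synthetic cohorts, trial tables, and source-level epochs.

Everything downstream of EEG preprocessing starts from *source-level
epochs*: independent-component (IC) activations around a flanker stimulus,
each IC carrying an equivalent-dipole location in MNI space.  This module
simulates that entry point from a ground-truth coupled MVAR network so
that connectivity and spectral-power recovery can be checked against a
known answer.

The default generator parameters describe a pediatric
chronic-tic-disorder (CTD) case-control cohort: 35 healthy
controls (HC) and 60 CTD children aged 8-12, a flanker task with 72
congruent and 144 incongruent trials, epochs from -2000 to +2000 ms
around stimulus onset, and group differences in reaction time, gender
ratio, IQ and clinical scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "GroupEffectSpec",
    "TaskSpec",
    "GroupEffect",
    "PowerEffect",
    "GroundTruthNetwork",
    "SourceEpochs",
    "generate_cohort",
    "generate_trial_table",
    "generate_source_epochs",
    "companion_spectral_radius",
    "stable_random_network",
    "default_ground_truth",
    "save_epochs",
    "load_epochs",
    "save_table",
    "load_table",
]

EPOCH_WINDOW_MS = (-2000.0, 2000.0)

COHORT_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "gender",
    "iq",
    "ygtss_total",
    "ygtss_impairment",
    "cybocs",
    "swan",
    "medicated",
    "rt_mean_ms",
]


# ---------------------------------------------------------------------------
# cohort metadata
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupEffectSpec:
    """Configured between-group differences realized by :func:`generate_cohort`.

    Attributes mirror the instruments recorded for the cohort.  Each pair
    gives (HC, CTD) parameters; scores are clipped to instrument ranges
    (YGTSS total 0-100, impairment 0-50, ages 8-12).
    """

    age_mean: tuple[float, float] = (9.6, 10.0)
    age_sd: float = 1.4
    male_fraction: tuple[float, float] = (0.46, 0.80)
    iq_mean: tuple[float, float] = (115.0, 110.0)
    iq_sd: tuple[float, float] = (15.0, 13.0)
    ygtss_total_mean: float = 27.0
    ygtss_total_sd: float = 8.6
    ygtss_impairment_mean: float = 20.0
    ygtss_impairment_sd: float = 10.0
    cybocs_mean: tuple[float, float] = (1.0, 6.0)
    cybocs_sd: tuple[float, float] = (1.5, 6.0)
    swan_mean: tuple[float, float] = (0.0, 0.5)
    swan_sd: tuple[float, float] = (1.0, 1.0)
    medicated_fraction: tuple[float, float] = (0.0, 11.0 / 60.0)
    #: latent per-subject mean reaction time (congruent trials), ms
    rt_mean: float = 564.0
    rt_between_subject_sd: float = 80.0
    #: CTD minus HC shift of the latent RT mean, ms
    rt_shift_ms: float = -57.0

    @classmethod
    def null(cls) -> "GroupEffectSpec":
        """Both groups drawn from the identical (HC) distributions."""
        return cls(
            age_mean=(9.6, 9.6),
            male_fraction=(0.5, 0.5),
            iq_mean=(112.0, 112.0),
            iq_sd=(14.0, 14.0),
            ygtss_total_mean=0.0,
            ygtss_total_sd=0.0,
            ygtss_impairment_mean=0.0,
            ygtss_impairment_sd=0.0,
            cybocs_mean=(1.0, 1.0),
            cybocs_sd=(1.5, 1.5),
            swan_mean=(0.0, 0.0),
            medicated_fraction=(0.0, 0.0),
            rt_shift_ms=0.0,
        )


def generate_cohort(
    n_hc: int,
    n_ctd: int,
    effects: GroupEffectSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Draw a subject table with configured group differences.

    Returns a DataFrame with one row per subject (HC rows first) and the
    columns in :data:`COHORT_COLUMNS`.  Reproducible for a given seed.
    """
    if n_hc < 2 or n_ctd < 2:
        raise ValueError("need at least 2 subjects per group")
    eff = effects if effects is not None else GroupEffectSpec()
    rng = np.random.default_rng(seed)

    rows = []
    for gi, (grp, n) in enumerate((("HC", n_hc), ("CTD", n_ctd))):
        age = np.clip(rng.normal(eff.age_mean[gi], eff.age_sd, n), 8.0, 12.0)
        male = rng.random(n) < eff.male_fraction[gi]
        iq = np.clip(rng.normal(eff.iq_mean[gi], eff.iq_sd[gi], n), 55, 160)
        if grp == "CTD":
            ygtss = np.clip(
                rng.normal(eff.ygtss_total_mean, eff.ygtss_total_sd, n), 0, 100
            )
            impair = np.clip(
                rng.normal(eff.ygtss_impairment_mean, eff.ygtss_impairment_sd, n),
                0,
                50,
            )
        else:
            ygtss = np.zeros(n)
            impair = np.zeros(n)
        cybocs = np.clip(rng.normal(eff.cybocs_mean[gi], eff.cybocs_sd[gi], n), 0, 40)
        swan = np.clip(rng.normal(eff.swan_mean[gi], eff.swan_sd[gi], n), -3, 3)
        med = rng.random(n) < eff.medicated_fraction[gi]
        rt_mu = eff.rt_mean + (eff.rt_shift_ms if grp == "CTD" else 0.0)
        rt = np.clip(rng.normal(rt_mu, eff.rt_between_subject_sd, n), 250, 1100)
        for k in range(n):
            rows.append(
                dict(
                    subject_id=f"{grp.lower()}{k:03d}",
                    group=grp,
                    age=float(age[k]),
                    gender="M" if male[k] else "F",
                    iq=float(iq[k]),
                    ygtss_total=float(ygtss[k]),
                    ygtss_impairment=float(impair[k]),
                    cybocs=float(cybocs[k]),
                    swan=float(swan[k]),
                    medicated=bool(med[k]),
                    rt_mean_ms=float(rt[k]),
                )
            )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)


# ---------------------------------------------------------------------------
# trial tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TaskSpec:
    """Flanker-task configuration: trial counts, accuracies, RT model.

    Reaction times follow a lognormal with subject-level mean ``rt_mean_ms``
    (from the cohort table) for congruent trials, shifted by
    ``incongruent_rt_shift_ms`` for incongruent trials.  Draws exceeding
    ``rt_deadline_ms`` (trial expiration) and random lapses are recorded as
    no-response trials (rt absent, incorrect).
    """

    n_congruent: int = 72
    n_incongruent: int = 144
    #: P(correct | responded), per (group, condition)
    p_correct: dict = field(
        default_factory=lambda: {
            ("HC", "congruent"): 0.78,
            ("HC", "incongruent"): 0.65,
            ("CTD", "congruent"): 0.75,
            ("CTD", "incongruent"): 0.59,
        }
    )
    rt_within_subject_sd: dict = field(
        default_factory=lambda: {"congruent": 130.0, "incongruent": 115.0}
    )
    incongruent_rt_shift_ms: float = 40.0
    rt_deadline_ms: float = 1300.0
    lapse_rate: float = 0.02

    def accuracy(self, group: str, condition: str) -> float:
        p = self.p_correct[(group, condition)]
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"accuracy probability {p} outside [0, 1]")
        return p


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def generate_trial_table(
    subject: pd.Series | dict,
    task: TaskSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate one subject's trial-by-trial flanker behavior.

    Returns columns ``trial_index, condition, correct, rt`` with exact
    per-condition counts, randomized order, and rt = NaN on no-response
    trials.
    """
    task = task if task is not None else TaskSpec()
    rng = np.random.default_rng(seed)
    group = subject["group"]
    rt_base = float(subject.get("rt_mean_ms", 550.0))

    conditions = np.array(
        ["congruent"] * task.n_congruent + ["incongruent"] * task.n_incongruent
    )
    rng.shuffle(conditions)

    n = len(conditions)
    rt = np.empty(n)
    correct = np.empty(n, dtype=bool)
    for cond in ("congruent", "incongruent"):
        m = conditions == cond
        mean = rt_base + (task.incongruent_rt_shift_ms if cond == "incongruent" else 0)
        mu, sig = _lognormal_params(mean, task.rt_within_subject_sd[cond])
        rt[m] = rng.lognormal(mu, sig, m.sum())
        correct[m] = rng.random(m.sum()) < task.accuracy(group, cond)

    lapse = rng.random(n) < task.lapse_rate
    no_resp = lapse | (rt > task.rt_deadline_ms)
    rt[no_resp] = np.nan
    correct[no_resp] = False

    return pd.DataFrame(
        {
            "trial_index": np.arange(n),
            "condition": conditions,
            "correct": correct,
            "rt": rt,
        }
    )


# ---------------------------------------------------------------------------
# ground-truth networks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupEffect:
    """Multiplicative scaling of one directed coupling for CTD subjects.

    ``edge`` is (sender j, receiver i); all lags of coefficient a_ij are
    multiplied by ``multiplier`` for samples whose post-stimulus time lies
    within ``window_ms``.  ``band_hz`` documents where the planted coupling
    resonates (metadata; the scaling itself is broadband in lag space).
    """

    edge: tuple[int, int]
    multiplier: float
    window_ms: tuple[float, float] = (0.0, 2000.0)
    band_hz: tuple[float, float] | None = None


@dataclass(frozen=True)
class PowerEffect:
    """Band-limited oscillatory burst added time-locked to the stimulus.

    ``db_offset`` maps group name to the burst size in dB relative to that
    source's pre-stimulus band power (0 dB = no burst).
    """

    source: int
    band_hz: tuple[float, float]
    window_ms: tuple[float, float]
    db_offset: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GroundTruthNetwork:
    """A stationary MVAR(p) generative network with planted group effects.

    ``coeffs[r-1, i, j]`` is a_ij(r): the weight of source j's value r lags
    back in source i's present value.  ``noise_cov`` is the innovation
    covariance.  ``centroids_mni`` gives the nominal dipole location of
    each source; per-subject dipoles are jittered around these.
    """

    coeffs: np.ndarray  # (p, K, K)
    noise_cov: np.ndarray  # (K, K)
    centroids_mni: np.ndarray  # (K, 3)
    group_effects: tuple[GroupEffect, ...] = ()
    power_effects: tuple[PowerEffect, ...] = ()

    def __post_init__(self):
        A = np.asarray(self.coeffs, dtype=float)
        S = np.asarray(self.noise_cov, dtype=float)
        if A.ndim != 3 or A.shape[1] != A.shape[2]:
            raise ValueError("coeffs must have shape (p, K, K)")
        if S.shape != (A.shape[1], A.shape[1]):
            raise ValueError("noise_cov shape mismatch")
        if not np.allclose(S, S.T):
            raise ValueError("noise_cov must be symmetric")
        if np.linalg.eigvalsh(S).min() <= 0:
            raise ValueError("noise_cov must be positive definite")
        if companion_spectral_radius(A) >= 1.0:
            raise ValueError("unstable network: companion spectral radius >= 1")

    @property
    def n_sources(self) -> int:
        return self.coeffs.shape[1]

    @property
    def order(self) -> int:
        return self.coeffs.shape[0]


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the MVAR companion matrix (stationary iff < 1)."""
    A = np.asarray(coeffs, dtype=float)
    p, K, _ = A.shape
    comp = np.zeros((K * p, K * p))
    comp[:K, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[K:, :-K] = np.eye(K * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


def stable_random_network(
    n_sources: int,
    order: int = 2,
    density: float = 0.15,
    strength: float = 0.4,
    seed: int = 0,
    centroids_mni: np.ndarray | None = None,
    target_radius: float = 0.9,
    ensure_edges: tuple = (),
) -> GroundTruthNetwork:
    """Random sparse coupling network rescaled to a stable spectral radius.

    Diagonal (self) lags get damped oscillatory AR terms; off-diagonal
    couplings are present independently with probability ``density``.
    ``ensure_edges`` lists (sender, receiver) pairs whose lag-1 coupling is
    forced to ``strength`` so that multiplicative group effects planted on
    them act on a nonzero coefficient.
    """
    rng = np.random.default_rng(seed)
    K, p = n_sources, order
    A = np.zeros((p, K, K))
    # self-dynamics: mildly resonant AR(2)-style poles
    A[0, np.arange(K), np.arange(K)] = rng.uniform(0.3, 0.6, K)
    if p > 1:
        A[1, np.arange(K), np.arange(K)] = rng.uniform(-0.4, -0.1, K)
    off = (rng.random((p, K, K)) < density) & ~np.eye(K, dtype=bool)
    A[off] = rng.normal(0.0, strength, off.sum())
    for j, i in ensure_edges:
        if i == j:
            raise ValueError("ensure_edges must be off-diagonal (sender != receiver)")
        A[0, i, j] = strength
    rho = companion_spectral_radius(A)
    if rho >= target_radius:
        A *= target_radius / rho
        # rescaling lag r by c^r would preserve pole angles; a flat rescale
        # is sufficient here and re-checked below
        while companion_spectral_radius(A) >= 1.0:  # pragma: no cover
            A *= 0.95
    if centroids_mni is None:
        centroids_mni = _default_centroids(K, rng)
    cov = np.eye(K)
    return GroundTruthNetwork(A, cov, np.asarray(centroids_mni, dtype=float))


def _default_centroids(K: int, rng: np.random.Generator) -> np.ndarray:
    """Spread K nominal dipoles through a brain-shaped ellipsoid."""
    pts = []
    while len(pts) < K:
        q = rng.uniform(-1, 1, 3)
        if (q**2).sum() <= 1:
            pts.append(q * np.array([55.0, 70.0, 50.0]) + np.array([0.0, -18.0, 18.0]))
    return np.array(pts)


def default_ground_truth(seed: int = 0) -> GroundTruthNetwork:
    """Study-sized default: 10 sources, order-2 couplings, one CTD-scaled
    edge (source 0 -> 1, x2 between 100 and 700 ms) and an anterior alpha
    burst attenuated in CTD (+2 dB HC vs +1 dB CTD at 250-600 ms)."""
    net = stable_random_network(10, order=2, seed=seed, ensure_edges=((0, 1),))
    return replace(
        net,
        group_effects=(
            GroupEffect(edge=(0, 1), multiplier=2.0, window_ms=(100.0, 700.0)),
        ),
        power_effects=(
            PowerEffect(
                source=2,
                band_hz=(8.0, 12.0),
                window_ms=(250.0, 600.0),
                db_offset={"HC": 2.0, "CTD": 1.0},
            ),
        ),
    )


# ---------------------------------------------------------------------------
# source-level epochs
# ---------------------------------------------------------------------------


@dataclass
class SourceEpochs:
    """One subject's IC activations around the stimulus.

    ``activations`` has shape (K sources, T samples, N trials) spanning
    ``epoch_window`` ms around stimulus onset at ``fs`` Hz.  ``dipole_mni``
    holds the per-IC equivalent-dipole location; ``variance_rank`` the
    explained-variance order (1 = most variance).
    """

    subject_id: str
    activations: np.ndarray
    fs: float
    dipole_mni: np.ndarray
    variance_rank: np.ndarray
    epoch_window: tuple[float, float] = EPOCH_WINDOW_MS
    trial_ref: pd.DataFrame | None = None

    @property
    def n_sources(self) -> int:
        return self.activations.shape[0]

    @property
    def n_samples(self) -> int:
        return self.activations.shape[1]

    @property
    def n_trials(self) -> int:
        return self.activations.shape[2]

    @property
    def times_ms(self) -> np.ndarray:
        """Sample times in ms relative to stimulus onset."""
        t0, _ = self.epoch_window
        return t0 + 1000.0 * np.arange(self.n_samples) / self.fs

    def select_trials(self, mask: np.ndarray) -> "SourceEpochs":
        mask = np.asarray(mask)
        ref = self.trial_ref.loc[mask].reset_index(drop=True) if self.trial_ref is not None else None
        return SourceEpochs(
            self.subject_id,
            self.activations[:, :, mask],
            self.fs,
            self.dipole_mni,
            self.variance_rank,
            self.epoch_window,
            ref,
        )


BURN_IN_SAMPLES = 500


def generate_source_epochs(
    subject: pd.Series | dict,
    truth: GroundTruthNetwork,
    trials: pd.DataFrame,
    fs: float = 100.0,
    seed: int = 0,
    epoch_window_ms: tuple[float, float] = EPOCH_WINDOW_MS,
    dipole_jitter_mm: float = 8.0,
) -> SourceEpochs:
    """Simulate stimulus-locked MVAR epochs for one subject.

    Each trial is an independent realization of the ground-truth network,
    with a 500-sample burn-in discarded.  For CTD subjects the configured
    group effects scale coupling coefficients inside their time windows;
    power effects add band-limited bursts.  Dipoles are jittered
    isotropically (sigma ``dipole_jitter_mm``) around the network
    centroids, once per subject.
    """
    if fs not in (100.0, 250.0, 100, 250):
        raise ValueError("supported sampling rates are 100 and 250 Hz")
    group = subject["group"]
    K, p = truth.n_sources, truth.order
    n_trials = len(trials)
    t0, t1 = epoch_window_ms
    T = int(round(fs * (t1 - t0) / 1000.0))
    rng = np.random.default_rng(seed)

    times_ms = t0 + 1000.0 * np.arange(T) / fs

    # coefficient schedule: (p, K, K) base and, for CTD, effect-modified
    A_base = truth.coeffs
    A_mod = A_base.copy()
    active_windows = []
    if group == "CTD":
        for ge in truth.group_effects:
            j, i = ge.edge
            A_mod[:, i, j] = A_base[:, i, j] * ge.multiplier
            active_windows.append(ge.window_ms)
    modified = np.zeros(T, dtype=bool)
    for w0, w1 in active_windows:
        modified |= (times_ms >= w0) & (times_ms <= w1)

    Ab = np.concatenate(list(A_base), axis=1)  # (K, K*p)
    Am = np.concatenate(list(A_mod), axis=1)
    L = np.linalg.cholesky(truth.noise_cov)

    # simulate all trials in lockstep
    z = np.zeros((K * p, n_trials))  # stacked state [x(t-1); ...; x(t-p)]
    X = np.empty((K, T, n_trials))
    n_steps = BURN_IN_SAMPLES + T
    eps = rng.standard_normal((n_steps, K, n_trials))
    for step in range(n_steps):
        t_idx = step - BURN_IN_SAMPLES
        A_now = Am if (t_idx >= 0 and modified[t_idx]) else Ab
        x = A_now @ z + L @ eps[step]
        if t_idx >= 0:
            X[:, t_idx, :] = x
        if p > 1:
            z[K:] = z[:-K]
        z[:K] = x

    # band-limited oscillatory bursts (per-group dB offsets)
    pre_stim = times_ms < -100.0
    for pe in truth.power_effects:
        db = pe.db_offset.get(group, 0.0)
        if db == 0.0:
            continue
        ratio = 10.0 ** (db / 10.0)
        base = X[pe.source][pre_stim]  # (T_pre, n_trials)
        band_p = _band_power(base, fs, pe.band_hz)
        w0, w1 = pe.window_ms
        in_win = (times_ms >= w0) & (times_ms <= w1)
        env = _tukey_envelope(in_win.sum(), fs, ramp_ms=25.0)
        amp = np.sqrt(2.0 * (ratio - 1.0) * band_p / np.mean(env**2))
        f_c = 0.5 * (pe.band_hz[0] + pe.band_hz[1])
        phase = rng.uniform(0, 2 * np.pi, n_trials)
        tt = times_ms[in_win] / 1000.0
        burst = amp * env[:, None] * np.sin(
            2 * np.pi * f_c * tt[:, None] + phase[None, :]
        )
        X[pe.source][in_win] += burst

    dipoles = truth.centroids_mni + rng.normal(0.0, dipole_jitter_mm, (K, 3))
    var = X.reshape(K, -1).var(axis=1)
    # rank 1 = largest variance
    rank = np.empty(K, dtype=int)
    rank[np.argsort(-var)] = np.arange(1, K + 1)

    return SourceEpochs(
        subject_id=str(subject.get("subject_id", "sim")),
        activations=X,
        fs=float(fs),
        dipole_mni=dipoles,
        variance_rank=rank,
        epoch_window=epoch_window_ms,
        trial_ref=trials.reset_index(drop=True),
    )


def _band_power(x: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Mean-square amplitude of ``x`` within ``band`` (Hz), via the FFT."""
    n = x.shape[0]
    F = np.fft.rfft(x, axis=0)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    psd = (np.abs(F) ** 2) / n**2
    psd[1:-1] *= 2.0  # fold negative frequencies
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(psd[sel].sum(axis=0).mean())


def _tukey_envelope(n: int, fs: float, ramp_ms: float = 25.0) -> np.ndarray:
    """Flat envelope with raised-cosine on/off ramps."""
    n_ramp = max(1, int(round(fs * ramp_ms / 1000.0)))
    env = np.ones(n)
    if 2 * n_ramp < n:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        env[:n_ramp] = ramp
        env[-n_ramp:] = ramp[::-1]
    return env


# ---------------------------------------------------------------------------
# IO: HDF5 epoch container, TSV tables
# ---------------------------------------------------------------------------


def save_epochs(path, epochs_list: list[SourceEpochs]) -> None:
    """Write epochs to the HDF5 container layout.

    Layout: ``/subjects/<id>/activations`` (K x T x N), ``dipoles`` (K x 3),
    ``variance_rank`` (K,), with attrs ``fs`` and ``epoch_window_ms``.
    """
    with h5py.File(path, "w") as f:
        root = f.create_group("subjects")
        for ep in epochs_list:
            g = root.create_group(ep.subject_id)
            g.create_dataset("activations", data=ep.activations)
            g.create_dataset("dipoles", data=ep.dipole_mni)
            g.create_dataset("variance_rank", data=ep.variance_rank)
            g.attrs["fs"] = ep.fs
            g.attrs["epoch_window_ms"] = list(ep.epoch_window)


def load_epochs(path, subject_id: str | None = None) -> list[SourceEpochs]:
    """Read epochs back from the HDF5 container (all subjects or one)."""
    out = []
    with h5py.File(path, "r") as f:
        ids = [subject_id] if subject_id is not None else sorted(f["subjects"])
        for sid in ids:
            g = f["subjects"][sid]
            out.append(
                SourceEpochs(
                    subject_id=sid,
                    activations=g["activations"][()],
                    fs=float(g.attrs["fs"]),
                    dipole_mni=g["dipoles"][()],
                    variance_rank=g["variance_rank"][()],
                    epoch_window=tuple(g.attrs["epoch_window_ms"]),
                )
            )
    return out


def save_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index=False)


def load_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
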