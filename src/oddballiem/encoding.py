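"""Forward (inverted) encoding of orientation and mismatch information.

The encoder assumes the linear model ``B = W C + N``: sensor data ``B``
(electrodes x trials) are a weighted sum of hypothetical feature-channel
activations ``C`` (channels x trials) through a spatial weight matrix ``W``
plus noise. Channels are nine half-wave rectified cosines raised to the 8th
power, centred on the presented orientations (0..160 deg in 20-deg steps) in
180-degree circular space. Weights are trained per channel by least squares,
and inverted via noise-covariance-aware spatial filters

    v_i = Sigma_i^{-1} w_i / (w_i^T Sigma_i^{-1} w_i),

where ``Sigma_i`` is the shrinkage-regularized covariance of the training
residuals for channel ``i`` (Ledoit-Wolf analytic intensity, identity
target). Applying ``V^T`` to held-out data recovers single-trial channel
responses, which are circularly recentred on the coded feature and averaged
per condition. Cross-validation folds at block granularity, with per-fold
condition balancing, follow the estimator's standard recipe (3 folds,
many iterations). A statsmodels-style model class,
:class:`InvertedEncoding`, wraps the primitives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.ndimage import uniform_filter1d

from .design import wrap_mismatch
from .tuning import fit_timecourse

__all__ = [
    "BasisSet",
    "evaluate_basis",
    "make_design_matrix",
    "default_window_samples",
    "temporal_smooth",
    "train_weights",
    "shrinkage_covariance",
    "compute_filter",
    "train_encoder",
    "apply_encoder",
    "recenter_responses",
    "FoldPlan",
    "crossval_decode",
    "temporal_generalization",
    "InvertedEncoding",
    "InvertedEncodingResults",
]


# ---------------------------------------------------------------------------
# Basis and design matrices
# ---------------------------------------------------------------------------


def _wrap180(delta):
    """Wrap an angle difference into [-90, 90] on the 180-deg circle."""
    return np.mod(np.asarray(delta, dtype=float) + 90.0, 180.0) - 90.0


def evaluate_basis(theta, center, power: int = 8):
    """Idealised channel tuning: ``max(0, cos(delta))**power`` with ``delta``
    the 180-deg-wrapped difference between ``theta`` and ``center`` (deg).

    Within the wrapped range [-90, 90] the cosine is non-negative, so the
    half-wave rectification only matters at the +/-90 boundary (value 0).
    """
    if power < 1:
        raise ValueError("power must be >= 1")
    delta = np.deg2rad(_wrap180(np.asarray(theta, dtype=float) - center))
    c = np.maximum(0.0, np.cos(delta))
    # exact zero at the +/-90 deg rectification boundary (cos underflows there)
    c = np.where(c < 1e-12, 0.0, c)
    return c**power


@dataclass
class BasisSet:
    """Nine-channel rectified-cosine basis over the 180-deg orientation space."""

    n_channels: int = 9
    power: int = 8
    step: float = field(init=False)

    def __post_init__(self):
        self.step = 180.0 / self.n_channels

    @property
    def centers(self) -> np.ndarray:
        return np.arange(self.n_channels) * self.step

    def __call__(self, theta) -> np.ndarray:
        """Evaluate all channels at ``theta``; returns channels x len(theta)."""
        theta = np.atleast_1d(np.asarray(theta, dtype=float))
        return evaluate_basis(theta[None, :], self.centers[:, None], self.power)

    @property
    def offsets(self) -> np.ndarray:
        """Channel offsets after recentring: -80, ..., 0, ..., +80 for n=9."""
        half = self.n_channels // 2
        return (np.arange(self.n_channels) - half) * self.step


def coded_angles(events: pd.DataFrame, feature_mode: str) -> np.ndarray:
    """Per-trial coded angle on the 0..180 grid for the given feature.

    ``orientation``: the presented orientation. ``mismatch``: the signed
    circular difference current-minus-previous, mapped onto the 0..160 grid
    by the 180-deg wrap (e.g. -40 deg codes as 140 deg).
    """
    if feature_mode == "orientation":
        ang = events["orientation_deg"].to_numpy(dtype=float)
    elif feature_mode == "mismatch":
        mm = events["mismatch_deg"].to_numpy(dtype=float)
        if np.isnan(mm).any():
            raise ValueError("mismatch coding requires mismatch_deg for every trial")
        ang = np.mod(mm, 180.0)
    else:
        raise ValueError(f"unknown feature_mode {feature_mode!r}")
    return ang


def make_design_matrix(
    events: pd.DataFrame, basis: BasisSet, feature_mode: str = "orientation"
) -> np.ndarray:
    """Design matrix C (channels x trials): basis evaluated at each trial's
    coded angle. Angles must sit on the basis grid (grid-locked design)."""
    ang = coded_angles(events, feature_mode)
    if not np.allclose(np.mod(ang, basis.step), 0.0):
        raise ValueError("coded angles must lie on the channel-center grid")
    return basis(ang)


def coded_channel_index(events: pd.DataFrame, basis: BasisSet, feature_mode: str) -> np.ndarray:
    """Index of the channel whose center equals each trial's coded angle."""
    ang = coded_angles(events, feature_mode)
    idx = np.round(ang / basis.step).astype(int) % basis.n_channels
    return idx


# ---------------------------------------------------------------------------
# Temporal smoothing
# ---------------------------------------------------------------------------


def default_window_samples(sampling_rate: float, target_ms: float = 30.0) -> int:
    """Largest odd sample count whose duration does not exceed ``target_ms``
    (7 samples = 27.3 ms at 256 Hz)."""
    n = int(np.floor(target_ms / 1000.0 * sampling_rate))
    if n % 2 == 0:
        n -= 1
    return max(n, 1)


def temporal_smooth(data: np.ndarray, t: int, window_samples: int) -> np.ndarray:
    """Mean over ``window_samples`` consecutive samples centred on sample ``t``.

    ``data`` is trials x electrodes x samples; returns electrodes x trials.
    The window must fit inside the epoch.
    """
    if window_samples % 2 != 1:
        raise ValueError("window_samples must be odd")
    half = window_samples // 2
    if t - half < 0 or t + half >= data.shape[-1]:
        raise IndexError("smoothing window exceeds epoch bounds")
    return data[:, :, t - half : t + half + 1].mean(axis=-1).T


def smooth_all(data: np.ndarray, window_samples: int) -> np.ndarray:
    """Moving-average the sample axis (same shape); used to precompute the
    per-timepoint smoothed slices in one pass."""
    return uniform_filter1d(data, size=window_samples, axis=-1, mode="nearest")


def valid_timepoints(n_samples: int, window_samples: int, stride: int = 1) -> np.ndarray:
    """Sample indices at which a centred smoothing window fits fully."""
    half = window_samples // 2
    return np.arange(half, n_samples - half, stride)


# ---------------------------------------------------------------------------
# Estimator primitives
# ---------------------------------------------------------------------------


def train_weights(B_train: np.ndarray, c_i: np.ndarray) -> np.ndarray:
    """Per-channel least-squares spatial weights: w = B c^T / (c c^T)."""
    c_i = np.asarray(c_i, dtype=float).ravel()
    denom = float(c_i @ c_i)
    if denom == 0.0:
        raise ValueError("channel activations are all zero (degenerate design)")
    return (B_train @ c_i) / denom


def _lw_intensity(gram: np.ndarray, sample_sq: np.ndarray, n: int) -> np.ndarray:
    """Analytic Ledoit-Wolf shrinkage intensity toward the scaled identity.

    Vectorized over a leading channel axis. ``gram`` is ... x p x p
    (= eps eps^T), ``sample_sq`` ... x n holds per-sample squared norms
    ||x_i||^2. Uses the identity
    sum_i ||x_i x_i^T - S||_F^2 = sum_i ||x_i||^4 - n ||S||_F^2
    with S the 1/n empirical covariance.
    """
    p = gram.shape[-1]
    emp0 = gram / n
    mu = np.trace(emp0, axis1=-2, axis2=-1) / p
    d2 = (
        np.sum(emp0**2, axis=(-2, -1))
        - 2.0 * mu * np.trace(emp0, axis1=-2, axis2=-1)
        + p * mu**2
    ) / p
    b2bar = (np.sum(sample_sq**2, axis=-1) - n * np.sum(emp0**2, axis=(-2, -1))) / n**2 / p
    with np.errstate(invalid="ignore", divide="ignore"):
        lam = np.where(d2 > 0, np.minimum(b2bar, d2) / d2, 0.0)
    return np.clip(lam, 0.0, 1.0)


def shrinkage_covariance(residuals: np.ndarray, n_train: int | None = None) -> np.ndarray:
    """Shrinkage-regularized residual covariance.

    Empirical covariance ``eps eps^T / (n-1)`` shrunk toward ``nu * I`` with
    ``nu`` the mean eigenvalue, using the analytic Ledoit-Wolf intensity.
    The result is symmetric positive definite whenever the residuals are
    nonzero.
    """
    eps = np.asarray(residuals, dtype=float)
    n = eps.shape[1] if n_train is None else int(n_train)
    if n < 2:
        raise ValueError("need at least two training trials")
    gram = eps @ eps.T
    emp = gram / (n - 1)
    nu = np.trace(emp) / emp.shape[0]
    if nu <= 0.0:
        raise ValueError("zero residuals: covariance is degenerate")
    lam = float(_lw_intensity(gram, np.sum(eps**2, axis=0), n))
    sigma = (1.0 - lam) * emp + lam * nu * np.eye(emp.shape[0])
    return 0.5 * (sigma + sigma.T)


def compute_filter(w_i: np.ndarray, sigma_i: np.ndarray) -> np.ndarray:
    """Optimal spatial filter v = Sigma^{-1} w / (w^T Sigma^{-1} w).

    Satisfies the unit-gain constraint v^T w = 1.
    """
    w_i = np.asarray(w_i, dtype=float).ravel()
    if not np.any(w_i):
        raise ValueError("zero weight vector")
    try:
        cf = cho_factor(sigma_i)
        siw = cho_solve(cf, w_i)
    except np.linalg.LinAlgError as exc:  # pragma: no cover
        raise np.linalg.LinAlgError(f"singular channel covariance: {exc}")
    return siw / (w_i @ siw)


@dataclass
class EncoderModel:
    """Trained per-timepoint encoder: weights, filters, training means."""

    W: np.ndarray  # electrodes x channels
    V: np.ndarray  # electrodes x channels
    train_means: np.ndarray  # electrodes
    n_train: int


def train_encoder(B_train: np.ndarray, C_train: np.ndarray) -> EncoderModel:
    """Train weights, residual covariances and filters for all channels.

    ``B_train`` is electrodes x trials (raw, not yet de-meaned); ``C_train``
    channels x trials.
    """
    means = B_train.mean(axis=1)
    B = B_train - means[:, None]
    n_ch = C_train.shape[0]
    n_el, n_tr = B.shape
    if n_tr < 2:
        raise ValueError("need at least two training trials")
    denom = np.einsum("ct,ct->c", C_train, C_train)
    if np.any(denom == 0.0):
        raise ValueError("channel activations are all zero (degenerate design)")
    W = (B @ C_train.T) / denom[None, :]  # per-channel scalar least squares

    # residuals, per-channel shrunk covariances and filters, vectorized
    eps = B[None, :, :] - W.T[:, :, None] * C_train[:, None, :]  # ch x el x tr
    gram = np.matmul(eps, eps.transpose(0, 2, 1))
    emp = gram / (n_tr - 1)
    nu = np.trace(emp, axis1=1, axis2=2) / n_el
    if np.any(nu <= 0.0):
        raise ValueError("zero residuals: covariance is degenerate")
    lam = _lw_intensity(gram, np.sum(eps**2, axis=1), n_tr)
    eye = np.eye(n_el)
    sigma = (1.0 - lam)[:, None, None] * emp + (lam * nu)[:, None, None] * eye
    V = np.empty((n_el, n_ch))
    for i in range(n_ch):
        V[:, i] = compute_filter(W[:, i], sigma[i])
    return EncoderModel(W=W, V=V, train_means=means, n_train=n_tr)


def apply_encoder(model: EncoderModel, B_test: np.ndarray) -> np.ndarray:
    """Decode channel activations ``C_test = V^T B_test`` from held-out data.

    Test data are de-meaned with the training-set electrode means so the
    affine contract matches training.
    """
    if B_test.shape[0] != model.V.shape[0]:
        raise ValueError("electrode count mismatch between model and data")
    return model.V.T @ (B_test - model.train_means[:, None])


def recenter_responses(activations: np.ndarray, coded_index: np.ndarray) -> np.ndarray:
    """Circularly shift each trial's channel axis so the coded channel sits at
    the central offset (0 deg).

    ``activations`` is channels x trials; returns channels x trials with the
    channel axis reinterpreted as offsets (-80..+80 for nine channels).
    """
    n_ch, n_tr = activations.shape
    half = n_ch // 2
    rows = (np.arange(n_ch)[:, None] - half + coded_index[None, :]) % n_ch
    return activations[rows, np.arange(n_tr)[None, :]]


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------


@dataclass
class FoldPlan:
    """Block-granular 3-way partition with per-fold condition balancing.

    ``folds`` holds, per fold, the balanced trial indices (equal counts per
    condition label within the fold). Usage counts accumulate across
    iterations so later iterations prefer the least-used trials.
    """

    folds: list
    usage: np.ndarray


def plan_folds(
    blocks: np.ndarray,
    labels: np.ndarray,
    n_folds: int,
    usage: np.ndarray,
    rng,
) -> FoldPlan:
    # round-robin at block granularity, stratified by each block's label
    # composition so every condition reaches every fold whenever it spans
    # at least n_folds blocks
    uniq_blocks = np.unique(blocks)
    composition = {
        b: tuple(sorted(map(str, np.unique(labels[blocks == b])))) for b in uniq_blocks
    }
    assign = {}
    for comp in sorted(set(composition.values())):
        group = rng.permutation([b for b in uniq_blocks if composition[b] == comp])
        offset = int(rng.integers(n_folds))
        for i, b in enumerate(group):
            assign[b] = (offset + i) % n_folds
    fold_of = np.array([assign[b] for b in blocks])
    uniq_labels = np.unique(labels)
    folds = []
    for f in range(n_folds):
        in_fold = np.flatnonzero(fold_of == f)
        counts = {lab: np.sum(labels[in_fold] == lab) for lab in uniq_labels}
        if min(counts.values()) == 0:
            missing = [lab for lab, c in counts.items() if c == 0]
            raise ValueError(f"condition(s) {missing} absent from fold {f}")
        n_keep = min(counts.values())
        chosen = []
        for lab in uniq_labels:
            cand = in_fold[labels[in_fold] == lab]
            # least-used-first selection, random tie-break
            order = np.lexsort((rng.random(cand.size), usage[cand]))
            chosen.append(cand[order[:n_keep]])
        fold_idx = np.concatenate(chosen)
        usage[fold_idx] += 1
        folds.append(np.sort(fold_idx))
    return FoldPlan(folds=folds, usage=usage)


def crossval_decode(
    data: np.ndarray,
    events: pd.DataFrame,
    basis: BasisSet,
    feature_mode: str = "orientation",
    condition_labels=None,
    folds: int = 3,
    iterations: int = 100,
    window_samples: int = 7,
    timepoints=None,
    rng=None,
):
    """Cross-validated decoding of recentred channel-response profiles.

    Per iteration, blocks are partitioned into ``folds`` folds; each fold is
    decoded with an encoder trained on the balanced trials of the other
    folds; single-trial profiles are recentred on the coded channel and
    accumulated. Returns ``(trial_profiles, trial_counts, timepoints)`` where
    ``trial_profiles`` is trials x channels x timepoints (mean over the
    iterations in which the trial was selected; NaN where never selected)
    and ``trial_counts`` counts selections per trial.

    ``condition_labels`` (per-trial array) drives the within-fold balancing;
    defaults to the events' ``condition`` column.
    """
    rng = np.random.default_rng(rng)
    n_trials = data.shape[0]
    if len(events) != n_trials:
        raise ValueError("event count must match trial count")
    if condition_labels is None:
        condition_labels = events["condition"].to_numpy()
    condition_labels = np.asarray(condition_labels)
    blocks = events["block"].to_numpy()
    if np.unique(blocks).size < folds:
        raise ValueError("need at least as many blocks as folds")

    C = make_design_matrix(events, basis, feature_mode)
    coded_idx = coded_channel_index(events, basis, feature_mode)
    smoothed = smooth_all(np.asarray(data, dtype=float), window_samples)
    if timepoints is None:
        timepoints = valid_timepoints(data.shape[-1], window_samples)
    timepoints = np.asarray(timepoints)

    n_ch = basis.n_channels
    n_t = timepoints.size
    sums = np.zeros((n_trials, n_ch, n_t))
    counts = np.zeros(n_trials)
    usage = np.zeros(n_trials)
    sm = np.ascontiguousarray(smoothed[:, :, timepoints])  # trials x el x n_t

    for _ in range(iterations):
        plan = plan_folds(blocks, condition_labels, folds, usage, rng)
        for f in range(folds):
            test_idx = plan.folds[f]
            train_idx = np.concatenate([plan.folds[g] for g in range(folds) if g != f])
            sm_tr, sm_te = sm[train_idx], sm[test_idx]
            C_tr = C[:, train_idx]
            coded_te = coded_idx[test_idx]
            local = np.empty((test_idx.size, n_ch, n_t))
            for ti in range(n_t):
                model = train_encoder(sm_tr[:, :, ti].T, C_tr)
                act = apply_encoder(model, sm_te[:, :, ti].T)
                local[:, :, ti] = recenter_responses(act, coded_te).T
            sums[test_idx] += local
            counts[test_idx] += 1

    with np.errstate(invalid="ignore"):
        profiles = sums / counts[:, None, None]
    return profiles, counts, timepoints


def condition_average(profiles: np.ndarray, labels, order=None) -> dict:
    """Average single-trial profiles (trials x channels x times) per label,
    ignoring never-decoded trials (NaN rows) and unlabelled (None/NaN) trials."""
    labels = np.asarray(labels)
    if order is not None:
        keys = order
    else:
        keys = [
            k
            for k in pd.unique(labels)
            if k is not None and not (isinstance(k, float) and np.isnan(k))
        ]
        keys = sorted(keys, key=str)
    out = {}
    for key in keys:
        sel = profiles[labels == key]
        out[key] = np.nanmean(sel, axis=0)
    return out


def temporal_generalization(
    data: np.ndarray,
    events: pd.DataFrame,
    basis: BasisSet,
    feature_mode: str = "mismatch",
    condition_labels=None,
    folds: int = 3,
    iterations: int = 10,
    window_samples: int = 7,
    stride: int = 3,
    rng=None,
):
    """Train the encoder at each strided timepoint and test it at every
    strided timepoint, under the same cross-validation contract.

    Returns ``(gen_map, timepoints)`` where ``gen_map`` is a dict mapping
    condition label -> channels x train_times x test_times recentred
    condition-average profiles.
    """
    rng = np.random.default_rng(rng)
    n_trials = data.shape[0]
    if condition_labels is None:
        condition_labels = events["condition"].to_numpy()
    condition_labels = np.asarray(condition_labels)
    blocks = events["block"].to_numpy()

    C = make_design_matrix(events, basis, feature_mode)
    coded_idx = coded_channel_index(events, basis, feature_mode)
    smoothed = smooth_all(np.asarray(data, dtype=float), window_samples)
    timepoints = valid_timepoints(data.shape[-1], window_samples, stride)
    n_t = timepoints.size
    n_ch = basis.n_channels

    sums = np.zeros((n_trials, n_ch, n_t, n_t))
    counts = np.zeros(n_trials)
    usage = np.zeros(n_trials)
    sm = np.ascontiguousarray(smoothed[:, :, timepoints])

    for _ in range(iterations):
        plan = plan_folds(blocks, condition_labels, folds, usage, rng)
        for f in range(folds):
            test_idx = plan.folds[f]
            train_idx = np.concatenate([plan.folds[g] for g in range(folds) if g != f])
            sm_tr, sm_te = sm[train_idx], sm[test_idx]
            C_tr = C[:, train_idx]
            coded_te = coded_idx[test_idx]
            local = np.empty((test_idx.size, n_ch, n_t, n_t))
            for ti in range(n_t):
                model = train_encoder(sm_tr[:, :, ti].T, C_tr)
                for tj in range(n_t):
                    act = apply_encoder(model, sm_te[:, :, tj].T)
                    local[:, :, ti, tj] = recenter_responses(act, coded_te).T
            sums[test_idx] += local
            counts[test_idx] += 1

    with np.errstate(invalid="ignore"):
        profiles = sums / counts[:, None, None, None]
    gen = condition_average(profiles, condition_labels)
    return gen, timepoints


# ---------------------------------------------------------------------------
# Model / Results front-end
# ---------------------------------------------------------------------------


class InvertedEncoding:
    """Inverted encoding model of orientation or mismatch information.

    Parameters
    ----------
    epochs : EpochSet or ndarray
        Trials x electrodes x samples data (an :class:`~oddballiem.containers.EpochSet`
        or a bare array plus ``events``/``sampling_rate``).
    events : DataFrame, optional
        Labelled event table aligned to trials (taken from the EpochSet when
        omitted).
    feature : {'orientation', 'mismatch'}
        Which trial feature the channels code. Mismatch decoding drops trials
        with an undefined mismatch angle.
    condition_on : str or array, optional
        Column name (or per-trial array) whose labels drive within-fold
        balancing and the condition averages; defaults to ``condition``.
    """

    def __init__(
        self,
        epochs,
        events: pd.DataFrame | None = None,
        feature: str = "orientation",
        condition_on="condition",
        basis: BasisSet | None = None,
        sampling_rate: float | None = None,
        window_ms: float = 30.0,
    ):
        if events is None:
            events = epochs.events
        data = epochs.data if hasattr(epochs, "data") else np.asarray(epochs)
        if sampling_rate is None:
            sampling_rate = getattr(epochs, "sampling_rate", 256.0)
        if isinstance(condition_on, str):
            labels = events[condition_on].to_numpy()
        else:
            labels = np.asarray(condition_on)
        if feature == "mismatch":
            keep = ~events["mismatch_deg"].isna().to_numpy()
            keep &= np.asarray([lab is not None for lab in labels])
            data, events, labels = data[keep], events.loc[keep].reset_index(drop=True), labels[keep]
        self.data = np.asarray(data, dtype=float)
        self.events = events
        self.labels = labels
        self.feature = feature
        self.basis = basis if basis is not None else BasisSet()
        self.sampling_rate = float(sampling_rate)
        self.window_samples = default_window_samples(self.sampling_rate, window_ms)
        self.times = getattr(epochs, "times", None)

    def fit(
        self,
        folds: int = 3,
        iterations: int = 100,
        timepoints=None,
        seed=None,
    ) -> "InvertedEncodingResults":
        profiles, counts, tps = crossval_decode(
            self.data,
            self.events,
            self.basis,
            feature_mode=self.feature,
            condition_labels=self.labels,
            folds=folds,
            iterations=iterations,
            window_samples=self.window_samples,
            timepoints=timepoints,
            rng=np.random.default_rng(seed),
        )
        return InvertedEncodingResults(self, profiles, counts, tps)

    def temporal_generalization(
        self, folds: int = 3, iterations: int = 10, stride: int = 3, seed=None
    ):
        return temporal_generalization(
            self.data,
            self.events,
            self.basis,
            feature_mode=self.feature,
            condition_labels=self.labels,
            folds=folds,
            iterations=iterations,
            window_samples=self.window_samples,
            stride=stride,
            rng=np.random.default_rng(seed),
        )


class InvertedEncodingResults:
    """Decoded channel-response profiles and their tuning quantification."""

    def __init__(self, model: InvertedEncoding, trial_profiles, trial_counts, timepoints):
        self.model = model
        self.trial_profiles = trial_profiles
        self.trial_counts = trial_counts
        self.timepoints = np.asarray(timepoints)

    @property
    def offsets(self) -> np.ndarray:
        return self.model.basis.offsets

    @property
    def times_s(self) -> np.ndarray:
        """Decoded timepoints in seconds (when the model knows its time axis)."""
        if self.model.times is not None:
            return np.asarray(self.model.times)[self.timepoints]
        return self.timepoints / self.model.sampling_rate

    def condition_profiles(self, labels=None) -> dict:
        """Condition-average recentred profiles: label -> channels x times."""
        labels = self.model.labels if labels is None else np.asarray(labels)
        return condition_average(self.trial_profiles, labels)

    def tuning(self, labels=None, mu_mode: str = "fixed-zero") -> pd.DataFrame:
        """Exponentiated-cosine fits per condition and timepoint (long table)."""
        prof = self.condition_profiles(labels)
        frames = []
        for lab, arr in prof.items():
            tab = fit_timecourse(arr.T, self.offsets, mu_mode=mu_mode)
            tab.insert(0, "condition", lab)
            tab["time_s"] = self.times_s
            frames.append(tab)
        return pd.concat(frames, ignore_index=True)

    def amplitude(self, labels=None, mu_mode: str = "fixed-zero") -> pd.DataFrame:
        """Amplitude time courses (wide: time x condition)."""
        tab = self.tuning(labels, mu_mode)
        return tab.pivot_table(index="time_s", columns="condition", values="A")

    def summary(self, labels=None) -> str:
        prof = self.condition_profiles(labels)
        tab = self.tuning(labels)
        lines = [
            "Inverted encoding model results",
            f"  feature:        {self.model.feature}",
            f"  trials decoded: {int((self.trial_counts > 0).sum())} / {len(self.trial_counts)}",
            f"  timepoints:     {self.timepoints.size}"
            f" ({self.times_s[0] * 1e3:.0f}..{self.times_s[-1] * 1e3:.0f} ms)",
            f"  channels:       {self.model.basis.n_channels} "
            f"(offsets {self.offsets[0]:.0f}..{self.offsets[-1]:.0f} deg)",
            "",
            "  peak fitted amplitude per condition (a.u.):",
        ]
        for lab in prof:
            amp = tab.loc[tab["condition"] == lab, "A"]
            t_peak = tab.loc[amp.idxmax(), "time_s"]
            lines.append(f"    {lab:<24s} {amp.max():+.3f} at {t_peak * 1e3:.0f} ms")
        return "\n".join(lines)
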