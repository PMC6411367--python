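"""Inference layer: ERPs and mismatch contrasts, cluster-based permutation
tests, permutation-normalised univariate sensitivity, and uniform-prior
Bayes factors.

Cluster tests follow the nonparametric family-wise-error recipe: a
dependent-samples statistic (paired t, or one-way repeated-measures F for
three levels) per sample, thresholded at ``alpha_sample``; contiguous
supra-threshold samples (4-connected cells on 2-D train-by-test grids) form
clusters scored by their summed statistic; the null is built by permuting
condition labels within participant, keeping the maximal cluster mass of
each permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sps

__all__ = [
    "condition_erp",
    "mismatch_contrasts",
    "dependent_t",
    "dependent_f",
    "cluster_permutation",
    "ClusterResult",
    "univariate_sensitivity",
    "SensitivityResult",
    "bayes_factor_uniform",
    "BFResult",
]


# ---------------------------------------------------------------------------
# ERPs
# ---------------------------------------------------------------------------


def condition_erp(epochs, events: pd.DataFrame | None = None, by=("condition", "attention")):
    """Trial-average ERPs per condition cell.

    Returns a dict mapping the ``by`` tuple to an electrodes x samples mean.
    """
    if events is None:
        events = epochs.events
    data = epochs.data if hasattr(epochs, "data") else np.asarray(epochs)
    out = {}
    for key, idx in events.groupby(list(by)).groups.items():
        loc = events.index.get_indexer(idx)
        out[key] = data[loc].mean(axis=0)
    if not out:
        raise ValueError("no condition cells found")
    return out


def mismatch_contrasts(erps: dict) -> dict:
    """Classic (deviant - standard) and genuine (deviant - control) mismatch
    responses, per attention level present in the ERP dict keys."""
    out = {}
    attentions = {k[1] for k in erps}
    for att in attentions:
        dev = erps.get(("deviant", att))
        if dev is None:
            continue
        if ("standard", att) in erps:
            out[("classic", att)] = dev - erps[("standard", att)]
        if ("control", att) in erps:
            out[("genuine", att)] = dev - erps[("control", att)]
    return out


# ---------------------------------------------------------------------------
# Cluster-based permutation tests
# ---------------------------------------------------------------------------


def dependent_t(data: np.ndarray) -> np.ndarray:
    """Paired-samples t per map point; data is participants x 2 x map."""
    d = data[:, 0] - data[:, 1]
    n = d.shape[0]
    mean = d.mean(axis=0)
    se = d.std(axis=0, ddof=1) / np.sqrt(n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / se, 0.0)
    return t


def dependent_f(data: np.ndarray) -> np.ndarray:
    """One-way repeated-measures F per map point; data is participants x k x map."""
    n, k = data.shape[:2]
    grand = data.mean(axis=(0, 1))
    subj = data.mean(axis=1)  # participants x map
    cond = data.mean(axis=0)  # k x map
    ss_cond = n * ((cond - grand) ** 2).sum(axis=0)
    resid = data - subj[:, None] - cond[None, :] + grand
    ss_err = (resid**2).sum(axis=(0, 1))
    df1 = k - 1
    df2 = (k - 1) * (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(ss_err > 0, (ss_cond / df1) / (ss_err / df2), 0.0)
    return f


def _find_clusters(stat_map, threshold, tail):
    """Supra-threshold clusters and their signed masses.

    1-D maps use run contiguity; 2-D maps 4-connectivity. For two-tailed
    tests positive and negative clusters are found separately.
    """
    clusters = []
    masses = []
    signs = [1] if tail == "one" else [1, -1]
    structure = None
    if stat_map.ndim == 2:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    for sign in signs:
        supra = sign * stat_map > threshold
        labelled, n_lab = ndimage.label(supra, structure=structure)
        for lab in range(1, n_lab + 1):
            mask = labelled == lab
            clusters.append(mask)
            masses.append(stat_map[mask].sum())
    return clusters, np.asarray(masses)


@dataclass
class ClusterResult:
    clusters: list
    cluster_mass: np.ndarray
    p_values: np.ndarray
    observed_stat: np.ndarray
    null_max: np.ndarray
    settings: dict = field(default_factory=dict)

    def significant(self, alpha: float | None = None):
        alpha = alpha if alpha is not None else self.settings.get("alpha_cluster", 0.05)
        return [c for c, p in zip(self.clusters, self.p_values) if p < alpha]

    def report(self) -> pd.DataFrame:
        rows = []
        for i, (mask, mass, p) in enumerate(
            zip(self.clusters, self.cluster_mass, self.p_values)
        ):
            where = np.argwhere(mask)
            rows.append(
                {
                    "cluster": i,
                    "start": tuple(where.min(axis=0)),
                    "end": tuple(where.max(axis=0)),
                    "n_points": int(mask.sum()),
                    "mass": mass,
                    "p": p,
                }
            )
        return pd.DataFrame(rows)


def cluster_permutation(
    data: np.ndarray,
    contrast: str = "t",
    tail: str = "two",
    n_perm: int = 5000,
    alpha_sample: float = 0.05,
    alpha_cluster: float = 0.05,
    rng=None,
) -> ClusterResult:
    """Cluster-based permutation test over within-participant condition maps.

    ``data`` is participants x conditions x map (map 1-D or 2-D). ``contrast``
    't' (2 conditions, two-tailed by default) or 'f' (>= 2 conditions,
    one-tailed). The null permutes condition labels independently within each
    participant; cluster p-values are (r + 1) / (n_perm + 1) with r the
    number of permutation maxima at least as large as the observed mass.
    """
    data = np.asarray(data, dtype=float)
    n, k = data.shape[:2]
    if n < 2:
        raise ValueError("need at least two participants")
    if contrast == "t":
        if k != 2:
            raise ValueError("t contrast requires exactly two conditions")
        stat_fun = dependent_t
        thr = sps.t.ppf(1 - alpha_sample / 2, df=n - 1)
    elif contrast == "f":
        stat_fun = dependent_f
        tail = "one"
        thr = sps.f.ppf(1 - alpha_sample, dfn=k - 1, dfd=(k - 1) * (n - 1))
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    rng = np.random.default_rng(rng)

    observed = stat_fun(data)
    clusters, masses = _find_clusters(observed, thr, tail)

    null_max = np.zeros(n_perm)
    for p in range(n_perm):
        perm = data[np.arange(n)[:, None], np.argsort(rng.random((n, k)), axis=1)]
        pstat = stat_fun(perm)
        _, pmasses = _find_clusters(pstat, thr, tail)
        if pmasses.size:
            null_max[p] = np.abs(pmasses).max() if tail == "two" else pmasses.max()

    if masses.size:
        obs = np.abs(masses) if tail == "two" else masses
        p_values = (np.sum(null_max[None, :] >= obs[:, None], axis=1) + 1) / (n_perm + 1)
    else:
        p_values = np.asarray([])
    return ClusterResult(
        clusters=clusters,
        cluster_mass=masses,
        p_values=p_values,
        observed_stat=observed,
        null_max=null_max,
        settings={
            "contrast": contrast,
            "tail": tail,
            "n_perm": n_perm,
            "alpha_sample": alpha_sample,
            "alpha_cluster": alpha_cluster,
            "threshold": thr,
        },
    )


# ---------------------------------------------------------------------------
# Univariate electrode sensitivity
# ---------------------------------------------------------------------------


@dataclass
class SensitivityResult:
    beta_sin: np.ndarray
    beta_cos: np.ndarray
    S: np.ndarray
    z: np.ndarray
    n_perm: int


def univariate_sensitivity(
    data: np.ndarray,
    angles: np.ndarray,
    n_perm: int = 1000,
    rng=None,
) -> SensitivityResult:
    """Circular-regression sensitivity of each electrode/timepoint to an
    angular variable (orientation or mismatch) on the 180-deg circle.

    Each signal is regressed on [sin(2 theta), cos(2 theta), 1] (angles are
    doubled so the 180-deg circularity maps onto the full circle);
    sensitivity S = sqrt(beta_sin^2 + beta_cos^2) is rank-normalised against
    a design-shuffling null and z-scored through the inverse normal CDF
    (mid-rank convention, so z is finite).

    ``data`` is trials x electrodes x samples (or trials x anything).
    """
    rng = np.random.default_rng(rng)
    angles = np.asarray(angles, dtype=float)
    if np.unique(angles).size < 2:
        raise ValueError("angles are constant: sensitivity design is degenerate")
    n = angles.size
    Y = np.asarray(data, dtype=float).reshape(n, -1)
    shape = data.shape[1:]

    theta = np.deg2rad(2.0 * angles)
    X = np.column_stack([np.sin(theta), np.cos(theta), np.ones(n)])
    pinv = np.linalg.pinv(X)
    betas = pinv @ Y
    S = np.hypot(betas[0], betas[1])

    null = np.empty((n_perm, Y.shape[1]))
    for p in range(n_perm):
        Xp = X[rng.permutation(n)]
        bp = np.linalg.pinv(Xp) @ Y
        null[p] = np.hypot(bp[0], bp[1])

    r = (null >= S[None, :]).sum(axis=0)
    p_mid = (r + 0.5) / (n_perm + 1.0)
    z = sps.norm.ppf(1.0 - p_mid)
    return SensitivityResult(
        beta_sin=betas[0].reshape(shape),
        beta_cos=betas[1].reshape(shape),
        S=S.reshape(shape),
        z=z.reshape(shape),
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# Bayes factors
# ---------------------------------------------------------------------------


@dataclass
class BFResult:
    bf10: float
    prior_lower: float
    prior_upper: float
    observed_mean: float
    observed_se: float


def bayes_factor_uniform(
    observed_mean: float, observed_se: float, lower: float, upper: float
) -> BFResult:
    """Bayes factor (alternative over point null) with a uniform prior on the
    effect, in the Dienes-calculator convention.

    The marginal likelihood under H1 averages the normal likelihood of the
    observed mean over a uniform prior on [lower, upper]; H0 is the point
    null at zero.
    """
    if upper <= lower:
        raise ValueError("upper must exceed lower")
    if observed_se <= 0:
        raise ValueError("observed_se must be positive")
    m, se = float(observed_mean), float(observed_se)
    marginal = (sps.norm.cdf((upper - m) / se) - sps.norm.cdf((lower - m) / se)) / (
        upper - lower
    )
    null_like = sps.norm.pdf(m, loc=0.0, scale=se)
    return BFResult(
        bf10=float(marginal / null_like),
        prior_lower=lower,
        prior_upper=upper,
        observed_mean=m,
        observed_se=se,
    )
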