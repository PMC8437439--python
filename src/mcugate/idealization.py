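"""Single-channel idealization by Baum-Welch fitting and Viterbi decoding.

The workflow mirrors standard single-channel practice: the 50 kHz record
is decimated to 2.5 kHz by block averaging, a Gaussian-emission hidden
Markov model over K conductance levels is fitted by expectation-
maximization (Baum-Welch with scaled forward-backward recursions), the
trace is idealized with the Viterbi algorithm, and per-level amplitudes,
occupancy probabilities, open probability and the time-averaged unitary
current are derived from the decoded path. The time-averaged current is
the occupancy-weighted sum of level amplitudes over all conducting
levels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from ._kernels import (
    backward_scaled,
    forward_scaled,
    transition_counts,
    viterbi_path,
)
from .records import SingleChannelRecording

__all__ = [
    "HMMModel",
    "IdealizedTrace",
    "ChannelStats",
    "GroupComparison",
    "resample",
    "decimate_states",
    "baum_welch_fit",
    "viterbi_idealize",
    "suppress_brief_events",
    "channel_stats",
    "idealize_recording",
    "compare_genotypes",
]

_SD_FLOOR = 1e-6


@dataclass
class HMMModel:
    """Gaussian-emission HMM over conductance levels.

    State 0 is the closed level (mean nearest 0 pA); open levels follow
    in decreasing amplitude magnitude. ``sd`` is shared across levels by
    default; a per-level array is accepted.
    """

    means: np.ndarray
    sd: np.ndarray
    trans: np.ndarray
    init: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        K = self.means.size
        sd = np.asarray(self.sd, dtype=float)
        self.sd = np.full(K, float(sd)) if sd.ndim == 0 else sd
        self.trans = np.asarray(self.trans, dtype=float)
        self.init = np.asarray(self.init, dtype=float)
        if self.trans.shape != (K, K) or self.init.shape != (K,):
            raise ValueError("trans/init shapes must match the number of levels")
        if np.any(self.sd <= 0):
            raise ValueError("emission SDs must be positive")
        if not np.allclose(self.trans.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("trans rows must sum to 1 (within 1e-10)")
        if not np.isclose(self.init.sum(), 1.0, atol=1e-10):
            raise ValueError("init must sum to 1 (within 1e-10)")

    @property
    def K(self) -> int:
        return self.means.size

    @property
    def closed_index(self) -> int:
        return int(np.argmin(np.abs(self.means)))

    def reordered(self) -> "HMMModel":
        """Canonical level order: closed first, then descending |mean|."""
        closed = self.closed_index
        opens = [k for k in range(self.K) if k != closed]
        opens.sort(key=lambda k: -abs(self.means[k]))
        order = np.array([closed] + opens)
        return HMMModel(
            means=self.means[order],
            sd=self.sd[order],
            trans=self.trans[np.ix_(order, order)],
            init=self.init[order],
        )


@dataclass
class IdealizedTrace:
    """Decoded level index per (resampled) sample."""

    states: np.ndarray
    resample_rate: float

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=int)
        if self.states.size == 0:
            raise ValueError("idealized trace is empty")


@dataclass
class ChannelStats:
    """Per-level amplitudes/occupancies and derived single-channel metrics."""

    amplitudes: np.ndarray
    occupancy: np.ndarray
    p_open: float
    i_avg: float
    voltage: float = np.nan
    label: str = ""

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        self.occupancy = np.asarray(self.occupancy, dtype=float)
        if not np.isclose(self.occupancy.sum(), 1.0, atol=1e-9):
            raise ValueError("occupancy must sum to 1")
        if not 0.0 <= self.p_open <= 1.0:
            raise ValueError("p_open must lie in [0, 1]")
        if not np.isclose(self.i_avg, float(self.occupancy @ self.amplitudes), atol=1e-9):
            raise ValueError("i_avg must equal occupancy-weighted amplitude sum")


def resample(rec: SingleChannelRecording, target_rate: float) -> SingleChannelRecording:
    """Decimate by averaging non-overlapping blocks.

    The decimation factor ``sample_rate / target_rate`` must be an
    integer; a trailing partial block is dropped.
    """
    if target_rate > rec.sample_rate:
        raise ValueError("target_rate must not exceed the acquisition rate")
    factor = rec.sample_rate / target_rate
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"decimation factor {factor:g} is not an integer; choose a "
            "target rate that divides the acquisition rate"
        )
    factor = int(round(factor))
    if factor == 1:
        return rec
    n_blocks = rec.samples.size // factor
    blocked = rec.samples[: n_blocks * factor].reshape(n_blocks, factor).mean(axis=1)
    return SingleChannelRecording(
        samples=blocked,
        sample_rate=target_rate,
        filter_cutoff=rec.filter_cutoff,
        voltage=rec.voltage,
        permeant_ion=rec.permeant_ion,
        genotype=rec.genotype,
    )


def decimate_states(states: np.ndarray, factor: int) -> np.ndarray:
    """Down-sample a ground-truth state path: per-block majority vote.

    Companion to :func:`resample` for comparing decoded paths against
    simulation ground truth at the analysis rate.
    """
    states = np.asarray(states)
    n_blocks = states.size // factor
    blocks = states[: n_blocks * factor].reshape(n_blocks, factor)
    K = int(states.max()) + 1
    counts = np.stack([(blocks == k).sum(axis=1) for k in range(K)], axis=1)
    return counts.argmax(axis=1)


def _gaussian_emissions(x: np.ndarray, means: np.ndarray, sd: np.ndarray) -> np.ndarray:
    z = (x[:, None] - means[None, :]) / sd[None, :]
    b = np.exp(-0.5 * z * z) / (np.sqrt(2 * np.pi) * sd[None, :])
    # guard against all-zero rows (far outliers) which would break scaling
    return np.maximum(b, 1e-300)


def _kmeans_1d(x: np.ndarray, centers: np.ndarray, n_iter: int = 50) -> np.ndarray:
    centers = np.sort(np.asarray(centers, dtype=float))
    for _ in range(n_iter):
        edges = 0.5 * (centers[1:] + centers[:-1])
        labels = np.searchsorted(edges, x)
        new = centers.copy()
        for k in range(centers.size):
            sel = x[labels == k]
            if sel.size:
                new[k] = sel.mean()
        if np.allclose(new, centers, atol=1e-12):
            centers = new
            break
        centers = np.sort(new)
    return centers


def _em_run(
    x: np.ndarray,
    means: np.ndarray,
    sd: np.ndarray,
    trans: np.ndarray,
    init: np.ndarray,
    max_iter: int,
    tol_per_sample: float,
    shared_sd: bool,
) -> tuple[HMMModel, np.ndarray]:
    T = x.size
    loglik = []
    for _ in range(max_iter):
        b = _gaussian_emissions(x, means, sd)
        alpha, c = forward_scaled(b, trans, init)
        ll = float(np.log(c).sum())
        loglik.append(ll)
        beta = backward_scaled(b, trans, c)
        gamma = alpha * beta
        gamma /= gamma.sum(axis=1, keepdims=True)
        xi = transition_counts(b, trans, alpha, beta, c)
        denom = gamma[:-1].sum(axis=0)
        trans = xi / np.maximum(denom[:, None], 1e-300)
        trans /= trans.sum(axis=1, keepdims=True)
        init = gamma[0] / gamma[0].sum()
        w = gamma.sum(axis=0)
        means = (gamma * x[:, None]).sum(axis=0) / np.maximum(w, 1e-300)
        resid2 = (x[:, None] - means[None, :]) ** 2
        if shared_sd:
            var = float((gamma * resid2).sum() / T)
            sd = np.full(means.size, max(np.sqrt(var), _SD_FLOOR))
        else:
            var = (gamma * resid2).sum(axis=0) / np.maximum(w, 1e-300)
            sd = np.maximum(np.sqrt(var), _SD_FLOOR)
        if len(loglik) >= 2 and (loglik[-1] - loglik[-2]) < tol_per_sample * T:
            break
    # final likelihood under the updated parameters
    b = _gaussian_emissions(x, means, sd)
    _, c = forward_scaled(b, trans, init)
    loglik.append(float(np.log(c).sum()))
    model = HMMModel(means=means, sd=sd, trans=trans, init=init)
    return model, np.asarray(loglik)


def baum_welch_fit(
    rec: SingleChannelRecording,
    K: int,
    init: HMMModel | None = None,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 3,
    shared_sd: bool = True,
) -> tuple[HMMModel, np.ndarray]:
    """Fit a K-level Gaussian HMM by Baum-Welch EM.

    Initialization is 1-D k-means on the amplitude distribution plus
    ``n_restarts`` seeded random perturbations; the restart with the best
    final log-likelihood wins. ``tol`` is the per-sample log-likelihood
    improvement threshold. Returns the fitted model (levels in canonical
    order) and the log-likelihood trajectory of the winning run, which is
    non-decreasing by the EM guarantee.

    If two fitted means collapse onto each other (more levels requested
    than distinguishable modes) the fit is still returned; callers can
    detect duplicates via near-equal means.
    """
    if K < 1:
        raise ValueError("K must be at least 1")
    x = rec.samples
    if K == 1:
        mu = float(x.mean())
        sd = max(float(x.std()), _SD_FLOOR)
        model = HMMModel(
            means=[mu], sd=[sd], trans=np.eye(1), init=np.ones(1)
        )
        return model, np.array([float(np.sum(sps.norm.logpdf(x, mu, sd)))])

    rng = np.random.default_rng(seed)
    span = np.quantile(x, [0.005, 0.995])
    base_centers = _kmeans_1d(x, np.linspace(span[0], span[1], K))
    # robust noise estimate from first differences (level jumps are rare,
    # so the median absolute difference reflects emission noise, not
    # gating); a too-large initial SD would merge nearby sublevels in the
    # first E-step
    mad = float(np.median(np.abs(np.diff(x))))
    sd0 = max(mad / (np.sqrt(2) * 0.6745), _SD_FLOOR)
    sticky = np.full((K, K), 0.02 / (K - 1))
    np.fill_diagonal(sticky, 0.98)

    # start list: k-means centers, evenly spaced quantiles, and random
    # data-quantile draws — diverse enough to escape splits of a dominant
    # mode; the best final likelihood wins
    starts = [base_centers, np.quantile(x, (np.arange(K) + 0.5) / K)]
    for _ in range(n_restarts):
        starts.append(np.sort(np.quantile(x, rng.uniform(0, 1, K))))

    if init is not None:
        model, traj = _em_run(
            x, init.means.copy(), init.sd.copy(), init.trans.copy(),
            init.init.copy(), max_iter, tol, shared_sd,
        )
        return model.reordered(), traj

    # short-runs-then-long-run: a burn-in pass over all starts, then the
    # best is run to convergence — bad starts never consume a full budget
    burn_in = min(25, max_iter)
    best: tuple[HMMModel, np.ndarray] | None = None
    for centers in starts:
        model, traj = _em_run(
            x, np.sort(centers), np.full(K, sd0), sticky.copy(),
            np.full(K, 1.0 / K), burn_in, tol, shared_sd,
        )
        if best is None or traj[-1] > best[1][-1]:
            best = (model, traj)
    model, traj = best
    if len(traj) - 1 >= burn_in:  # burn-in did not converge: continue
        model, traj2 = _em_run(
            x, model.means, model.sd, model.trans, model.init,
            max_iter - burn_in, tol, shared_sd,
        )
        traj = np.concatenate([traj[:-1], traj2])
    return model.reordered(), traj


def viterbi_idealize(rec: SingleChannelRecording, model: HMMModel) -> IdealizedTrace:
    """Maximum a posteriori state path under ``model`` (Viterbi)."""
    if np.any(model.trans.sum(axis=1) <= 0) or model.init.sum() <= 0:
        raise ValueError("degenerate model: zero-probability rows")
    x = rec.samples
    with np.errstate(divide="ignore"):
        log_b = np.log(_gaussian_emissions(x, model.means, model.sd))
        log_trans = np.log(model.trans)
        log_init = np.log(model.init)
    path = viterbi_path(log_b, log_trans, log_init)
    return IdealizedTrace(states=path, resample_rate=rec.sample_rate)


def suppress_brief_events(states: np.ndarray, min_samples: int = 2) -> np.ndarray:
    """Dead-time correction: merge sojourns shorter than ``min_samples``
    into the preceding level (the following level for a leading run).

    The acquisition filter cannot convey events shorter than its rise
    time, and block-average decimation smears level edges across one
    resampled sample; single-sample sojourns in a decoded path are
    therefore edge artifacts, not detections. Applied once, left to
    right, so corrected runs can absorb subsequent brief neighbours.
    """
    states = np.asarray(states).copy()
    if states.size == 0 or min_samples <= 1:
        return states
    # run-length encode
    change = np.nonzero(np.diff(states))[0] + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [states.size]])
    out = states.copy()
    prev_level = None
    for s, e in zip(starts, ends):
        if e - s < min_samples and prev_level is not None:
            out[s:e] = prev_level
        else:
            prev_level = out[s]
    if ends[0] - starts[0] < min_samples and len(starts) > 1:
        out[starts[0]:ends[0]] = out[ends[0]]
    return out


def channel_stats(
    ideal: IdealizedTrace,
    model: HMMModel,
    voltage: float = np.nan,
    label: str = "",
) -> ChannelStats:
    """Occupancy, open probability and time-averaged unitary current.

    ``i_avg`` is the sum over all conductance levels of occupancy times
    amplitude, which equals the mean of the idealized (noise-free
    reconstructed) current trace.
    """
    if ideal.states.size == 0:
        raise ValueError("empty idealized path")
    occ = np.bincount(ideal.states, minlength=model.K).astype(float)
    occ /= occ.sum()
    p_open = float(1.0 - occ[model.closed_index])
    i_avg = float(occ @ model.means)
    return ChannelStats(
        amplitudes=model.means.copy(),
        occupancy=occ,
        p_open=p_open,
        i_avg=i_avg,
        voltage=voltage,
        label=label,
    )


def idealize_recording(
    rec: SingleChannelRecording,
    K: int = 4,
    resample_rate: float = 2_500.0,
    seed: int = 0,
    min_dwell_samples: int = 2,
    **fit_kwargs,
) -> tuple[HMMModel, IdealizedTrace, ChannelStats]:
    """Resample -> Baum-Welch -> Viterbi -> dead-time correction ->
    statistics, in one call. ``min_dwell_samples=1`` disables the
    brief-event suppression."""
    low = resample(rec, resample_rate)
    model, _ = baum_welch_fit(low, K=K, seed=seed, **fit_kwargs)
    ideal = viterbi_idealize(low, model)
    ideal = IdealizedTrace(
        states=suppress_brief_events(ideal.states, min_dwell_samples),
        resample_rate=ideal.resample_rate,
    )
    stats = channel_stats(ideal, model, voltage=rec.voltage, label=rec.genotype)
    return model, ideal, stats


@dataclass
class GroupComparison:
    """Two-group summary of a single-channel metric."""

    labels: tuple[str, str]
    means: tuple[float, float]
    sems: tuple[float, float]
    ratio_of_means: float
    t_statistic: float
    p_value: float
    metric: str = "p_open"


def compare_genotypes(
    stats_by_group: dict[str, Sequence[ChannelStats]],
    metric: str = "p_open",
) -> GroupComparison:
    """Two-tailed unpaired t-test between two groups of channel statistics.

    ``metric`` is ``"p_open"``, ``"i_avg"`` or ``"full_amplitude"`` (the
    largest-magnitude open level). The ratio of means is first group over
    second, in dict insertion order.
    """
    if len(stats_by_group) != 2:
        raise ValueError("exactly two groups are required")
    (la, sa), (lb, sb) = stats_by_group.items()
    if len(sa) < 2 or len(sb) < 2:
        raise ValueError("each group needs at least 2 recordings for a SEM")

    def extract(stats: ChannelStats) -> float:
        if metric == "p_open":
            return stats.p_open
        if metric == "i_avg":
            return stats.i_avg
        if metric == "full_amplitude":
            opens = np.delete(stats.amplitudes, np.argmin(np.abs(stats.amplitudes)))
            return float(opens[np.argmax(np.abs(opens))])
        raise ValueError(f"unknown metric {metric!r}")

    a = np.array([extract(s) for s in sa])
    b = np.array([extract(s) for s in sb])
    if a.std() == 0 and b.std() == 0 and a.mean() == b.mean():
        t, p = 0.0, 1.0  # identical groups: no evidence of a difference
    else:
        t, p = sps.ttest_ind(a, b)
    return GroupComparison(
        labels=(la, lb),
        means=(float(a.mean()), float(b.mean())),
        sems=(float(sps.sem(a)), float(sps.sem(b))),
        ratio_of_means=float(a.mean() / b.mean()),
        t_statistic=float(t),
        p_value=float(p),
        metric=metric,
    )
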