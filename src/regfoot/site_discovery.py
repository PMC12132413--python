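"""From footprints to binding-site calls and emergent-TSS hypotheses.

Footprints fall into three classes: *active_with_sites* (contiguous groups of
high-MI positions, i.e. putative binding sites), *emergent_tss_candidate*
(an isolated single-position spike, the signature of a point mutation that
creates a new transcription start site) and *inactive*.  Classification uses
how the coefficient of variation of the footprint changes upon Gaussian
smoothing: smoothing destroys an isolated spike but leaves a genuine site
block nearly untouched.  Active footprints are segmented with a two-state
Gaussian HMM on log-MI; spike candidates are screened against the sigma-70
-10 element rule (consensus TATAAT; positions 1, 2 and 6 dominate binding).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

import numpy as np
from hmmlearn.hmm import GaussianHMM
from hmmlearn.base import ConvergenceMonitor

from .footprint_stats import ExpressionShiftMatrix, Footprint, smooth_footprint

LOG_MI_FLOOR = 1e-12  # added before the log transform of MI values

#: sigma-70 -10 element consensus and its dominant positions (1-based 1, 2, 6)
MINUS10_CONSENSUS = "TATAAT"
IMPORTANT_POSITIONS = (0, 1, 5)
IMPORTANT_BASES = ("T", "A", "T")

ACTIVE = "active_with_sites"
EMERGENT = "emergent_tss_candidate"
INACTIVE = "inactive"


@dataclass(frozen=True)
class ClassifierConfig:
    """Footprint classification parameters.

    ``activity_threshold`` is the minimum peak MI (bits) for a footprint to
    count as active at all; the default was calibrated on null simulations at
    sequencing depths 1e4-1e6 (see scripts/calibrate_thresholds.py).
    ``cv_ratio_threshold`` is the smoothed/raw CV ratio below which an active
    footprint is called a single-spike (emergent TSS) candidate.
    """

    kernel_sigma: float = 3.0
    cv_ratio_threshold: float = 0.5
    activity_threshold: float = 2e-3

    def __post_init__(self):
        if min(self.kernel_sigma, self.cv_ratio_threshold,
               self.activity_threshold) <= 0:
            raise ValueError("classifier parameters must be positive")


def classify_footprint(fp: Footprint, cfg: ClassifierConfig = ClassifierConfig()
                       ) -> str:
    """Assign one of the three footprint outcome classes."""
    mi = fp.mi
    if mi.max() <= 0 or mi.mean() == 0:
        return INACTIVE
    if mi.max() < cfg.activity_threshold:
        return INACTIVE
    cv_raw = mi.std() / mi.mean()
    if cv_raw == 0:
        return INACTIVE
    smoothed = smooth_footprint(fp, cfg.kernel_sigma).mi
    cv_smooth = smoothed.std() / smoothed.mean()
    if cv_smooth / cv_raw < cfg.cv_ratio_threshold:
        return EMERGENT
    return ACTIVE


# ---------------------------------------------------------------------------
# Two-state HMM segmentation


class _FullHistoryMonitor(ConvergenceMonitor):
    """Convergence monitor that retains every per-iteration log-likelihood."""

    def __init__(self, tol, n_iter, verbose=False):
        super().__init__(tol, n_iter, verbose)
        self.full_history: list[float] = []

    def report(self, log_prob):
        self.full_history.append(log_prob)
        super().report(log_prob)


@dataclass
class TwoStateHMM:
    """Fitted site/background segmentation model over log-transformed MI.

    State 1 ("site") has the larger emission mean.  ``fallback`` marks a
    degenerate EM fit that was replaced by simple threshold segmentation at
    the 90th percentile.
    """

    initial: np.ndarray       # (2,)
    transition: np.ndarray    # (2, 2) row-stochastic
    means: np.ndarray         # (2,) emission means on log MI
    variances: np.ndarray     # (2,) emission variances
    log_likelihoods: list[float] = field(default_factory=list)
    fallback: bool = False
    fallback_threshold: float = float("nan")

    def posterior(self, fp: Footprint) -> np.ndarray:
        """P(site) at every position by forward-backward smoothing."""
        x = transform_mi(fp.mi)
        if self.fallback:
            return (fp.mi >= self.fallback_threshold).astype(float)
        logB = _gaussian_loglik(x, self.means, self.variances)
        with np.errstate(divide="ignore"):
            log_pi = np.log(self.initial)
            log_A = np.log(self.transition)
        gamma = forward_backward(log_pi, log_A, logB)
        return gamma[:, 1]


def transform_mi(mi: np.ndarray) -> np.ndarray:
    """Log transform of the MI footprint used as HMM observations."""
    return np.log(np.asarray(mi, dtype=float) + LOG_MI_FLOOR)


def _gaussian_loglik(x: np.ndarray, means: np.ndarray,
                     variances: np.ndarray) -> np.ndarray:
    x = x[:, None]
    return (-0.5 * np.log(2 * np.pi * variances)[None, :]
            - (x - means[None, :]) ** 2 / (2 * variances[None, :]))


def forward_backward(log_pi: np.ndarray, log_A: np.ndarray,
                     logB: np.ndarray) -> np.ndarray:
    """Posterior state probabilities, computed in log space for stability."""
    from scipy.special import logsumexp

    L, K = logB.shape
    alpha = np.zeros((L, K))
    alpha[0] = log_pi + logB[0]
    for t in range(1, L):
        alpha[t] = logB[t] + logsumexp(alpha[t - 1][:, None] + log_A, axis=0)
    beta = np.zeros((L, K))
    for t in range(L - 2, -1, -1):
        beta[t] = logsumexp(log_A + (logB[t + 1] + beta[t + 1])[None, :], axis=1)
    log_gamma = alpha + beta
    log_gamma -= logsumexp(log_gamma, axis=1, keepdims=True)
    return np.exp(log_gamma)


def fit_two_state_hmm(fp: Footprint, tol: float = 1e-6, n_iter: int = 500,
                      seed: int = 0, min_variance: float = 0.25) -> TwoStateHMM:
    """Baum-Welch fit of the two-state Gaussian HMM on log-transformed MI.

    Emission parameters are initialized from the 25th/90th percentile split
    of the observations; EM stops when the log-likelihood gain falls below
    ``tol`` or after ``n_iter`` iterations.  ``min_variance`` floors the
    emission variances (log-MI units): binding sites of different strength
    produce distinct MI plateaus, and without the floor the site state
    collapses onto the strongest plateau and drops weaker sites into the
    background.  A degenerate fit (collapsed states) falls back to threshold
    segmentation at the 90th percentile.
    """
    x = transform_mi(fp.mi)
    q25, q90 = np.percentile(x, [25, 90])
    lo, hi = x[x <= q25], x[x >= q90]
    spread = max(x.std(), 1e-8)
    if np.ptp(x) < 1e-9:
        return _fallback_model(fp)

    model = GaussianHMM(n_components=2, covariance_type="diag", tol=tol,
                        n_iter=n_iter, init_params="", params="stmc",
                        random_state=seed, min_covar=min_variance)
    model.startprob_ = np.array([0.9, 0.1])
    model.transmat_ = np.array([[0.95, 0.05], [0.1, 0.9]])
    model.means_ = np.array([[lo.mean()], [hi.mean()]])
    model.covars_ = np.array([[max(lo.var(), min_variance)],
                              [max(hi.var(), min_variance)]])
    model.monitor_ = _FullHistoryMonitor(model.monitor_.tol,
                                         model.monitor_.n_iter)
    obs = x[:, None]
    model.fit(obs)

    means = model.means_.ravel()
    variances = model.covars_.ravel()
    order = np.argsort(means)  # state 1 = larger mean = site
    means = means[order]
    variances = variances[order]
    startprob = model.startprob_[order]
    transmat = model.transmat_[np.ix_(order, order)]
    if abs(means[1] - means[0]) < 0.05 * spread:
        return _fallback_model(fp)
    return TwoStateHMM(initial=startprob, transition=transmat, means=means,
                       variances=variances,
                       log_likelihoods=list(model.monitor_.full_history))


def _fallback_model(fp: Footprint) -> TwoStateHMM:
    thr = float(np.percentile(fp.mi, 90))
    return TwoStateHMM(initial=np.array([0.5, 0.5]),
                       transition=np.full((2, 2), 0.5),
                       means=np.zeros(2), variances=np.ones(2),
                       fallback=True, fallback_threshold=thr)


# ---------------------------------------------------------------------------
# Site calls


@dataclass
class SiteCall:
    """One putative binding-site interval on the promoter window."""

    promoter_id: str
    condition: str
    start: int   # 0-based window index, half-open
    end: int
    mean_mi: float
    sign: str    # {"activator-like", "repressor-like", "mixed"}
    posterior: float


def call_sites(fp: Footprint, hmm: TwoStateHMM,
               shifts: ExpressionShiftMatrix | None = None,
               min_site_length: int = 4, merge_gap: int = 2,
               posterior_cut: float = 0.5,
               shift_noise_floor: float = 0.15) -> list[SiteCall]:
    """Posterior-decode binding-site intervals and sign them from shifts.

    Positions with P(site) > ``posterior_cut`` are segmented; gaps up to
    ``merge_gap`` are bridged and segments shorter than ``min_site_length``
    dropped.  The sign is the coverage-weighted mean expression shift of
    mutations inside the interval: positive shifts mean mutations increase
    expression (repressor-like), negative activator/RNAP-like, magnitudes
    below ``shift_noise_floor`` log2 units are reported as mixed.
    """
    post = hmm.posterior(fp)
    on = post > posterior_cut
    segments = _segments(on, merge_gap, min_site_length)
    calls = []
    for start, end in segments:
        if shifts is None:
            sign = "mixed"
        else:
            mean_shift = shifts.mean_shift(start, end)
            if not np.isfinite(mean_shift) or abs(mean_shift) < shift_noise_floor:
                sign = "mixed"
            elif mean_shift > 0:
                sign = "repressor-like"
            else:
                sign = "activator-like"
        calls.append(SiteCall(promoter_id=fp.promoter_id, condition=fp.condition,
                              start=start, end=end,
                              mean_mi=float(fp.mi[start:end].mean()), sign=sign,
                              posterior=float(post[start:end].mean())))
    return calls


def _segments(on: np.ndarray, merge_gap: int, min_length: int
              ) -> list[tuple[int, int]]:
    idx = np.flatnonzero(on)
    if idx.size == 0:
        return []
    segments = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev - 1 <= merge_gap:
            prev = i
        else:
            segments.append((start, prev + 1))
            start = prev = i
    segments.append((start, prev + 1))
    return [(s, e) for s, e in segments if e - s >= min_length]


def jaccard(calls: list[SiteCall] | list[tuple[int, int]],
            truth: list[tuple[int, int]], length: int = 160) -> float:
    """Jaccard index between called and true site intervals (position sets)."""
    called = np.zeros(length, bool)
    for c in calls:
        s, e = (c.start, c.end) if isinstance(c, SiteCall) else c
        called[s:e] = True
    planted = np.zeros(length, bool)
    for s, e in truth:
        planted[s:e] = True
    union = (called | planted).sum()
    return float((called & planted).sum() / union) if union else 1.0


# ---------------------------------------------------------------------------
# Emergent transcription start sites (single-mutation -10 creation)


@dataclass(frozen=True)
class EmergentTss:
    """A single substitution completing the -10 element's important triple."""

    position: int          # 0-based window index of the mutated base
    creating_base: str
    hexamer_start: int     # 0-based start of the hexamer frame
    pre_match: tuple[bool, bool, bool]
    post_match: tuple[bool, bool, bool]


def _triple_match(hexamer: str) -> tuple[bool, bool, bool]:
    return tuple(hexamer[i] == b
                 for i, b in zip(IMPORTANT_POSITIONS, IMPORTANT_BASES))


def minus10_completing_events(sequence: str, position: int,
                              base: str) -> list[EmergentTss]:
    """All hexamer frames where substituting ``base`` at ``position`` makes
    positions 1, 2 and 6 match TATAAT while they did not before."""
    if sequence[position] == base:
        return []
    mutant = sequence[:position] + base + sequence[position + 1:]
    events = []
    for f in range(6):
        start = position - f
        if start < 0 or start + 6 > len(sequence):
            continue  # frame truncated at the window edge
        pre = _triple_match(sequence[start:start + 6])
        post = _triple_match(mutant[start:start + 6])
        if all(post) and not all(pre):
            events.append(EmergentTss(position=position, creating_base=base,
                                      hexamer_start=start, pre_match=pre,
                                      post_match=post))
    return events


def detect_emergent_tss(wildtype: str, shifts: ExpressionShiftMatrix,
                        spike_position: int,
                        shift_threshold: float = 1.0) -> list[EmergentTss]:
    """Screen a classified spike position for -10-creating substitutions.

    For every substitution at the spike with a strongly positive expression
    shift (> ``shift_threshold`` log2 units) and each of the six hexamer
    frames covering the position, report frames where the mutation completes
    the important TATAAT triple (positions 1, 2, 6).
    """
    events = []
    for code, base in enumerate("ACGT"):
        if base == wildtype[spike_position]:
            continue
        delta = shifts.shifts[code, spike_position]
        if not np.isfinite(delta) or delta <= shift_threshold:
            continue
        events.extend(minus10_completing_events(wildtype, spike_position, base))
    return events


def scan_minus10_creations(sequence: str) -> list[EmergentTss]:
    """Enumerate every single substitution anywhere that creates the triple."""
    events = []
    for pos, base in product(range(len(sequence)), "ACGT"):
        events.extend(minus10_completing_events(sequence, pos, base))
    return events
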