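"""Trial-wise spike-train statistics.

Turns per-trial spike times into the response measures used throughout the
study: PSTHs, firing rates, the summation index (SmI) with its inclusion
criteria and MAX-like / sublinear / AND-like classes, pitch selectivity
(response sparseness), cross-adaptation ratios, and leave-one-trial-out
SmI variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

MAX_LIKE = "MAX-like"
SUBLINEAR = "sublinear"
AND_LIKE = "AND-like"


@dataclass
class TrialSet:
    """Spike times for repeated presentations of one stimulus.

    Times are in ms relative to stimulus onset; the spontaneous window
    precedes the stimulus (negative times).
    """

    trials: list  # list of sorted 1-D arrays (ms)
    window_ms: tuple[float, float]
    spont_window_ms: tuple[float, float] = (-500.0, 0.0)
    stimulus_id: str = ""

    def __post_init__(self):
        if len(self.trials) < 1:
            raise ValueError("TrialSet needs at least one trial")
        self.trials = [np.sort(np.asarray(t, dtype=float))
                       for t in self.trials]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def counts(self, window: tuple[float, float] | None = None) -> np.ndarray:
        t0, t1 = window or self.window_ms
        return np.array([np.count_nonzero((t >= t0) & (t < t1))
                         for t in self.trials])

    def rates(self, window: tuple[float, float] | None = None) -> np.ndarray:
        t0, t1 = window or self.window_ms
        return 1000.0 * self.counts((t0, t1)) / (t1 - t0)

    def mean_rate(self) -> float:
        return float(np.mean(self.rates()))

    def spont_counts(self) -> np.ndarray:
        return self.counts(self.spont_window_ms)

    def spont_rate(self) -> float:
        t0, t1 = self.spont_window_ms
        return float(1000.0 * np.mean(self.spont_counts()) / (t1 - t0))


def psth(trials: TrialSet, bin_ms: float = 10.0,
         t_range: tuple[float, float] | None = None
         ) -> tuple[np.ndarray, np.ndarray]:
    """Peristimulus time histogram in Hz.

    Returns ``(rates, edges)``: per-bin spike counts averaged over trials
    and divided by the bin width.
    """
    if bin_ms <= 0:
        raise ValueError("bin width must be positive")
    t0, t1 = t_range or trials.window_ms
    edges = np.arange(t0, t1 + bin_ms, bin_ms)
    counts = np.zeros(edges.size - 1)
    for t in trials.trials:
        counts += np.histogram(t, bins=edges)[0]
    rates = 1000.0 * counts / (trials.n_trials * bin_ms)
    return rates, edges


def summation_index(r_a: float, r_b: float, r_ab: float) -> float:
    """SmI = (R_ab - max(R_a, R_b)) / min(R_a, R_b).

    0 marks a MAX-like (OR-type) response, 1 a linear sum, and values >= 1
    AND-like (supralinear) pooling.  Undefined when the weaker individual
    response is zero.
    """
    lo = min(r_a, r_b)
    if lo <= 0:
        raise ValueError(
            "SmI undefined for min(R_a, R_b) = 0; use the subthreshold "
            "inclusion path instead")
    return (r_ab - max(r_a, r_b)) / lo


def classify_smi(smi: float, and_boundary: float = 1.0) -> str:
    """Map an SmI value to its integration class."""
    if not np.isfinite(smi) and smi > 0:
        return AND_LIKE  # subthreshold-pair sentinel (+inf)
    if smi <= 0:
        return MAX_LIKE
    if smi < and_boundary:
        return SUBLINEAR
    return AND_LIKE


def inclusion_filter(set_a: TrialSet, set_b: TrialSet, set_ab: TrialSet,
                     alpha: float = 0.05) -> tuple[bool, str]:
    """Decide whether a stimulus pair enters the SmI analysis.

    Path (i): each individual response significantly exceeds spontaneous
    activity (one-sided Wilcoxon signed-rank on per-trial evoked minus
    spontaneous counts).  Path (ii): the combined response is at least 25%
    above the dominant individual response.
    """
    def significant(ts: TrialSet) -> bool:
        if ts.n_trials < 3:
            return False
        t0, t1 = ts.window_ms
        s0, s1 = ts.spont_window_ms
        # compare rates so unequal window lengths do not bias the test
        diff = ts.rates() - 1000.0 * ts.spont_counts() / (s1 - s0)
        if np.all(diff == 0):
            return False
        try:
            res = stats.wilcoxon(diff[diff != 0], alternative="greater")
        except ValueError:
            return False
        return res.pvalue < alpha and np.median(diff) > 0

    if set_a.n_trials < 3 or set_b.n_trials < 3:
        logger.info("fewer than 3 trials: only the 25%%-above-dominant "
                    "inclusion path is evaluated")
        path_i = False
    else:
        path_i = significant(set_a) and significant(set_b)
    if path_i:
        return True, "individual responses above spontaneous"
    dominant = max(set_a.mean_rate(), set_b.mean_rate())
    if dominant > 0 and set_ab.mean_rate() >= 1.25 * dominant:
        return True, "combined response >= 1.25 x dominant"
    return False, "excluded"


@dataclass
class SmIRecord:
    """SmI and bookkeeping for one syllable pair under one condition."""

    r_a: float
    r_b: float
    r_ab: float
    smi: float
    smi_class: str
    lag_ms: float
    included: bool = True
    inclusion_reason: str = ""
    pair_id: int = -1
    r_spatial: float = np.nan
    r_temporal: float = np.nan
    overlap_label: str = ""


def smi_record(set_a: TrialSet, set_b: TrialSet, set_ab: TrialSet,
               lag_ms: float = 0.0, pair_id: int = -1) -> SmIRecord:
    """Build a full SmIRecord from the three trial sets.

    Subthreshold pairs (min individual rate = 0) that pass the combined-
    response inclusion path are recorded with SmI = +inf and class
    AND-like, mirroring pairs of individually ineffective syllables that
    drive the neuron only in conjunction.
    """
    r_a, r_b, r_ab = (set_a.mean_rate(), set_b.mean_rate(),
                      set_ab.mean_rate())
    included, reason = inclusion_filter(set_a, set_b, set_ab)
    if min(r_a, r_b) > 0:
        smi = summation_index(r_a, r_b, r_ab)
    else:
        smi = np.inf if (included and r_ab > 0) else np.nan
    cls = classify_smi(smi) if not np.isnan(smi) else ""
    return SmIRecord(r_a=r_a, r_b=r_b, r_ab=r_ab, smi=smi, smi_class=cls,
                     lag_ms=lag_ms, included=included,
                     inclusion_reason=reason, pair_id=pair_id)


def pitch_selectivity(rates) -> float:
    """Sparseness of responses across n pitch-shifted variants.

    S = [1 - (sum r_i / n)^2 / (sum r_i^2 / n)] / (1 - 1/n), in [0, 1]:
    0 for a uniform response across variants, 1 when exactly one variant
    drives the neuron.
    """
    r = np.asarray(rates, dtype=float)
    if r.size < 2:
        raise ValueError("need at least two pitch variants")
    if np.any(r < 0):
        raise ValueError("rates must be nonnegative")
    if np.all(r == 0):
        raise ValueError("selectivity undefined for all-zero rates")
    n = r.size
    s = 1.0 - (np.sum(r) / n) ** 2 / (np.sum(r ** 2) / n)
    return float(s / (1.0 - 1.0 / n))


@dataclass
class AdaptationResult:
    ratio_fwd: float
    ratio_rev: float
    category: str  # bidirectional | asymmetric | none


def cross_adaptation(before_fwd: TrialSet, after_fwd: TrialSet,
                     before_rev: TrialSet, after_rev: TrialSet,
                     threshold: float = 0.6) -> AdaptationResult:
    """Input-independence categories from the cross-adaptation protocol.

    For each presentation order, the ratio of the deviant-syllable
    response after versus before adaptation is computed; a ratio >= 0.6
    indicates a preserved (input-independent) response.  Independence in
    both orders is bidirectional, in exactly one asymmetric, otherwise
    none.
    """
    def ratio(before: TrialSet, after: TrialSet) -> float:
        rb = before.mean_rate()
        if rb == 0:
            raise ValueError("adaptation ratio undefined: zero pre-"
                             "adaptation response")
        return after.mean_rate() / rb

    fwd = ratio(before_fwd, after_fwd)
    rev = ratio(before_rev, after_rev)
    n_pass = int(fwd >= threshold) + int(rev >= threshold)
    category = {2: "bidirectional", 1: "asymmetric", 0: "none"}[n_pass]
    return AdaptationResult(ratio_fwd=fwd, ratio_rev=rev, category=category)


def loto_smi_variability(set_a: TrialSet, set_b: TrialSet,
                         set_ab: TrialSet) -> float:
    """Leave-one-trial-out standard deviation of the SmI.

    Trials are paired by index across the three conditions; if the trial
    counts differ the procedure runs over the smallest count (logged).
    """
    n = min(set_a.n_trials, set_b.n_trials, set_ab.n_trials)
    if n < 3:
        raise ValueError("leave-one-trial-out needs at least 3 trials")
    if len({set_a.n_trials, set_b.n_trials, set_ab.n_trials}) > 1:
        logger.warning("unequal trial counts; leave-one-out over the "
                       "first %d trials of each condition", n)

    def loo_rate(ts: TrialSet, k: int) -> float:
        rates = ts.rates()[:n]
        return float(np.mean(np.delete(rates, k)))

    smis = []
    for k in range(n):
        smis.append(summation_index(loo_rate(set_a, k), loo_rate(set_b, k),
                                    loo_rate(set_ab, k)))
    return float(np.std(smis, ddof=1))


def optimal_lag(records: list[SmIRecord]) -> SmIRecord:
    """The record with maximal combined-stimulus response.

    Ties are broken toward the smaller absolute lag, then the negative
    lag, so the choice is deterministic.
    """
    if not records:
        raise ValueError("no records")
    return max(records,
               key=lambda r: (r.r_ab, -abs(r.lag_ms), -r.lag_ms))
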