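"""Derived statistics: dendritic-spike detection, NRLE, tuning metrics,
Euler-formula preference expectation, spike classification, and the
morphometry-matched apical/basal comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .synapses import orientation_distance


# ---------------------------------------------------------------------------
# Dendritic spike detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DendriticSpikeCriterion:
    """A local transient counts as a dendritic spike when its peak rises at
    least `min_amplitude` above baseline AND its maximal rate of rise is at
    least `min_slope`. The published detection rule is not printed; this
    two-gate criterion is the package default and is echoed in outputs."""
    min_slope: float = 10.0      # mV/ms
    min_amplitude: float = 20.0  # mV above baseline


def detect_dendritic_spike(local_trace: np.ndarray, dt: float,
                           baseline: float | None = None,
                           criterion: DendriticSpikeCriterion =
                           DendriticSpikeCriterion()) -> tuple[bool, dict]:
    """Returns (is_spike, {'peak_amplitude', 'max_slope'})."""
    v = np.asarray(local_trace, dtype=float)
    if baseline is None:
        baseline = v[0]
    peak = float(v.max() - baseline)
    slope = float(np.diff(v).max() / dt) if v.size > 1 else 0.0
    ok = (slope >= criterion.min_slope) and (peak >= criterion.min_amplitude)
    return ok, {"peak_amplitude": peak, "max_slope": slope}


# ---------------------------------------------------------------------------
# NRLE
# ---------------------------------------------------------------------------

def nrle(actual_peaks: np.ndarray) -> float:
    """Nonlinearity Relative to Linear Extrapolation.

    actual_peaks[n-1] is the peak response to n simultaneous inputs.
    NRLE = max_{n>=2} actual(n) / (n * actual(1)); 1 is linear, < 1
    sublinear, > 1 supralinear.
    """
    a = np.asarray(actual_peaks, dtype=float)
    if a.size < 2:
        raise ValueError("need responses for at least n = 1, 2")
    if a[0] <= 0:
        raise ValueError("unitary response must be positive")
    n = np.arange(2, a.size + 1)
    return float(np.max(a[1:] / (n * a[0])))


def expected_peaks(actual_unitary: float, n_max: int) -> np.ndarray:
    """Linear-dendrite expectation: n times the unitary response."""
    return actual_unitary * np.arange(1, n_max + 1)


# ---------------------------------------------------------------------------
# Orientation tuning metrics
# ---------------------------------------------------------------------------

@dataclass
class TuningCurve:
    orientations: np.ndarray  # degrees, unique
    mean_rate: np.ndarray     # Hz
    sem_rate: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        self.orientations = np.asarray(self.orientations, dtype=float)
        self.mean_rate = np.asarray(self.mean_rate, dtype=float)
        self.sem_rate = np.asarray(self.sem_rate, dtype=float)
        if len(np.unique(self.orientations)) != self.orientations.size:
            raise ValueError("orientations must be unique")


@dataclass
class TuningMetrics:
    osi: float
    width: float        # sigma of the wrapped-Gaussian fit, degrees
    preferred: float    # degrees in [0, 180)
    rate_pref: float
    rate_orth: float
    defined: bool = True


def _wrapped_gaussian(theta, base, amp, mu, sigma):
    d = orientation_distance(theta, mu)
    return base + amp * np.exp(-d**2 / (2.0 * sigma**2))


def tuning_metrics(curve: TuningCurve) -> TuningMetrics:
    """Fit a wrapped Gaussian to the curve; preferred = fitted center,
    width = fitted sigma, OSI = (R_pref - R_orth)/(R_pref + R_orth) using
    the curve interpolated at the fitted preferred and preferred + 90."""
    th, r = curve.orientations, curve.mean_rate
    if np.all(r <= 0):
        return TuningMetrics(math.nan, math.nan, math.nan, 0.0, 0.0,
                             defined=False)
    mu0 = float(th[np.argmax(r)])
    base0 = float(max(r.min(), 1e-9))
    amp0 = float(max(r.max() - r.min(), 1e-9))
    try:
        popt, _ = optimize.curve_fit(
            _wrapped_gaussian, th, r, p0=[base0, amp0, mu0, 30.0],
            bounds=([0.0, 0.0, -360.0, 1.0],
                    [np.inf, np.inf, 360.0, 200.0]), maxfev=10000)
        base, amp, mu, sigma = popt
        mu %= 180.0
    except RuntimeError:
        mu, sigma = mu0, math.nan
    r_pref = _interp_circular(th, r, mu)
    r_orth = _interp_circular(th, r, (mu + 90.0) % 180.0)
    if r_pref + r_orth > 0:
        osi = (r_pref - r_orth) / (r_pref + r_orth)
    else:
        osi = math.nan
    return TuningMetrics(float(osi), float(sigma), float(mu),
                         float(r_pref), float(r_orth))


def _interp_circular(th: np.ndarray, r: np.ndarray, x: float) -> float:
    """Linear interpolation on the 180-degree circle."""
    order = np.argsort(th)
    th_s, r_s = th[order], r[order]
    th_ext = np.concatenate([th_s, th_s[:1] + 180.0])
    r_ext = np.concatenate([r_s, r_s[:1]])
    x = x % 180.0
    if x < th_ext[0]:
        x += 180.0
    return float(np.interp(x, th_ext, r_ext))


def osi_from_rates(rate_pref: float, rate_orth: float) -> float:
    if rate_pref + rate_orth <= 0:
        raise ValueError("rates must be positive")
    return (rate_pref - rate_orth) / (rate_pref + rate_orth)


# ---------------------------------------------------------------------------
# Euler-formula expected preference
# ---------------------------------------------------------------------------

def expected_preference_euler(preferences, weights=None
                              ) -> tuple[float | None, float]:
    """Linear-summation expectation of the somatic orientation preference:
    0.5 * arg(sum_j w_j e^{i 2 theta_j}), mapped to [0, 180).

    Returns (preference_or_None, resultant_magnitude); the preference is
    None (undefined) when the resultant vanishes (antipodal inputs).
    """
    th = np.asarray(preferences, dtype=float)
    if th.size == 0:
        raise ValueError("need at least one preference")
    w = np.ones_like(th) if weights is None else np.asarray(weights, float)
    if np.any(w < 0) or np.all(w == 0):
        raise ValueError("weights must be non-negative, not all zero")
    z = np.sum(w * np.exp(1j * 2.0 * np.deg2rad(th)))
    mag = float(abs(z)) / float(np.sum(w))
    if abs(z) < 1e-9 * np.sum(w):
        return None, mag
    return float(np.rad2deg(np.angle(z)) / 2.0) % 180.0, mag


# ---------------------------------------------------------------------------
# Somatic spike classification under paired interventions
# ---------------------------------------------------------------------------

LABELS = ("apically_driven", "basally_driven", "cooperative", "independent")


def classify_spike(survived_apical: bool, survived_basal: bool) -> str:
    """A spike lost only under the apical intervention is apically driven;
    lost only under basal, basally driven; lost under both, cooperative;
    lost under neither, independent."""
    if not survived_apical and survived_basal:
        return "apically_driven"
    if survived_apical and not survived_basal:
        return "basally_driven"
    if not survived_apical and not survived_basal:
        return "cooperative"
    return "independent"


def class_percentages(labels: list[str]) -> dict[str, float]:
    n = len(labels)
    return {lab: (100.0 * labels.count(lab) / n if n else math.nan)
            for lab in LABELS}


# ---------------------------------------------------------------------------
# Morphometry-matched comparisons
# ---------------------------------------------------------------------------

@dataclass
class MatchedComparison:
    response: str
    covariate: str | None
    normalized: bool
    apical_mean: float
    apical_sd: float
    basal_mean: float
    basal_sd: float
    n_apical: int
    n_basal: int
    t_stat: float
    p_value: float
    excluded: tuple[int, ...] = ()


def matched_compare(profiles: pd.DataFrame, response_col: str,
                    covariate_col: str | None = None,
                    normalize: bool = False,
                    paired: bool = False,
                    exclude_segments: tuple[int, ...] = ()
                    ) -> MatchedComparison:
    """Apical-vs-basal comparison of a per-segment response, optionally
    normalized by a morphometric covariate. Unpaired groups use the
    independent two-sample t-test; paired designs the dependent t-test.
    Outlier exclusion is explicit by segment id and recorded in the result.
    """
    df = profiles[~profiles["segment_id"].isin(exclude_segments)].copy()
    y = df[response_col].astype(float)
    if normalize:
        if covariate_col is None:
            raise ValueError("normalize requires a covariate")
        y = y / df[covariate_col].astype(float)
    ap = y[df["tree_label"] == "apical"].to_numpy()
    ba = y[df["tree_label"] == "basal"].to_numpy()
    if len(ap) < 2 or len(ba) < 2:
        raise ValueError("need at least two segments per tree")
    if np.ptp(np.concatenate([ap, ba])) == 0:
        t, p = 0.0, 1.0  # degenerate: all values identical
    elif paired:
        if len(ap) != len(ba):
            raise ValueError("paired design requires equal group sizes")
        t, p = stats.ttest_rel(ap, ba)
    else:
        t, p = stats.ttest_ind(ap, ba)
    return MatchedComparison(
        response_col, covariate_col, normalize,
        float(np.mean(ap)), float(np.std(ap, ddof=1)),
        float(np.mean(ba)), float(np.std(ba, ddof=1)),
        len(ap), len(ba), float(t), float(p), tuple(exclude_segments))
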