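"""Go/no-go psychophysics: d-prime, constrained logistic fits, LR test.

Hit rates per (location, spatial frequency) are modeled as a decreasing
logistic of spatial frequency with the guess rate fixed at the session's
false-alarm rate and a lapse rate shared across locations. The "full" model
gives each location its own inflexion point (threshold) with a shared slope;
the "restricted" model shares the inflexion point too. Location dependence is
tested with the likelihood ratio LR = -2*(ll_restricted - ll_full) against a
chi-squared distribution (1 df by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2, norm


def _corrected_rate(k: int, n: int) -> float:
    if n <= 0:
        raise ValueError("zero trials")
    r = k / n
    if r <= 0.0:
        return 1.0 / (2.0 * n)
    if r >= 1.0:
        return 1.0 - 1.0 / (2.0 * n)
    return r


def dprime(n_hits: int, n_go: int, n_fas: int, n_nogo: int) -> float:
    """d' = Z(HR) - Z(FAR) with 0/1 rates corrected to 1/(2N), 1 - 1/(2N)."""
    hr = _corrected_rate(n_hits, n_go)
    far = _corrected_rate(n_fas, n_nogo)
    return float(norm.ppf(hr) - norm.ppf(far))


@dataclass
class PsychometricFit:
    """Constrained logistic psychometric model fit by binomial ML.

    alpha maps location -> inflexion point (threshold, cycles/deg); slope is
    shared across locations; guess is fixed at the false-alarm rate; lapse is
    shared. For the restricted model all locations share one alpha.
    """

    model: str
    guess: float
    lapse: float
    slope: float
    alpha: dict = field(default_factory=dict)
    log_likelihood: float = np.nan
    n_params: int = 0
    identifiable: bool = True

    def predict(self, sf, location=None):
        a = self.alpha[location] if location is not None else next(iter(self.alpha.values()))
        z = self.slope * (np.asarray(sf, dtype=float) - a)
        return self.guess + (1.0 - self.guess - self.lapse) / (1.0 + np.exp(z))

    def threshold(self, location=None):
        if location is None:
            return dict(self.alpha)
        return self.alpha[location]


def _binom_ll(p, hits, n):
    p = np.clip(p, 1e-9, 1.0 - 1e-9)
    return float(np.sum(hits * np.log(p) + (n - hits) * np.log(1.0 - p)))


def fit_psychometric(
    table: pd.DataFrame,
    n_nogo: int,
    n_false_alarms: int,
    model: str = "full",
) -> PsychometricFit:
    """ML fit of the constrained logistic to per-(location, sf) hit counts.

    ``table`` columns: location, sf, n_go, n_hits. P(hit | sf, loc) =
    guess + (1 - guess - lapse) / (1 + exp(slope*(sf - alpha_loc))), so the
    curve decreases with spatial frequency for positive slope. guess is fixed
    at FAR = n_false_alarms / n_nogo. Multi-start L-BFGS-B; the best converged
    start wins. A fit whose hit rates barely exceed guess across the range is
    flagged as unidentifiable (alpha poorly constrained).
    """
    if model not in ("full", "restricted"):
        raise ValueError(f"unknown model {model!r}")
    locs = sorted(table["location"].unique())
    for loc in locs:
        if (table["location"] == loc).sum() < 3:
            raise ValueError(f"location {loc!r} has fewer than 3 SF levels")
    guess = _corrected_rate(n_false_alarms, n_nogo)
    sf = table["sf"].to_numpy(dtype=float)
    n = table["n_go"].to_numpy(dtype=float)
    hits = table["n_hits"].to_numpy(dtype=float)
    loc_idx = np.array([locs.index(l) for l in table["location"]])
    n_alpha = 1 if model == "restricted" else len(locs)

    sf_lo, sf_hi = sf.min(), sf.max()
    span = max(sf_hi - sf_lo, 1e-6)

    # params: [log_slope, logit-ish lapse (raw in [0, 1-guess)), alpha...]
    def unpack(p):
        slope = np.exp(p[0])
        lapse = (1.0 - guess - 1e-6) / (1.0 + np.exp(-p[1]))
        alphas = p[2:]
        return slope, lapse, alphas

    def nll(p):
        slope, lapse, alphas = unpack(p)
        a = alphas[0] if n_alpha == 1 else alphas[loc_idx]
        z = np.clip(slope * (sf - a), -500, 500)
        prob = guess + (1.0 - guess - lapse) / (1.0 + np.exp(z))
        return -_binom_ll(prob, hits, n)

    starts = []
    for s0 in (2.0 / span, 8.0 / span, 30.0 / span):
        for a0 in (sf_lo + 0.25 * span, sf_lo + 0.5 * span, sf_lo + 0.75 * span):
            starts.append(np.concatenate([[np.log(s0), -2.0], np.full(n_alpha, a0)]))
    best = None
    bounds = [(None, None), (-20.0, 20.0)] + [(sf_lo - span, sf_hi + span)] * n_alpha
    for p0 in starts:
        res = minimize(nll, p0, method="L-BFGS-B", bounds=bounds)
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise ValueError("psychometric fit failed from every start")
    slope, lapse, alphas = unpack(best.x)
    alpha = {loc: float(alphas[0] if n_alpha == 1 else alphas[i])
             for i, loc in enumerate(locs)}
    # identifiability: the fitted curve must actually move across the range
    rng_p = abs(
        (1.0 - guess - lapse)
        * (1.0 / (1.0 + np.exp(slope * (sf_lo - np.mean(list(alpha.values())))))
           - 1.0 / (1.0 + np.exp(slope * (sf_hi - np.mean(list(alpha.values()))))))
    )
    return PsychometricFit(
        model=model,
        guess=float(guess),
        lapse=float(lapse),
        slope=float(slope),
        alpha=alpha,
        log_likelihood=float(-best.fun),
        n_params=2 + n_alpha,
        identifiable=bool(rng_p > 0.05),
    )


@dataclass
class LRTestResult:
    lr: float
    df: int
    p: float


def lr_test(
    full: PsychometricFit,
    restricted: PsychometricFit,
    df: int | str = 1,
) -> LRTestResult:
    """Likelihood-ratio test LR = -2*(ll_restricted - ll_full) vs chi2(df).

    ``df`` defaults to 1; pass "locations" to use (n_locations - 1) instead
    (the conventional count for per-location inflexion parameters).
    Negative LR beyond -1e-6 signals an optimizer failure and raises.
    """
    lr = -2.0 * (restricted.log_likelihood - full.log_likelihood)
    if lr < -1e-6:
        raise ValueError(f"negative LR ({lr}): full model fit worse than restricted")
    lr = max(lr, 0.0)
    if df == "locations":
        df = max(len(full.alpha) - 1, 1)
    p = float(chi2.sf(lr, df))
    return LRTestResult(float(lr), int(df), p)
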