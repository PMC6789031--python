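"""Information per spike over stimulus categories.

The statistic (Skaggs-style) is

    I = (1 / lam) * sum_i  lam_i * log2(lam_i / lam) * p_i        [bits/spike]

where ``p_i`` is the occupancy probability of category ``i``, ``lam_i`` the
firing rate within it, and ``lam = sum_i p_i lam_i`` the occupancy-weighted
mean rate.  Categories here are the touch episodes of each individual
partner (identity coding) or {baseline, touch-with-male, touch-with-female}
(sex coding).  Significance comes from a circular-shift null; the excess of
real over sex-shuffled information is tested with a per-unit random-
intercept mixed model because shuffles within a unit are dependent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session import Session

__all__ = [
    "info_per_spike",
    "InfoResult",
    "category_rates",
    "unit_info",
    "info_shuffle_test",
    "sex_info_delta",
    "delta_info_test",
]


def info_per_spike(rates, probs) -> float:
    """Bits of category information per spike.

    ``0 * log 0 := 0``; raises if the mean rate is zero (no spikes to carry
    information) or the occupancies do not sum to 1.
    """
    lam_i = np.asarray(rates, dtype=float)
    p = np.asarray(probs, dtype=float)
    if lam_i.shape != p.shape:
        raise ValueError("rates and probabilities must align")
    if np.any(p < 0) or not np.isclose(p.sum(), 1.0):
        raise ValueError("occupancy probabilities must be >= 0 and sum to 1")
    lam = float(p @ lam_i)
    if lam <= 0:
        raise ValueError("mean rate is zero; information per spike undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = lam_i * np.log2(lam_i / lam) * p
    terms[lam_i == 0] = 0.0
    return float(terms.sum() / lam)


@dataclass
class InfoResult:
    info_per_spike: float
    p_shuffle: float | None
    n_shuffles: int
    categories: list
    rates: np.ndarray
    probs: np.ndarray


def _occupancy_and_counts(spike_times, intervals_by_cat):
    """Per-category occupancy time and spike count.

    ``intervals_by_cat`` maps category -> list of (start, stop).  Rates are
    estimated as total spikes / total occupancy time per category.
    """
    cats = list(intervals_by_cat)
    occ = np.zeros(len(cats))
    cnt = np.zeros(len(cats))
    t = np.asarray(spike_times)
    for j, c in enumerate(cats):
        for a, b in intervals_by_cat[c]:
            occ[j] += b - a
            cnt[j] += int(((t >= a) & (t < b)).sum())
    return cats, occ, cnt


def category_rates(spike_times, intervals_by_cat):
    """(categories, rates, occupancy probabilities) for arbitrary interval
    categories."""
    cats, occ, cnt = _occupancy_and_counts(spike_times, intervals_by_cat)
    if occ.sum() <= 0:
        raise ValueError("zero total occupancy")
    keep = occ > 0
    cats = [c for c, k in zip(cats, keep) if k]
    occ, cnt = occ[keep], cnt[keep]
    return cats, cnt / occ, occ / occ.sum()


def _partner_intervals(session: Session):
    by = {}
    for e in session.episodes:
        by.setdefault(e.partner_id, []).append((e.onset, e.offset))
    return by


def _sex_intervals(session: Session, partner_label=None):
    """{baseline, touch_male, touch_female} intervals.  ``partner_label``
    optionally overrides each partner's sex (1 = male), for label shuffles."""
    partners = sorted({e.partner_id for e in session.episodes})
    if partner_label is None:
        lab = {
            p: next(e.partner_sex for e in session.episodes if e.partner_id == p)
            for p in partners
        }
    else:
        lab = {p: ("M" if partner_label[j] else "F")
               for j, p in enumerate(partners)}
    male, female = [], []
    for e in session.episodes:
        (male if lab[e.partner_id] == "M" else female).append((e.onset, e.offset))
    touch_time = sum(b - a for a, b in male + female)
    baseline = [(0.0, session.end)]
    base_occ = session.end - touch_time
    return {"baseline": baseline, "touch_male": male, "touch_female": female}, base_occ


def _sex_info(session, spike_times, partner_label=None):
    ivals, base_occ = _sex_intervals(session, partner_label)
    # baseline = session minus touch; compute via complement counts
    t = np.asarray(spike_times)
    occ, cnt, cats = [], [], []
    n_total = t.size
    touch_cnt = 0
    for c in ("touch_male", "touch_female"):
        o = sum(b - a for a, b in ivals[c])
        k = sum(int(((t >= a) & (t < b)).sum()) for a, b in ivals[c])
        touch_cnt += k
        if o > 0:
            cats.append(c)
            occ.append(o)
            cnt.append(k)
    cats.append("baseline")
    occ.append(base_occ)
    cnt.append(n_total - touch_cnt)
    occ = np.array(occ, dtype=float)
    cnt = np.array(cnt, dtype=float)
    return info_per_spike(cnt / occ, occ / occ.sum())


def unit_info(session: Session, unit_id) -> InfoResult:
    """Observed information per spike over per-partner touch episodes."""
    cats, rates, probs = category_rates(
        session.units[unit_id], _partner_intervals(session)
    )
    return InfoResult(
        info_per_spike=info_per_spike(rates, probs),
        p_shuffle=None, n_shuffles=0, categories=cats, rates=rates, probs=probs,
    )


def info_shuffle_test(
    session: Session, unit_id, n_shuffles=200, seed=None, min_shift=1.0
) -> InfoResult:
    """Circular-shift significance test of per-partner information.

    The null rotates the spike train relative to the episode timeline
    (equivalent to circularly shifting the episode timing over the
    recording); p is the plus-one upper-tail permutation estimate.
    """
    rng = np.random.default_rng(seed)
    t = np.asarray(session.units[unit_id], dtype=float)
    T = session.end
    ivals = _partner_intervals(session)
    cats, rates, probs = category_rates(t, ivals)
    obs = info_per_spike(rates, probs)
    null = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shift = rng.uniform(min_shift, T - min_shift)
        ts = np.sort((t + shift) % T)
        _, r, p = category_rates(ts, ivals)
        null[k] = info_per_spike(r, p)
    pval = (1 + int((null >= obs).sum())) / (n_shuffles + 1)
    return InfoResult(
        info_per_spike=obs, p_shuffle=pval, n_shuffles=n_shuffles,
        categories=cats, rates=rates, probs=probs,
    )


def sex_info_delta(session: Session, unit_id, n_shuffles=20, seed=None
                   ) -> pd.DataFrame:
    """Per-shuffle excess information about real vs shuffled partner sex.

    For each shuffle, partner sex labels are permuted at the partner level
    (the same convention as the GLM sex shuffle) and

        dI = I(baseline, touch-male, touch-female)  -  I(same, labels shuffled)

    is recorded.  Returns a frame with columns ``unit_id, shuffle, delta_i``.
    """
    rng = np.random.default_rng(seed)
    t = session.units[unit_id]
    partners = sorted({e.partner_id for e in session.episodes})
    labels = np.array(
        [next(e.partner_sex for e in session.episodes if e.partner_id == p) == "M"
         for p in partners], dtype=float,
    )
    if labels.min() == labels.max():
        warnings.warn("all partners share one sex; delta-information undefined")
    real = _sex_info(session, t)
    rows = []
    for k in range(n_shuffles):
        perm = rng.permutation(labels)
        rows.append(
            dict(unit_id=unit_id, shuffle=k,
                 delta_i=real - _sex_info(session, t, perm))
        )
    return pd.DataFrame(rows)


def delta_info_test(delta_frame: pd.DataFrame):
    """Mixed-model test of whether mean excess information is positive.

    Fits ``delta_i ~ 1 + (1 | unit)`` by maximum likelihood.  With a single
    observation per unit the random intercept is unidentifiable and the test
    degenerates to a one-sample t test on the per-unit values.

    Returns ``(intercept, p_value, fit_object)``.
    """
    df = delta_frame
    units = df["unit_id"].unique()
    if len(units) < 2:
        raise ValueError("need at least two units")
    if np.std(df["delta_i"].to_numpy()) == 0:
        # degenerate: no variability; the intercept is known exactly
        m = float(df["delta_i"].mean())
        return m, (1.0 if m == 0 else 0.0), None
    per_unit = df.groupby("unit_id").size()
    if per_unit.max() == 1:
        from scipy.stats import ttest_1samp

        res = ttest_1samp(df["delta_i"].to_numpy(), 0.0)
        return float(df["delta_i"].mean()), float(res.pvalue), res
    import statsmodels.formula.api as smf

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm("delta_i ~ 1", df, groups=df["unit_id"])
        fit = md.fit(reml=False)
    return float(fit.params["Intercept"]), float(fit.pvalues["Intercept"]), fit
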