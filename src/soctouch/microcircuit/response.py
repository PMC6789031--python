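"""Classification of the network response pattern by BIC model selection.

Given per-neuron touch responses ``beta`` under non-modulated (X) and
modulated (Y) conditions, three nested linear descriptions are compared:

    bias:         Y - X ~ 1          (slope fixed at unity, free offset)
    potentiation: Y ~ X              (no offset, free slope)
    full:         Y ~ 1 + X

each fitted by ordinary least squares; the Bayesian information criterion
``BIC = n ln(RSS / n) + k ln(n)`` selects the best description.  A pure
inhibitory-drive increase appears as potentiation (slope < 1); a pure
excitability increase appears as a bias (positive offset); combined they
approximately cancel to the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ResponseModelFit", "response_model_selection",
           "ei_response_comparison"]


@dataclass
class ResponseModelFit:
    coefficients: dict       # model -> dict of fitted parameters
    bic: dict                # model -> BIC
    rss: dict
    n: int
    selected: str

    def summary(self) -> str:
        lines = [f"Response-pattern selection (n = {self.n} neurons)"]
        for m in ("bias", "potentiation", "full"):
            c = ", ".join(f"{k}={v:.4f}" for k, v in self.coefficients[m].items())
            mark = "  <- selected" if m == self.selected else ""
            lines.append(f"  {m:>12}: BIC={self.bic[m]:9.2f}  {c}{mark}")
        return "\n".join(lines)


def _bic(rss, n, k):
    return n * np.log(rss / n) + k * np.log(n)


def response_model_selection(beta_nonmod, beta_mod) -> ResponseModelFit:
    """Fit the three response models and select by BIC."""
    x = np.asarray(beta_nonmod, dtype=float)
    y = np.asarray(beta_mod, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = x.size
    if n < 10:
        raise ValueError(f"only {n} usable neurons; need at least 10")

    import statsmodels.api as sm

    # bias: Y - X ~ 1
    d = y - x
    intercept = float(d.mean())
    rss_bias = float(((d - intercept) ** 2).sum())
    # potentiation: Y ~ X through the origin
    pot = sm.OLS(y, x[:, None]).fit()
    slope = float(pot.params[0])
    rss_pot = float(pot.ssr)
    # full: Y ~ 1 + X
    full = sm.OLS(y, sm.add_constant(x)).fit()
    rss_full = float(full.ssr)

    rss = {"bias": rss_bias, "potentiation": rss_pot, "full": rss_full}
    k = {"bias": 1, "potentiation": 1, "full": 2}
    bic = {m: float(_bic(rss[m], n, k[m])) for m in rss}
    coefs = {
        "bias": {"intercept": intercept},
        "potentiation": {"slope": slope},
        "full": {"intercept": float(full.params[0]),
                 "slope": float(full.params[1])},
    }
    selected = min(bic, key=bic.get)
    return ResponseModelFit(coefficients=coefs, bic=bic, rss=rss, n=n,
                            selected=selected)


def ei_response_comparison(result) -> pd.DataFrame:
    """Per-class (putative E vs I) summary of touch responses.

    ``result`` is a :class:`~soctouch.microcircuit.simulate.TrialResult`;
    class membership is exact in simulation.  Returns per-condition,
    per-class count, median and IQR of ``beta_touch``.
    """
    rows = []
    inh = result.is_inhibitory[result.included]
    for cond, beta in result.beta.items():
        for cls, mask in (("E", ~inh), ("I", inh)):
            b = beta[mask]
            rows.append(
                dict(condition=cond, cell_class=cls, n=int(b.size),
                     median_beta=float(np.median(b)) if b.size else np.nan,
                     q25=float(np.percentile(b, 25)) if b.size else np.nan,
                     q75=float(np.percentile(b, 75)) if b.size else np.nan)
            )
    return pd.DataFrame(rows)
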