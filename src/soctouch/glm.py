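"""Poisson point-process GLM for touch and sex-touch responses.

The spiking of each unit is modeled as an inhomogeneous Poisson process on a
1-ms grid with a log link,

    lambda_i = exp(P_i . beta),     beta = [b0, h1..h11, rec_1..rec_{n-1},
                                            b_touch, b_sex]

where the predictor matrix ``P`` contains a constant, eleven spike-history
regressors (five 1-ms lags and six 25-ms lag windows spanning the previous
155 ms), per-recording baseline indicators, a touch indicator (1 during
social-touch episodes), and a partner-sex indicator (female = 0, male = 1,
raised during touch episodes with a male partner; a block-constant sex
column would be an exact linear combination of the recording indicators and
leave the sex coefficient unidentifiable, so under this coding
``exp(b_touch)`` and ``exp(b_touch + b_sex)`` are the female- and male-touch
fold changes over baseline).  Significance of the touch and sex terms
is assessed nonparametrically: the fitted log likelihood is compared with
likelihoods of the same model fitted after circularly permuting the touch
column, or after shuffling partner-sex labels at the partner level.

The same predictor construction drives both inference and the forward
simulator used by the synthetic-session generator, so encode and decode
cannot drift apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln

from .session import BIN_WIDTH, Session, bin_spikes, trim_baseline

__all__ = [
    "HISTORY_FINE_LAGS",
    "HISTORY_COARSE_WINDOWS",
    "PredictorMatrix",
    "GLMFit",
    "ShuffleTestResult",
    "SignificanceResult",
    "build_predictor_matrix",
    "history_matrix",
    "log_likelihood",
    "fit_poisson_glm",
    "TouchGLM",
    "TouchGLMResults",
    "shuffle_touch_test",
    "shuffle_sex_test",
    "classify",
    "classify_unit",
    "model_psth",
    "simulate_glm_counts",
]

# lags are in 1-ms bins: fine lags 1..5 cover the previous 0-5 ms,
# coarse windows (inclusive lag ranges) cover 5-30, 30-55, ... 130-155 ms
HISTORY_FINE_LAGS = (1, 2, 3, 4, 5)
HISTORY_COARSE_WINDOWS = tuple(
    (6 + 25 * k, 30 + 25 * k) for k in range(6)
)  # (6,30), (31,55), ..., (131,155)
N_HISTORY = len(HISTORY_FINE_LAGS) + len(HISTORY_COARSE_WINDOWS)


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# predictor construction
# ---------------------------------------------------------------------------

def history_matrix(counts: np.ndarray) -> np.ndarray:
    """Spike-history regressors h1..h11 on the full timeline.

    Row ``i`` is computed only from bins ``< i``; history windows are
    evaluated on the original (untrimmed) timeline so that spikes emitted
    inside later-dropped baseline spans still contribute to the history of
    retained bins.
    """
    counts = np.asarray(counts, dtype=float)
    n = counts.size
    H = np.zeros((n, N_HISTORY))
    for j, lag in enumerate(HISTORY_FINE_LAGS):
        H[lag:, j] = counts[:-lag] if lag else counts
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    for j, (a, b) in enumerate(HISTORY_COARSE_WINDOWS):
        # count over inclusive lag range [a, b] via cumsum differences
        lo_idx = np.maximum(np.arange(n) - b, 0)
        hi_idx = np.maximum(np.arange(n) - (a - 1), 0)
        col = csum[hi_idx] - csum[lo_idx]
        H[:, 5 + j] = col
    return H


@dataclass
class PredictorMatrix:
    """Design matrix over retained 1-ms bins for one unit."""

    X: np.ndarray
    y: np.ndarray
    names: list
    kept_idx: np.ndarray
    n_bins_total: int
    bin_width: float
    touch_col: int
    sex_col: int | None
    partner_code: np.ndarray        # per retained row; -1 outside blocks
    partner_ids: list
    partner_sex: np.ndarray         # "F"/"M" per partner id
    block_code: np.ndarray = field(default=None)

    @property
    def include_sex(self) -> bool:
        return self.sex_col is not None

    def with_touch_column(self, touch: np.ndarray) -> "PredictorMatrix":
        X = self.X.copy()
        X[:, self.touch_col] = touch
        return PredictorMatrix(
            X, self.y, self.names, self.kept_idx, self.n_bins_total,
            self.bin_width, self.touch_col, self.sex_col, self.partner_code,
            self.partner_ids, self.partner_sex, self.block_code,
        )

    def with_partner_labels(self, labels: np.ndarray) -> "PredictorMatrix":
        """Rebuild the sex column from a per-partner label array (1 = male)."""
        if self.sex_col is None:
            raise ValueError("matrix has no sex column")
        X = self.X.copy()
        sex = np.zeros(X.shape[0])
        mask = self.partner_code >= 0
        sex[mask] = labels[self.partner_code[mask]]
        X[:, self.sex_col] = sex
        return PredictorMatrix(
            X, self.y, self.names, self.kept_idx, self.n_bins_total,
            self.bin_width, self.touch_col, self.sex_col, self.partner_code,
            self.partner_ids, self.partner_sex, self.block_code,
        )


def build_predictor_matrix(
    session: Session,
    unit_id,
    include_sex: bool = True,
    margin: float = 5.0,
    bin_width: float = BIN_WIDTH,
) -> PredictorMatrix:
    """Build the retained-bin predictor matrix for one unit.

    Columns: const, h1..h11, rec_2..rec_n (first recording is the baseline),
    touch, and optionally sex.  With ``n_rec`` recordings and the sex column
    the matrix has ``13 + (n_rec - 1) + 1`` columns.
    """
    if not session.blocks:
        raise ValueError("session has no recording blocks")
    bst = bin_spikes(session.units[unit_id], session.end, bin_width)
    bst = trim_baseline(bst, session.episodes, margin=margin)
    centers = bst.bin_centers
    n = bst.n_bins

    H = history_matrix(bst.counts)

    n_rec = len(session.blocks)
    rec_cols = np.zeros((n, n_rec - 1))
    block_code = np.full(n, -1, dtype=np.int64)
    for j, b in enumerate(session.blocks):
        in_b = (centers >= b.start) & (centers < b.end)
        block_code[in_b] = j
        if j >= 1:
            rec_cols[in_b, j - 1] = 1.0

    # touch indicator and per-bin partner (episode-level: a bin carries a
    # partner code only while inside that partner's touch episode)
    touch = np.zeros(n)
    partner_ids = sorted({e.partner_id for e in session.episodes})
    pid_index = {p: k for k, p in enumerate(partner_ids)}
    psex = np.array(
        [next(e.partner_sex for e in session.episodes if e.partner_id == p)
         for p in partner_ids]
    )
    partner_code = np.full(n, -1, dtype=np.int64)
    for e in session.episodes:
        in_e = (centers >= e.onset) & (centers < e.offset)
        touch[in_e] = 1.0
        partner_code[in_e] = pid_index[e.partner_id]

    cols = [np.ones(n)] + [H[:, j] for j in range(N_HISTORY)]
    names = ["const"] + [f"h_{k}" for k in range(1, 12)]
    for j in range(1, n_rec):
        cols.append(rec_cols[:, j - 1])
        names.append(f"rec_{j + 1}")
    cols.append(touch)
    names.append("touch")
    touch_col = len(names) - 1
    sex_col = None
    if include_sex:
        male = psex == "M"
        sex = np.zeros(n)
        mask = partner_code >= 0
        sex[mask] = male[partner_code[mask]].astype(float)
        cols.append(sex)
        names.append("sex")
        sex_col = len(names) - 1

    X = np.column_stack(cols)
    kept = bst.kept_mask
    return PredictorMatrix(
        X=X[kept],
        y=bst.counts[kept].astype(float),
        names=names,
        kept_idx=np.flatnonzero(kept),
        n_bins_total=n,
        bin_width=bin_width,
        touch_col=touch_col,
        sex_col=sex_col,
        partner_code=partner_code[kept],
        partner_ids=partner_ids,
        partner_sex=psex,
        block_code=block_code[kept],
    )


# ---------------------------------------------------------------------------
# likelihood and fitting
# ---------------------------------------------------------------------------

def log_likelihood(beta, X, y, bin_width=BIN_WIDTH) -> float:
    """Poisson log likelihood in nats, including all constant terms.

    ``sum(y eta) + log(dt) sum(y) - sum(log y!) - dt sum(exp(eta))`` with
    ``eta = X beta`` so that absolute values are comparable across model
    variants fitted to the same spike train.
    """
    eta = X @ np.asarray(beta, dtype=float)
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite linear predictor")
    lam_dt = np.exp(eta) * bin_width
    if not np.all(np.isfinite(lam_dt)):
        raise ValueError("non-finite rate")
    return float(
        y @ eta + np.log(bin_width) * y.sum() - gammaln(y + 1).sum() - lam_dt.sum()
    )


@dataclass
class GLMFit:
    """Maximum-likelihood fit of the point-process GLM."""

    beta: np.ndarray
    names: list
    log_likelihood: float
    converged: bool
    n_iter: int
    model_variant: str
    flags: list

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.beta, index=self.names)


_ETA_CLIP = 30.0


def fit_poisson_glm(
    X, y, bin_width=BIN_WIDTH, beta0=None, names=None, tol=1e-8,
    max_iter=100, model_variant="touch+sex",
) -> GLMFit:
    """Newton's method with step-halving for the Poisson log-link MLE.

    The likelihood is concave in ``beta`` so the optimum is global.
    All-zero columns are dropped from the solve and assigned coefficient 0.
    Convergence: infinity-norm of the gradient below ``tol * max(1, sum y)``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    active = X.any(axis=0)
    flags = []
    if active.all():
        Xa = X
    else:
        flags.append("dropped_zero_columns")
        Xa = X[:, active]
    pa = Xa.shape[1]
    log_dt = np.log(bin_width)

    if beta0 is None:
        beta = np.zeros(pa)
        mean_rate = max(y.mean() / bin_width, 1e-3)
        const_j = int(np.flatnonzero(active)[0]) if names[0] == "const" else None
        if names[0] == "const" and active[0]:
            beta[0] = np.log(mean_rate)
    else:
        beta = np.asarray(beta0, dtype=float)[active].copy()

    gtol = tol * max(1.0, y.sum())

    def _ll(b):
        eta = np.clip(Xa @ b, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta + log_dt)
        ll = y @ eta + log_dt * y.sum() - mu.sum()
        return ll, eta, mu

    ll, eta, mu = _ll(beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = Xa.T @ (y - mu)
        if np.max(np.abs(grad)) < gtol:
            converged = True
            break
        Hm = (Xa * mu[:, None]).T @ Xa
        try:
            step = np.linalg.solve(Hm, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(Hm, grad, rcond=None)[0]
            flags.append("singular_hessian")
        # step-halving line search on the log likelihood
        t = 1.0
        for _ in range(40):
            cand = beta + t * step
            ll_new, eta_new, mu_new = _ll(cand)
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        else:
            flags.append("line_search_failed")
            break
        beta, ll, eta, mu = cand, ll_new, eta_new, mu_new

    if np.any(np.abs(beta) > 25):
        flags.append("possible_separation")
        converged = False
    if not converged and "possible_separation" not in flags and it >= max_iter:
        flags.append("max_iter")

    beta_full = np.zeros(p)
    beta_full[active] = beta
    llf = ll - gammaln(y + 1).sum()
    return GLMFit(
        beta=beta_full,
        names=names,
        log_likelihood=float(llf),
        converged=converged,
        n_iter=it,
        model_variant=model_variant,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# model / results objects
# ---------------------------------------------------------------------------

class TouchGLM:
    """Point-process GLM for one unit of a session.

    Parameters
    ----------
    session : Session
    unit_id : hashable
    include_sex : bool
        Include the partner-sex column (``touch+sex`` variant) or not
        (``touch_only`` variant, used by the touch shuffle test).
    """

    def __init__(self, session, unit_id, include_sex=True, margin=5.0,
                 bin_width=BIN_WIDTH):
        self.session = session
        self.unit_id = unit_id
        self.include_sex = include_sex
        self.bin_width = bin_width
        self.pm = build_predictor_matrix(
            session, unit_id, include_sex=include_sex, margin=margin,
            bin_width=bin_width,
        )

    def fit(self, beta0=None, tol=1e-8) -> "TouchGLMResults":
        fit = fit_poisson_glm(
            self.pm.X, self.pm.y, self.bin_width, beta0=beta0,
            names=self.pm.names, tol=tol,
            model_variant="touch+sex" if self.include_sex else "touch_only",
        )
        if not fit.converged:
            warnings.warn(
                f"unit {self.unit_id!r}: fit flagged {fit.flags}; "
                "exclude from downstream analyses"
            )
        return TouchGLMResults(self, fit)


class TouchGLMResults:
    """Results wrapper: named coefficients, likelihood, Wald diagnostics."""

    def __init__(self, model: TouchGLM, fit: GLMFit):
        self.model = model
        self.fit = fit

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def llf(self) -> float:
        return self.fit.log_likelihood

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def bse(self) -> pd.Series:
        """Wald standard errors from the observed Fisher information."""
        pm = self.model.pm
        eta = np.clip(pm.X @ self.fit.beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta) * pm.bin_width
        H = (pm.X * mu[:, None]).T @ pm.X
        cov = np.linalg.pinv(H)
        return pd.Series(np.sqrt(np.diag(cov)), index=pm.names)

    def summary(self) -> str:
        se = self.bse()
        z = self.params / se.replace(0, np.nan)
        from scipy.stats import norm

        lines = [
            f"Poisson point-process GLM ({self.fit.model_variant})",
            f"unit: {self.model.unit_id}   "
            f"n_bins: {self.model.pm.y.size}   "
            f"log-likelihood: {self.llf:.2f}   converged: {self.converged}",
            f"{'coef':>8} {'estimate':>10} {'std err':>9} {'z':>8} {'P>|z|':>8}",
        ]
        for name in self.params.index:
            pz = 2 * norm.sf(abs(z[name])) if np.isfinite(z[name]) else np.nan
            lines.append(
                f"{name:>8} {self.params[name]:>10.4f} {se[name]:>9.4f} "
                f"{z[name]:>8.2f} {pz:>8.4f}"
            )
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# shuffle significance tests
# ---------------------------------------------------------------------------

@dataclass
class ShuffleTestResult:
    p_value: float
    llf_observed: float
    llf_shuffled: np.ndarray
    n_shuffles: int


@dataclass
class SignificanceResult:
    p_touch: float
    p_sex: float
    n_shuffles: int
    label: str


class _ShuffleRefitter:
    """Warm-started refits for shuffle nulls, sharing one design matrix.

    Only a single column changes between shuffles, so the matrix is edited
    in place and the Newton solve uses a single-precision Hessian (the
    convergence check stays in double precision on the exact gradient, so
    the optimum is unchanged; verified against the reference fitter)."""

    def __init__(self, pm, beta0, bin_width, tol=1e-5, max_iter=50):
        self.X = pm.X.copy()
        self.X32 = self.X.astype(np.float32)
        self.y = pm.y
        # clamp plateaued (quasi-separated) coefficients: beyond ~|12| the
        # likelihood is flat to double precision and huge values only
        # destabilize the Hessian
        self.beta0 = np.clip(beta0, -12.0, 12.0)
        self.log_dt = np.log(bin_width)
        self.gtol = tol * max(1.0, self.y.sum())
        self.max_iter = max_iter
        self.ll_const = (
            self.log_dt * self.y.sum() - gammaln(self.y + 1).sum()
        )

    def refit(self, col, values):
        """Maximized log likelihood (nats, with constants) after replacing
        design column ``col`` with ``values``."""
        if float(self.y @ (np.asarray(values) > 0)) == 0.0:
            # no spikes under the shuffled indicator: the MLE sends the
            # coefficient to -inf and the limiting likelihood is the fit
            # with those bins excluded (they contribute zero in the limit)
            return self._refit_separated(col, values)
        X, X32, y = self.X, self.X32, self.y
        X[:, col] = values
        X32[:, col] = values
        beta = self.beta0.copy()
        eta = np.clip(X @ beta, -_ETA_CLIP, _ETA_CLIP)
        mu = np.exp(eta + self.log_dt)
        ll = y @ eta - mu.sum()
        for _ in range(self.max_iter):
            grad = X.T @ (y - mu)
            if np.max(np.abs(grad)) < self.gtol:
                break
            H = (X32 * mu.astype(np.float32)[:, None]).T @ X32
            H64 = H.astype(np.float64)
            # tiny ridge guards against singular directions from dead columns
            H64.flat[:: H64.shape[0] + 1] += 1e-9 * np.trace(H64) / H64.shape[0]
            try:
                step = np.linalg.solve(H64, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H64, grad, rcond=None)[0]
            t = 1.0
            for _ in range(30):
                cand = beta + t * step
                eta_c = np.clip(X @ cand, -_ETA_CLIP, _ETA_CLIP)
                mu_c = np.exp(eta_c + self.log_dt)
                ll_c = y @ eta_c - mu_c.sum()
                if ll_c >= ll - 1e-12:
                    break
                t *= 0.5
            beta, eta, mu, ll = cand, eta_c, mu_c, ll_c
        return ll + self.ll_const

    def _refit_separated(self, col, values):
        keep = np.asarray(values) <= 0
        cols = np.ones(self.X.shape[1], dtype=bool)
        cols[col] = False
        Xs = self.X[np.ix_(keep, cols)]
        ys = self.y[keep]
        beta = self.beta0[cols].copy()
        ll = -np.inf
        for _ in range(self.max_iter):
            eta = np.clip(Xs @ beta, -_ETA_CLIP, _ETA_CLIP)
            mu = np.exp(eta + self.log_dt)
            ll_new = ys @ eta - mu.sum()
            grad = Xs.T @ (ys - mu)
            if np.max(np.abs(grad)) < self.gtol:
                ll = ll_new
                break
            H = (Xs * mu[:, None]).T @ Xs
            H.flat[:: H.shape[0] + 1] += 1e-9 * np.trace(H) / H.shape[0]
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, grad, rcond=None)[0]
            t = 1.0
            for _ in range(30):
                eta_c = np.clip(Xs @ (beta + t * step), -_ETA_CLIP, _ETA_CLIP)
                mu_c = np.exp(eta_c + self.log_dt)
                ll_c = ys @ eta_c - mu_c.sum()
                if ll_c >= ll_new - 1e-12:
                    break
                t *= 0.5
            beta = beta + t * step
            ll = ll_c
        return ll + self.ll_const


def _plus_one_p(llf_obs, llf_shuf):
    llf_shuf = np.asarray(llf_shuf)
    return (1 + int((llf_shuf >= llf_obs).sum())) / (llf_shuf.size + 1)


def shuffle_touch_test(
    session, unit_id, n_shuffles=100, seed=None, min_shift=1.0, margin=5.0,
    bin_width=BIN_WIDTH,
) -> ShuffleTestResult:
    """Circular-permutation significance test for the touch response.

    The touch-only model is fitted to the data and to ``n_shuffles``
    predictor matrices in which the touch column has been circularly
    rotated along the concatenated retained-bin axis (preserving episode
    durations and spike-train autocorrelation).  Shifts are uniform over the
    axis, at least ``min_shift`` seconds away from identity on either side.
    The p value is the plus-one upper-tail permutation estimate.
    """
    rng = np.random.default_rng(seed)
    model = TouchGLM(session, unit_id, include_sex=False, margin=margin,
                     bin_width=bin_width)
    res = model.fit()
    pm = model.pm
    touch = pm.X[:, pm.touch_col].copy()
    n = touch.size
    lo = max(1, int(round(min_shift / bin_width)))
    if n <= 2 * lo:
        lo = 1
    refitter = _ShuffleRefitter(pm, res.fit.beta, bin_width)
    llfs = np.empty(n_shuffles)
    for k in range(n_shuffles):
        shift = int(rng.integers(lo, n - lo))
        llfs[k] = refitter.refit(pm.touch_col, np.roll(touch, shift))
    return ShuffleTestResult(
        p_value=_plus_one_p(res.llf, llfs),
        llf_observed=res.llf,
        llf_shuffled=llfs,
        n_shuffles=n_shuffles,
    )


def shuffle_sex_test(
    session, unit_id, n_shuffles=100, seed=None, margin=5.0,
    bin_width=BIN_WIDTH,
) -> ShuffleTestResult:
    """Partner-label shuffle test for the sex-touch response.

    Partner sex labels (one per partner animal, preserving the overall
    male/female counts) are permuted at the partner level; each permutation
    rebuilds the block-constant sex column and refits the touch+sex model.
    With all partners of one sex the test is undefined and returns p = 1
    with a warning.
    """
    rng = np.random.default_rng(seed)
    model = TouchGLM(session, unit_id, include_sex=True, margin=margin,
                     bin_width=bin_width)
    res = model.fit()
    pm = model.pm
    labels = (pm.partner_sex == "M").astype(float)
    if labels.min() == labels.max():
        warnings.warn("all partners share one sex; sex shuffle undefined, p = 1")
        return ShuffleTestResult(1.0, res.llf, np.array([]), 0)
    refitter = _ShuffleRefitter(pm, res.fit.beta, bin_width)
    mask = pm.partner_code >= 0
    llfs = np.empty(n_shuffles)
    for k in range(n_shuffles):
        perm = rng.permutation(labels)
        sex = np.zeros(pm.y.size)
        sex[mask] = perm[pm.partner_code[mask]]
        llfs[k] = refitter.refit(pm.sex_col, sex)
    return ShuffleTestResult(
        p_value=_plus_one_p(res.llf, llfs),
        llf_observed=res.llf,
        llf_shuffled=llfs,
        n_shuffles=n_shuffles,
    )


def classify(p_touch: float, p_sex: float, alpha: float = 0.05) -> str:
    """Unit label: ``sex_touch`` iff p_sex < alpha; ``touch`` iff p_sex >=
    alpha and p_touch < alpha; else ``nonsignificant``."""
    if p_sex < alpha:
        return "sex_touch"
    if p_touch < alpha:
        return "touch"
    return "nonsignificant"


def classify_unit(
    session, unit_id, n_shuffles=100, seed=None, alpha=0.05, **kw
) -> SignificanceResult:
    """Run both shuffle tests and label the unit."""
    ss = np.random.SeedSequence(seed)
    s_touch, s_sex = ss.spawn(2)
    rt = shuffle_touch_test(session, unit_id, n_shuffles, seed=s_touch, **kw)
    rs = shuffle_sex_test(session, unit_id, n_shuffles, seed=s_sex, **kw)
    return SignificanceResult(
        p_touch=rt.p_value,
        p_sex=rs.p_value,
        n_shuffles=n_shuffles,
        label=classify(rt.p_value, rs.p_value, alpha),
    )


# ---------------------------------------------------------------------------
# forward simulation (shared with the synthetic-session generator)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _simulate_loop(eta_static, h, log_dt, seed):  # pragma: no cover - numba
    np.random.seed(seed)
    n = eta_static.size
    counts = np.zeros(n, dtype=np.int64)
    wsum = np.zeros(6)
    n_hot = 0
    for i in range(n):
        eta = eta_static[i]
        for k in range(5):
            j = i - (k + 1)
            if j >= 0:
                eta += h[k] * counts[j]
        for w in range(6):
            eta += h[5 + w] * wsum[w]
        mu = np.exp(min(eta + log_dt, 30.0))
        if mu > 1.0:
            n_hot += 1
        c = np.random.poisson(mu)
        counts[i] = c
        # advance the six coarse windows (inclusive lag ranges 6-30, 31-55, ...)
        for w in range(6):
            a = 6 + 25 * w
            b = 30 + 25 * w
            j_in = i + 1 - a
            if j_in >= 0:
                wsum[w] += counts[j_in]
            j_out = i - b
            if j_out >= 0:
                wsum[w] -= counts[j_out]
    return counts, n_hot


def simulate_glm_counts(eta_static, h_coefs, bin_width=BIN_WIDTH, seed=0):
    """Draw a spike-count train from the GLM run forward, bin by bin.

    In each 1-ms bin the count is Poisson with mean ``dt * exp(row . beta)``
    where the row encodes the static covariates (baseline, recording, touch,
    sex) through ``eta_static`` and the history of the counts emitted so far
    through ``h_coefs`` (h1..h11).  Emits a warning if ``lambda * dt``
    exceeds 1 in more than 1% of bins (outside the sparse-spiking regime).
    """
    eta_static = np.ascontiguousarray(eta_static, dtype=np.float64)
    h = np.ascontiguousarray(h_coefs, dtype=np.float64)
    if h.size != N_HISTORY:
        raise ValueError(f"expected {N_HISTORY} history coefficients")
    counts, n_hot = _simulate_loop(eta_static, h, np.log(bin_width), int(seed))
    if n_hot > 0.01 * eta_static.size:
        warnings.warn(
            f"lambda*dt > 1 in {n_hot} bins; model left the sparse-spiking regime"
        )
    return counts


def model_psth(
    results: TouchGLMResults, session: Session, n_reps=20, seed=None,
    window=(-2.5, 1.0), tau=0.075,
):
    """Predicted per-partner-sex PSTH from the fitted model.

    The fitted GLM is forward-simulated over the session's episode
    structure ``n_reps`` times; simulated trains are aligned to touch
    onsets, split by partner sex, and smoothed exactly like the empirical
    PSTH.  Returns ``{"F": PSTHResult, "M": PSTHResult}`` (a sex with no
    episodes is omitted).
    """
    from .session import psth as _psth

    model = results.model
    pm_full = build_predictor_matrix(
        session, model.unit_id, include_sex=model.include_sex,
        margin=np.inf, bin_width=model.bin_width,
    )
    beta = results.params.reindex(pm_full.names).fillna(0.0).to_numpy()
    h = beta[1:12]
    static = beta.copy()
    X_static = pm_full.X.copy()
    X_static[:, 1:12] = 0.0
    eta_static = X_static @ static

    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_reps)]
    bw = model.bin_width
    all_times = []
    for sd in seeds:
        counts = simulate_glm_counts(eta_static, h, bw, seed=sd)
        idx = np.flatnonzero(counts)
        t = np.repeat((idx + 0.5) * bw, counts[idx])
        all_times.append(t)

    out = {}
    for sex in ("F", "M"):
        onsets = np.array(
            [e.onset for e in session.episodes if e.partner_sex == sex]
        )
        if onsets.size == 0:
            continue
        rep_on = np.concatenate(
            [onsets + r * session.end for r in range(n_reps)]
        )
        spikes = np.concatenate(
            [all_times[r] + r * session.end for r in range(n_reps)]
        )
        out[sex] = _psth(spikes, rep_on, window=window, tau=tau, bin_width=bw)
    return out
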