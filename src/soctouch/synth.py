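"""Synthetic session generator.

Emulates the statistical structure the analysis assumes, so every stage of
the pipeline can be exercised without recorded data:

* touch-episode durations and inter-touch intervals drawn i.i.d. log-normal,
  calibrated so the population median and interquartile range match the
  behavioral statistics of naturalistic social facial touch in rats
  (median duration 1.33 s, IQR 0.77-2.53 s; median inter-touch interval
  4.68 s, IQR 1.24-23.78 s, spanning orders of magnitude);
* spike trains drawn from the touch GLM itself run forward bin by bin with
  chosen coefficients (the predictor construction is shared with inference);
* population modulation tables with bias / potentiation / interaction
  structure and per-subject random intercepts;
* two-cluster waveform-feature samples for the spike-shape classifier.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import glm as _glm
from .session import BIN_WIDTH, BinnedSpikeTrain, RecordingBlock, Session, TouchEpisode

__all__ = [
    "GeneratorParams",
    "calibrate_lognormal",
    "sample_durations",
    "sample_intervals",
    "generate_episodes",
    "make_beta",
    "generate_spike_train",
    "generate_session",
    "generate_population",
    "generate_waveforms",
]

# printed behavioral calibration (median s, 25th and 75th percentiles, s)
DURATION_STATS = (1.33, 0.77, 2.53)
INTERVAL_STATS = (4.68, 1.24, 23.78)

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal


def calibrate_lognormal(median, q25, q75):
    """Log-normal (mu, sigma) from a median and interquartile range.

    ``mu = ln median``; ``sigma = (ln q75 - ln q25) / (2 * 0.6745)``.
    """
    return np.log(median), (np.log(q75) - np.log(q25)) / (2 * _Z75)


@dataclass
class GeneratorParams:
    """Study-condition parameters of the synthetic-session generator.

    Defaults reproduce the behavioral statistics above with four 600-s
    recording blocks and two partners of each sex (one partner per block),
    matching the alternating-partner experimental design.
    """

    duration_lognormal: tuple = calibrate_lognormal(*DURATION_STATS)
    interval_lognormal: tuple = calibrate_lognormal(*INTERVAL_STATS)
    n_blocks: int = 4
    block_length: float = 600.0
    partners: tuple = (("f1", "F"), ("m1", "M"), ("f2", "F"), ("m2", "M"))
    first_onset_mean: float | None = 5.0
    seed: int | None = None

    def __post_init__(self):
        if not np.isfinite(self.duration_lognormal[0]):
            raise ValueError("duration median must be positive")
        if not np.isfinite(self.interval_lognormal[0]):
            raise ValueError("interval median must be positive")


def sample_durations(params: GeneratorParams, n, rng=None):
    rng = np.random.default_rng(params.seed if rng is None else rng)
    mu, sd = params.duration_lognormal
    return np.exp(mu + sd * rng.standard_normal(n))


def sample_intervals(params: GeneratorParams, n, rng=None):
    rng = np.random.default_rng(params.seed if rng is None else rng)
    mu, sd = params.interval_lognormal
    return np.exp(mu + sd * rng.standard_normal(n))


def generate_episodes(params: GeneratorParams, seed=None):
    """Draw touch episodes tiled into recording blocks.

    Durations and intervals are i.i.d. log-normal; each block hosts a single
    partner (cycled from ``params.partners``).  An episode that would cross
    the block end is dropped and the block closed.  The latency from
    partner introduction (block start) to the first touch is exponential
    with mean ``first_onset_mean`` (animals typically engage within
    seconds of introduction; the heavy-tailed between-bout interval law
    does not describe this latency); with ``first_onset_mean=None`` the
    first onset is drawn from the interval law instead.

    Returns ``(blocks, episodes)``.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    mu_d, sd_d = params.duration_lognormal
    mu_i, sd_i = params.interval_lognormal
    blocks, episodes = [], []
    t0 = 0.0
    for b in range(params.n_blocks):
        pid, psex = params.partners[b % len(params.partners)]
        end = t0 + params.block_length
        blocks.append(
            RecordingBlock(block_index=b, start=t0, end=end,
                           partner_ids=frozenset([pid]))
        )
        if params.first_onset_mean is None:
            t = t0 + float(np.exp(mu_i + sd_i * rng.standard_normal()))
        else:
            t = t0 + float(rng.exponential(params.first_onset_mean))
        while True:
            dur = float(np.exp(mu_d + sd_d * rng.standard_normal()))
            if t + dur > end:
                break
            episodes.append(TouchEpisode(t, t + dur, pid, psex))
            t = t + dur + float(np.exp(mu_i + sd_i * rng.standard_normal()))
            if t >= end:
                break
        t0 = end
    return blocks, episodes


def make_beta(beta0, h=None, rec=None, touch=0.0, sex=0.0) -> dict:
    """Assemble a named coefficient dictionary for the forward model.

    ``beta0`` is the log baseline rate in log(1/s); ``h`` the 11 history
    coefficients (default all zero); ``rec`` the per-recording baseline
    offsets for recordings 2..n; ``touch`` and ``sex`` the modulation
    coefficients on the natural-log scale.
    """
    beta = {"const": float(beta0), "touch": float(touch), "sex": float(sex)}
    h = np.zeros(11) if h is None else np.asarray(h, dtype=float)
    if h.size != 11:
        raise ValueError("h must have 11 entries")
    for k in range(11):
        beta[f"h_{k + 1}"] = float(h[k])
    for j, v in enumerate(rec or []):
        beta[f"rec_{j + 2}"] = float(v)
    return beta


def _eta_static(session: Session, unit_id, beta: dict, bin_width):
    """Static linear predictor over the full timeline via the shared
    predictor-matrix builder (history columns zeroed)."""
    pm = _glm.build_predictor_matrix(
        session, unit_id, include_sex=True, margin=np.inf, bin_width=bin_width
    )
    vec = np.array([beta.get(name, 0.0) for name in pm.names])
    X = pm.X.copy()
    X[:, 1:12] = 0.0
    h = np.array([beta.get(f"h_{k}", 0.0) for k in range(1, 12)])
    return X @ vec, h


def generate_spike_train(
    episodes, blocks, true_beta: dict, seed=0, bin_width=BIN_WIDTH
) -> BinnedSpikeTrain:
    """Simulate one unit's binned spike train from the GLM run forward.

    In each 1-ms bin the count is Poisson with mean ``dt * exp(row . beta)``
    where the row encodes the current spike history, recording block, touch
    state and partner sex exactly as the inference-side predictor matrix
    defines them.
    """
    shell = Session(
        subject_id="synthetic", subject_sex="F", area="S1",
        blocks=list(blocks), episodes=list(episodes),
        units={"_": np.array([])},
    )
    eta, h = _eta_static(shell, "_", true_beta, bin_width)
    counts = _glm.simulate_glm_counts(eta, h, bin_width, seed=seed)
    return BinnedSpikeTrain(counts=counts, bin_width=bin_width)


def _counts_to_times(counts, bin_width, rng=None):
    """Spike times at bin centers (ties spread deterministically)."""
    idx = np.flatnonzero(counts)
    reps = counts[idx]
    t = np.repeat((idx + 0.5) * bin_width, reps)
    return np.sort(t)


def generate_session(
    params: GeneratorParams,
    unit_betas: dict,
    seed=0,
    subject_id="synthetic",
    subject_sex="F",
    area="S1",
    bin_width=BIN_WIDTH,
) -> Session:
    """Generate a full synthetic session.

    ``unit_betas`` maps unit id to a named coefficient dict (see
    :func:`make_beta`).  Episode structure and every unit's spike train are
    derived from independent streams spawned from ``seed``.
    """
    ss = np.random.SeedSequence(seed)
    s_ep, *s_units = ss.spawn(1 + len(unit_betas))
    blocks, episodes = generate_episodes(params, seed=s_ep)
    shell = Session(
        subject_id=subject_id, subject_sex=subject_sex, area=area,
        blocks=blocks, episodes=episodes, units={"_": np.array([])},
    )
    units = {}
    for (uid, beta), s_u in zip(unit_betas.items(), s_units):
        eta, h = _eta_static(shell, "_", beta, bin_width)
        cseed = int(s_u.generate_state(1)[0] % (2**31))
        counts = _glm.simulate_glm_counts(eta, h, bin_width, seed=cseed)
        units[uid] = _counts_to_times(counts, bin_width)
    return Session(
        subject_id=subject_id, subject_sex=subject_sex, area=area,
        blocks=blocks, episodes=episodes, units=units,
    )


def generate_population(
    n_per_subject=25,
    subjects=(("rf1", "F"), ("rf2", "F"), ("rf3", "F"),
              ("rm1", "M"), ("rm2", "M"), ("rm3", "M")),
    bias=0.0,
    slope=1.0,
    sex_effect=0.0,
    interaction=0.0,
    subject_sd=0.1,
    noise_sd=0.3,
    female_sd=1.2,
    area="S1",
    seed=0,
) -> pd.DataFrame:
    """Synthetic population modulation table on the log2 fold-change scale.

    ``female_mod`` (log2) is centered normal with spread ``female_sd``;
    ``male_mod`` (log2) follows the population response model

        male = bias + slope * female + sex_effect * subject_sex
               + interaction * female * subject_sex + u_subject + noise

    with ``u_subject ~ N(0, subject_sd)``.  The returned table stores fold
    ratios (``2**log2``); ground-truth parameters live in ``df.attrs``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for sid, ssex in subjects:
        u = rng.normal(0, subject_sd)
        sx = 1.0 if ssex == "M" else 0.0
        f = rng.normal(0, female_sd, n_per_subject)
        m = (bias + slope * f + sex_effect * sx + interaction * f * sx + u
             + rng.normal(0, noise_sd, n_per_subject))
        for k in range(n_per_subject):
            rows.append(
                dict(unit_id=f"{sid}_u{k}", area=area, subject_id=sid,
                     subject_sex=ssex, female_mod=float(2.0 ** f[k]),
                     male_mod=float(2.0 ** m[k]), label="touch")
            )
    df = pd.DataFrame(rows)
    df.attrs["truth"] = dict(
        bias=bias, slope=slope, sex_effect=sex_effect, interaction=interaction,
        subject_sd=subject_sd, noise_sd=noise_sd,
    )
    return df


@dataclass
class WaveformClusterSpec:
    """Gaussian cluster in (spike width ms, post-positivity) feature space."""

    mean: tuple
    sd: tuple
    label: str


DEFAULT_CLUSTERS = (
    WaveformClusterSpec(mean=(0.55, 0.35), sd=(0.06, 0.07), label="putative_E"),
    WaveformClusterSpec(mean=(0.25, 0.05), sd=(0.03, 0.05), label="putative_I"),
)


def generate_waveforms(
    n_per_class=(100, 40), clusters=DEFAULT_CLUSTERS, seed=0
) -> pd.DataFrame:
    """Labeled two-cluster waveform-feature sample (fixture for the
    spike-shape classifier)."""
    rng = np.random.default_rng(seed)
    frames = []
    for n, spec in zip(n_per_class, clusters):
        if n == 0:
            continue
        w = rng.normal(spec.mean[0], spec.sd[0], n)
        p = rng.normal(spec.mean[1], spec.sd[1], n)
        frames.append(
            pd.DataFrame(
                {"width_half_max": np.abs(w), "post_positivity": p,
                 "label": spec.label}
            )
        )
    if not frames:
        raise ValueError("no clusters requested")
    return pd.concat(frames, ignore_index=True)
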