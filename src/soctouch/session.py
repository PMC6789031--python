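"""Core data model for social-facial-touch recording sessions.

A session holds the spike times of the recorded single units, the table of
social-touch episodes (onset/offset/partner), and the recording blocks that
partition the session.  All times are in seconds (double precision); spike
trains are discretized on a 1-ms grid with half-open bins ``[t, t + dt)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats as sstats

__all__ = [
    "TouchEpisode",
    "RecordingBlock",
    "Session",
    "BinnedSpikeTrain",
    "ValidationError",
    "touch_statistics",
    "bin_spikes",
    "trim_baseline",
    "psth",
    "alpha_kernel",
    "PSTHResult",
]

BIN_WIDTH = 1e-3  # s; the 1-ms discretization used throughout

SEX_CODES = ("F", "M")


class ValidationError(ValueError):
    """A session component violates a structural invariant."""


@dataclass(frozen=True)
class TouchEpisode:
    """One social facial-touch episode.

    Parameters
    ----------
    onset, offset : float
        Episode boundaries in seconds; ``offset > onset``.
    partner_id : str
        Identity of the interaction partner.
    partner_sex : {"F", "M"}
    """

    onset: float
    offset: float
    partner_id: str
    partner_sex: str

    def __post_init__(self):
        if not self.offset > self.onset:
            raise ValidationError(
                f"episode offset ({self.offset}) must exceed onset ({self.onset})"
            )
        if self.partner_sex not in SEX_CODES:
            raise ValidationError(f"unknown sex code {self.partner_sex!r}")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class RecordingBlock:
    """A contiguous recording block (one partner presentation period)."""

    block_index: int
    start: float
    end: float
    partner_ids: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.end > self.start:
            raise ValidationError("block end must exceed start")
        object.__setattr__(self, "partner_ids", frozenset(self.partner_ids))


@dataclass
class Session:
    """A recording session: blocks, touch episodes and unit spike trains.

    Invariants enforced at construction: episodes are sorted and
    non-overlapping, every episode lies inside exactly one block, blocks are
    non-overlapping, spike times lie within ``[0, end]``.  A warning (not an
    error) is raised when fewer than two partners of each sex are present,
    because the partner-sex shuffle test is then poorly supported.
    """

    subject_id: str
    subject_sex: str
    area: str
    blocks: list
    episodes: list
    units: dict

    def __post_init__(self):
        if self.subject_sex not in SEX_CODES:
            raise ValidationError(f"unknown sex code {self.subject_sex!r}")
        self.blocks = sorted(self.blocks, key=lambda b: b.start)
        for a, b in zip(self.blocks[:-1], self.blocks[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"blocks {a.block_index} and {b.block_index} overlap"
                )
        self.episodes = sorted(self.episodes, key=lambda e: e.onset)
        for a, b in zip(self.episodes[:-1], self.episodes[1:]):
            if b.onset < a.offset:
                raise ValidationError(
                    f"episodes at {a.onset:.3f}s and {b.onset:.3f}s overlap"
                )
        for ep in self.episodes:
            if self.block_of(ep) is None:
                raise ValidationError(
                    f"episode at {ep.onset:.3f}s lies outside every block"
                )
        end = self.end
        for uid, t in self.units.items():
            t = np.asarray(t, dtype=float)
            if t.size and (np.any(np.diff(t) < 0)):
                raise ValidationError(f"unit {uid!r}: spike times not sorted")
            if t.size and (t[0] < 0 or t[-1] > end):
                raise ValidationError(
                    f"unit {uid!r}: spike times outside [0, {end:.3f}]"
                )
            self.units[uid] = t
        n_f = len({e.partner_id for e in self.episodes if e.partner_sex == "F"})
        n_m = len({e.partner_id for e in self.episodes if e.partner_sex == "M"})
        if self.episodes and (n_f < 2 or n_m < 2):
            warnings.warn(
                f"session has {n_f} female / {n_m} male partners; "
                "the partner-sex shuffle test needs >= 2 of each",
                stacklevel=2,
            )

    @property
    def end(self) -> float:
        return max(b.end for b in self.blocks)

    def block_of(self, episode: TouchEpisode):
        """Return the block containing an episode, or None."""
        for b in self.blocks:
            if b.start <= episode.onset and episode.offset <= b.end:
                return b
        return None

    def episodes_in_block(self, block: RecordingBlock) -> list:
        return [e for e in self.episodes if block.start <= e.onset < block.end]


@dataclass
class BinnedSpikeTrain:
    """Spike counts on the 1-ms grid, with an optional retained-bin mask."""

    counts: np.ndarray
    bin_width: float = BIN_WIDTH
    kept_mask: np.ndarray | None = None

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.counts.size, dtype=bool)

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width


def touch_statistics(episodes) -> dict:
    """Summarize touch-episode durations and inter-touch intervals.

    Intervals are measured between consecutive episodes
    (``offset_k -> onset_{k+1}``).  Returns medians and interquartile ranges
    in seconds; an empty input yields an empty summary, a single episode an
    empty interval set.
    """
    episodes = sorted(episodes, key=lambda e: e.onset)
    durations = np.array([e.duration for e in episodes])
    intervals = np.array(
        [b.onset - a.offset for a, b in zip(episodes[:-1], episodes[1:])]
    )

    def _summ(x):
        if x.size == 0:
            return {"n": 0, "median": np.nan, "iqr": (np.nan, np.nan)}
        q25, q50, q75 = np.percentile(x, [25, 50, 75])
        return {"n": int(x.size), "median": float(q50), "iqr": (float(q25), float(q75))}

    return {
        "durations": durations,
        "intervals": intervals,
        "duration": _summ(durations),
        "interval": _summ(intervals),
    }


def bin_spikes(spike_times, session_end, bin_width=BIN_WIDTH) -> BinnedSpikeTrain:
    """Discretize spike times onto the 1-ms grid.

    A spike at time ``t`` increments bin ``floor(t / dt)``; the total count
    is conserved.  Spikes exactly at ``session_end`` land in the last bin.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size and t.min() < 0:
        raise ValueError("negative spike times")
    if t.size and t.max() > session_end:
        raise ValueError("spike times beyond session end")
    n_bins = int(np.ceil(session_end / bin_width - 1e-9))
    idx = np.minimum((t / bin_width).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins) if t.size else np.zeros(n_bins, int)
    return BinnedSpikeTrain(counts=counts.astype(np.int64), bin_width=bin_width)


def trim_baseline(bst: BinnedSpikeTrain, episodes, margin=5.0) -> BinnedSpikeTrain:
    """Mark bins further than ``margin`` seconds from any touch episode as dropped.

    A bin is retained iff its center lies within ``margin`` of the nearest
    episode boundary (bins inside an episode are always retained).  The
    counts are left untouched; only ``kept_mask`` changes.  Dropped bins are
    excluded from all downstream likelihoods.
    """
    if not np.isfinite(margin):
        return replace(bst, kept_mask=np.ones(bst.n_bins, dtype=bool))
    centers = bst.bin_centers
    kept = np.zeros(bst.n_bins, dtype=bool)
    for e in episodes:
        lo, hi = e.onset - margin, e.offset + margin
        kept |= (centers >= lo) & (centers <= hi)
    return replace(bst, kept_mask=kept)


def alpha_kernel(tau=0.075, bin_width=BIN_WIDTH, support=8.0):
    """Causal PSP-shaped alpha kernel ``f(x) = (x/tau) exp(1 - x/tau)``.

    The peak value is 1 at ``x = tau``; the kernel is zero for ``x < 0``.
    ``support`` is the kernel length in multiples of ``tau``.
    """
    x = np.arange(0, support * tau, bin_width)
    return (x / tau) * np.exp(1 - x / tau)


@dataclass
class PSTHResult:
    """Smoothed peri-stimulus rate, its s.e.m. across episodes, and the
    baseline-vs-post signed-rank comparison."""

    times: np.ndarray        # s, relative to touch onset
    rate: np.ndarray         # Hz, mean over episodes, smoothed
    sem: np.ndarray          # Hz, across-episode s.e.m. of the smoothed traces
    p_value: float | None    # Wilcoxon signed-rank, baseline vs post window
    n_episodes: int
    baseline_rates: np.ndarray
    post_rates: np.ndarray


def psth(
    spike_times,
    onsets,
    window=(-2.5, 1.0),
    tau=0.075,
    bin_width=BIN_WIDTH,
    baseline_window=(-2.5, 0.0),
    post_window=(0.0, 0.5),
) -> PSTHResult:
    """Peri-stimulus time histogram aligned to touch onsets.

    Per-episode spike counts on the 1-ms grid are smoothed with the causal
    alpha kernel (normalized to unit area so the trace is a rate in Hz) and
    averaged across episodes.  Mean rates in the baseline and post windows
    (computed from raw counts, not the smoothed trace) are compared with a
    Wilcoxon signed-rank test; with fewer than two episodes the test is
    skipped with a warning.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    onsets = np.asarray(onsets, dtype=float)
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_width))
    kernel = alpha_kernel(tau, bin_width)
    norm = kernel.sum() * bin_width  # unit-area normalization -> rate estimate

    traces = np.empty((onsets.size, n_bins))
    base_r = np.empty(onsets.size)
    post_r = np.empty(onsets.size)
    for k, t0 in enumerate(onsets):
        rel = spike_times - t0
        sel = rel[(rel >= lo) & (rel < hi)]
        idx = ((sel - lo) / bin_width).astype(np.int64)
        idx = np.clip(idx, 0, n_bins - 1)
        counts = np.bincount(idx, minlength=n_bins).astype(float)
        smoothed = np.convolve(counts, kernel)[:n_bins] / norm
        traces[k] = smoothed
        base_r[k] = ((rel >= baseline_window[0]) & (rel < baseline_window[1])).sum() / (
            baseline_window[1] - baseline_window[0]
        )
        post_r[k] = ((rel >= post_window[0]) & (rel < post_window[1])).sum() / (
            post_window[1] - post_window[0]
        )

    if onsets.size >= 2:
        diff = post_r - base_r
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(sstats.wilcoxon(base_r, post_r).pvalue)
    else:
        warnings.warn("fewer than two episodes; signed-rank test skipped")
        p = None

    times = lo + (np.arange(n_bins) + 0.5) * bin_width
    mean = traces.mean(axis=0) if onsets.size else np.zeros(n_bins)
    sem = (
        traces.std(axis=0, ddof=1) / np.sqrt(onsets.size)
        if onsets.size > 1
        else np.zeros(n_bins)
    )
    return PSTHResult(
        times=times,
        rate=mean,
        sem=sem,
        p_value=p,
        n_episodes=int(onsets.size),
        baseline_rates=base_r,
        post_rates=post_r,
    )
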