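"""Attention-to-breath neural analysis.

Participants breathe with eyes closed and tap after every 2 breaths while
EEG is recorded. The inter-tap interval is the trial's response time (RT);
trials are split per participant into high-consistency (|RT - median| <= 1
MAD) and low-consistency (beyond 1 MAD) classes, the premise being that
consistent tapping reflects sustained interoceptive attention. EEG epochs in
the 4 s before each tap are projected to a source space with a
Tikhonov-regularized minimum-norm inverse of the lead field, alpha-band
(8-12 Hz) power is computed per source, averaged within canonical networks
(FPN, CON, DMN), and the low-minus-high consistency differential per network
is the session's neural statistic. The pre/post intervention contrast on
that differential is a one-sided paired signed-rank test.

The MAD consistency rule is implemented two-sided by default: a literal
"RT <= median + 1 MAD" reading would label extremely fast taps consistent,
contradicting the premise; ``two_sided=False`` restores the literal rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .stats_report import cohens_d_paired, signed_rank_one_sided

__all__ = [
    "BreathSeries",
    "EEGRecording",
    "ConsistencySplit",
    "NetworkROISet",
    "NetworkActivity",
    "NETWORKS",
    "taps_to_rts",
    "split_consistency",
    "clean_eeg",
    "epoch_eeg",
    "reject_epochs",
    "alpha_power",
    "make_inverse",
    "network_activity",
    "consistency_differential",
    "session_differential",
    "prepost_contrast",
]

NETWORKS = ("FPN", "CON", "DMN")

#: Default analysis window relative to each tap, half-open [t-4, t) seconds.
DEFAULT_WINDOW = (-4.0, 0.0)
ALPHA_BAND = (8.0, 12.0)
#: Minimal cleaning defaults: band-pass edges (Hz) and epoch-rejection
#: peak amplitude (same units as the data; microvolts for scalp EEG).
BANDPASS = (1.0, 40.0)
REJECT_PEAK_UV = 150.0


@dataclass(frozen=True)
class BreathSeries:
    """Tap-event times for one breath-monitoring run (one or more blocks)."""

    blocks: tuple  # tuple of 1-D arrays, tap times in s from block start
    participant_id: str = "p0"
    role: str = "child"  # "child" | "parent"
    session: str = "pre"  # "pre" | "post"
    block_duration_s: float = 150.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "blocks", tuple(np.asarray(b, dtype=float) for b in self.blocks)
        )
        for b in self.blocks:
            if b.ndim != 1:
                raise ValueError("each block must be a 1-D array of tap times")
            if np.any(np.diff(b) <= 0):
                raise ValueError("tap times must be strictly increasing within a block")

    @property
    def n_taps(self) -> int:
        return int(sum(b.size for b in self.blocks))


@dataclass(frozen=True)
class EEGRecording:
    """Multichannel EEG for one run, stored per block as channels x samples."""

    blocks: tuple  # tuple of 2-D arrays (n_channels, n_samples)
    fs: float
    channel_labels: tuple
    tap_times: tuple = ()  # per block, tap marker times in s from block start

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "blocks", tuple(np.asarray(b, dtype=float) for b in self.blocks)
        )
        object.__setattr__(
            self, "tap_times", tuple(np.asarray(t, dtype=float) for t in self.tap_times)
        )
        n_ch = len(self.channel_labels)
        for b in self.blocks:
            if b.ndim != 2 or b.shape[0] != n_ch:
                raise ValueError("each block must be (n_channels, n_samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")


@dataclass(frozen=True)
class ConsistencySplit:
    """Per-trial RTs with their high/low consistency labels."""

    rts: np.ndarray
    median: float
    mad: float
    labels: np.ndarray  # "high" | "low" per trial

    @property
    def high(self) -> np.ndarray:
        return self.labels == "high"

    @property
    def low(self) -> np.ndarray:
        return self.labels == "low"


@dataclass(frozen=True)
class NetworkROISet:
    """Mapping from network name to a disjoint set of source labels."""

    rois: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set = set()
        for net, sources in self.rois.items():
            if not sources:
                raise ValueError(f"network {net!r} has an empty ROI")
            overlap = seen & set(sources)
            if overlap:
                raise ValueError(f"sources {sorted(overlap)} appear in multiple networks")
            seen |= set(sources)

    def indices(self, source_labels) -> dict:
        """Resolve each network's sources to indices into ``source_labels``."""
        lut = {lab: i for i, lab in enumerate(source_labels)}
        out = {}
        for net, sources in self.rois.items():
            missing = [s for s in sources if s not in lut]
            if missing:
                raise ValueError(f"sources {missing} not in the lead field")
            out[net] = np.array([lut[s] for s in sources], dtype=int)
        return out


@dataclass(frozen=True)
class NetworkActivity:
    """Per-trial, per-network alpha source power for one session."""

    power: pd.DataFrame  # trials x networks, nonnegative
    window: tuple = DEFAULT_WINDOW
    band: tuple = ALPHA_BAND


def taps_to_rts(series: BreathSeries) -> np.ndarray:
    """Inter-tap RTs computed within block (never across a block boundary)."""
    rts = []
    for b in series.blocks:
        if b.size < 2:
            warnings.warn("block has fewer than 2 taps; no RTs from it", stacklevel=2)
            continue
        rts.append(np.diff(b))
    return np.concatenate(rts) if rts else np.array([])


def split_consistency(rts, two_sided: bool = True) -> ConsistencySplit:
    """Split trials into high/low consistency around the participant's median RT.

    High consistency: ``|RT - median| <= MAD`` (or ``RT <= median + MAD`` under
    the literal one-sided rule); low consistency otherwise. Median and MAD are
    the participant's own. All-identical RTs give MAD 0 and all-high labels
    with a warning.
    """
    rts = np.asarray(rts, dtype=float)
    if rts.size < 4:
        raise ValueError("need at least 4 RTs to split by consistency")
    med = float(np.median(rts))
    mad = float(np.median(np.abs(rts - med)))
    if mad == 0 and np.all(rts == rts[0]):
        warnings.warn("all RTs identical; every trial labeled high consistency", stacklevel=2)
    dev = np.abs(rts - med) if two_sided else rts - med
    labels = np.where(dev <= mad, "high", "low")
    return ConsistencySplit(rts=rts, median=med, mad=mad, labels=labels)


def clean_eeg(eeg: EEGRecording, band: tuple = BANDPASS) -> EEGRecording:
    """Minimal cleaning: zero-phase band-pass (order-2 Butterworth) per block."""
    nyq = eeg.fs / 2.0
    if not (0 < band[0] < band[1] < nyq):
        raise ValueError(f"band {band} invalid for fs={eeg.fs}")
    sos = spsig.butter(2, band, btype="bandpass", fs=eeg.fs, output="sos")
    blocks = tuple(spsig.sosfiltfilt(sos, b, axis=-1) for b in eeg.blocks)
    return EEGRecording(blocks, eeg.fs, eeg.channel_labels, eeg.tap_times)


def epoch_eeg(eeg: EEGRecording, tap_times=None, window: tuple = DEFAULT_WINDOW):
    """Cut pre-response epochs around tap events.

    Each epoch is the half-open window ``[t + window[0], t + window[1])``
    around a tap, as exact sample indices; taps without full support inside
    their block are dropped and counted.

    Returns
    -------
    epochs : ndarray, shape (n_trials, n_channels, n_samples)
    kept : list of (block_index, tap_index) identifying surviving taps
    n_dropped : int
    """
    taps = tap_times if tap_times is not None else eeg.tap_times
    if len(taps) != len(eeg.blocks):
        raise ValueError("need one tap-time array per block")
    n_samp = int(round((window[1] - window[0]) * eeg.fs))
    if n_samp < 1:
        raise ValueError("empty analysis window")
    epochs, kept, n_dropped = [], [], 0
    for bi, (block, block_taps) in enumerate(zip(eeg.blocks, taps)):
        for ti, t in enumerate(np.asarray(block_taps, dtype=float)):
            start = int(round((t + window[0]) * eeg.fs))
            stop = start + n_samp
            if start < 0 or stop > block.shape[1]:
                n_dropped += 1
                continue
            epochs.append(block[:, start:stop])
            kept.append((bi, ti))
    if not epochs:
        raise ValueError("no taps have full window support")
    return np.stack(epochs), kept, n_dropped


def reject_epochs(epochs: np.ndarray, peak: float = REJECT_PEAK_UV):
    """Drop epochs whose absolute amplitude exceeds ``peak`` on any channel."""
    keep = np.abs(epochs).max(axis=(1, 2)) <= peak
    return epochs[keep], keep


def alpha_power(epochs, fs: float, band: tuple = ALPHA_BAND) -> np.ndarray:
    """Mean spectral power density in ``band`` along the last (time) axis.

    Welch's periodogram-averaging estimator with 1-second Hann segments and
    50% overlap; returns the mean PSD over frequencies inside the inclusive
    band, preserving the leading axes (e.g. per channel, or per trial and
    source). Nonnegative by construction.
    """
    x = np.asarray(epochs, dtype=float)
    if x.shape[-1] < fs:
        raise ValueError("epoch must be at least 1 s long")
    if band[1] > fs / 2.0:
        raise ValueError(f"band {band} exceeds Nyquist for fs={fs}")
    nperseg = int(min(x.shape[-1], round(fs)))
    freqs, psd = spsig.welch(x, fs=fs, nperseg=nperseg, axis=-1)
    sel = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(sel):
        raise ValueError("no spectral bins inside the band")
    return psd[..., sel].mean(axis=-1)


def make_inverse(lead_field, lam: float | None = None) -> np.ndarray:
    """Tikhonov-regularized minimum-norm inverse of a lead field.

    For a channels x sources gain matrix ``L`` returns the sources x channels
    operator ``L.T @ inv(L L.T + lam I)``. The default ``lam`` is 0.1 times
    the mean diagonal of ``L L.T``; ``lam=0`` requires an invertible
    ``L L.T`` and then yields an exact right-inverse.
    """
    L = np.asarray(lead_field, dtype=float)
    if L.ndim != 2:
        raise ValueError("lead field must be 2-D (channels x sources)")
    n_ch, n_src = L.shape
    if lam is None:
        lam = 0.1 * float(np.mean(np.einsum("cs,cs->c", L, L)))
    if lam < 0:
        raise ValueError("regularization must be nonnegative")
    # the channel-space form L^T (LL^T + lam I)^-1 equals the source-space
    # form (L^T L + lam I)^-1 L^T for lam > 0; the latter stays well posed
    # at lam=0 whenever the lead field has full column rank, so use the
    # smaller nonsingular Gram
    if n_src <= n_ch:
        A = L.T @ L + lam * np.eye(n_src)
        if lam == 0 and np.linalg.cond(A) > 1e12:
            raise np.linalg.LinAlgError(
                "lead field is column-rank deficient at lam=0; pass lam > 0"
            )
        return np.linalg.solve(A, L.T)
    A = L @ L.T + lam * np.eye(n_ch)
    if lam == 0 and np.linalg.cond(A) > 1e12:
        raise np.linalg.LinAlgError(
            "L L^T is singular at lam=0; pass a positive regularization"
        )
    return L.T @ np.linalg.inv(A)


def network_activity(
    epochs: np.ndarray,
    inverse: np.ndarray,
    roi: NetworkROISet,
    source_labels,
    fs: float,
    band: tuple = ALPHA_BAND,
    window: tuple = DEFAULT_WINDOW,
) -> NetworkActivity:
    """Project epochs to source space and average alpha power within networks.

    Per trial: channels -> sources via the inverse operator, Welch alpha
    power per source, then the unweighted mean over each network's ROI
    (project-then-power ordering).
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or inverse.shape[1] != epochs.shape[1]:
        raise ValueError("epochs (trials, channels, samples) must match the inverse")
    idx = roi.indices(source_labels)
    source_epochs = np.einsum("sc,tcn->tsn", inverse, epochs)
    power = alpha_power(source_epochs, fs=fs, band=band)  # (trials, sources)
    cols = {net: power[:, ix].mean(axis=1) for net, ix in idx.items()}
    return NetworkActivity(power=pd.DataFrame(cols), window=window, band=band)


def consistency_differential(activity: NetworkActivity, split: ConsistencySplit) -> dict:
    """Low-minus-high consistency mean network activity, per network.

    Raises ``ValueError`` when either consistency class is empty (degenerate
    run; the session yields no differential).
    """
    if len(activity.power) != split.rts.size:
        raise ValueError("activity trials and RT labels are misaligned")
    if not split.low.any() or not split.high.any():
        raise ValueError("a consistency class is empty; differential undefined")
    return {
        net: float(vals[split.low].mean() - vals[split.high].mean())
        for net, vals in ((n, activity.power[n].to_numpy()) for n in activity.power)
    }


def session_differential(
    eeg: EEGRecording,
    series: BreathSeries,
    lead_field: np.ndarray,
    roi: NetworkROISet,
    source_labels,
    band: tuple = ALPHA_BAND,
    window: tuple = DEFAULT_WINDOW,
    lam: float | None = None,
    bandpass: tuple | None = BANDPASS,
    reject_peak: float | None = REJECT_PEAK_UV,
    two_sided: bool = True,
) -> dict:
    """Full single-session pipeline: one consistency differential per network.

    Aligns trials as taps that both (a) have an RT (every within-block tap
    after the first) and (b) have full epoch support; cleans, epochs,
    projects, and splits on the retained RTs. Epoch rejection drops the
    corresponding RTs too, keeping activity and labels aligned.
    """
    if bandpass is not None:
        eeg = clean_eeg(eeg, band=bandpass)
    # taps eligible for an RT: index >= 1 within each block
    rt_taps = tuple(b[1:] for b in series.blocks)
    epochs, kept, _ = epoch_eeg(eeg, tap_times=rt_taps, window=window)
    rts_all = [np.diff(b) for b in series.blocks]
    rts = np.array([rts_all[bi][ti] for bi, ti in kept])
    if reject_peak is not None:
        epochs, keep = reject_epochs(epochs, peak=reject_peak)
        rts = rts[keep]
    if rts.size < 4:
        raise ValueError("fewer than 4 analyzable trials")
    inverse = make_inverse(lead_field, lam=lam)
    activity = network_activity(
        epochs, inverse, roi, source_labels, fs=eeg.fs, band=band, window=window
    )
    split = split_consistency(rts, two_sided=two_sided)
    return consistency_differential(activity, split)


def prepost_contrast(pre, post, direction: str = "decrease") -> pd.DataFrame:
    """Paired pre/post contrast of per-participant network differentials.

    Parameters
    ----------
    pre, post : mapping participant_id -> {network: differential}
        Participants missing from either session are dropped (listwise; no
        imputation) and counted.
    direction : str
        Hypothesized change of the differential ("decrease" by default:
        training is expected to reduce state-linked network activity).

    Returns
    -------
    pandas.DataFrame indexed by network with columns
    ``n, n_dropped, mean_change, d, z, p``.
    """
    common = sorted(set(pre) & set(post))
    n_dropped = len(set(pre) | set(post)) - len(common)
    if len(common) < 4:
        raise ValueError("fewer than 4 participants with both sessions; refusing")
    rows = {}
    networks = list(next(iter(pre.values())).keys())
    for net in networks:
        pre_v = np.array([pre[p][net] for p in common])
        post_v = np.array([post[p][net] for p in common])
        test = signed_rank_one_sided(pre_v, post_v, direction)
        try:
            d = cohens_d_paired(pre_v, post_v)
        except ValueError:  # zero change variance (e.g. post == pre)
            d = float("nan")
        rows[net] = {
            "n": len(common),
            "n_dropped": n_dropped,
            "mean_change": float(np.mean(post_v - pre_v)),
            "d": d,
            "z": test["z"],
            "p": test["p"],
        }
    return pd.DataFrame(rows).T
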