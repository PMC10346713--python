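"""Synthetic trial-structured multichannel time series.

This module emulates a single-subject passive-BCI recording session: a
binary-class session is divided into trials of a configurable duration,
presented in random order, and each trial yields a multichannel band-limited
signal.  Two knobs control the statistical structure that matters for
cross-validation studies:

``class_gain`` / ``delta``
    The class effect: per-class, per-band, per-channel amplitude multipliers
    on the band-limited components.  The helper :func:`gain_profile` builds a
    profile in which one class has its alpha-band amplitude raised by a
    relative factor ``delta`` on every channel, the separability knob.

``trial_gain_sd`` (tau)
    A per-trial multiplicative random effect ``g ~ Normal(1, tau^2)`` shared
    by every band and channel of the trial.  Epochs cut from the same trial
    therefore share the same overall power level, which makes them more
    correlated with each other than with epochs from other trials of the
    same class -- the leakage mechanism under study.

Band-limited noise is synthesized by frequency-domain masking of Gaussian
white noise (bins outside the band zeroed, inverse transform) and scaled so
the band-limited process has unit variance.  Within a band the spectrum is
flat, so the in-band Fourier energies are sufficient statistics for the
class; :func:`bayes_rate_oracle` exploits this to estimate the best
achievable single-epoch accuracy by Monte Carlo.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import norm

__all__ = [
    "DEFAULT_BAND_EDGES",
    "BAND_NAMES",
    "SessionConfig",
    "TrialRecord",
    "TrialDataset",
    "gain_profile",
    "plan_session",
    "generate_session",
    "band_limited_noise",
    "bayes_rate_oracle",
    "save_dataset",
    "load_dataset",
]

#: delta / theta / alpha / beta / gamma edges in Hz
DEFAULT_BAND_EDGES: tuple[tuple[float, float], ...] = (
    (1.0, 4.0),
    (4.0, 8.0),
    (8.0, 12.0),
    (12.0, 30.0),
    (30.0, 50.0),
)
BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: lower truncation of the per-trial gain; keeps power positive so the
#: multiplicative random effect never flips the sign of the band amplitude
MIN_TRIAL_GAIN = 0.05


class ConfigurationError(ValueError):
    """Raised when a session configuration violates its invariants."""


@dataclasses.dataclass(frozen=True)
class SessionConfig:
    """Design of one synthetic recording session.

    Parameters
    ----------
    n_classes
        Number of mental-state classes; the binary designs studied here fix
        this at 2.
    minutes_per_class
        Recording time per class (default 6 minutes).
    trial_duration_s
        Duration of one trial in seconds; 5 / 15 / 60 s give 1 / 3 / 12
        five-second epochs per trial.
    epoch_duration_s
        Duration of the non-overlapping epochs later cut from each trial.
    fs
        Sampling rate in Hz.
    n_channels
        Number of recording channels.
    class_gain
        Array of shape ``(n_classes, n_bands, n_channels)`` of amplitude
        multipliers on the band-limited components.  ``None`` means all ones
        (no class effect); see :func:`gain_profile`.
    trial_gain_sd
        Standard deviation tau of the per-trial multiplicative gain
        ``g ~ Normal(1, tau^2)`` (truncated below at ``MIN_TRIAL_GAIN``).
        tau = 0 gives i.i.d. trials.
    noise_sd
        Standard deviation of the broadband white-noise floor.
    band_edges
        ``(low, high)`` Hz pairs of the band-limited components.
    seed
        Default seed for :func:`generate_session` when none is passed.
    """

    n_classes: int = 2
    minutes_per_class: float = 6.0
    trial_duration_s: float = 60.0
    epoch_duration_s: float = 5.0
    fs: float = 250.0
    n_channels: int = 8
    class_gain: np.ndarray | None = None
    trial_gain_sd: float = 0.0
    noise_sd: float = 1.0
    band_edges: tuple[tuple[float, float], ...] = DEFAULT_BAND_EDGES
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes != 2:
            raise ConfigurationError(
                f"n_classes must be 2 for binary session designs, got {self.n_classes}"
            )
        if self.trial_gain_sd < 0:
            raise ConfigurationError(f"trial_gain_sd must be >= 0, got {self.trial_gain_sd}")
        if self.noise_sd <= 0:
            raise ConfigurationError(f"noise_sd must be > 0, got {self.noise_sd}")
        if self.trial_duration_s <= 0 or self.epoch_duration_s <= 0:
            raise ConfigurationError("trial_duration_s and epoch_duration_s must be positive")
        if self.fs <= 0 or self.n_channels < 1:
            raise ConfigurationError("fs must be positive and n_channels >= 1")
        nyquist = self.fs / 2.0
        for low, high in self.band_edges:
            if low >= high:
                raise ConfigurationError(f"degenerate band ({low}, {high}): low >= high")
            if high > nyquist:
                raise ConfigurationError(
                    f"band ({low}, {high}) exceeds the Nyquist frequency {nyquist} Hz"
                )
        if self.class_gain is not None:
            gain = np.asarray(self.class_gain, dtype=float)
            expected = (self.n_classes, len(self.band_edges), self.n_channels)
            if gain.shape != expected:
                raise ConfigurationError(
                    f"class_gain shape {gain.shape} != (n_classes, n_bands, n_channels) {expected}"
                )
            if np.any(gain < 0):
                raise ConfigurationError("class_gain entries must be non-negative")
            object.__setattr__(self, "class_gain", gain)

    # -- derived quantities -------------------------------------------------

    @property
    def trials_per_class(self) -> int:
        total_s = self.minutes_per_class * 60.0
        n = total_s / self.trial_duration_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                f"minutes_per_class ({self.minutes_per_class} min = {total_s} s) is not "
                f"divisible by trial_duration_s ({self.trial_duration_s} s)"
            )
        return int(round(n))

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.fs * self.trial_duration_s))

    @property
    def epochs_per_trial(self) -> int:
        n = int(self.trial_duration_s // self.epoch_duration_s)
        if n < 1:
            raise ConfigurationError("epoch_duration_s exceeds trial_duration_s")
        return n

    def resolved_class_gain(self) -> np.ndarray:
        if self.class_gain is None:
            return np.ones((self.n_classes, len(self.band_edges), self.n_channels))
        return np.asarray(self.class_gain, dtype=float)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.class_gain is not None:
            d["class_gain"] = np.asarray(self.class_gain).tolist()
        d["band_edges"] = [list(b) for b in self.band_edges]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SessionConfig":
        d = dict(d)
        if d.get("class_gain") is not None:
            d["class_gain"] = np.asarray(d["class_gain"], dtype=float)
        d["band_edges"] = tuple(tuple(b) for b in d["band_edges"])
        return cls(**d)


def gain_profile(
    delta: float,
    n_channels: int,
    band_index: int = 2,
    n_bands: int = len(DEFAULT_BAND_EDGES),
    channels: Sequence[int] | None = None,
) -> np.ndarray:
    """Build a binary class-gain array with a single-band amplitude contrast.

    Class 0 has unit gain everywhere; class 1 has gain ``1 + delta`` in band
    ``band_index`` (alpha by default) on the given channels (all by default).
    ``delta`` is therefore the relative amplitude difference between classes
    and the separability knob of the generator.
    """
    if delta < 0:
        raise ConfigurationError(f"delta must be >= 0, got {delta}")
    gain = np.ones((2, n_bands, n_channels))
    sel = np.arange(n_channels) if channels is None else np.asarray(channels, dtype=int)
    gain[1, band_index, sel] = 1.0 + delta
    return gain


@dataclasses.dataclass
class TrialRecord:
    """One trial: a continuous recording of a single class."""

    trial_id: str
    class_label: int
    section: str
    order_index: int
    signal: np.ndarray  # channels x time
    fs: float


@dataclasses.dataclass
class TrialDataset:
    """Ordered collection of trials from one synthetic session."""

    trials: list[TrialRecord]
    config: SessionConfig

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def class_labels(self) -> np.ndarray:
        return np.array([t.class_label for t in self.trials])


def plan_session(config: SessionConfig, seed: int | None = None) -> list[dict]:
    """Enumerate the trial slots of a session in randomized presentation order.

    Returns a list of ``{"trial_id", "class_label", "order_index"}`` dicts,
    one per trial, sorted by ``order_index``.  Trial counts follow from the
    design arithmetic ``trials_per_class = minutes_per_class * 60 /
    trial_duration_s`` (a non-integer ratio raises
    :class:`ConfigurationError` naming the offending fields), and the class
    sequence is a uniformly random interleaving under the plan seed.
    """
    tpc = config.trials_per_class  # raises on non-divisible durations
    rng = np.random.default_rng(config.seed if seed is None else seed)
    labels = np.repeat(np.arange(config.n_classes), tpc)
    order = rng.permutation(labels.size)
    ordered_labels = labels[order]
    counters = {c: 0 for c in range(config.n_classes)}
    plan = []
    for position, label in enumerate(ordered_labels):
        idx = counters[int(label)]
        counters[int(label)] += 1
        plan.append(
            {
                "trial_id": f"c{int(label)}t{idx:03d}",
                "class_label": int(label),
                "order_index": position,
            }
        )
    return plan


def _band_masks(n: int, fs: float, band_edges) -> list[np.ndarray]:
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    masks = []
    for low, high in band_edges:
        mask = (freqs >= low) & (freqs < high)
        mask[0] = False  # never include DC
        if n % 2 == 0:
            mask[-1] = False  # exclude the Nyquist bin
        if not mask.any():
            raise ConfigurationError(
                f"band ({low}, {high}) Hz contains no Fourier bins at n={n}, fs={fs}"
            )
        masks.append(mask)
    return masks


def band_limited_noise(
    rng: np.random.Generator,
    n_samples: int,
    fs: float,
    band: tuple[float, float],
    n_channels: int = 1,
) -> np.ndarray:
    """Unit-variance Gaussian noise exactly confined to ``band`` Hz.

    White noise is transformed to the frequency domain, bins outside the
    band are zeroed, and the result is scaled so the band-limited process
    has unit variance (the scale is the analytic one, so the in-band
    spectrum stays exactly flat and Gaussian).
    """
    mask = _band_masks(n_samples, fs, [band])[0]
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    spectrum[:, ~mask] = 0.0
    m_b = int(mask.sum())
    scale = np.sqrt(n_samples / (2.0 * m_b))
    return np.fft.irfft(spectrum, n=n_samples, axis=1) * scale


def generate_session(
    config: SessionConfig, seed: int | None = None, plan_seed: int | None = None
) -> TrialDataset:
    """Simulate a full session as a :class:`TrialDataset`.

    For each trial a gain ``g ~ Normal(1, tau^2)`` (truncated at
    ``MIN_TRIAL_GAIN``) is drawn once and shared by all bands and channels;
    each channel's signal is::

        sum_b class_gain[c, b, ch] * g * eta_b(t)  +  noise_sd * w(t)

    with ``eta_b`` unit-variance band-limited noise and ``w`` white noise.
    The session plan and the signal noise use two independent seed streams
    (``plan_seed`` overrides the former), so the trial ordering can be
    varied while the waveforms are held fixed.  Deterministic given the
    seeds.
    """
    base = np.random.SeedSequence(config.seed if seed is None else seed)
    plan_seq, noise_seq = base.spawn(2)
    if plan_seed is None:
        plan_seed = int(plan_seq.generate_state(1)[0])
    plan = plan_session(config, seed=plan_seed)
    noise_rng = np.random.default_rng(noise_seq)

    gain = config.resolved_class_gain()
    n = config.samples_per_trial
    section = f"T{config.trial_duration_s:g}"
    trials = []
    for slot in plan:
        c = slot["class_label"]
        g = max(MIN_TRIAL_GAIN, noise_rng.normal(1.0, config.trial_gain_sd))
        signal = config.noise_sd * noise_rng.standard_normal((config.n_channels, n))
        for b, band in enumerate(config.band_edges):
            eta = band_limited_noise(noise_rng, n, config.fs, band, config.n_channels)
            signal += (gain[c, b, :, None] * g) * eta
        trials.append(
            TrialRecord(
                trial_id=slot["trial_id"],
                class_label=c,
                section=section,
                order_index=slot["order_index"],
                signal=signal,
                fs=config.fs,
            )
        )
    return TrialDataset(trials=trials, config=config)


# ---------------------------------------------------------------------------
# Bayes-rate oracle
# ---------------------------------------------------------------------------


def _gain_grid(tau: float, n_grid: int = 201) -> tuple[np.ndarray, np.ndarray]:
    """Quadrature nodes and weights for the truncated trial-gain distribution."""
    if tau == 0:
        return np.array([1.0]), np.array([1.0])
    lo, hi = MIN_TRIAL_GAIN, 1.0 + 6.0 * tau
    gs = np.linspace(lo, hi, n_grid)
    w = norm.pdf(gs, loc=1.0, scale=tau)
    w = w / w.sum() * (1.0 - norm.cdf(lo, loc=1.0, scale=tau))
    # the truncation piles the lower tail onto MIN_TRIAL_GAIN
    w[0] += norm.cdf(lo, loc=1.0, scale=tau)
    return gs, w / w.sum()


def bayes_rate_oracle(
    config: SessionConfig,
    n_mc: int = 100_000,
    seed: int = 0,
    n_grid: int = 201,
) -> tuple[float, float]:
    """Monte-Carlo estimate of the best achievable single-epoch accuracy.

    Under the generator, conditional on the trial gain ``g``, the in-band
    Fourier energies of an epoch are independent Gamma variates with known
    shape (the number of in-band bins) and scale (band amplitude squared
    plus the white-noise floor).  Those energies are sufficient for the
    class, so the optimal classifier is the likelihood-ratio rule with ``g``
    marginalized out (numerical quadrature over its truncated normal
    distribution).  ``n_mc`` independent single epochs are simulated from
    their exact sampling distribution and classified by that rule.

    Returns ``(accuracy, standard_error)`` on the 0-1 scale.
    """
    if n_mc < 1000:
        raise ValueError(f"n_mc must be >= 1000, got {n_mc}")
    rng = np.random.default_rng(seed)
    n_e = int(round(config.fs * config.epoch_duration_s))
    masks = _band_masks(n_e, config.fs, config.band_edges)
    m_b = np.array([int(m.sum()) for m in masks])  # bins per band
    gain = config.resolved_class_gain()  # (2, n_bands, n_channels)
    sigma2 = config.noise_sd**2

    n_bands, n_ch = len(config.band_edges), config.n_channels
    n_feat = n_bands * n_ch
    shapes = np.repeat(m_b, n_ch)  # (n_feat,)

    gs, gw = _gain_grid(config.trial_gain_sd, n_grid)
    # per-bin variance of a complex rfft coefficient, up to the common
    # factor n_e which cancels in the likelihood ratio
    # band component per-bin: (gain*g)^2 * n_e / (2 m_b); white: sigma^2
    # (divide the common n_e out)
    band_perbin = gain[:, :, :, None] ** 2 * gs[None, None, None, :] ** 2 / (
        2.0 * m_b[None, :, None, None]
    ) * n_e  # (2, n_bands, n_ch, n_grid) -- actually scaled by n_e below
    v = band_perbin + sigma2  # same units for both terms after the n_e scale
    # v has shape (2, n_bands, n_ch, n_grid); flatten (band, ch) -> feature
    v = v.reshape(2, n_feat, len(gs))

    # simulate energies: class balanced, each sample has its own g
    n0 = n_mc // 2
    labels = np.repeat([0, 1], [n0, n_mc - n0])
    g_samp = np.maximum(MIN_TRIAL_GAIN, rng.normal(1.0, config.trial_gain_sd, size=n_mc))
    scale_samp = (
        gain[labels, :, :] ** 2 * g_samp[:, None, None] ** 2 / (2.0 * m_b[None, :, None]) * n_e
        + sigma2
    ).reshape(n_mc, n_feat)
    energies = rng.gamma(shape=shapes[None, :], scale=scale_samp)

    # log-likelihood per (sample, class) marginalized over the gain grid
    log_v = np.log(v)  # (2, n_feat, n_grid)
    const = np.einsum("f,cfj->cj", shapes, log_v)  # (2, n_grid)
    inv_v = (1.0 / v).transpose(0, 2, 1).reshape(2 * len(gs), n_feat)  # (2*J, n_feat)
    s = energies @ inv_v.T  # (n_mc, 2*J)
    ll = -s.reshape(n_mc, 2, len(gs)) - const[None, :, :] + np.log(gw)[None, None, :]
    log_post = logsumexp(ll, axis=2)  # (n_mc, 2)
    pred = np.argmax(log_post, axis=1)
    acc = float(np.mean(pred == labels))
    se = float(np.sqrt(acc * (1.0 - acc) / n_mc))
    return acc, se


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------


def save_dataset(dataset: TrialDataset, out_dir: str | Path) -> Path:
    """Persist a dataset: ``manifest.json`` plus one CSV per trial
    (rows = channels, columns = time samples)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": dataset.config.to_dict(),
        "trials": [
            {
                "trial_id": t.trial_id,
                "class_label": t.class_label,
                "section": t.section,
                "order_index": t.order_index,
                "fs": t.fs,
                "file": f"{t.trial_id}.csv",
            }
            for t in dataset.trials
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for t in dataset.trials:
        np.savetxt(out / f"{t.trial_id}.csv", t.signal, delimiter=",")
    return out


def load_dataset(in_dir: str | Path) -> TrialDataset:
    """Load a dataset written by :func:`save_dataset`."""
    src = Path(in_dir)
    manifest = json.loads((src / "manifest.json").read_text())
    config = SessionConfig.from_dict(manifest["config"])
    trials = []
    for entry in manifest["trials"]:
        signal = np.loadtxt(src / entry["file"], delimiter=",", ndmin=2)
        trials.append(
            TrialRecord(
                trial_id=entry["trial_id"],
                class_label=int(entry["class_label"]),
                section=entry["section"],
                order_index=int(entry["order_index"]),
                signal=signal,
                fs=float(entry["fs"]),
            )
        )
    trials.sort(key=lambda t: t.order_index)
    return TrialDataset(trials=trials, config=config)
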