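"""Synthetic EEG for the ambiguous-stimulus classification design.

The emulated experiment presents Necker-cube images whose inner-edge
contrast ``I`` controls perceptual ambiguity ``a``: ``a`` rises linearly
from 0 at ``I = 0`` to 100% at ``I = 0.5`` and mirrors for right-oriented
cubes (``I > 0.5``).  The eight study contrasts split into a low-ambiguity
class (LA: a = 30, 50%) and a high-ambiguity class (HA: a = 80, 90%).

Each subject's recording is emulated as stimulus-locked 4-s epochs of
31-channel EEG: 1/f background noise with a shared spatial component, an
ongoing alpha-range oscillation, and — on HA trials only — band-limited
oscillatory bursts confined to known channel sets, frequency bands and
post-stimulus windows.  Those injected boxes are the ground truth that the
downstream cluster statistics must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .montage import Montage, make_standard_montage

#: the study's eight inner-edge contrasts (left-oriented first)
STUDY_CONTRASTS: tuple[float, ...] = (0.15, 0.25, 0.4, 0.45, 0.55, 0.6, 0.75, 0.85)

LA_AMBIGUITIES = (30.0, 50.0)
HA_AMBIGUITIES = (80.0, 90.0)


def contrast_to_ambiguity(I: float) -> float:
    """Map inner-edge contrast ``I`` in [0, 1] to ambiguity ``a`` in percent.

    Linear with anchors a=0 at I=0 and a=100 at I=0.5; symmetric about
    I=0.5 for right-oriented stimuli.
    """
    I = float(I)
    if not 0.0 <= I <= 1.0:
        raise ValueError(f"contrast I={I} outside [0, 1]")
    # round away float fuzz (e.g. 100*(1-0.85)/0.5 -> 30.000000000000004)
    return round(100.0 * (I if I <= 0.5 else 1.0 - I) / 0.5, 9)


def ambiguity_class(a: float) -> str:
    """LA for a in {30, 50}, HA for a in {80, 90} (tolerant comparison)."""
    for ref in LA_AMBIGUITIES:
        if np.isclose(a, ref):
            return "LA"
    for ref in HA_AMBIGUITIES:
        if np.isclose(a, ref):
            return "HA"
    raise ValueError(f"ambiguity {a}% is outside the study's LA/HA grouping")


@dataclass(frozen=True)
class StimulusSpec:
    """One presented stimulus."""

    contrast_I: float
    orientation: str            # "left" | "right"
    ambiguity_a: float          # percent
    class_label: str            # "LA" | "HA"
    presentation_s: float       # uniform in [1.0, 1.5]
    pause_s: float              # uniform in [3.0, 5.0]

    def __post_init__(self) -> None:
        if not np.isclose(self.ambiguity_a, contrast_to_ambiguity(self.contrast_I)):
            raise ValueError("ambiguity_a inconsistent with contrast_I")
        if self.class_label != ambiguity_class(self.ambiguity_a):
            raise ValueError("class_label inconsistent with ambiguity_a")
        if not 1.0 <= self.presentation_s <= 1.5:
            raise ValueError("presentation_s outside [1.0, 1.5] s")
        if not 3.0 <= self.pause_s <= 5.0:
            raise ValueError("pause_s outside [3.0, 5.0] s")


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered trial list for one subject's session."""

    trials: tuple[StimulusSpec, ...]

    @property
    def labels(self) -> np.ndarray:
        return np.array([t.class_label for t in self.trials])

    def class_counts(self) -> dict[str, int]:
        lab = self.labels
        return {"LA": int(np.sum(lab == "LA")), "HA": int(np.sum(lab == "HA"))}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contrast_I": [t.contrast_I for t in self.trials],
                "orientation": [t.orientation for t in self.trials],
                "ambiguity_a": [t.ambiguity_a for t in self.trials],
                "class_label": [t.class_label for t in self.trials],
                "presentation_s": [t.presentation_s for t in self.trials],
                "pause_s": [t.pause_s for t in self.trials],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def generate_schedule(
    n_per_contrast: int = 25,
    contrasts=STUDY_CONTRASTS,
    seed: int | np.random.Generator = 0,
) -> StimulusSchedule:
    """Randomized presentation order with the study's per-contrast balance.

    Defaults reproduce the session design: 25 presentations of each of the
    eight contrasts, i.e. 100 LA + 100 HA trials, each class balanced 50/50
    by orientation.
    """
    if n_per_contrast < 1:
        raise ValueError("n_per_contrast must be >= 1")
    contrasts = tuple(contrasts)
    if not contrasts:
        raise ValueError("empty contrast list")
    rng = np.random.default_rng(seed)
    specs = []
    for I in contrasts:
        a = contrast_to_ambiguity(I)
        orientation = "left" if I <= 0.5 else "right"
        label = ambiguity_class(a)
        for _ in range(n_per_contrast):
            specs.append(
                StimulusSpec(
                    contrast_I=I,
                    orientation=orientation,
                    ambiguity_a=a,
                    class_label=label,
                    presentation_s=float(rng.uniform(1.0, 1.5)),
                    pause_s=float(rng.uniform(3.0, 5.0)),
                )
            )
    order = rng.permutation(len(specs))
    return StimulusSchedule(tuple(specs[i] for i in order))


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth class effect: an HA-only power increase in a box.

    ``amplitude_gain`` is the approximate multiplicative factor on band
    power inside the (channels x [f_lo,f_hi] x [t_lo,t_hi]) box; gain 1
    means no injected effect (null data).  ``jitter`` scales per-subject
    Gaussian perturbations of the bounds (Hz, s) and a lognormal
    perturbation of the gain.
    """

    channel_set: tuple[str, ...]
    f_lo: float
    f_hi: float
    t_lo: float
    t_hi: float
    amplitude_gain: float = 2.0
    jitter_f: float = 0.0
    jitter_t: float = 0.0
    jitter_gain: float = 0.0

    def __post_init__(self) -> None:
        if not 4.0 <= self.f_lo < self.f_hi <= 40.0:
            raise ValueError("effect frequency band must satisfy 4 <= f_lo < f_hi <= 40 Hz")
        if not 0.0 <= self.t_lo < self.t_hi <= 0.5:
            raise ValueError("effect time window must satisfy 0 <= t_lo < t_hi <= 0.5 s")
        if self.amplitude_gain <= 0:
            raise ValueError("amplitude_gain must be positive")

    def perturbed(self, rng: np.random.Generator) -> "EffectSpec":
        """Per-subject realization under the jitter model."""
        if self.jitter_f == self.jitter_t == self.jitter_gain == 0:
            return self
        f_lo = self.f_lo + rng.normal(0, self.jitter_f)
        f_hi = self.f_hi + rng.normal(0, self.jitter_f)
        t_lo = self.t_lo + rng.normal(0, self.jitter_t)
        t_hi = self.t_hi + rng.normal(0, self.jitter_t)
        gain = self.amplitude_gain * float(np.exp(rng.normal(0, self.jitter_gain)))
        # clamp into the legal box, preserving a minimal width
        f_lo = float(np.clip(f_lo, 4.0, 39.0))
        f_hi = float(np.clip(max(f_hi, f_lo + 0.5), f_lo + 0.5, 40.0))
        t_lo = float(np.clip(t_lo, 0.0, 0.45))
        t_hi = float(np.clip(max(t_hi, t_lo + 0.02), t_lo + 0.02, 0.5))
        return replace(self, f_lo=f_lo, f_hi=f_hi, t_lo=t_lo, t_hi=t_hi,
                       amplitude_gain=gain)


def default_effects(gain: float = 2.5,
                    jitter_f: float = 0.25, jitter_t: float = 0.01,
                    jitter_gain: float = 0.1) -> tuple[EffectSpec, ...]:
    """Three effects loosely mimicking the study's significant clusters:

    anterior theta (7-9 Hz, 0-0.15 s), occipito-parietal beta
    (22-24 Hz, 0.02-0.2 s), and a late fronto-parietal high-beta burst
    (31-32 Hz, 0.35-0.42 s).
    """
    kw = dict(jitter_f=jitter_f, jitter_t=jitter_t, jitter_gain=jitter_gain)
    return (
        EffectSpec(("Fp1", "Fp2", "F3", "Fz", "F4"), 7.0, 9.0, 0.0, 0.15,
                   amplitude_gain=gain, **kw),
        EffectSpec(("P3", "Pz", "P4", "PO3", "POz", "PO4", "O1", "Oz", "O2"),
                   22.0, 24.0, 0.02, 0.2, amplitude_gain=gain, **kw),
        EffectSpec(("F3", "Fz", "F4", "P3", "Pz", "P4"), 31.0, 32.0, 0.35, 0.42,
                   amplitude_gain=gain, **kw),
    )


@dataclass(frozen=True)
class NoiseParams:
    """Background model: 1/f^chi noise + shared spatial component + alpha.

    ``spatial_mix`` is the amplitude fraction of a channel-shared 1/f
    process (spatial correlation); ``alpha_amplitude`` the ongoing
    ~10 Hz oscillation amplitude (same units as the noise SD of 1).
    """

    chi: float = 1.0
    spatial_mix: float = 0.3
    alpha_freq: float = 10.0
    alpha_freq_sd: float = 0.5
    alpha_amplitude: float = 0.5


@dataclass
class EpochSet:
    """Stimulus-locked trials of one subject."""

    subject_id: int
    channels: tuple[str, ...]
    fs: float
    window: tuple[float, float]          # seconds relative to onset
    data: np.ndarray                     # (n_trials, n_channels, n_samples)
    labels: np.ndarray                   # (n_trials,) of "LA"/"HA"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.labels = np.asarray(self.labels)
        n_samples = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.ndim != 3 or self.data.shape[1] != len(self.channels):
            raise ValueError("data must be (trials, channels, samples)")
        if self.data.shape[2] != n_samples:
            raise ValueError(f"expected {n_samples} samples for window {self.window} at fs={self.fs}")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length mismatch")
        if not np.all(np.isin(self.labels, ("LA", "HA"))):
            raise ValueError("labels must be 'LA' or 'HA'")

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window[0] + np.arange(n) / self.fs


def _one_over_f_weights(n_samples: int, fs: float, chi: float) -> np.ndarray:
    """rFFT amplitude weights for unit-variance 1/f^chi noise (DC zeroed)."""
    f = np.fft.rfftfreq(n_samples, 1.0 / fs)
    w = np.zeros_like(f)
    w[1:] = f[1:] ** (-chi / 2.0)
    return w


def _synth_noise(rng: np.random.Generator, shape_leading: tuple, weights: np.ndarray,
                 n_samples: int) -> np.ndarray:
    """Gaussian noise with the given rFFT amplitude profile, unit variance."""
    n_f = len(weights)
    re = rng.standard_normal(shape_leading + (n_f,))
    im = rng.standard_normal(shape_leading + (n_f,))
    spec = (re + 1j * im) * weights
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    # irfft of CN(0, 2 w_k^2) bins has per-sample variance 4*sum(w^2)/n^2;
    # rescale to exactly unit variance
    x *= n_samples / (2.0 * np.sqrt(np.sum(weights**2)))
    return x


def generate_epochs(
    n_subjects: int = 20,
    schedule: StimulusSchedule | None = None,
    effects: tuple[EffectSpec, ...] | None = None,
    noise_params: NoiseParams | None = None,
    fs: float = 250.0,
    window: tuple[float, float] = (-2.0, 2.0),
    montage: Montage | None = None,
    seed: int = 0,
    max_analysis_freq: float = 40.0,
) -> list[EpochSet]:
    """Simulate stimulus-locked epochs for a cohort of subjects.

    Each subject gets an independent schedule (same design), independent
    noise, and a per-subject jittered realization of every effect.  Per
    trial: background = (1-mix)*own 1/f + mix*shared 1/f, plus an ongoing
    alpha oscillation with random phase/frequency; HA trials additionally
    receive, for each effect, a Hann-windowed sinusoidal burst at the
    band's center frequency on the effect channels, with amplitude set so
    that band power inside the box is multiplied by about
    ``amplitude_gain``.

    One master ``seed`` fans out into independent per-subject streams.
    """
    if fs < 2.0 * max_analysis_freq:
        raise ValueError(f"fs={fs} below Nyquist for {max_analysis_freq} Hz analysis")
    if montage is None:
        montage = make_standard_montage()
    if noise_params is None:
        noise_params = NoiseParams()
    if effects is None:
        effects = default_effects()
    for e in effects:
        if e.f_hi > max_analysis_freq:
            raise ValueError(f"effect band up to {e.f_hi} Hz outside analysis range")
        montage.index(e.channel_set)  # raises on unresolvable channels

    n_samples = int(round((window[1] - window[0]) * fs))
    times = window[0] + np.arange(n_samples) / fs
    weights = _one_over_f_weights(n_samples, fs, noise_params.chi)

    master = np.random.SeedSequence(seed)
    subject_seeds = master.spawn(n_subjects)

    out: list[EpochSet] = []
    for sid, ss in enumerate(subject_seeds):
        rng = np.random.default_rng(ss)
        sched = schedule if schedule is not None else generate_schedule(seed=rng)
        labels = sched.labels
        n_trials = len(labels)
        n_ch = montage.n_channels

        own = _synth_noise(rng, (n_trials, n_ch), weights, n_samples)
        shared = _synth_noise(rng, (n_trials, 1), weights, n_samples)
        mix = noise_params.spatial_mix
        data = (1.0 - mix) * own + mix * shared

        # ongoing alpha oscillation, random phase & frequency per trial
        a_f = rng.normal(noise_params.alpha_freq, noise_params.alpha_freq_sd,
                         size=(n_trials, 1, 1))
        a_ph = rng.uniform(0, 2 * np.pi, size=(n_trials, 1, 1))
        data += noise_params.alpha_amplitude * np.sin(2 * np.pi * a_f * times + a_ph)

        # calibrate burst amplitudes against the background power the
        # analysis wavelet actually measures in each effect box
        from .spectral import measure_box_power

        ha = np.flatnonzero(labels == "HA")
        n_probe = min(20, n_trials)
        for eff in effects:
            e = eff.perturbed(rng)
            ch_idx = montage.index(e.channel_set)
            extra_gain = e.amplitude_gain - 1.0
            if extra_gain <= 0:
                continue
            probe = data[:n_probe][:, ch_idx].reshape(n_probe * len(ch_idx), -1)
            p_bg = measure_box_power(probe, fs, window[0],
                                     e.f_lo, e.f_hi, e.t_lo, e.t_hi)
            fc = 0.5 * (e.f_lo + e.f_hi)
            sel = (times >= e.t_lo) & (times <= e.t_hi)
            env = np.zeros(n_samples)
            env[sel] = np.hanning(sel.sum())
            # in-box wavelet power of the unit-amplitude burst itself,
            # averaged over carrier phase, sets the scaling exactly
            unit = env * np.stack([np.sin(2 * np.pi * fc * times),
                                   np.cos(2 * np.pi * fc * times)])
            p_unit = measure_box_power(unit, fs, window[0],
                                       e.f_lo, e.f_hi, e.t_lo, e.t_hi)
            amp = np.sqrt(extra_gain * p_bg / p_unit)
            ph = rng.uniform(0, 2 * np.pi, size=(len(ha), 1, 1))
            burst = amp * env * np.sin(2 * np.pi * fc * times + ph)
            data[np.ix_(ha, ch_idx)] += burst

        out.append(EpochSet(subject_id=sid, channels=montage.channels, fs=fs,
                            window=window, data=data, labels=labels))
    return out


def generate_null_subject_ersp(
    n_subjects: int = 8,
    n_channels: int = 8,
    n_freqs: int = 10,
    n_times: int = 10,
    smooth_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exchangeable HA/LA subject-mean ERSP maps on a reduced grid.

    Intended for calibrating the cluster test's false-alarm rate without
    simulating raw EEG: both conditions are a shared subject map plus
    independent spatio-spectrally smoothed noise, so HA and LA are
    exchangeable within subject (the null of the paired contrast holds).

    Returns ``(ersp_ha, ersp_la)`` of shape (n_subjects, n_channels,
    n_freqs, n_times).
    """
    from scipy.ndimage import gaussian_filter

    rng = np.random.default_rng(seed)
    shape = (n_subjects, n_channels, n_freqs, n_times)
    base = rng.standard_normal(shape)
    ha = base + rng.standard_normal(shape)
    la = base + rng.standard_normal(shape)
    if smooth_sigma > 0:
        sig = (0.0, 0.0, smooth_sigma, smooth_sigma)
        ha = gaussian_filter(ha, sigma=sig)
        la = gaussian_filter(la, sigma=sig)
    return ha, la
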