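"""Synthetic studies with the statistical structure the analysis assumes.

Two generators are provided, at the two levels the pipeline consumes:

* :func:`generate_study` builds full continuous EEG recordings (1/f
  background noise plus an amplitude-modulated alpha oscillation whose
  hemispheric gains encode a configured lateralization-index time course),
  together with per-session cortisol profiles and a ground-truth record.
  This is the input to the complete preprocessing + time-frequency path.
* :func:`simulate_trial_power` draws studies directly at the level of
  trial-wise contralateral/ipsilateral time-frequency power, which is the
  quantity the statistical stages actually consume. It reproduces the same
  latent structure (condition-dependent LI profiles, subject
  heterogeneity, cortisol coupling) at a configurable grid and is what
  makes repeated-study calibration experiments affordable.

Everything is deterministic given the configured seed: identical
(config, seed) reproduce the study byte for byte.

The defaults encode the emulated study design: 20 subjects x 2 sessions
(stress / control, counterbalanced), 288 cue trials per session with
left/right cues balanced and one third catch trials, 32 channels at
1000 Hz, cue-locked lateralization over the posterior pairs P7/P8, P3/P4
and CP5/CP6 with the control condition's LI dipping in the middle third of
the cue-target interval while the stress condition sustains it, and a
salivary cortisol response peaking at the 20-min post-stressor sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .cortisol import DEFAULT_SAMPLE_TIMES, CortisolSeries
from .lateralization import DEFAULT_PAIRS, hemisphere, smooth_time, lateralization_index
from .preprocess import ContinuousRecording

__all__ = [
    "DEFAULT_CHANNELS",
    "StudyConfig",
    "GroundTruth",
    "StudyResult",
    "TrialParams",
    "StudySession",
    "generate_trial_signal",
    "generate_cortisol_profile",
    "generate_study",
    "iter_sessions",
    "study_ground_truth",
    "stress_response_area_factor",
    "PowerStudyConfig",
    "TrialPowerStudy",
    "simulate_trial_power",
    "coupling_slope_for_r",
]

#: 32-channel 10-20 montage including the three analysis pairs.
DEFAULT_CHANNELS = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "CP5", "CP1", "CP2", "CP6", "P7", "P3", "Pz", "P4", "P8",
    "PO7", "PO3", "PO4", "PO8", "O1", "Oz", "O2",
)

#: Fraction of the subject's peak response at each cortisol sample time in
#: the stress condition: flat at baseline through 0 min, rising by 15 min,
#: peaking at 20 min, decaying through 65 min.
STRESS_RESPONSE_FRACTIONS = (0.0, 0.0, 0.6, 1.0, 0.7, 0.35, 0.1)


@dataclass
class StudyConfig:
    """Configuration of a synthetic study (EEG + cortisol).

    LI amplitudes are the target lateralization-index depth; the piecewise
    profiles are multiplicative gains on the three thirds of the
    cue-target interval. Cortisol units are nmol/L; the coupling slope is
    in LI units per (nmol/L * min) of dAUCi.
    """

    n_subjects: int = 20
    n_trials_per_session: int = 288
    catch_fraction: float = 1.0 / 3.0
    fs_acquisition: float = 1000.0
    channels: tuple = DEFAULT_CHANNELS
    epoch_window: tuple = (-1500.0, 4000.0)
    cue_onset: float = 0.0
    target_onset: float = 2610.0
    alpha_freq_mean: float = 10.0
    alpha_freq_sd: float = 0.8
    alpha_amplitude: float = 8.0
    noise_amplitude: float = 6.0
    noise_exponent: float = 1.0
    li_amplitude_control: float = 0.12
    li_amplitude_stress: float = 0.12
    li_profile_control: tuple = (1.0, 0.25, 1.0)
    li_profile_stress: tuple = (1.0, 1.0, 1.0)
    coupling_window: tuple = (870.0, 1535.0)
    coupling_slope: float = 0.0
    coupling_noise_sd: float = 0.05
    cortisol_baseline: float = 5.0
    cortisol_peak_delta_mean: float = 8.0
    cortisol_peak_delta_sd: float = 4.0
    cortisol_noise_sd: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not 0.0 < self.catch_fraction < 1.0:
            raise ValueError("catch_fraction must be in (0, 1)")
        if not (self.epoch_window[0] <= -500.0 and self.epoch_window[1] >= 3200.0):
            raise ValueError("epoch window must contain [-500, 3200] ms")
        for name in ("li_amplitude_control", "li_amplitude_stress",
                     "alpha_amplitude", "noise_amplitude", "coupling_slope",
                     "cortisol_baseline", "cortisol_peak_delta_mean"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"non-finite config value: {name}")
        missing = {"P7", "P8", "P3", "P4", "CP5", "CP6"} - set(self.channels)
        if missing:
            raise ValueError(f"analysis channels missing from montage: {missing}")


@dataclass
class GroundTruth:
    """What was injected: recoverable targets for every downstream stage."""

    subjects: list
    conditions: dict
    alpha_freq: dict
    delta_auci_true: dict
    window_boost: dict
    li_amplitude: dict
    coupling_slope: float
    coupling_window: tuple

    def to_json_dict(self) -> dict:
        def keyed(d):
            return {"|".join(map(str, k)) if isinstance(k, tuple) else str(k): v
                    for k, v in d.items()}
        return {
            "subjects": list(self.subjects),
            "conditions": keyed(self.conditions),
            "alpha_freq": keyed(self.alpha_freq),
            "delta_auci_true": keyed(self.delta_auci_true),
            "window_boost": keyed(self.window_boost),
            "li_amplitude": keyed(self.li_amplitude),
            "coupling_slope": self.coupling_slope,
            "coupling_window": list(self.coupling_window),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), indent=2, sort_keys=True)


@dataclass
class StudyResult:
    """A generated study: recordings, cortisol and the ground truth."""

    config: StudyConfig
    recordings: dict
    cortisol: dict
    conditions: dict
    ground_truth: GroundTruth


def _powerlaw_noise(n_channels: int, n_samples: int, exponent: float,
                    fs: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent noise, independent per channel, unit variance."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = freqs[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    white = rng.standard_normal((n_channels, n_samples))
    shaped = np.fft.irfft(np.fft.rfft(white, axis=-1) * scale, n=n_samples, axis=-1)
    sd = shaped.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return shaped / sd


@dataclass
class TrialParams:
    """Everything needed to synthesize one trial slot of EEG.

    ``li_profile`` is the target LI over the slot's samples (0 before cue
    onset, so hemispheric gains revert to symmetric pre-cue);
    ``pair_channels`` maps each lateralized channel label to its
    hemisphere.
    """

    fs: float
    n_samples: int
    cue_sample: int
    cue_side: str
    channels: tuple
    pair_channels: dict
    alpha_freq: float
    alpha_amplitude: float
    noise_amplitude: float
    noise_exponent: float
    li_profile: np.ndarray
    amp_jitter_sd: float = 0.2


def generate_trial_signal(params: TrialParams, rng: np.random.Generator) -> np.ndarray:
    """One trial of multi-channel EEG in uV: 1/f noise + lateralized alpha.

    The alpha component is a sinusoid at the subject's alpha frequency
    whose hemispheric gains are ``g = sqrt(1 -/+ LI(t))`` (minus for the
    hemisphere contralateral to the cue), so that the expected power-based
    LI equals the configured profile. Non-pair channels carry symmetric
    alpha (gain 1).
    """
    if not 2.0 <= params.alpha_freq <= 20.0:
        raise ValueError("alpha frequency must lie within 2-20 Hz")
    if params.cue_side not in ("L", "R"):
        raise ValueError(f"invalid cue side {params.cue_side!r}")
    n_ch = len(params.channels)
    n = params.n_samples
    li = np.asarray(params.li_profile, dtype=float)
    if li.shape != (n,):
        raise ValueError("li_profile must have one value per sample")
    if np.any(np.abs(li) > 1.0):
        raise ValueError("target LI must stay within [-1, 1]")
    out = np.zeros((n_ch, n))
    if params.noise_amplitude > 0:
        out += params.noise_amplitude * _powerlaw_noise(
            n_ch, n, params.noise_exponent, params.fs, rng
        )
    t = np.arange(n) / params.fs
    # independent phase per channel: posterior alpha is not globally
    # phase-coherent, and a coherent carrier would be removed by the
    # common average reference
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_ch)
    amp = params.alpha_amplitude * float(
        np.exp(rng.normal(0.0, params.amp_jitter_sd))
    )
    contra_hemi = "R" if params.cue_side == "L" else "L"
    g_contra = np.sqrt(1.0 - li)
    g_ipsi = np.sqrt(1.0 + li)
    for ci, name in enumerate(params.channels):
        carrier = amp * np.sin(2.0 * np.pi * params.alpha_freq * t + phases[ci])
        hemi = params.pair_channels.get(name)
        if hemi is None:
            out[ci] += carrier
        elif hemi == contra_hemi:
            out[ci] += g_contra * carrier
        else:
            out[ci] += g_ipsi * carrier
    return out


def generate_cortisol_profile(
    condition: str,
    responder_delta: float,
    rng: np.random.Generator,
    baseline: float = 5.0,
    noise_sd: float = 0.5,
    times: tuple = DEFAULT_SAMPLE_TIMES,
) -> CortisolSeries:
    """One session's cortisol profile.

    Control sessions are flat at baseline (plus assay noise); stress
    sessions rise from the 15-min sample to a peak of baseline +
    ``responder_delta`` at 20 min and decay through 65 min.
    """
    if condition not in ("stress", "control"):
        raise ValueError(f"unknown condition {condition!r}")
    if not responder_delta >= 0:
        raise ValueError("responder_delta must be >= 0")
    frac = np.array(STRESS_RESPONSE_FRACTIONS if condition == "stress"
                    else np.zeros(len(times)))
    conc = baseline + responder_delta * frac
    if noise_sd > 0:
        conc = conc + rng.normal(0.0, noise_sd, size=len(times))
    return CortisolSeries(np.asarray(times, dtype=float), np.clip(conc, 0.0, None))


def stress_response_area_factor(times: tuple = DEFAULT_SAMPLE_TIMES) -> float:
    """AUCi of the noiseless stress profile per unit of peak delta."""
    return float(np.trapezoid(np.array(STRESS_RESPONSE_FRACTIONS),
                              np.asarray(times, dtype=float)))


def _piecewise_profile(t_ms: np.ndarray, gains: tuple, interval: tuple) -> np.ndarray:
    """Gain per time point: thirds of the cue-target interval, 0 outside."""
    lo, hi = interval
    third = (hi - lo) / 3.0
    out = np.zeros_like(t_ms, dtype=float)
    inside = (t_ms >= lo) & (t_ms < hi)
    idx = np.minimum(((t_ms[inside] - lo) // third).astype(int), 2)
    out[inside] = np.asarray(gains, dtype=float)[idx]
    return out


def _subject_ids(n: int) -> list:
    return [f"S{i + 1:02d}" for i in range(n)]


@dataclass
class _SubjectTraits:
    subject: str
    seed_cortisol: object
    seeds_session: list
    alpha_freq: float
    delta: float
    dauc_true: float
    boost: float
    order: tuple


def _subject_traits(config: StudyConfig) -> list:
    """Draw per-subject latent traits. Deterministic given config.seed."""
    root = np.random.SeedSequence(config.seed)
    area = stress_response_area_factor()
    traits = []
    for si, (subj, sseed) in enumerate(
        zip(_subject_ids(config.n_subjects), root.spawn(config.n_subjects))
    ):
        trait_seed, cort_seed, *sess_seeds = sseed.spawn(4)
        trait_rng = np.random.default_rng(trait_seed)
        alpha_freq = float(np.clip(
            trait_rng.normal(config.alpha_freq_mean, config.alpha_freq_sd),
            8.0, 12.0,
        ))
        delta = float(np.clip(
            trait_rng.normal(config.cortisol_peak_delta_mean,
                             config.cortisol_peak_delta_sd),
            0.0, None,
        ))
        dauc_true = delta * area
        boost = float(config.coupling_slope * dauc_true
                      + trait_rng.normal(0.0, config.coupling_noise_sd))
        order = ("stress", "control") if si % 2 == 0 else ("control", "stress")
        traits.append(_SubjectTraits(
            subject=subj, seed_cortisol=cort_seed, seeds_session=sess_seeds,
            alpha_freq=alpha_freq, delta=delta, dauc_true=dauc_true,
            boost=boost, order=order,
        ))
    return traits


def study_ground_truth(config: StudyConfig) -> GroundTruth:
    """The ground-truth record of a study, without synthesizing any EEG."""
    config.validate()
    traits = _subject_traits(config)
    return GroundTruth(
        subjects=[t.subject for t in traits],
        conditions={(t.subject, sess): cond
                    for t in traits for sess, cond in zip((1, 2), t.order)},
        alpha_freq={t.subject: t.alpha_freq for t in traits},
        delta_auci_true={t.subject: t.dauc_true for t in traits},
        window_boost={t.subject: t.boost for t in traits},
        li_amplitude={(t.subject, cond): float(
            config.li_amplitude_stress if cond == "stress"
            else config.li_amplitude_control)
            for t in traits for cond in ("stress", "control")},
        coupling_slope=config.coupling_slope,
        coupling_window=tuple(config.coupling_window),
    )


@dataclass
class StudySession:
    """One subject-session of a generated study."""

    subject: str
    session: int
    condition: str
    recording: ContinuousRecording
    cortisol: CortisolSeries


def iter_sessions(config: StudyConfig):
    """Yield the study's sessions one at a time (memory-friendly).

    Each subject contributes two sessions (stress/control, order
    counterbalanced across subjects). Trials are laid out in fixed slots
    with the cue 1.8 s into each slot; cue sides are balanced and shuffled,
    one third of trials are tagged as catch trials (same cue-locked
    structure). The stress condition's LI gains an additive boost inside
    the coupling window equal to coupling_slope * dAUCi + noise, tying the
    endocrine and electrophysiological effects together.
    """
    config.validate()
    pair_channels = {}
    for pair in DEFAULT_PAIRS:
        for lab in pair:
            pair_channels[lab] = hemisphere(lab)

    slot_s = 6.4
    cue_in_slot_s = 1.8
    pad_s = 1.0
    fs = config.fs_acquisition
    slot_n = int(round(slot_s * fs))
    pad_n = int(round(pad_s * fs))
    n_trials = config.n_trials_per_session
    rec_n = 2 * pad_n + n_trials * slot_n
    t_slot_ms = (np.arange(slot_n) / fs - cue_in_slot_s) * 1000.0

    for t in _subject_traits(config):
        cort_rng = np.random.default_rng(t.seed_cortisol)
        for session, cond, sess_seed in zip((1, 2), t.order, t.seeds_session):
            srng = np.random.default_rng(sess_seed)
            amp = (config.li_amplitude_stress if cond == "stress"
                   else config.li_amplitude_control)
            gains = (config.li_profile_stress if cond == "stress"
                     else config.li_profile_control)
            li_t = amp * _piecewise_profile(
                t_slot_ms, gains, (config.cue_onset, config.target_onset)
            )
            if cond == "stress":
                in_win = ((t_slot_ms >= config.coupling_window[0])
                          & (t_slot_ms <= config.coupling_window[1]))
                li_t = li_t + t.boost * in_win
            li_t = np.clip(li_t, -0.95, 0.95)

            sides = np.array(["L", "R"])[
                srng.permutation(np.arange(n_trials) % 2)
            ]
            n_catch = int(round(config.catch_fraction * n_trials))
            catch = np.zeros(n_trials, dtype=bool)
            catch[srng.permutation(n_trials)[:n_catch]] = True

            data = np.zeros((len(config.channels), rec_n))
            if config.noise_amplitude > 0:
                data[:, :pad_n] = config.noise_amplitude * _powerlaw_noise(
                    len(config.channels), pad_n, config.noise_exponent, fs, srng
                )
                data[:, rec_n - pad_n:] = config.noise_amplitude * _powerlaw_noise(
                    len(config.channels), pad_n, config.noise_exponent, fs, srng
                )
            events = []
            for k in range(n_trials):
                start = pad_n + k * slot_n
                params = TrialParams(
                    fs=fs, n_samples=slot_n,
                    cue_sample=int(round(cue_in_slot_s * fs)),
                    cue_side=str(sides[k]),
                    channels=tuple(config.channels),
                    pair_channels=pair_channels,
                    alpha_freq=t.alpha_freq,
                    alpha_amplitude=config.alpha_amplitude,
                    noise_amplitude=config.noise_amplitude,
                    noise_exponent=config.noise_exponent,
                    li_profile=li_t,
                )
                data[:, start:start + slot_n] = generate_trial_signal(params, srng)
                cue_samp = start + params.cue_sample
                events.append((cue_samp, "cueL" if sides[k] == "L" else "cueR"))
            rec = ContinuousRecording(
                data=data, fs=fs, ch_names=list(config.channels), events=events,
                info={"subject": t.subject, "session": session,
                      "condition": cond, "catch": catch.tolist()},
            )
            series = generate_cortisol_profile(
                cond, t.delta if cond == "stress" else 0.0, cort_rng,
                baseline=config.cortisol_baseline,
                noise_sd=config.cortisol_noise_sd,
            )
            yield StudySession(subject=t.subject, session=session,
                               condition=cond, recording=rec, cortisol=series)


def generate_study(config: StudyConfig) -> StudyResult:
    """Generate a full synthetic study and hold it in memory.

    Convenience wrapper around :func:`iter_sessions`; for default-sized
    studies (20 subjects x 2 sessions of 32-channel EEG at 1000 Hz) prefer
    iterating sessions and processing them one at a time.
    """
    recordings, cortisol, conditions = {}, {}, {}
    for sess in iter_sessions(config):
        key = (sess.subject, sess.session)
        recordings[key] = sess.recording
        cortisol[key] = sess.cortisol
        conditions[key] = sess.condition
    return StudyResult(config=config, recordings=recordings, cortisol=cortisol,
                       conditions=conditions,
                       ground_truth=study_ground_truth(config))


# ---------------------------------------------------------------------------
# Trial-power-level generator (calibration fast path)
# ---------------------------------------------------------------------------

@dataclass
class PowerStudyConfig:
    """Configuration for studies drawn at the trial-power level.

    The latent structure matches :class:`StudyConfig` (condition-dependent
    LI profiles in the alpha band over the cue-target interval, subject
    heterogeneity, cortisol coupling), but trials are drawn directly as
    contralateral/ipsilateral time-frequency power:

        pow_{contra,ipsi} = base_power * (1 -/+ L(f, t)) * exp(sd * z)

    with independent lognormal trial noise per side, so the expected LI of
    trial-averaged power equals L. The grid defaults to 15 frequencies x
    150 frames over the pruned analysis extent.
    """

    n_subjects: int = 20
    n_trials: int = 216
    n_pairs: int = 1
    n_freqs: int = 15
    n_times: int = 150
    f_range: tuple = (2.0, 20.0)
    t_range: tuple = (-500.0, 3200.0)
    base_power: float = 1.0
    trial_noise_sd: float = 1.0
    subject_sd: float = 0.05
    li_amplitude_control: float = 0.12
    li_amplitude_stress: float = 0.12
    li_profile_control: tuple = (1.0, 0.25, 1.0)
    li_profile_stress: tuple = (1.0, 1.0, 1.0)
    band: tuple = (8.0, 14.0)
    cue_interval: tuple = (0.0, 2610.0)
    window: tuple = (870.0, 1535.0)
    window_boost_stress: float = 0.0
    coupling_slope: float = 0.0
    delta_auci_mean: float = 260.0
    delta_auci_sd: float = 130.0
    coupling_noise_sd: float = 0.08
    seed: int = 0

    @property
    def freqs(self) -> np.ndarray:
        return np.linspace(*self.f_range, self.n_freqs)

    @property
    def times(self) -> np.ndarray:
        return np.linspace(*self.t_range, self.n_times)


@dataclass
class TrialPowerStudy:
    """A study at the trial-power level, conditions ('stress', 'control').

    ``pow_contra``/``pow_ipsi`` have shape
    (n_subjects, 2, n_trials, n_pairs, n_freqs, n_times).
    """

    pow_contra: np.ndarray
    pow_ipsi: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    conditions: tuple
    delta_auci: np.ndarray
    config: PowerStudyConfig
    truth: dict = field(default_factory=dict)

    def smooth_frames(self, smooth_ms: float = 250.0) -> int:
        """Moving-average width in frames equivalent to ``smooth_ms``."""
        dt = float(self.times[1] - self.times[0])
        return max(1, int(round(smooth_ms / dt)))

    def subject_li_maps(self, smooth_ms: float | None = 250.0) -> dict:
        """Smoothed subject LI maps per condition, shape (n_subj, nf, nt).

        The temporal smoothing width is given in ms (250 ms matches the
        50-frame window of the 200 Hz analysis grid) and converted to this
        grid's frame spacing.
        """
        mean_c = self.pow_contra.mean(axis=2, dtype=np.float64)
        mean_i = self.pow_ipsi.mean(axis=2, dtype=np.float64)
        li = lateralization_index(mean_c, mean_i).mean(axis=2)  # pair average
        if smooth_ms:
            li = smooth_time(li, self.smooth_frames(smooth_ms))
        return {cond: li[:, k] for k, cond in enumerate(self.conditions)}

    def delta_li_maps(self, smooth_ms: float | None = 250.0) -> np.ndarray:
        maps = self.subject_li_maps(smooth_ms)
        return maps["stress"] - maps["control"]

    def pair_li_maps(self, smooth_ms: float | None = 250.0) -> np.ndarray:
        """Per-pair smoothed LI maps, (n_subj, 2, n_pairs, nf, nt)."""
        mean_c = self.pow_contra.mean(axis=2, dtype=np.float64)
        mean_i = self.pow_ipsi.mean(axis=2, dtype=np.float64)
        li = lateralization_index(mean_c, mean_i)
        if smooth_ms:
            li = smooth_time(li, self.smooth_frames(smooth_ms))
        return li

    def trial_arrays(self, condition: str | None = None) -> tuple[list, list]:
        """Per-subject trial-level (contra, ipsi) lists for the cue test.

        With ``condition=None`` trials are pooled across both sessions
        (the cue-lateralization test is run irrespective of condition).
        """
        pc_list, pi_list = [], []
        for s in range(self.pow_contra.shape[0]):
            if condition is None:
                pc = self.pow_contra[s].reshape(-1, *self.pow_contra.shape[3:])
                pi = self.pow_ipsi[s].reshape(-1, *self.pow_ipsi.shape[3:])
            else:
                k = self.conditions.index(condition)
                pc, pi = self.pow_contra[s, k], self.pow_ipsi[s, k]
            pc_list.append(pc)
            pi_list.append(pi)
        return pc_list, pi_list


def coupling_slope_for_r(cfg: PowerStudyConfig, r: float) -> float:
    """Coupling slope giving a latent in-window dLI ~ dAUCi correlation r.

    Accounts for the between-subject LI variance contributed by the
    condition amplitudes and the coupling noise; finite-trial estimation
    noise (small after smoothing) is neglected, so the realized correlation
    sits marginally below r.
    """
    if not 0 < r < 1:
        raise ValueError("target correlation must be in (0, 1)")
    p_s = np.asarray(cfg.li_profile_stress, dtype=float)[1]
    p_c = np.asarray(cfg.li_profile_control, dtype=float)[1]
    noise_var = cfg.subject_sd**2 * (p_s**2 + p_c**2) + cfg.coupling_noise_sd**2
    return float(np.sqrt(noise_var) * r / np.sqrt(1.0 - r**2) / cfg.delta_auci_sd)


def simulate_trial_power(cfg: PowerStudyConfig) -> TrialPowerStudy:
    """Draw one study at the trial-power level. Deterministic given seed."""
    if cfg.n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    freqs, times = cfg.freqs, cfg.times
    nf, nt = cfg.n_freqs, cfg.n_times
    band_mask = ((freqs >= cfg.band[0]) & (freqs <= cfg.band[1]))[:, None]
    win_mask = band_mask & (
        (times >= cfg.window[0]) & (times <= cfg.window[1])
    )[None, :]
    prof_c = _piecewise_profile(times, cfg.li_profile_control, cfg.cue_interval)
    prof_s = _piecewise_profile(times, cfg.li_profile_stress, cfg.cue_interval)
    conditions = ("stress", "control")
    shape = (cfg.n_subjects, 2, cfg.n_trials, cfg.n_pairs, nf, nt)
    pow_c = np.empty(shape, dtype=np.float32)
    pow_i = np.empty(shape, dtype=np.float32)
    delta_auci = cfg.delta_auci_mean + cfg.delta_auci_sd * rng.standard_normal(
        cfg.n_subjects
    )
    truth_L = np.zeros((cfg.n_subjects, 2, nf, nt))
    for s in range(cfg.n_subjects):
        amp_s = cfg.li_amplitude_stress + rng.normal(0.0, cfg.subject_sd)
        amp_c = cfg.li_amplitude_control + rng.normal(0.0, cfg.subject_sd)
        boost = (cfg.window_boost_stress
                 + cfg.coupling_slope * delta_auci[s]
                 + rng.normal(0.0, cfg.coupling_noise_sd))
        for k, cond in enumerate(conditions):
            if cond == "stress":
                L = amp_s * prof_s[None, :] * band_mask
                L = L + boost * win_mask
            else:
                L = amp_c * prof_c[None, :] * band_mask
            L = np.clip(L, -0.95, 0.95)
            truth_L[s, k] = L
            base_c = (cfg.base_power * (1.0 - L)).astype(np.float32)
            base_i = (cfg.base_power * (1.0 + L)).astype(np.float32)
            trial_shape = (cfg.n_trials, cfg.n_pairs, nf, nt)
            zc = rng.standard_normal(trial_shape, dtype=np.float32)
            zi = rng.standard_normal(trial_shape, dtype=np.float32)
            sd = np.float32(cfg.trial_noise_sd)
            pow_c[s, k] = base_c[None, None] * np.exp(sd * zc)
            pow_i[s, k] = base_i[None, None] * np.exp(sd * zi)
    return TrialPowerStudy(
        pow_contra=pow_c, pow_ipsi=pow_i, freqs=freqs, times=times,
        conditions=conditions, delta_auci=delta_auci, config=cfg,
        truth={"target_li": truth_L, "delta_auci": delta_auci.copy()},
    )
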