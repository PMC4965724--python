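"""Synthetic sEMG + accelerometer recordings following the collection protocol.

The generator reproduces the statistical structure the downstream classifiers
rely on, not motor-unit physiology:

* Each activity class has a per-channel activation amplitude (mV scale).
  Within an action group the movement classes share the base grip's
  activation (the grip is held while raising/turning/lowering) plus
  movement-specific additions on semantically chosen channels (raising loads
  the biceps/brachioradialis, pronation the pronator quadratus, ...), so
  classes within a group overlap the way real recordings do.
* The EMG of a channel is a class-conditional envelope multiplied by a
  sign-alternating carrier (+1/-1 at the sample rate) plus white noise.  The
  absolute value of the noise-free signal equals the envelope, so the MAV of
  a plateau recovers the activation amplitude in closed form.
* Raises ramp the envelope up, lowers ramp it down; other activities hold a
  plateau.  Envelopes are smoothed with a raised-cosine kernel (rise/fall
  time), modulated by a slow log-normal AR(1) process (contraction-strength
  fluctuation) and by a per-repetition gain (between-repetition variability).
* The six hand-ACC channels carry a 300 ms raised-cosine transient at every
  movement onset; grips get a half-amplitude transient that *ends* at the
  grip onset (the reach toward the object), matching how the labelling stage
  uses ACC evidence.
* Activity onsets are jittered by up to a few hundred milliseconds, as in the
  study, and the ground-truth track records the jittered times.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as sio
from .protocol import (
    ACTIVITIES,
    CLASS_CODES,
    CLASS_INDEX,
    GROUPS,
    GROUP_GRIP,
    NR,
    ProtocolSchedule,
    make_schedule,
)

__all__ = [
    "SubjectProfile",
    "RawRun",
    "build_amplitudes",
    "default_profiles",
    "well_separated_profile",
    "quiet_profile",
    "generate_run",
    "generate_dataset",
    "load_profile",
    "save_profile",
]

EMG_RATE = sio.EMG_RATE
ACC_RATE = sio.ACC_RATE
RUN_DURATION = 120.0
N_ACC_CHANNELS = 6

# channel indices by muscle (see io.EMG_SENSORS)
_ED, _EI, _FCR, _FDS, _FCU, _PQ, _BRA, _BIC = range(8)

#: movement-specific channel additions: code kind -> [(channel, lo, hi)]
_MOVEMENT_KIND = {
    "HR": "raise", "TPR": "raise", "3JCR": "raise",
    "HL": "lower", "TPL": "lower", "3JCL": "lower",
    "KTS": "sup", "DKS": "sup", "JLS": "sup",
    "KTP": "pro", "DKP": "pro", "JLP": "pro",
    "BSQ": "squeeze", "SCO": "open", "SCC": "close", "HGR": "hold",
}

_KIND_DELTAS = {
    # raising and lowering engage the same muscles (concentric vs eccentric);
    # their envelopes differ in direction, not in which channels light up
    "raise": [(_BIC, 0.5, 0.9), (_BRA, 0.2, 0.5)],
    "lower": [(_BIC, 0.5, 0.9), (_BRA, 0.2, 0.5)],
    "sup": [(_BRA, 0.3, 0.6), (_BIC, 0.2, 0.4)],
    "pro": [(_PQ, 0.4, 0.8), (_FCR, 0.1, 0.3)],
    "squeeze": [(_FDS, 0.3, 0.6), (_FCR, 0.2, 0.4)],
    "open": [(_ED, 0.3, 0.6), (_EI, 0.2, 0.5)],
    "close": [(_FDS, 0.3, 0.6), (_EI, 0.1, 0.2)],
    "hold": [(_BIC, 0.3, 0.5)],
}

#: envelope shape within an interval: raises ramp up, lowers ramp down
_RAMP_UP = {"HR", "TPR", "3JCR"}
_RAMP_DOWN = {"HL", "TPL", "3JCL"}


@dataclass
class SubjectProfile:
    """Per-subject generator parameters (a synthetic 'subject')."""

    name: str
    amplitudes: np.ndarray  # (25, 8) mV, rows in CLASS_CODES order
    rise_time_s: float = 0.15
    emg_noise_std: float = 0.03  # mV
    mod_sigma: float = 0.22  # log-normal per-channel amplitude scatter
    mod_common_sigma: float = 0.20  # log-normal common-drive scatter (all channels)
    mod_tau_s: float = 0.05
    rep_gain_sigma: float = 0.05  # log-normal per-repetition gain
    artifact_rate: float = 0.03  # per-instance, per-channel spike probability
    artifact_scale: float = 2.0  # spike amplitude multiplier scale
    burst_rate: float = 0.08  # per-instance probability of a common-mode burst
    acc_transient_g: float = 1.0
    acc_noise_std_g: float = 0.02
    jitter_s: float = 0.25  # onset timing jitter bound
    hybrid_as_activity: bool = True  # how hybrid protocol slots are performed
    reach_time_s: float = 0.10  # generic motion-onset transient duration

    @property
    def reach_vector(self) -> np.ndarray:
        """Shared reach/settling activation at the start of every activity.

        All activities begin with the hand moving toward or settling on the
        object, a motion whose muscle pattern is largely class-agnostic; its
        level is tied to the subject's overall activation scale.
        """
        non_nr = np.delete(self.amplitudes, CLASS_INDEX[NR], axis=0)
        return 0.8 * non_nr.mean(axis=0)

    def __post_init__(self) -> None:
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if self.amplitudes.shape != (25, 8):
            raise ValueError(f"amplitudes must be (25, 8), got {self.amplitudes.shape}")
        if np.any(self.amplitudes < 0):
            raise ValueError("activation amplitudes must be non-negative")
        if not 0 <= self.jitter_s <= 0.5:
            raise ValueError("timing jitter bound must be within 0..0.5 s")
        for v in (self.emg_noise_std, self.mod_sigma, self.rep_gain_sigma,
                  self.acc_transient_g, self.acc_noise_std_g, self.rise_time_s):
            if v < 0:
                raise ValueError("profile parameters must be non-negative")
        # distinct classes within a group must have distinct activation vectors
        by_group: dict[str, list[str]] = {}
        for group, code, _ in ACTIVITIES:
            by_group.setdefault(group, []).append(code)
        for group, codes in by_group.items():
            for i, a in enumerate(codes):
                for b in codes[i + 1:]:
                    if np.array_equal(self.amplitudes[CLASS_INDEX[a]], self.amplitudes[CLASS_INDEX[b]]):
                        raise ValueError(
                            f"classes {a} and {b} in group {group!r} have identical activation vectors"
                        )

    def amplitude(self, code: str) -> np.ndarray:
        return self.amplitudes[CLASS_INDEX[code]]


@dataclass
class RawRun:
    """One simulated two-minute collection run with ground truth."""

    group_id: str
    emg: np.ndarray  # (8, 240000) mV
    acc: np.ndarray  # (6, 17772) g
    truth: list[tuple[str, float, float]]  # (code, onset_s, offset_s), tiles [0, 120]
    seed: int
    emg_rate: float = EMG_RATE
    acc_rate: float = ACC_RATE

    def as_bundle(self) -> sio.RunBundle:
        emg = [
            sio.ChannelSeries(f"{num}:{code}", "EMG", self.emg_rate, self.emg[j])
            for j, (num, _, code) in enumerate(sio.EMG_SENSORS)
        ]
        acc = []
        k = 0
        for num, _, code in sio.ACC_SENSORS:
            for axis in sio.ACC_AXES:
                acc.append(sio.ChannelSeries(f"{num}:{code}:{axis}", "ACC", self.acc_rate, self.acc[k]))
                k += 1
        return sio.RunBundle(emg=emg, acc=acc, group_id=self.group_id, truth=list(self.truth))


def build_amplitudes(rng: np.random.Generator, separation: float = 1.0) -> np.ndarray:
    """Draw a (25, 8) class-by-channel activation matrix.

    ``separation`` scales the movement-specific additions: 1.0 gives the
    default overlap between a group's classes; larger values pull the classes
    apart (used for well-separated profiles).
    """
    amps = np.zeros((25, 8))
    amps[CLASS_INDEX[NR]] = rng.uniform(0.02, 0.06, size=8)
    for group in GROUPS:
        base = rng.uniform(0.04, 0.10, size=8)
        for ch in (_ED, _FDS, _FCU):
            base[ch] = rng.uniform(0.4, 0.9)
        grip = GROUP_GRIP[group]
        codes = [c for g, c, _ in ACTIVITIES if g == group]
        # raise/lower pairs in a group share one delta draw: the same muscles
        # produce both, so only the envelope direction separates them
        pair_deltas: dict[str, np.ndarray] = {}
        for code in codes:
            a = base.copy()
            if code != grip:
                kind = _MOVEMENT_KIND[code]
                if kind in ("raise", "lower"):
                    if "raise_lower" not in pair_deltas:
                        d = np.zeros(8)
                        for ch, lo, hi in _KIND_DELTAS[kind]:
                            d[ch] = separation * rng.uniform(lo, hi)
                        pair_deltas["raise_lower"] = d
                    a += pair_deltas["raise_lower"]
                else:
                    for ch, lo, hi in _KIND_DELTAS[kind]:
                        a[ch] += separation * rng.uniform(lo, hi)
            # small idiosyncratic spread so every class vector is distinct
            a += rng.uniform(0.0, 0.05, size=8)
            amps[CLASS_INDEX[code]] = a
    return amps


def default_profiles() -> list[SubjectProfile]:
    """Three default synthetic subjects (mirrors the 3-subject reporting)."""
    specs = [
        ("subject1", 101, 0.20, 0.22, 0.05, 0.03),
        ("subject2", 202, 0.22, 0.25, 0.06, 0.04),
        ("subject3", 303, 0.24, 0.20, 0.05, 0.035),
    ]
    out = []
    for name, seed, common, chan, rep_sigma, noise in specs:
        rng = np.random.default_rng(seed)
        out.append(
            SubjectProfile(
                name=name,
                amplitudes=build_amplitudes(rng),
                mod_common_sigma=common,
                mod_sigma=chan,
                rep_gain_sigma=rep_sigma,
                emg_noise_std=noise,
            )
        )
    return out


def well_separated_profile(seed: int = 7) -> SubjectProfile:
    """A low-noise subject whose classes are well separated in MAV space."""
    rng = np.random.default_rng(seed)
    return SubjectProfile(
        name="well_separated",
        amplitudes=build_amplitudes(rng, separation=1.8),
        emg_noise_std=0.01,
        mod_sigma=0.04,
        mod_common_sigma=0.05,
        rep_gain_sigma=0.02,
        artifact_rate=0.0,
        jitter_s=0.1,
        reach_time_s=0.1,
    )


def quiet_profile(seed: int = 11) -> SubjectProfile:
    """Noise-free, jitter-free subject for closed-form checks."""
    rng = np.random.default_rng(seed)
    return SubjectProfile(
        name="quiet",
        amplitudes=build_amplitudes(rng),
        emg_noise_std=0.0,
        mod_sigma=0.0,
        mod_common_sigma=0.0,
        rep_gain_sigma=0.0,
        artifact_rate=0.0,
        acc_noise_std_g=0.0,
        jitter_s=0.0,
    )


def _jittered_truth(
    schedule: ProtocolSchedule, profile: SubjectProfile, rng: np.random.Generator
) -> list[tuple[str, float, float]]:
    nominal = schedule.nominal_intervals(profile.hybrid_as_activity)
    starts = [iv[1] for iv in nominal]
    j = profile.jitter_s
    if j > 0:
        for i in range(1, len(nominal)):
            if nominal[i][0] != NR:  # only activity onsets jitter
                starts[i] = nominal[i][1] + rng.uniform(-j, j)
    # keep boundaries ordered and inside the run
    starts[0] = 0.0
    for i in range(1, len(starts)):
        starts[i] = min(max(starts[i], starts[i - 1] + 1e-6), schedule.run_duration)
    out = []
    for i, (code, _, _) in enumerate(nominal):
        end = starts[i + 1] if i + 1 < len(nominal) else schedule.run_duration
        if end > starts[i]:
            out.append((code, starts[i], end))
    return out


def _ar1_lognormal(
    rng: np.random.Generator, n_coarse: int, sigma: float, rho: float
) -> np.ndarray:
    """Mean-one log-normal AR(1) series (coarse grid)."""
    z = np.empty(n_coarse)
    z[0] = rng.standard_normal()
    eps = rng.standard_normal(n_coarse - 1)
    for i in range(1, n_coarse):
        z[i] = rho * z[i - 1] + np.sqrt(1 - rho**2) * eps[i - 1]
    return np.exp(sigma * z - sigma**2 / 2)


def generate_run(
    schedule: ProtocolSchedule, profile: SubjectProfile, seed: int
) -> RawRun:
    """Simulate one two-minute run of the given action group."""
    rng = np.random.default_rng(seed)
    truth = _jittered_truth(schedule, profile, rng)
    dur = schedule.run_duration

    n_emg = int(np.floor(dur * EMG_RATE))
    n_acc = int(np.floor(dur * ACC_RATE))

    # --- class-conditional envelope, per channel -------------------------
    level = np.zeros((8, n_emg))
    rep_gain = np.exp(
        profile.rep_gain_sigma * rng.standard_normal((schedule.rep_count + 1, 8))
        - profile.rep_gain_sigma**2 / 2
    )
    if profile.rep_gain_sigma == 0:
        rep_gain[:] = 1.0
    for code, t0, t1 in truth:
        s0, s1 = int(round(t0 * EMG_RATE)), int(round(t1 * EMG_RATE))
        if s1 <= s0:
            continue
        amp = profile.amplitude(code).copy()
        if code != NR:
            amp = amp * rep_gain[schedule.rep_index_at(t0)]
        shape = np.ones(s1 - s0)
        if code in _RAMP_UP:
            shape = np.linspace(0.6, 1.3, s1 - s0)
        elif code in _RAMP_DOWN:
            shape = np.linspace(1.3, 0.6, s1 - s0)
        env = amp[:, None] * shape[None, :]
        if code != NR and profile.reach_time_s > 0:
            # class-agnostic reach/settling transient fading into the
            # class-specific activation
            n_tr = min(int(round(profile.reach_time_s * EMG_RATE)), (s1 - s0) // 2)
            if n_tr > 0:
                beta = np.linspace(1.0, 0.0, n_tr)
                env[:, :n_tr] = (
                    beta[None, :] * profile.reach_vector[:, None]
                    + (1.0 - beta[None, :]) * env[:, :n_tr]
                )
        level[:, s0:s1] = env

    # raised-cosine smoothing of transitions (rise/fall time)
    klen = int(round(profile.rise_time_s * EMG_RATE))
    if klen >= 3:
        kernel = np.hanning(klen)
        kernel /= kernel.sum()
        pad = np.pad(level, ((0, 0), (klen // 2, klen - klen // 2 - 1)), mode="edge")
        from scipy.signal import fftconvolve

        level = fftconvolve(pad, kernel[None, :], mode="valid")

    # contraction-strength fluctuation at the MAV-window scale: a common-drive
    # component shared by all channels plus smaller per-channel scatter
    if profile.mod_sigma > 0 or profile.mod_common_sigma > 0:
        n_coarse = int(dur / 0.05) + 2
        rho = float(np.exp(-0.05 / profile.mod_tau_s))
        t_coarse = 0.05 * np.arange(n_coarse)
        t_fine = np.arange(n_emg) / EMG_RATE
        if profile.mod_common_sigma > 0:
            common = _ar1_lognormal(rng, n_coarse, profile.mod_common_sigma, rho)
            level *= np.interp(t_fine, t_coarse, common)[None, :]
        if profile.mod_sigma > 0:
            for j in range(8):
                mod = _ar1_lognormal(rng, n_coarse, profile.mod_sigma, rho)
                level[j] *= np.interp(t_fine, t_coarse, mod)

    # sporadic motion/contact artifacts: isolated instances on isolated
    # channels get a large multiplicative spike
    if profile.artifact_rate > 0 or profile.burst_rate > 0:
        block = int(round(0.05 * EMG_RATE))  # one MAV step
        n_blocks = n_emg // block + 1
        gains = np.ones((8, n_blocks))
        if profile.artifact_rate > 0 and profile.artifact_scale > 0:
            spikes = rng.random((8, n_blocks)) < profile.artifact_rate
            gains += profile.artifact_scale * np.abs(rng.standard_normal((8, n_blocks))) * spikes
        if profile.burst_rate > 0 and profile.artifact_scale > 0:
            # short whole-arm adjustment bursts hit every channel at once
            bursts = rng.random(n_blocks) < profile.burst_rate
            gains *= 1.0 + profile.artifact_scale * np.abs(rng.standard_normal(n_blocks)) * bursts
        level *= np.repeat(gains, block, axis=1)[:, :n_emg]

    carrier = np.where(np.arange(n_emg) % 2 == 0, 1.0, -1.0)
    emg = level * carrier[None, :]
    if profile.emg_noise_std > 0:
        emg = emg + rng.normal(0.0, profile.emg_noise_std, size=emg.shape)

    # --- hand accelerometers --------------------------------------------
    acc = (
        rng.normal(0.0, profile.acc_noise_std_g, size=(N_ACC_CHANNELS, n_acc))
        if profile.acc_noise_std_g > 0
        else np.zeros((N_ACC_CHANNELS, n_acc))
    )
    t_acc = np.arange(n_acc) / ACC_RATE
    grip_code = schedule.grip_code
    for code, t0, t1 in truth:
        if code == NR:
            continue
        if code == grip_code:
            b0, b1, amp = t0 - 0.3, t0, 0.5 * profile.acc_transient_g
        else:
            b0, b1, amp = t0, t0 + 0.3, profile.acc_transient_g
        sel = (t_acc >= b0) & (t_acc < b1)
        if not np.any(sel):
            continue
        u = (t_acc[sel] - b0) / (b1 - b0)
        acc[:, sel] += amp * 0.5 * (1.0 - np.cos(2 * np.pi * u))

    return RawRun(group_id=schedule.group_id, emg=emg, acc=acc, truth=truth, seed=seed)


def generate_dataset(profile: SubjectProfile, seed: int) -> list[RawRun]:
    """One run per action group; per-run seed = master seed + group index."""
    return [
        generate_run(make_schedule(group), profile, seed + gi)
        for gi, group in enumerate(GROUPS)
    ]


# --- profile (de)serialisation ------------------------------------------

def save_profile(profile: SubjectProfile, path) -> Path:
    d = {
        "name": profile.name,
        "amplitudes": profile.amplitudes.tolist(),
        "rise_time_s": profile.rise_time_s,
        "emg_noise_std": profile.emg_noise_std,
        "mod_sigma": profile.mod_sigma,
        "mod_tau_s": profile.mod_tau_s,
        "rep_gain_sigma": profile.rep_gain_sigma,
        "acc_transient_g": profile.acc_transient_g,
        "acc_noise_std_g": profile.acc_noise_std_g,
        "jitter_s": profile.jitter_s,
        "hybrid_as_activity": profile.hybrid_as_activity,
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(d))
    return path


def load_profile(path) -> SubjectProfile:
    d = yaml.safe_load(Path(path).read_text())
    d["amplitudes"] = np.asarray(d["amplitudes"], dtype=float)
    return SubjectProfile(**d)
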