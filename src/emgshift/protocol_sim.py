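"""Synthetic sessions following the arm-translation acquisition protocol.

The emulated experiment records 16-channel surface EMG at 2 kHz plus an
18-sensor data glove while a participant holds one of six grasps (power,
lateral, pointer, tripod, open, rest) for 5 s.  The forearm is placed on a
3x3 grid of orientations P1-P9 (P5 = neutral); day 1 visits the plus-shaped
subset Con+ = {2,4,5,6,8} and day 2 the cross-shaped Conx = {1,3,5,7,9}, two
sessions per day.  Each session runs 5-trial blocks of a fixed
(position, grasp) pair in pseudorandomised block order: 5 positions x 6
grasps x 5 trials = 150 trials.

The signal model is deliberately phenomenological — it reproduces the
*statistical* structure the decoding experiments rely on, not motor-unit
physiology:

    emg_c(t) = (1 + delta * u[p, c]) * A[g, c] * n_c(t)
               + a_pl * sin(2 pi f_pl t + phi_c) + dc_c

with ``n_c`` unit-variance Gaussian noise band-limited to 20-450 Hz,
``A[g, c]`` a grasp-specific per-channel amplitude profile, and
``u[p, c]`` a smooth bump over the 16-electrode ring whose circular shift
depends on the grid position — a stand-in for the apparent muscle
displacement under arm rotation.  ``delta`` (``shift_magnitude``) dials the
position effect: at 0 every position shares one signal distribution per
grasp.

Holding the forearm in different orientations also requires different
*static postural muscle activity*, independent of the grasp being formed.
That is modelled by a second, additive component

    + delta * tone * v[p, c] * m_c(t)

where ``m_c`` is an independent band-limited unit-variance carrier and
``v[p, c]`` a fixed per-position random channel pattern.  Unlike the
multiplicative gain, this component does not pass through the grasp
amplitude profile, which is what makes the arm position linearly decodable
from the features when ``delta`` is large — without it, position
information only ever appears multiplied into grasp amplitudes and a linear
position encoder cannot disentangle the two.  Both components vanish at
``delta = 0``.  Glove channels relax exponentially from a rest posture
toward a grasp-specific target.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .dataset_io import RecordingParameters, TrialRecord, write_session
from .preprocess import FilterSpec, bandpass

GRASP_NAMES: Mapping[int, str] = {
    1: "power", 2: "lateral", 3: "pointer", 4: "tripod", 5: "open", 6: "rest",
}
CON_PLUS: tuple[int, ...] = (2, 4, 5, 6, 8)
CON_X: tuple[int, ...] = (1, 3, 5, 7, 9)
N_CHANNELS = 16
N_GLOVE = 18


@dataclass(frozen=True)
class ProtocolConfig:
    """Trial/block/session arithmetic of the acquisition protocol."""

    sampling_rate: float = 2000.0
    trial_length: float = 5.0
    trials_per_grasp: int = 5
    grasps: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    positions_day1: tuple[int, ...] = CON_PLUS
    positions_day2: tuple[int, ...] = CON_X
    sessions_per_day: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.trial_length <= 0:
            raise ValueError("sampling_rate and trial_length must be positive")
        if self.trials_per_grasp < 1 or self.sessions_per_day < 1:
            raise ValueError("trials_per_grasp and sessions_per_day must be >= 1")
        if len(self.grasps) == 0:
            raise ValueError("grasp set is empty")
        for positions in (self.positions_day1, self.positions_day2):
            if len(positions) == 0:
                raise ValueError("position set is empty")
            if not all(1 <= p <= 9 for p in positions):
                raise ValueError(f"positions must lie in 1-9, got {positions}")

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.sampling_rate * self.trial_length))

    def positions(self, day: int) -> tuple[int, ...]:
        if day == 1:
            return tuple(self.positions_day1)
        if day == 2:
            return tuple(self.positions_day2)
        raise ValueError(f"day must be 1 or 2, got {day}")

    def trials_per_session(self, day: int) -> int:
        return len(self.positions(day)) * len(self.grasps) * self.trials_per_grasp


def position_grid(position: int) -> tuple[int, int]:
    """(row, col) of a grid position, numbered 1-9 from the top-left corner."""
    if not 1 <= position <= 9:
        raise ValueError(f"position {position} outside 1-9")
    return (position - 1) // 3, (position - 1) % 3


def _ring_bump(n_channels: int, width: float) -> np.ndarray:
    ch = np.arange(n_channels)
    dist = np.minimum(ch, n_channels - ch)
    return np.exp(-0.5 * (dist / width) ** 2)


def default_shift_pattern(n_channels: int = N_CHANNELS,
                          width: float = 3.0) -> dict[int, np.ndarray]:
    """Per-position channel-gain vectors u[p] over the electrode ring.

    A fixed smooth bump is circularly shifted by an offset derived from the
    position's grid row and column, so neighbouring positions get
    neighbouring shifts and the neutral centre position gets the unshifted
    bump.  The construction mimics apparent muscle displacement under arm
    rotation without claiming physiological fidelity.
    """
    base = _ring_bump(n_channels, width)
    pattern = {}
    for p in range(1, 10):
        row, col = position_grid(p)
        roll = 5 * (row - 1) + 2 * (col - 1)
        pattern[p] = np.roll(base, roll)
    return pattern


def default_amp_profile(n_channels: int = N_CHANNELS) -> np.ndarray:
    """Grasp x channel amplitude gains (6 x 16).

    Each active grasp activates a different region of the electrode ring with
    a distinct width and strength, on a common baseline; "rest" (label 6) is
    a genuine low-amplitude class rather than absence of signal.
    """
    ch = np.arange(n_channels)
    centres = (0, 3, 6, 9, 12)
    widths = (2.0, 3.0, 2.5, 2.0, 3.5)
    peaks = (1.0, 0.9, 1.1, 0.8, 1.0)
    profile = np.empty((6, n_channels))
    for g in range(5):
        dist = np.minimum(np.abs(ch - centres[g]), n_channels - np.abs(ch - centres[g]))
        profile[g] = 0.15 + peaks[g] * np.exp(-0.5 * (dist / widths[g]) ** 2)
    profile[5] = 0.08  # rest: low uniform activity
    return profile


def default_tone_pattern(n_channels: int = N_CHANNELS) -> dict[int, np.ndarray]:
    """Per-position postural-activity channel patterns v[p].

    Fixed non-negative random vectors (constant internal seed — they are part
    of the model definition, not of the stochastic draw).  Random patterns
    carry energy outside the smooth subspace spanned by the grasp amplitude
    profiles, so the postural component stays linearly recoverable.
    """
    rng = np.random.default_rng(7)
    return {p: np.abs(rng.standard_normal(n_channels)) for p in range(1, 10)}


def default_glove_posture(n_sensors: int = N_GLOVE) -> np.ndarray:
    """Grasp x sensor target values (arbitrary uncalibrated sensor units)."""
    s = np.arange(n_sensors)
    targets = np.empty((6, n_sensors))
    for g in range(6):
        targets[g] = 40.0 + 25.0 * np.sin(2 * np.pi * s / n_sensors + 1.1 * g)
    targets[5] = 30.0  # rest: open relaxed hand
    return targets


@dataclass
class SimulationParams:
    """All knobs of the synthetic signal model.

    ``shift_magnitude`` (delta) controls the position effect; the real
    experiment does not quantify its effect size, so the default of 0.3 is an
    arbitrary moderate value — experiments that need a specific delta set it
    explicitly.  ``postural_tone`` scales the grasp-independent additive
    position component (see the module docstring); set it to 0 to isolate
    the purely multiplicative shift.
    """

    amp_profile: np.ndarray = field(default_factory=default_amp_profile)
    shift_magnitude: float = 0.3
    shift_pattern: dict[int, np.ndarray] = field(default_factory=default_shift_pattern)
    postural_tone: float = 0.5
    tone_pattern: dict[int, np.ndarray] = field(default_factory=default_tone_pattern)
    noise_band: tuple[float, float] = (20.0, 450.0)
    powerline_freq: float = 50.0
    powerline_amp: float = 0.1
    dc_offset: np.ndarray = field(
        default_factory=lambda: np.linspace(-0.05, 0.05, N_CHANNELS))
    glove_posture: np.ndarray = field(default_factory=default_glove_posture)
    glove_rest: np.ndarray = field(default_factory=lambda: np.full(N_GLOVE, 30.0))
    glove_tau: float = 0.3
    glove_noise: float = 0.5
    participant_jitter: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        self.amp_profile = np.asarray(self.amp_profile, dtype=np.float64)
        self.dc_offset = np.asarray(self.dc_offset, dtype=np.float64)
        self.glove_posture = np.asarray(self.glove_posture, dtype=np.float64)
        self.glove_rest = np.asarray(self.glove_rest, dtype=np.float64)
        if self.amp_profile.ndim != 2:
            raise ValueError("amp_profile must be grasps x channels")
        if np.any(self.amp_profile < 0):
            raise ValueError("amp_profile gains must be non-negative")
        if self.shift_magnitude < 0 or self.powerline_amp < 0 or self.postural_tone < 0:
            raise ValueError(
                "shift_magnitude, powerline_amp and postural_tone must be non-negative")
        if self.dc_offset.shape[0] != self.amp_profile.shape[1]:
            raise ValueError("dc_offset length must match the channel count")

    @property
    def n_channels(self) -> int:
        return self.amp_profile.shape[1]


def subseed(*keys: int) -> int:
    """Deterministic child seed from a tuple of integer keys (< 2**31)."""
    return int(np.random.SeedSequence([int(k) for k in keys]).generate_state(1)[0] % (2**31))


def make_schedule(config: ProtocolConfig, day: int, seed: int
                  ) -> list[tuple[int, int, int, int]]:
    """Pseudorandomised session schedule of (position, grasp, trial_no, block_no).

    Every (position, grasp) pair occupies exactly one block of
    ``trials_per_grasp`` consecutive trials; the block order is a seeded
    permutation, so two calls with the same seed agree exactly.
    """
    positions = config.positions(day)
    pairs = [(p, g) for p in positions for g in config.grasps]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    schedule = []
    for block_no, idx in enumerate(order):
        p, g = pairs[idx]
        for trial_no in range(config.trials_per_grasp):
            schedule.append((p, g, trial_no, block_no))
    return schedule


def simulate_trial(sp: SimulationParams, position: int, grasp: int, seed: int, *,
                   sampling_rate: float = 2000.0, trial_length: float = 5.0,
                   participant: int = 1, day: int = 1, session: int = 1,
                   trial_no: int = 0, block_no: int = 0, trial_id: int = 0,
                   ) -> TrialRecord:
    """One synthetic 5 s grasp hold (EMG + glove), deterministic given ``seed``."""
    if grasp not in range(1, sp.amp_profile.shape[0] + 1):
        raise ValueError(f"unknown grasp label {grasp}")
    if position not in sp.shift_pattern:
        raise ValueError(f"unknown position label {position}")
    n = int(round(sampling_rate * trial_length))
    rng = np.random.default_rng(seed)
    nch = sp.n_channels

    gain = (1.0 + sp.shift_magnitude * sp.shift_pattern[position]) \
        * sp.amp_profile[grasp - 1]
    tone = sp.shift_magnitude * sp.postural_tone * sp.tone_pattern[position]
    spec = FilterSpec(order=4, low_cutoff=sp.noise_band[0],
                      high_cutoff=sp.noise_band[1], sampling_rate=sampling_rate)

    need_gain = bool(np.any(gain > 0))
    need_tone = bool(np.any(tone > 0))
    emg = np.zeros((nch, n))
    if need_gain or need_tone:
        k = int(need_gain) + int(need_tone)
        x = bandpass(rng.standard_normal((k * nch, n)), spec)
        sd = x.std(axis=1, keepdims=True)
        x = x / np.where(sd == 0, 1.0, sd)  # unit-variance carriers
        row = 0
        if need_gain:
            emg = gain[:, None] * x[:nch]
            row = nch
        if need_tone:
            emg = emg + tone[:, None] * x[row:row + nch]
    if sp.powerline_amp > 0:
        t = np.arange(n) / sampling_rate
        phase = rng.uniform(0, 2 * np.pi, size=nch)
        wt = 2 * np.pi * sp.powerline_freq * t
        # sin(wt + phi) expanded so only two length-n trigs are evaluated
        emg = emg + sp.powerline_amp * (
            np.cos(phase)[:, None] * np.sin(wt)[None, :]
            + np.sin(phase)[:, None] * np.cos(wt)[None, :])
    emg = emg + sp.dc_offset[:, None]

    t = np.arange(n) / sampling_rate
    target = sp.glove_posture[grasp - 1]
    relax = 1.0 - np.exp(-t / sp.glove_tau)
    glove = sp.glove_rest[:, None] + (target - sp.glove_rest)[:, None] * relax[None, :]
    if sp.glove_noise > 0:
        # the real glove samples at ~100 Hz and is upsampled to the EMG rate,
        # so sensor noise is generated at low rate and step-upsampled
        up = max(1, int(round(sampling_rate / 100.0)))
        n_low = -(-n // up)  # ceil
        low = rng.standard_normal((sp.glove_posture.shape[1], n_low))
        glove = glove + sp.glove_noise * np.repeat(low, up, axis=1)[:, :n]

    return TrialRecord(participant=participant, day=day, session=session,
                       position=position, grasp=grasp, trial_no=trial_no,
                       block_no=block_no, emg=emg, glove=glove, trial_id=trial_id)


def participant_params(sp: SimulationParams, participant: int) -> SimulationParams:
    """Participant-specific copy of ``sp`` with jittered amplitude profiles.

    A small seeded multiplicative perturbation of ``amp_profile`` makes
    simulated participants differ the way real forearms do, while leaving the
    position-shift mechanism untouched.
    """
    if sp.participant_jitter == 0:
        return sp
    rng = np.random.default_rng(subseed(sp.seed, 7001, participant))
    jitter = 1.0 + sp.participant_jitter * rng.standard_normal(sp.amp_profile.shape)
    return replace(sp, amp_profile=sp.amp_profile * np.clip(jitter, 0.1, None))


def simulate_session(config: ProtocolConfig, sp: SimulationParams, participant: int,
                     day: int, session: int, *, positions: Sequence[int] | None = None,
                     with_glove: bool = True) -> list[TrialRecord]:
    """All trials of one session, in schedule order.

    ``positions`` optionally restricts which scheduled trials are actually
    synthesised (the schedule and every per-trial seed are unchanged, so the
    retained trials are bit-identical to a full run).  ``with_glove=False``
    skips glove synthesis for speed.
    """
    schedule = make_schedule(config, day, subseed(config.seed, 101, participant, day, session))
    records = []
    for i, (p, g, trial_no, block_no) in enumerate(schedule):
        if positions is not None and p not in positions:
            continue
        rec = simulate_trial(
            sp, p, g, subseed(sp.seed, 202, participant, day, session, block_no, trial_no),
            sampling_rate=config.sampling_rate, trial_length=config.trial_length,
            participant=participant, day=day, session=session,
            trial_no=trial_no, block_no=block_no, trial_id=i + 1)
        if not with_glove:
            rec.glove = None
        records.append(rec)
    return records


def simulate_participant(config: ProtocolConfig, sp: SimulationParams,
                         participant: int, out_dir: str | Path) -> list[Path]:
    """Write every session folder of one participant to ``out_dir``."""
    sp_i = participant_params(sp, participant)
    out_dir = Path(out_dir)
    written = []
    for day in (1, 2):
        for session in range(1, config.sessions_per_day + 1):
            records = simulate_session(config, sp_i, participant, day, session)
            params = RecordingParameters(
                low_cutoff=sp.noise_band[0],
                high_cutoff=sp.noise_band[1],
                trials_number=config.trials_per_grasp,
                trial_length=config.trial_length,
                n_channels=sp.n_channels,
                sampling_rate=config.sampling_rate,
                configuration="+" if day == 1 else "x",
                grasp_sequence=tuple(r.grasp for r in records if r.trial_no == 0),
                date_time=datetime.datetime(2024, 1, day, 9 + 3 * (session - 1)).isoformat(),
                participant=participant,
                day=day,
            )
            folder = out_dir / f"participant{participant}_day{day}_session{session}"
            written.append(write_session(folder, records, params))
    return written
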