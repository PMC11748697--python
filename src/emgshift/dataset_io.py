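"""Read and write the published session-folder layout.

A recording session lives in a folder named ``participantX_dayY_sessionZ``
containing

* ``emg_data.hdf5``   — one 16 x (rate*length) float matrix per trial,
  indexed by trial number,
* ``glove_data.hdf5`` — one 18 x (rate*length) matrix per trial (optional),
* ``trials.csv``      — per-trial labels (trial id, target position, grasp,
  trial number within its block, block number),
* ``recording_parameters.txt`` — flat ``key: value`` metadata.

The same layout is produced by the protocol simulator and expected from the
real deposition, so the analysis pipeline runs identically on either.  Key
naming inside third-party HDF5 files is probed rather than assumed: the
reader first tries zero-padded then plain decimal trial ids and finally
falls back to numerically sorted keys.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

EMG_FILE = "emg_data.hdf5"
GLOVE_FILE = "glove_data.hdf5"
TRIALS_FILE = "trials.csv"
PARAMS_FILE = "recording_parameters.txt"

#: canonical trials.csv column names (header aliases are normalised on read)
TRIAL_COLUMNS = ("trial_id", "target_position", "grasp", "trial_number", "block_number")

_SESSION_RE = re.compile(r"^participant(\d+)_day(\d+)_session(\d+)$")


@dataclass(frozen=True)
class SessionFolder:
    """A discovered session directory with its parsed identity."""

    participant: int
    day: int
    session: int
    path: Path

    def __post_init__(self) -> None:
        if self.participant < 1:
            raise ValueError(f"participant id must be >= 1, got {self.participant}")
        if self.day not in (1, 2):
            raise ValueError(f"day must be 1 or 2, got {self.day}")
        if self.session < 1:
            raise ValueError(f"session must be >= 1, got {self.session}")


@dataclass
class TrialRecord:
    """One grasp hold: raw signals plus all labels.

    ``emg`` is channels x time (16 x 10000 at the default 2 kHz / 5 s),
    ``glove`` is 18 x time or ``None`` when the glove file is absent.
    ``trial_no`` counts 0-4 within a 5-trial block; ``block_no`` indexes the
    block inside the session; trials sharing a block share (grasp, position).
    """

    participant: int
    day: int
    session: int
    position: int
    grasp: int
    trial_no: int
    block_no: int
    emg: np.ndarray
    glove: np.ndarray | None = None
    trial_id: int = 0  # 1-based index inside the session

    def __post_init__(self) -> None:
        self.emg = np.asarray(self.emg, dtype=np.float64)
        if self.emg.ndim != 2:
            raise ValueError(f"trial {self.trial_id}: emg must be 2-D, got {self.emg.ndim}-D")
        if self.glove is not None:
            self.glove = np.asarray(self.glove, dtype=np.float64)
            if self.glove.ndim != 2 or self.glove.shape[0] != 18:
                raise ValueError(
                    f"trial {self.trial_id}: glove must have 18 rows, got shape "
                    f"{self.glove.shape}"
                )
        if not 1 <= self.position <= 9:
            raise ValueError(f"trial {self.trial_id}: position {self.position} outside 1-9")
        if not 1 <= self.grasp <= 6:
            raise ValueError(f"trial {self.trial_id}: grasp {self.grasp} outside 1-6")


@dataclass
class RecordingParameters:
    """Metadata block mirrored from ``recording_parameters.txt``.

    ``window_size_ms`` carries the value printed in the parameters file
    (150 ms in the deposition); the analysis default of 128 ms is configured
    separately in :mod:`emgshift.preprocess`.
    """

    window_size_ms: float = 150.0
    low_cutoff: float = 20.0
    high_cutoff: float = 450.0
    filter_order: int = 4
    trials_number: int = 5
    trial_interval: float = 3.0
    trial_length: float = 5.0
    n_channels: int = 16
    sampling_rate: float = 2000.0
    configuration: str = "+"
    grasp_sequence: Sequence[int] = field(default_factory=tuple)
    date_time: str = ""
    participant: int = 0
    day: int = 1

    def __post_init__(self) -> None:
        if self.filter_order < 1:
            raise ValueError(f"filter_order must be >= 1, got {self.filter_order}")
        if not 0 < self.low_cutoff < self.high_cutoff:
            raise ValueError(
                f"need 0 < low_cutoff < high_cutoff, got {self.low_cutoff}/{self.high_cutoff}"
            )
        if self.high_cutoff >= self.sampling_rate / 2:
            raise ValueError(
                f"high_cutoff {self.high_cutoff} must lie below Nyquist "
                f"({self.sampling_rate / 2})"
            )
        if self.configuration not in ("+", "x"):
            raise ValueError(f"configuration must be '+' or 'x', got {self.configuration!r}")


def _trial_key(trial_id: int) -> str:
    return f"{trial_id:03d}"


def write_session(path: str | Path, records: Sequence[TrialRecord],
                  params: RecordingParameters) -> Path:
    """Write one session folder (HDF5 signals, CSV labels, text parameters).

    All records must share (participant, day, session) and EMG shape.  Trials
    are keyed by zero-padded 1-based trial id so lexicographic key order is
    numeric order.
    """
    if len(records) == 0:
        raise ValueError("cannot write an empty session")
    ident = (records[0].participant, records[0].day, records[0].session)
    shape = records[0].emg.shape
    for r in records:
        if (r.participant, r.day, r.session) != ident:
            raise ValueError("records mix different (participant, day, session) identities")
        if r.emg.shape != shape:
            raise ValueError(
                f"trial {r.trial_id}: emg shape {r.emg.shape} differs from {shape}"
            )

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)

    have_glove = all(r.glove is not None for r in records)
    rows = []
    with h5py.File(path / EMG_FILE, "w") as femg:
        for i, r in enumerate(records, start=1):
            tid = r.trial_id if r.trial_id else i
            femg.create_dataset(_trial_key(tid), data=r.emg)
            rows.append((tid, r.position, r.grasp, r.trial_no, r.block_no))
    if have_glove:
        with h5py.File(path / GLOVE_FILE, "w") as fglove:
            for i, r in enumerate(records, start=1):
                tid = r.trial_id if r.trial_id else i
                fglove.create_dataset(_trial_key(tid), data=r.glove)

    pd.DataFrame(rows, columns=list(TRIAL_COLUMNS)).to_csv(path / TRIALS_FILE, index=False)
    write_parameters(path / PARAMS_FILE, params)
    return path


def write_parameters(path: str | Path, params: RecordingParameters) -> None:
    lines = [
        f"participant: {params.participant}",
        f"configuration: {params.configuration}",
        f"grasp sequence: {','.join(str(g) for g in params.grasp_sequence)}",
        f"day: {params.day}",
        f"date time: {params.date_time}",
        f"window size: {params.window_size_ms:g} ms",
        f"low cut-off frequency: {params.low_cutoff:g} Hz",
        f"high cut-off frequency: {params.high_cutoff:g} Hz",
        f"filter order: {params.filter_order}",
        f"trials number: {params.trials_number}",
        f"trial interval time: {params.trial_interval:g} sec",
        f"trial length time: {params.trial_length:g} sec",
        f"number of channels: {params.n_channels}",
        f"sampling rate: {params.sampling_rate:g} Hz",
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _strip_unit(value: str) -> str:
    return re.sub(r"\s*(ms|hz|sec|s)$", "", value.strip(), flags=re.IGNORECASE)


def read_parameters(path: str | Path) -> RecordingParameters:
    """Parse a flat ``key: value`` parameters file; unknown keys are ignored."""
    raw: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if ":" not in line:
            continue
        key, value = line.split(":", 1)
        raw[key.strip().lower()] = value.strip()

    def fget(key: str, default: float) -> float:
        return float(_strip_unit(raw[key])) if key in raw else default

    seq: tuple[int, ...] = ()
    if raw.get("grasp sequence"):
        seq = tuple(int(tok) for tok in raw["grasp sequence"].split(",") if tok.strip())
    return RecordingParameters(
        window_size_ms=fget("window size", 150.0),
        low_cutoff=fget("low cut-off frequency", 20.0),
        high_cutoff=fget("high cut-off frequency", 450.0),
        filter_order=int(fget("filter order", 4)),
        trials_number=int(fget("trials number", 5)),
        trial_interval=fget("trial interval time", 3.0),
        trial_length=fget("trial length time", 5.0),
        n_channels=int(fget("number of channels", 16)),
        sampling_rate=fget("sampling rate", 2000.0),
        configuration=raw.get("configuration", "+"),
        grasp_sequence=seq,
        date_time=raw.get("date time", ""),
        participant=int(fget("participant", 0)),
        day=int(fget("day", 1)),
    )


def _normalise_columns(df: pd.DataFrame) -> pd.DataFrame:
    aliases = {
        "trial id": "trial_id",
        "trialid": "trial_id",
        "target position": "target_position",
        "position": "target_position",
        "trial number": "trial_number",
        "block number": "block_number",
    }
    cols = {}
    for c in df.columns:
        key = str(c).strip().lower().replace("-", " ")
        key = aliases.get(key, key.replace(" ", "_"))
        cols[c] = key
    df = df.rename(columns=cols)
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trials.csv is missing columns {missing}")
    return df


def _lookup_trial(h5: h5py.File, trial_id: int, sorted_keys: list[str]) -> np.ndarray:
    # fallback order: zero-padded id, plain id, 0-based id, numeric key rank
    for cand in (_trial_key(trial_id), str(trial_id), str(trial_id - 1)):
        if cand in h5:
            return np.asarray(h5[cand], dtype=np.float64)
    if 1 <= trial_id <= len(sorted_keys):
        return np.asarray(h5[sorted_keys[trial_id - 1]], dtype=np.float64)
    raise KeyError(f"trial {trial_id} not found in {h5.filename}")


def _numeric_sorted_keys(h5: h5py.File) -> list[str]:
    def rank(key: str) -> tuple:
        digits = re.sub(r"\D", "", key)
        return (0, int(digits)) if digits else (1, key)

    return sorted(h5.keys(), key=rank)


def read_session(path: str | Path,
                 session_info: SessionFolder | None = None
                 ) -> tuple[list[TrialRecord], RecordingParameters | None]:
    """Load one session folder into :class:`TrialRecord` objects.

    ``emg_data.hdf5`` and ``trials.csv`` are required; the glove file is
    optional (records then carry ``glove=None``).  EMG matrices are shape
    checked against the parameters file channel count, and errors name the
    offending trial.
    """
    path = Path(path)
    if session_info is None:
        m = _SESSION_RE.match(path.name)
        if m:
            session_info = SessionFolder(int(m.group(1)), int(m.group(2)),
                                         int(m.group(3)), path)
        else:
            session_info = SessionFolder(1, 1, 1, path)
    if not (path / EMG_FILE).exists():
        raise FileNotFoundError(f"{path} has no {EMG_FILE}")
    if not (path / TRIALS_FILE).exists():
        raise FileNotFoundError(f"{path} has no {TRIALS_FILE}")

    params = read_parameters(path / PARAMS_FILE) if (path / PARAMS_FILE).exists() else None
    labels = _normalise_columns(pd.read_csv(path / TRIALS_FILE))
    if labels["trial_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate trial ids in {TRIALS_FILE}")

    n_channels = params.n_channels if params is not None else None
    records: list[TrialRecord] = []
    glove_path = path / GLOVE_FILE
    fglove = h5py.File(glove_path, "r") if glove_path.exists() else None
    try:
        with h5py.File(path / EMG_FILE, "r") as femg:
            keys = _numeric_sorted_keys(femg)
            if len(keys) != len(labels):
                raise ValueError(
                    f"{path}: {len(labels)} rows in {TRIALS_FILE} but {len(keys)} "
                    f"trials in {EMG_FILE}"
                )
            gkeys = _numeric_sorted_keys(fglove) if fglove is not None else []
            for row in labels.itertuples(index=False):
                tid = int(row.trial_id)
                emg = _lookup_trial(femg, tid, keys)
                if emg.ndim != 2 or (n_channels is not None and emg.shape[0] != n_channels):
                    raise ValueError(
                        f"{path}: trial {tid} emg has shape {emg.shape}, "
                        f"expected {n_channels} channels"
                    )
                glove = _lookup_trial(fglove, tid, gkeys) if fglove is not None else None
                records.append(TrialRecord(
                    participant=session_info.participant,
                    day=session_info.day,
                    session=session_info.session,
                    position=int(row.target_position),
                    grasp=int(row.grasp),
                    trial_no=int(row.trial_number),
                    block_no=int(row.block_number),
                    emg=emg,
                    glove=glove,
                    trial_id=tid,
                ))
    finally:
        if fglove is not None:
            fglove.close()
    if fglove is None:
        logger.warning("%s: no %s, records carry glove=None", path, GLOVE_FILE)
    return records, params


def discover_sessions(root: str | Path) -> list[SessionFolder]:
    """Find all ``participantX_dayY_sessionZ`` folders under ``root``.

    Returns the list sorted by (participant, day, session); directories that
    do not match the naming scheme are skipped with a logged warning.
    """
    root = Path(root)
    if not root.exists():
        raise FileNotFoundError(f"dataset root {root} does not exist")
    found: list[SessionFolder] = []
    for child in sorted(root.iterdir()):
        if not child.is_dir():
            continue
        m = _SESSION_RE.match(child.name)
        if m is None:
            logger.warning("ignoring non-session folder %s", child)
            continue
        found.append(SessionFolder(int(m.group(1)), int(m.group(2)), int(m.group(3)), child))
    return sorted(found, key=lambda s: (s.participant, s.day, s.session))


def session_summary(path: str | Path) -> pd.DataFrame:
    """Trial counts per (grasp, position) for a quick folder inspection."""
    records, _ = read_session(path)
    df = pd.DataFrame({"grasp": [r.grasp for r in records],
                       "position": [r.position for r in records]})
    return df.value_counts(["position", "grasp"]).rename("trials").reset_index()
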