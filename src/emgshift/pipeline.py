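"""From raw trials to labelled feature tables.

Each trial is band-pass filtered, notch filtered, offset corrected, cut into
sliding windows and reduced to Hudgins features.  The result is a pandas
DataFrame with one row per window: the 64 feature columns from
:func:`emgshift.features.feature_columns` plus provenance
(participant, day, session, position, grasp, trial_id, block, window start).

Because every recorded sample belongs to the held grasp, all windows of a
trial inherit the trial's label; :func:`emgshift.preprocess.majority_label`
is still used so mixed-label windows would resolve correctly.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import dataset_io, protocol_sim
from .dataset_io import TrialRecord
from .features import FeatureThresholds, extract_batch, feature_columns
from .preprocess import (FilterSpec, WindowSpec, bandpass, majority_label,
                         notch, remove_offset, windows)

META_COLUMNS = ("participant", "day", "session", "position", "grasp",
                "trial_id", "block", "start")


def featurize_trial(record: TrialRecord, fspec: FilterSpec,
                    wspec: WindowSpec = WindowSpec(),
                    th: FeatureThresholds = FeatureThresholds(),
                    zero_phase: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Filter one trial and return (features, window starts)."""
    x = bandpass(record.emg, fspec, zero_phase=zero_phase)
    x = notch(x, fspec, zero_phase=zero_phase)
    x = remove_offset(x)
    segs, starts = windows(x, wspec, fspec.sampling_rate)
    return extract_batch(segs, th), starts


def featurize_records(records: Iterable[TrialRecord],
                      fspec: FilterSpec | None = None,
                      wspec: WindowSpec = WindowSpec(),
                      th: FeatureThresholds = FeatureThresholds(),
                      zero_phase: bool = False) -> pd.DataFrame:
    """Feature table for a collection of trials (one row per window)."""
    frames = []
    for rec in records:
        spec = fspec or FilterSpec()
        feats, starts = featurize_trial(rec, spec, wspec, th, zero_phase)
        df = pd.DataFrame(feats, columns=feature_columns(rec.emg.shape[0]))
        n = len(df)
        labels = [rec.grasp] * rec.emg.shape[1]
        df.insert(0, "participant", rec.participant)
        df.insert(1, "day", rec.day)
        df.insert(2, "session", rec.session)
        df.insert(3, "position", rec.position)
        df.insert(4, "grasp", majority_label(labels))
        df.insert(5, "trial_id", rec.trial_id)
        df.insert(6, "block", rec.block_no)
        df.insert(7, "start", starts[:n])
        frames.append(df)
    if not frames:
        raise ValueError("no trials to featurize")
    return pd.concat(frames, ignore_index=True)


def load_features(root: str | Path, fspec: FilterSpec | None = None,
                  wspec: WindowSpec = WindowSpec(),
                  th: FeatureThresholds = FeatureThresholds()) -> pd.DataFrame:
    """Read every session folder under ``root`` and featurize it."""
    frames = []
    for sess in dataset_io.discover_sessions(root):
        records, params = dataset_io.read_session(sess.path, sess)
        spec = fspec
        if spec is None and params is not None:
            spec = FilterSpec(order=params.filter_order, low_cutoff=params.low_cutoff,
                              high_cutoff=params.high_cutoff,
                              sampling_rate=params.sampling_rate)
        frames.append(featurize_records(records, spec, wspec, th))
    if not frames:
        raise ValueError(f"no session folders under {root}")
    return pd.concat(frames, ignore_index=True)


def simulate_features(config: protocol_sim.ProtocolConfig,
                      sp: protocol_sim.SimulationParams,
                      participants: Sequence[int],
                      days: Sequence[int] = (1, 2),
                      sessions: Sequence[int] | None = None,
                      positions: Sequence[int] | None = None,
                      wspec: WindowSpec = WindowSpec(),
                      th: FeatureThresholds = FeatureThresholds()) -> pd.DataFrame:
    """Simulate a cohort in memory and featurize it in one step.

    ``positions`` restricts synthesis to the trials actually needed (seed
    derivation is schedule-stable, so the retained windows equal those of a
    full run).  Glove synthesis is skipped — features use EMG only.
    """
    fspec = FilterSpec(sampling_rate=config.sampling_rate)
    if sessions is None:
        sessions = tuple(range(1, config.sessions_per_day + 1))
    frames = []
    for participant in participants:
        sp_i = protocol_sim.participant_params(sp, participant)
        for day in days:
            for session in sessions:
                records = protocol_sim.simulate_session(
                    config, sp_i, participant, day, session,
                    positions=positions, with_glove=False)
                if records:
                    frames.append(featurize_records(records, fspec, wspec, th))
    if not frames:
        raise ValueError("simulation produced no trials (position filter too strict?)")
    return pd.concat(frames, ignore_index=True)


def features_to_csv(features: pd.DataFrame, path: str | Path) -> None:
    """Export a feature table (provenance + 64 features per row)."""
    features.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML or flat ``key: value`` configuration file into a dict."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path} did not parse to a mapping")
    return {str(k).strip().lower().replace(" ", "_"): v for k, v in data.items()}


def filter_spec_from_config(cfg: dict) -> FilterSpec:
    """Build a :class:`FilterSpec` from configuration keys mirroring the
    recording-parameters file (``low_cut-off_frequency`` etc. accepted)."""
    def num(keys: tuple[str, ...], default: float) -> float:
        for k in keys:
            if k in cfg:
                return float(str(cfg[k]).split()[0])
        return default

    return FilterSpec(
        order=int(num(("filter_order", "butterworth_filter"), 4)),
        low_cutoff=num(("low_cutoff", "low_cut-off_frequency"), 20.0),
        high_cutoff=num(("high_cutoff", "high_cut-off_frequency"), 450.0),
        notch_freq=num(("notch_freq",), 50.0),
        notch_q=num(("notch_q",), 30.0),
        sampling_rate=num(("sampling_rate",), 2000.0),
    )
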