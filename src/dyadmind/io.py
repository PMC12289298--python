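"""Delimited-text readers and writers for every pipeline input and output.

All formats are plain text so runs are diffable and portable:

- surveys: one row per dyad x respondent x scale x timepoint x item
- emotion-bias trial logs: one row per trial
- breath taps: one row per tap
- EEG: a documented text container (header lines with sampling rate,
  channel labels and per-block tap markers, then a channels x samples
  matrix per block)
- lead fields and ROI sets: labeled delimited matrices

Native .xdf reading is deliberately not provided; :func:`convert_xdf_stub`
documents the channel/event layout a converter must produce.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .breath_eeg import BreathSeries, EEGRecording, NetworkROISet
from .emotion_bias import TrialRecord
from .survey_scoring import SurveyResponse
from .synthetic_data import LeadField

__all__ = [
    "write_surveys",
    "read_surveys",
    "write_trials",
    "read_trials",
    "write_taps",
    "read_taps",
    "write_eeg_text",
    "read_eeg_text",
    "write_leadfield",
    "read_leadfield",
    "write_roi_set",
    "read_roi_set",
    "convert_xdf_stub",
]

SEP = "\t"


def write_surveys(responses, path) -> None:
    rows = [
        {
            "dyad_id": r.dyad_id,
            "respondent": r.respondent,
            "scale_id": r.scale_id,
            "timepoint": r.timepoint,
            "item_index": i,
            "value": v,
        }
        for r in responses
        for i, v in enumerate(r.items)
    ]
    pd.DataFrame(rows).to_csv(path, sep=SEP, index=False)


def read_surveys(path) -> list:
    df = pd.read_csv(path, sep=SEP)
    out = []
    keys = ["dyad_id", "respondent", "scale_id", "timepoint"]
    for key, grp in df.groupby(keys, sort=True):
        grp = grp.sort_values("item_index")
        if not np.array_equal(grp["item_index"].to_numpy(), np.arange(len(grp))):
            raise ValueError(f"non-contiguous item indices for {key}")
        out.append(
            SurveyResponse(
                dyad_id=str(key[0]),
                respondent=str(key[1]),
                scale_id=str(key[2]),
                timepoint=str(key[3]),
                items=tuple(grp["value"].tolist()),
            )
        )
    return out


def write_trials(trials, path) -> None:
    pd.DataFrame(
        [
            {
                "trial_index": t.trial_index,
                "block": t.block,
                "emotion": t.emotion,
                "face_sex": t.face_sex,
                "field": t.field,
                "arrow_direction": t.arrow_direction,
                "response_window_ms": t.response_window_ms,
                "rt_ms": t.rt_ms,
                "correct": t.correct,
            }
            for t in trials
        ]
    ).to_csv(path, sep=SEP, index=False)


def read_trials(path) -> list:
    df = pd.read_csv(path, sep=SEP)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            TrialRecord(
                trial_index=int(row.trial_index),
                block=int(row.block),
                emotion=row.emotion,
                face_sex=row.face_sex,
                field=row.field,
                arrow_direction=row.arrow_direction,
                response_window_ms=(
                    None if pd.isna(row.response_window_ms) else float(row.response_window_ms)
                ),
                rt_ms=None if pd.isna(row.rt_ms) else float(row.rt_ms),
                correct=None if pd.isna(row.correct) else bool(row.correct),
            )
        )
    return out


def write_taps(series: BreathSeries, path) -> None:
    rows = [
        {
            "participant_id": series.participant_id,
            "role": series.role,
            "session": series.session,
            "block": bi,
            "tap_time_s": t,
        }
        for bi, block in enumerate(series.blocks)
        for t in block
    ]
    pd.DataFrame(rows).to_csv(path, sep=SEP, index=False)


def read_taps(path, block_duration_s: float = 150.0) -> BreathSeries:
    df = pd.read_csv(path, sep=SEP)
    meta = df.iloc[0]
    blocks = [
        grp.sort_values("tap_time_s")["tap_time_s"].to_numpy()
        for _, grp in df.groupby("block", sort=True)
    ]
    return BreathSeries(
        blocks=tuple(blocks),
        participant_id=str(meta.participant_id),
        role=str(meta.role),
        session=str(meta.session),
        block_duration_s=block_duration_s,
    )


def write_eeg_text(eeg: EEGRecording, path) -> None:
    """Write the EEG text container.

    Header lines start with ``#``: format tag, sampling rate, channel
    labels, then one ``# block`` line per block with its tap markers.
    Each block's channels x samples matrix follows its block line.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# eeg-text v1\n")
        fh.write(f"# fs={eeg.fs}\n")
        fh.write(f"# channels={','.join(eeg.channel_labels)}\n")
        for bi, block in enumerate(eeg.blocks):
            taps = eeg.tap_times[bi] if bi < len(eeg.tap_times) else []
            fh.write(
                f"# block={bi} n_samples={block.shape[1]} "
                f"taps={','.join(f'{t:.6f}' for t in taps)}\n"
            )
            np.savetxt(fh, block, fmt="%.6g", delimiter=SEP)


def read_eeg_text(path) -> EEGRecording:
    fs, channels = None, None
    blocks, taps, current = [], [], None
    with Path(path).open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("fs="):
                    fs = float(body[3:])
                elif body.startswith("channels="):
                    channels = tuple(body[len("channels="):].split(","))
                elif body.startswith("block="):
                    if current:
                        blocks.append(np.array(current, dtype=float))
                    current = []
                    tap_field = [f for f in body.split() if f.startswith("taps=")][0]
                    tap_str = tap_field[len("taps="):]
                    taps.append(
                        np.array([float(x) for x in tap_str.split(",")] if tap_str else [])
                    )
                continue
            if line:
                current.append([float(x) for x in line.split(SEP)])
    if current:
        blocks.append(np.array(current, dtype=float))
    if fs is None or channels is None or not blocks:
        raise ValueError("malformed EEG text container")
    return EEGRecording(
        blocks=tuple(blocks), fs=fs, channel_labels=channels, tap_times=tuple(taps)
    )


def write_leadfield(lf: LeadField, path) -> None:
    pd.DataFrame(
        lf.matrix, index=list(lf.channel_labels), columns=list(lf.source_labels)
    ).to_csv(path, sep=SEP, index_label="channel")


def read_leadfield(path) -> LeadField:
    df = pd.read_csv(path, sep=SEP, index_col="channel")
    return LeadField(
        matrix=df.to_numpy(),
        channel_labels=tuple(df.index),
        source_labels=tuple(df.columns),
    )


def write_roi_set(roi: NetworkROISet, path) -> None:
    rows = [
        {"network": net, "source": s}
        for net, sources in roi.rois.items()
        for s in sources
    ]
    pd.DataFrame(rows).to_csv(path, sep=SEP, index=False)


def read_roi_set(path) -> NetworkROISet:
    df = pd.read_csv(path, sep=SEP)
    rois = {
        net: tuple(grp["source"].tolist()) for net, grp in df.groupby("network", sort=True)
    }
    return NetworkROISet(rois=rois)


def convert_xdf_stub(path) -> None:
    """Placeholder for .xdf ingestion (not provided).

    A converter must produce (a) the EEG text container written by
    :func:`write_eeg_text` — 24 channels labeled per the 10-20 system,
    500 Hz, one matrix per task block — and (b) a tap table as written by
    :func:`write_taps`, with tap times in seconds from block start taken
    from the streamed response-event markers.
    """
    raise NotImplementedError(
        "native .xdf reading is not provided; convert recordings to the "
        "documented text container and tap table (see this function's docstring)"
    )
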