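"""File formats: event tables (TSV), flat YAML configuration, and
BrainVision core data (.vhdr/.vmrk/.eeg, IEEE float32 multiplexed).

The BrainVision writer emits the three-file core format directly; reading
goes through MNE's BrainVision reader, which serves as an independent
check that the written files conform.  A sidecar ``<base>_events.tsv``
(and ``<base>_presses.tsv``) preserves the full annotation table beyond
what marker codes can carry; the reader uses it when present and falls
back to the markers otherwise.
"""

from __future__ import annotations

import io
import os
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from tripletmmn.synth_eeg import MontageSpec, RawRecording

__all__ = [
    "write_events_tsv",
    "read_events_tsv",
    "dump_yaml",
    "load_yaml",
    "write_brainvision",
    "read_brainvision",
]

EVENT_COLUMNS = [
    "onset_ms",
    "block",
    "triplet_index",
    "position",
    "sound",
    "side",
    "category",
    "is_target",
]

_MARKER_CODES = {
    "root": 1,
    "standard": 2,
    "stat_deviant": 3,
    "phys_deviant": 4,
    "double_deviant": 5,
    "target": 6,
}
_CODE_CATEGORIES = {v: k for k, v in _MARKER_CODES.items()}


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> None:
    """UTF-8 TSV event table with a header line."""
    cols = [c for c in EVENT_COLUMNS if c in events.columns] + [
        c for c in events.columns if c not in EVENT_COLUMNS
    ]
    events[cols].to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", encoding="utf-8")
    if "is_target" in df.columns:
        df["is_target"] = df["is_target"].astype(bool)
    return df


def dump_yaml(data: dict, path: str | Path) -> None:
    """Write a (possibly sectioned) key: value configuration file."""
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_yaml(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def write_brainvision(rec: RawRecording, base: str | Path) -> Path:
    """Write ``base``.vhdr/.vmrk/.eeg (+ annotation sidecar TSVs).

    Data are stored multiplexed IEEE float32 in µV at the montage sampling
    rate; stimulus events become ``Stimulus`` markers (category-coded) and
    button presses ``Response`` markers.  Returns the .vhdr path.
    """
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    name = base.name
    fs = rec.montage.sampling_rate
    chans = rec.montage.channels

    vhdr = io.StringIO()
    vhdr.write("Brain Vision Data Exchange Header File Version 1.0\n")
    vhdr.write(f"; reference_state: {rec.reference_state}\n\n")
    vhdr.write("[Common Infos]\nCodepage=UTF-8\n")
    vhdr.write(f"DataFile={name}.eeg\nMarkerFile={name}.vmrk\n")
    vhdr.write("DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n")
    vhdr.write(f"NumberOfChannels={len(chans)}\n")
    vhdr.write(f"SamplingInterval={1e6 / fs:.0f}\n\n")
    vhdr.write("[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n\n")
    vhdr.write("[Channel Infos]\n")
    for i, ch in enumerate(chans, start=1):
        vhdr.write(f"Ch{i}={ch},,1,µV\n")
    (base.with_suffix(".vhdr")).write_text(vhdr.getvalue(), encoding="utf-8")

    vmrk = io.StringIO()
    vmrk.write("Brain Vision Data Exchange Marker File, Version 1.0\n\n")
    vmrk.write(f"[Common Infos]\nCodepage=UTF-8\nDataFile={name}.eeg\n\n")
    vmrk.write("[Marker Infos]\n")
    vmrk.write("Mk1=New Segment,,1,1,0,20000101000000000000\n")
    k = 2
    markers = []
    for _, ev in rec.annotations.iterrows():
        code = _MARKER_CODES.get(str(ev["category"]), 9)
        markers.append(("Stimulus", f"S{code:>3}", int(ev["sample"]) + 1))
    for _, pr in rec.presses.iterrows():
        markers.append(("Response", "R  1", int(pr["sample"]) + 1))
    for typ, desc, pos in sorted(markers, key=lambda m: m[2]):
        vmrk.write(f"Mk{k}={typ},{desc},{pos},1,0\n")
        k += 1
    (base.with_suffix(".vmrk")).write_text(vmrk.getvalue(), encoding="utf-8")

    rec.data.astype("<f4").T.tofile(base.with_suffix(".eeg"))
    write_events_tsv(rec.annotations, f"{base}_events.tsv")
    rec.presses.to_csv(f"{base}_presses.tsv", sep="\t", index=False)
    return base.with_suffix(".vhdr")


def read_brainvision(vhdr_path: str | Path, montage: MontageSpec | None = None) -> RawRecording:
    """Read a BrainVision triple back into a :class:`RawRecording`.

    Uses MNE for parsing; restores full annotations from the sidecar TSVs
    when present, otherwise reconstructs a minimal table from the markers.
    Raises on truncated binary files.
    """
    import mne

    vhdr_path = Path(vhdr_path)
    montage = montage or MontageSpec()
    eeg_path = vhdr_path.with_suffix(".eeg")
    n_ch = len(montage.channels)
    size = os.path.getsize(eeg_path)
    if size == 0 or size % (4 * n_ch):
        raise ValueError(
            f"{eeg_path} is truncated: {size} bytes is not a whole number of "
            f"{n_ch}-channel float32 frames"
        )
    raw = mne.io.read_raw_brainvision(vhdr_path, preload=True, verbose="error")
    if list(raw.ch_names) != montage.channels:
        raise ValueError("channel names in file do not match the montage")
    data = (raw.get_data() * 1e6).astype(np.float32)  # V → µV

    ref_state = "as_recorded"
    with open(vhdr_path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("; reference_state:"):
                ref_state = line.split(":", 1)[1].strip()
                break

    ev_path = Path(f"{vhdr_path.with_suffix('')}_events.tsv")
    pr_path = Path(f"{vhdr_path.with_suffix('')}_presses.tsv")
    if ev_path.exists():
        ann = read_events_tsv(ev_path)
    else:
        fs = montage.sampling_rate
        rows = []
        for on, desc in zip(raw.annotations.onset, raw.annotations.description):
            if not desc.startswith("Stimulus"):
                continue
            code = int(desc.split("/S")[-1])
            cat = _CODE_CATEGORIES.get(code, "unknown")
            rows.append(
                dict(
                    onset_ms=on * 1000.0,
                    sample=int(round(on * fs)),
                    category=cat,
                    is_target=cat == "target",
                )
            )
        ann = pd.DataFrame(rows)
    if pr_path.exists():
        presses = pd.read_csv(pr_path, sep="\t")
    else:
        presses = pd.DataFrame(columns=["press_time_ms", "target_onset_ms", "sample"])
    return RawRecording(data, montage, ann, presses, ref_state)
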