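"""Readers/writers for the plain-text interchange formats.

Spot/track tables are CSV with header (channel, track_id, frame, x_um, y_um)
or the channel-less variant (track_id, frame, x_um, y_um); ribosome
profiling counts are TSV with (gene, codon, input_count, ip_count).
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

TRACK_COLUMNS = ["track_id", "frame", "x_um", "y_um"]


def read_track_csv(path: str | Path, channel: str | None = None) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"track CSV {path} missing columns {missing}")
    if channel is not None and "channel" in df.columns:
        df = df[df["channel"] == channel]
    return df.reset_index(drop=True)


def write_track_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_counts_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = ["gene", "codon", "input_count", "ip_count"]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"counts TSV {path} missing columns {missing}")
    return df


def write_counts_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_durations(path: str | Path) -> pd.Series:
    """Durations CSV: one duration (seconds) per row, with or without header."""
    df = pd.read_csv(path, header=None)
    first = df.iloc[0, 0]
    try:
        float(first)
    except (TypeError, ValueError):
        df = df.iloc[1:]
    return df.iloc[:, -1].astype(float).reset_index(drop=True)
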