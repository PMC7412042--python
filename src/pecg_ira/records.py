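"""Core signal containers shared across the pipeline.

All signals are held as plain numpy arrays in millivolts at a common
sampling rate. Twelve-lead records carry every standard lead by name;
vectorcardiograms carry the three orthogonal dipole channels X, Y, Z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

#: Standard lead names in the order they appear on a 3x4 paper printout
#: (column-major: rows are the three simultaneously printed leads).
LEAD_NAMES = (
    "I", "II", "III",
    "aVR", "aVL", "aVF",
    "V1", "V2", "V3",
    "V4", "V5", "V6",
)

#: The eight linearly independent leads; III and the augmented limb leads
#: are linear combinations of I and II.
INDEPENDENT_LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

#: Column time offsets (s) of the 3x4 simultaneous-lead layout: each
#: column shows a successive 2.5-s window of one continuous 10-s record.
LAYOUT_COLUMNS = {
    ("I", "II", "III"): 0.0,
    ("aVR", "aVL", "aVF"): 2.5,
    ("V1", "V2", "V3"): 5.0,
    ("V4", "V5", "V6"): 7.5,
}

COLUMN_DURATION = 2.5
RECORD_DURATION = 10.0


def lead_column_offset(lead: str) -> float:
    """Time offset (s) of the layout column in which ``lead`` is printed."""
    for leads, offset in LAYOUT_COLUMNS.items():
        if lead in leads:
            return offset
    raise KeyError(f"unknown lead {lead!r}")


@dataclass
class ECGRecord:
    """A multi-lead ECG: mapping of lead name to samples (mV), plus rate."""

    leads: dict[str, np.ndarray]
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        lengths = {len(v) for v in self.leads.values()}
        if len(lengths) > 1:
            raise ValueError("all leads must share one length")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.leads.values())))

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def require_leads(self, names) -> None:
        missing = [n for n in names if n not in self.leads]
        if missing:
            raise KeyError(f"missing leads: {missing}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({k: np.asarray(v) for k, v in self.leads.items()})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fs: float) -> "ECGRecord":
        df = pd.read_csv(path)
        return cls({c: df[c].to_numpy(float) for c in df.columns}, fs=fs)


@dataclass
class VCGRecord:
    """Three-channel vectorcardiogram (X, Y, Z in mV)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if not (len(self.x) == len(self.y) == len(self.z)):
            raise ValueError("VCG channels must have equal length")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.x)

    def as_array(self) -> np.ndarray:
        """(n_samples, 3) array of the dipole trajectory."""
        return np.column_stack([self.x, self.y, self.z])

    def to_csv(self, path) -> None:
        pd.DataFrame({"X": self.x, "Y": self.y, "Z": self.z}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path, fs: float) -> "VCGRecord":
        df = pd.read_csv(path)
        return cls(
            df["X"].to_numpy(float),
            df["Y"].to_numpy(float),
            df["Z"].to_numpy(float),
            fs=fs,
        )


@dataclass
class PaperECGSignals:
    """Digitized content of one paper printout.

    Each of the twelve leads keeps only the 2.5-s window its layout column
    shows; one rhythm lead (lead II by convention) additionally keeps the
    full 10 s for alignment.
    """

    segments: dict[str, np.ndarray]      # lead -> 2.5-s samples
    offsets: dict[str, float]            # lead -> column start time (s)
    reference_lead: str
    reference_signal: np.ndarray         # full-length rhythm strip
    fs: float

    def __post_init__(self) -> None:
        if self.reference_lead not in self.segments:
            raise KeyError(
                f"reference lead {self.reference_lead!r} not among segments"
            )
        for lead, off in self.offsets.items():
            if not any(abs(off - o) < 1e-9 for o in (0.0, 2.5, 5.0, 7.5)):
                raise ValueError(f"lead {lead}: offset {off} not on the 3x4 grid")
        if len(self.reference_signal) / self.fs < RECORD_DURATION - 1e-9:
            raise ValueError("reference lead must cover the full 10 s")

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for lead, seg in self.segments.items():
            pd.DataFrame({lead: seg}).to_csv(directory / f"{lead}.csv", index=False)
        pd.DataFrame({self.reference_lead: self.reference_signal}).to_csv(
            directory / "reference.csv", index=False
        )
        meta = {
            "fs": self.fs,
            "reference_lead": self.reference_lead,
            "offsets": self.offsets,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory) -> "PaperECGSignals":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        segments = {}
        for lead in meta["offsets"]:
            segments[lead] = (
                pd.read_csv(directory / f"{lead}.csv")[lead].to_numpy(float)
            )
        ref = pd.read_csv(directory / "reference.csv")
        return cls(
            segments=segments,
            offsets={k: float(v) for k, v in meta["offsets"].items()},
            reference_lead=meta["reference_lead"],
            reference_signal=ref[meta["reference_lead"]].to_numpy(float),
            fs=float(meta["fs"]),
        )


def derive_limb_leads(lead_i: np.ndarray, lead_ii: np.ndarray) -> dict[str, np.ndarray]:
    """III and the augmented limb leads from Einthoven/Goldberger relations."""
    lead_i = np.asarray(lead_i, float)
    lead_ii = np.asarray(lead_ii, float)
    return {
        "III": lead_ii - lead_i,
        "aVR": -(lead_i + lead_ii) / 2.0,
        "aVL": lead_i - lead_ii / 2.0,
        "aVF": lead_ii - lead_i / 2.0,
    }
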