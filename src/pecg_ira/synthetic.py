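"""Synthetic 12-lead ECG / VCG cohorts with class-dependent morphology.

The generator models the cardiac dipole as a sum of Gaussian wave
deflections (P, Q, R, S, T) along fixed 3-D directions — the same
closed-form family used by ECGSYN-style simulators — with beat-to-beat
RR jitter. The 12-lead ECG is the forward Dower projection of that
dipole, plus independent per-channel measurement noise; at zero noise
the ECG/VCG pair is exactly consistent with the linear lead model.

Disease classes perturb the dipole in three clinically motivated ways:
a rigid rotation of the electrical axis (20-90 degrees for infarct
classes), an ST-segment baseline shift, and T-wave inversion. Each
infarct-related-artery class carries its own (rotation, ST, T-flip)
signature so that downstream classifiers have a recoverable ground
truth; the healthy class is unperturbed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .records import ECGRecord, VCGRecord, PaperECGSignals
from .records import LAYOUT_COLUMNS, COLUMN_DURATION, RECORD_DURATION, LEAD_NAMES
from .vcg import vcg_to_ecg

CLASS_LABELS = ("HC", "E", "LAD", "LCX", "RCA")
MI_LABELS = ("E", "LAD", "LCX", "RCA")


@dataclass(frozen=True)
class Wave:
    """One Gaussian deflection of the dipole loop."""

    amplitude: float      # mV, signed
    width: float          # s (Gaussian sigma)
    offset: float         # s relative to the R peak
    azimuth: float        # direction of the deflection, degrees
    elevation: float      # degrees

    def direction(self) -> np.ndarray:
        az, el = np.radians(self.azimuth), np.radians(self.elevation)
        return np.array(
            [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
        )


#: Default P-QRS-T morphology. Directions are chosen so the loop spans
#: several octants: positive deflections point into the (+,+) X-Y
#: quadrant at mixed elevations, Q and S point opposite.
DEFAULT_WAVES = {
    "P": Wave(0.12, 0.025, -0.20, 65.0, 25.0),
    "Q": Wave(-0.10, 0.010, -0.035, 40.0, 10.0),
    "R": Wave(1.00, 0.012, 0.0, 30.0, 20.0),
    "S": Wave(-0.18, 0.010, 0.035, 10.0, -35.0),
    "T": Wave(0.35, 0.055, 0.28, 50.0, 5.0),
}


@dataclass
class DipoleParams:
    """Configuration of the rotating-dipole beat model."""

    waves: dict[str, Wave] = field(default_factory=lambda: dict(DEFAULT_WAVES))
    hr_mean: float = 72.0        # bpm
    hr_sd: float = 2.0           # bpm, beat-period jitter source
    azimuth: float = 0.0         # extra rigid rotation of the whole loop, deg
    elevation: float = 0.0
    fs: float = 500.0            # Hz
    duration: float = RECORD_DURATION  # s

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.hr_mean <= 0:
            raise ValueError("heart-rate mean must be positive")
        for name, w in self.waves.items():
            if w.width <= 0:
                raise ValueError(f"wave {name}: width must be positive")


@dataclass
class ClassPerturbation:
    """Morphology perturbation implementing one diagnostic class."""

    label: str
    rotation_deg: float = 0.0    # electrical-axis deviation
    st_offset: float = 0.0       # mV, plateau between S and T
    t_flip: bool = False
    noise_sd: float = 0.01       # mV, per-channel measurement noise (10 uV RMS)

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(
                f"unknown class {self.label!r}; expected one of {CLASS_LABELS}"
            )
        if self.label == "HC":
            if self.rotation_deg != 0:
                raise ValueError("healthy class must have zero axis rotation")
        elif not (20.0 <= abs(self.rotation_deg) <= 90.0):
            raise ValueError(
                "infarct classes rotate the electrical axis by 20-90 degrees"
            )


#: Per-class perturbation defaults. The three artery classes get distinct
#: (rotation, ST, T-flip) signatures; E is synthesized per record as one
#: of the artery signatures at half magnitude (clipped to the 20-degree
#: floor), reflecting "location not discernible".
CLASS_PERTURBATIONS = {
    "HC": ClassPerturbation("HC", 0.0, 0.0, False),
    "LAD": ClassPerturbation("LAD", 35.0, 0.20, True),
    "LCX": ClassPerturbation("LCX", 60.0, -0.15, False),
    "RCA": ClassPerturbation("RCA", 85.0, 0.10, True),
}


def _e_perturbation(rng: np.random.Generator) -> ClassPerturbation:
    base = CLASS_PERTURBATIONS[rng.choice(["LAD", "LCX", "RCA"])]
    return ClassPerturbation(
        "E",
        rotation_deg=max(20.0, base.rotation_deg / 2.0),
        st_offset=base.st_offset / 2.0,
        t_flip=base.t_flip,
        noise_sd=base.noise_sd,
    )


def perturbation_for(label: str, rng: np.random.Generator) -> ClassPerturbation:
    if label == "E":
        return _e_perturbation(rng)
    try:
        return CLASS_PERTURBATIONS[label]
    except KeyError:
        raise ValueError(f"unknown class label {label!r}") from None


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * k + (1 - np.cos(a)) * (k @ k)


def _axis_rotation(r_direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotation that tilts the mean electrical axis by exactly ``angle_deg``.

    The rotation axis is chosen perpendicular to the R-wave direction so
    the angle between the healthy and perturbed axes equals the requested
    deviation.
    """
    if angle_deg == 0:
        return np.eye(3)
    z = np.array([0.0, 0.0, 1.0])
    axis = np.cross(r_direction, z)
    if np.linalg.norm(axis) < 1e-12:  # R along z: any perpendicular works
        axis = np.array([1.0, 0.0, 0.0])
    return _rotation_about(axis, angle_deg)


def _st_window(t: np.ndarray) -> np.ndarray:
    """Smooth plateau over the ST segment (between S end and T onset)."""
    tau = 0.012
    rise = 1.0 / (1.0 + np.exp(-(t - 0.055) / tau))
    fall = 1.0 / (1.0 + np.exp(-(t - 0.215) / tau))
    return rise - fall


def r_peak_times(params: DipoleParams, rng: np.random.Generator) -> np.ndarray:
    """Ground-truth R-peak times with truncated-Gaussian RR jitter."""
    period = 60.0 / params.hr_mean
    sd = period * params.hr_sd / params.hr_mean  # bpm jitter -> period jitter
    times = []
    t = period / 2.0
    while t < params.duration:
        times.append(t)
        jitter = rng.normal(0.0, sd) if sd > 0 else 0.0
        jitter = float(np.clip(jitter, -3 * sd, 3 * sd)) if sd > 0 else 0.0
        t += period + jitter
    return np.array(times)


def generate_dipole_record(
    params: DipoleParams,
    perturbation: ClassPerturbation,
    seed: int,
) -> tuple[ECGRecord, VCGRecord]:
    """Simulate one beat train and return the (ECG, VCG) pair.

    The ECG is the forward Dower projection of the dipole trajectory;
    with zero noise the pair satisfies the linear lead model exactly,
    otherwise independent per-channel measurement noise is added to
    both recordings.
    """
    rng = np.random.default_rng(seed)
    n = int(round(params.duration * params.fs))
    t = np.arange(n) / params.fs

    waves = dict(params.waves)
    if perturbation.t_flip:
        w = waves["T"]
        waves["T"] = replace(w, amplitude=-w.amplitude)

    base_rot = _rotation_about(np.array([0.0, 0.0, 1.0]), params.azimuth) @ (
        _rotation_about(np.array([0.0, 1.0, 0.0]), -params.elevation)
    )
    r_dir = base_rot @ waves["R"].direction()
    rot = _axis_rotation(r_dir, perturbation.rotation_deg) @ base_rot

    directions = {name: rot @ w.direction() for name, w in waves.items()}

    xyz = np.zeros((n, 3))
    peaks = r_peak_times(params, rng)
    for tk in peaks:
        local = t - tk
        # only evaluate near the beat to keep cost linear in duration
        sel = np.abs(local) < 0.6
        lt = local[sel]
        beat = np.zeros((lt.size, 3))
        for name, w in waves.items():
            beat += (
                w.amplitude
                * np.exp(-((lt - w.offset) ** 2) / (2 * w.width**2))
            )[:, None] * directions[name]
        if perturbation.st_offset != 0.0:
            beat += (perturbation.st_offset * _st_window(lt))[:, None] * directions["R"]
        xyz[sel] += beat

    vcg = VCGRecord(xyz[:, 0], xyz[:, 1], xyz[:, 2], fs=params.fs)
    ecg = vcg_to_ecg(vcg)
    if perturbation.noise_sd > 0:
        # measurement noise is per electrode/channel, independent across
        # leads (not a coherent dipole perturbation)
        for lead in ecg.leads:
            ecg.leads[lead] = ecg.leads[lead] + rng.normal(
                0.0, perturbation.noise_sd, size=n
            )
        vcg = VCGRecord(
            xyz[:, 0] + rng.normal(0.0, perturbation.noise_sd, size=n),
            xyz[:, 1] + rng.normal(0.0, perturbation.noise_sd, size=n),
            xyz[:, 2] + rng.normal(0.0, perturbation.noise_sd, size=n),
            fs=params.fs,
        )
    return ecg, vcg


@dataclass
class SyntheticCohort:
    """A labeled collection of synthetic (ECG, VCG) record pairs."""

    records: list[tuple[ECGRecord, VCGRecord, str]]
    seed: int
    counts: dict[str, int]

    def __len__(self) -> int:
        return len(self.records)

    @property
    def labels(self) -> list[str]:
        return [label for _, _, label in self.records]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = []
        for i, (ecg, vcg, label) in enumerate(self.records):
            ecg_path = directory / f"rec{i:03d}_ecg.csv"
            vcg_path = directory / f"rec{i:03d}_vcg.csv"
            ecg.to_csv(ecg_path)
            vcg.to_csv(vcg_path)
            manifest.append(
                {
                    "index": i,
                    "label": label,
                    "ecg": ecg_path.name,
                    "vcg": vcg_path.name,
                    "fs": ecg.fs,
                }
            )
        (directory / "manifest.json").write_text(
            json.dumps({"seed": self.seed, "records": manifest}, indent=2)
        )


def make_cohort(
    n_per_class: dict[str, int],
    params: DipoleParams | None = None,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a labeled cohort with exactly the requested class counts."""
    params = params or DipoleParams()
    for label, count in n_per_class.items():
        if label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {label!r}")
        if count < 0:
            raise ValueError("class counts must be non-negative")
    root = np.random.SeedSequence(seed)
    records = []
    counts = {k: int(v) for k, v in n_per_class.items()}
    labels = [lab for lab in CLASS_LABELS if counts.get(lab, 0) > 0]
    children = iter(root.spawn(sum(counts.get(lab, 0) for lab in labels)))
    for label in labels:
        for _ in range(counts[label]):
            child = next(children)
            pert_rng = np.random.default_rng(child)
            pert = perturbation_for(label, pert_rng)
            rec_seed = int(child.generate_state(1)[0] % (2**31))
            ecg, vcg = generate_dipole_record(params, pert, rec_seed)
            records.append((ecg, vcg, label))
    return SyntheticCohort(records=records, seed=seed, counts=counts)


def mask_to_paper_layout(
    record: ECGRecord, reference_lead: str = "II"
) -> PaperECGSignals:
    """Reduce a full 10-s 12-lead record to what a 3x4 printout shows.

    Leads I/II/III keep [0, 2.5) s, aVR/aVL/aVF keep [2.5, 5) s, V1-V3
    keep [5, 7.5) s and V4-V6 keep [7.5, 10) s; the rhythm lead
    additionally keeps its full 10 s.
    """
    record.require_leads(LEAD_NAMES)
    if record.duration < RECORD_DURATION - 1e-9:
        raise ValueError("record must cover at least 10 s")
    fs = record.fs
    win = int(round(COLUMN_DURATION * fs))
    segments, offsets = {}, {}
    for leads, offset in LAYOUT_COLUMNS.items():
        start = int(round(offset * fs))
        for lead in leads:
            segments[lead] = np.asarray(record.leads[lead], float)[
                start : start + win
            ].copy()
            offsets[lead] = offset
    n_ref = int(round(RECORD_DURATION * fs))
    reference = np.asarray(record.leads[reference_lead], float)[:n_ref].copy()
    return PaperECGSignals(
        segments=segments,
        offsets=offsets,
        reference_lead=reference_lead,
        reference_signal=reference,
        fs=fs,
    )
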