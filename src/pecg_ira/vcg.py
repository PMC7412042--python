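"""ECG <-> VCG linear transforms.

The vectorcardiogram is a 3-channel representation of the cardiac dipole.
It relates to the 8 independent ECG leads (I, II, V1-V6) through fixed
affine maps: the Dower matrix projects the dipole onto the leads, and the
inverse Dower matrix recovers the dipole from them. The inverse Dower
coefficients used here are the standard published values; any 3x8 matrix
can be supplied instead (e.g. an MI-specific empirical transform) via
``TransformMatrix``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ECGRecord, INDEPENDENT_LEADS, VCGRecord

#: Dower matrix: rows = leads (I, II, V1..V6), columns = (X, Y, Z).
#: ECG(lead) = D @ (X, Y, Z).
DOWER_MATRIX = np.array(
    [
        [0.632, -0.235, 0.059],   # I
        [0.235, 1.066, -0.132],   # II
        [-0.515, 0.157, -0.917],  # V1
        [0.044, 0.164, -1.387],   # V2
        [0.882, 0.098, -1.277],   # V3
        [1.213, 0.127, -0.601],   # V4
        [1.125, 0.127, -0.086],   # V5
        [0.831, 0.076, 0.230],    # V6
    ]
)

#: Inverse Dower matrix: rows = (X, Y, Z), columns = leads (I, II, V1..V6).
INVERSE_DOWER = np.array(
    [
        [0.156, -0.010, -0.172, -0.074, 0.122, 0.231, 0.239, 0.194],
        [-0.227, 0.887, 0.057, -0.019, -0.106, -0.022, 0.041, 0.048],
        [0.022, 0.102, -0.229, -0.310, -0.246, -0.063, 0.055, 0.108],
    ]
)


@dataclass
class TransformMatrix:
    """A named 3x8 linear map from (I, II, V1..V6) to (X, Y, Z)."""

    coefficients: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, float)
        if self.coefficients.shape != (3, 8):
            raise ValueError("transform matrix must be 3x8")
        if not np.all(np.isfinite(self.coefficients)):
            raise ValueError("transform matrix must be finite")
        if np.linalg.matrix_rank(self.coefficients) < 3:
            raise ValueError("transform matrix must have full row rank")


#: Registry of built-in transforms, keyed by name.
TRANSFORMS = {"inverse_dower": TransformMatrix(INVERSE_DOWER, "inverse_dower")}


def get_transform(name_or_matrix) -> TransformMatrix:
    if isinstance(name_or_matrix, TransformMatrix):
        return name_or_matrix
    if isinstance(name_or_matrix, str):
        try:
            return TRANSFORMS[name_or_matrix]
        except KeyError:
            raise KeyError(
                f"unknown transform {name_or_matrix!r}; "
                f"available: {sorted(TRANSFORMS)}"
            ) from None
    return TransformMatrix(np.asarray(name_or_matrix, float))


def ecg_to_vcg(record: ECGRecord, matrix=None) -> VCGRecord:
    """Project a 12-lead ECG onto the 3 VCG channels, sample-wise.

    Only the 8 independent leads are consumed; III/aVR/aVL/aVF are
    redundant combinations of I and II and are ignored, which keeps the
    transform consistent when the redundant leads were reconstructed
    independently.
    """
    tm = get_transform(matrix) if matrix is not None else TRANSFORMS["inverse_dower"]
    record.require_leads(INDEPENDENT_LEADS)
    stacked = np.vstack([np.asarray(record.leads[l], float) for l in INDEPENDENT_LEADS])
    xyz = tm.coefficients @ stacked
    return VCGRecord(xyz[0], xyz[1], xyz[2], fs=record.fs)


def vcg_to_ecg(vcg: VCGRecord, lead_matrix: np.ndarray | None = None) -> ECGRecord:
    """Forward-project a VCG to a full 12-lead ECG via the Dower matrix.

    The 8 independent leads are the matrix projection; III and the
    augmented leads follow from the Einthoven/Goldberger relations.
    """
    from .records import derive_limb_leads

    mat = DOWER_MATRIX if lead_matrix is None else np.asarray(lead_matrix, float)
    ecg8 = mat @ vcg.as_array().T
    leads = dict(zip(INDEPENDENT_LEADS, ecg8))
    leads.update(derive_limb_leads(leads["I"], leads["II"]))
    return ECGRecord(leads, fs=vcg.fs)
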