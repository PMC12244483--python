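"""Vectorcardiogram construction and electrical axis definitions.

A median-beat 12-lead ECG carries 8 independent leads (I, II, V1-V6; the
remaining limb leads are linear combinations). The Kors regression matrix
maps those 8 leads to the three orthogonal Frank leads (X left, Y inferior,
Z posterior). The Frank system is then re-expressed in the DICOM LPS patient
frame so electrical directions are directly comparable with mesh-derived
anatomical directions. The QRS-windowed segment of the VCG, re-origined at
QRS onset, is the QRS loop from which four electrical axis definitions are
computed:

``maxQRS``
    Direction of the dipole sample with the largest magnitude.
``meanQRS``
    Component-wise mean dipole over the loop.
``vavgQRS``
    Arc-length (dipole-velocity) weighted mean dipole; insensitive to the
    oversampling of slow loop segments at constant sampling frequency.
``eig1QRS``
    First right singular vector of the mean-centered loop (dominant
    propagation direction), sign-matched to meanQRS.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from cardaxes.errors import (
    ConfigError,
    DegenerateGeometryError,
    FormatError,
    FrameError,
    UsageError,
)

#: The 8 independent leads, in Kors column order.
LEADS = ("I", "II", "V1", "V2", "V3", "V4", "V5", "V6")

ELECTRICAL_METHODS = ("maxQRS", "meanQRS", "vavgQRS", "eig1QRS")

#: Frank (X, Y, Z) -> LPS (x, y, z): Frank X points left, Y inferior,
#: Z posterior, so x_LPS = X, y_LPS = Z, z_LPS = -Y.
FRANK_TO_LPS = np.array(
    [
        [1.0, 0.0, 0.0],
        [0.0, 0.0, 1.0],
        [0.0, -1.0, 0.0],
    ]
)


@dataclass
class MedianBeatECG:
    """Median beat of the 8 independent leads, in microvolts.

    ``qrs_onset``/``qrs_offset`` index the half-open QRS window
    [onset, offset) in samples.
    """

    samples: dict[str, np.ndarray]
    fs: float = 500.0
    qrs_onset: int = 0
    qrs_offset: int = 0
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        missing = [l for l in LEADS if l not in self.samples]
        if missing:
            raise FormatError(f"missing leads: {missing}")
        lengths = {len(np.asarray(self.samples[l])) for l in LEADS}
        if len(lengths) != 1:
            raise FormatError("all leads must have the same length")
        self.samples = {l: np.asarray(self.samples[l], dtype=float) for l in LEADS}
        n = lengths.pop()
        if self.fs <= 0:
            raise FormatError("sampling frequency must be positive")
        if not (0 <= self.qrs_onset < self.qrs_offset <= n):
            raise FormatError(
                f"invalid QRS window [{self.qrs_onset}, {self.qrs_offset}) "
                f"for length {n}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.samples["I"])

    def lead_matrix(self) -> np.ndarray:
        """(8, n) matrix in Kors lead order."""
        return np.vstack([self.samples[l] for l in LEADS])


@dataclass
class Vectorcardiogram:
    """Three-component dipole time series (microvolts) with a frame tag."""

    vx: np.ndarray
    vy: np.ndarray
    vz: np.ndarray
    fs: float
    qrs_onset: int
    qrs_offset: int
    frame: str = "FRANK"
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.vx = np.asarray(self.vx, dtype=float)
        self.vy = np.asarray(self.vy, dtype=float)
        self.vz = np.asarray(self.vz, dtype=float)
        if not (len(self.vx) == len(self.vy) == len(self.vz)):
            raise FormatError("VCG components must have equal length")
        if self.frame not in ("FRANK", "LPS"):
            raise FrameError(f"unknown frame tag {self.frame!r}")

    def as_matrix(self) -> np.ndarray:
        """(n, 3) stacked components."""
        return np.column_stack([self.vx, self.vy, self.vz])


@dataclass
class QRSLoop:
    """Ordered 3D dipole samples re-origined so points[0] == (0, 0, 0)."""

    points: np.ndarray
    fs: float
    subject_id: str = "unknown"

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise FormatError("loop points must be (n, 3)")
        if len(self.points) < 3:
            raise DegenerateGeometryError("QRS loop needs at least 3 samples")
        if np.any(self.points[0] != 0.0):
            raise FormatError("loop must start exactly at the origin")


def kors_matrix(path: str | Path | None = None) -> np.ndarray:
    """Load the 3x8 Kors regression matrix (rows X, Y, Z; columns I..V6).

    The coefficients ship as a package data file so they are configuration,
    not code; an alternative transform (e.g. inverse Dower) can be supplied
    as a CSV with the same layout.
    """
    if path is None:
        ref = importlib.resources.files("cardaxes.data") / "kors_coefficients.csv"
        with importlib.resources.as_file(ref) as p:
            table = pd.read_csv(p, index_col=0)
    else:
        table = pd.read_csv(path, index_col=0)
    if list(table.columns) != list(LEADS) or list(table.index) != ["X", "Y", "Z"]:
        raise ConfigError(
            "coefficient table must have rows X,Y,Z and columns I,II,V1..V6"
        )
    return table.to_numpy(dtype=float)


def qrs_amplitude(ecg: MedianBeatECG, lead: str, baseline: str = "onset") -> float:
    """Maximum absolute deflection from the isoelectric baseline inside QRS.

    ``baseline="onset"`` uses the sample value at QRS onset;
    ``baseline="pre40ms"`` uses the median of the 40 ms preceding onset
    (clipped to the record start).
    """
    if lead not in ecg.samples:
        raise UsageError(f"lead {lead!r} not present")
    x = ecg.samples[lead]
    if baseline == "onset":
        base = x[ecg.qrs_onset]
    elif baseline == "pre40ms":
        k = max(ecg.qrs_onset - int(round(0.040 * ecg.fs)), 0)
        seg = x[k : ecg.qrs_onset]
        base = float(np.median(seg)) if len(seg) else x[ecg.qrs_onset]
    else:
        raise UsageError(f"unknown baseline rule {baseline!r}")
    window = x[ecg.qrs_onset : ecg.qrs_offset]
    return float(np.max(np.abs(window - base)))


def kors_transform(
    ecg: MedianBeatECG, coefficients: np.ndarray | None = None
) -> Vectorcardiogram:
    """Linear 8-lead -> Frank-system VCG transform (no filtering)."""
    M = kors_matrix() if coefficients is None else np.asarray(coefficients, float)
    if M.shape != (3, 8):
        raise ConfigError(f"coefficient matrix must be 3x8, got {M.shape}")
    xyz = M @ ecg.lead_matrix()
    return Vectorcardiogram(
        vx=xyz[0],
        vy=xyz[1],
        vz=xyz[2],
        fs=ecg.fs,
        qrs_onset=ecg.qrs_onset,
        qrs_offset=ecg.qrs_offset,
        frame="FRANK",
        subject_id=ecg.subject_id,
    )


def frank_to_lps(
    vcg: Vectorcardiogram, mapping: np.ndarray | None = None
) -> Vectorcardiogram:
    """Re-express a Frank-frame VCG in the DICOM LPS patient frame.

    The default signed permutation assumes Frank X = left, Y = inferior,
    Z = posterior; ``mapping`` may override it with any orthogonal 3x3
    matrix applied to Frank (X, Y, Z) column vectors.
    """
    if vcg.frame != "FRANK":
        raise FrameError(f"expected frame 'FRANK', got {vcg.frame!r}")
    R = FRANK_TO_LPS if mapping is None else np.asarray(mapping, dtype=float)
    if R.shape != (3, 3) or not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
        raise ConfigError("frame mapping must be an orthogonal 3x3 matrix")
    xyz = R @ vcg.as_matrix().T
    return replace(vcg, vx=xyz[0], vy=xyz[1], vz=xyz[2], frame="LPS")


def extract_qrs_loop(vcg: Vectorcardiogram) -> QRSLoop:
    """Slice [onset, offset) and re-origin at the onset sample."""
    if vcg.frame != "LPS":
        raise FrameError("QRS loop must be extracted from an LPS-frame VCG")
    if vcg.qrs_offset - vcg.qrs_onset < 3:
        raise DegenerateGeometryError("QRS window shorter than 3 samples")
    pts = vcg.as_matrix()[vcg.qrs_onset : vcg.qrs_offset]
    pts = pts - pts[0]
    pts[0] = 0.0
    return QRSLoop(points=pts, fs=vcg.fs, subject_id=vcg.subject_id)


def _arc_length_weights(points: np.ndarray, fs: float) -> np.ndarray:
    """Local dipole speed per sample: central differences inside,
    one-sided at the ends. Equivalent (up to the constant fs) to the arc
    length attributed to each sample."""
    n = len(points)
    w = np.empty(n)
    w[1:-1] = np.linalg.norm(points[2:] - points[:-2], axis=1) / 2.0
    w[0] = np.linalg.norm(points[1] - points[0])
    w[-1] = np.linalg.norm(points[-1] - points[-2])
    return w * fs


def electrical_axis(loop: QRSLoop, method: str) -> "CardiacAxis":
    """Compute one electrical axis definition from a QRS loop.

    Only the unit direction of each candidate dipole is retained; the origin
    is the loop origin (QRS onset).
    """
    from cardaxes.mesh_anatomy import CardiacAxis  # shared axis container

    pts = loop.points
    norms = np.linalg.norm(pts, axis=1)
    if norms.max() <= 0:
        raise DegenerateGeometryError("degenerate loop: all samples at origin")

    if method == "maxQRS":
        candidate = pts[int(np.argmax(norms))]  # argmax -> earliest tie wins
    elif method == "meanQRS":
        candidate = pts.mean(axis=0)
    elif method == "vavgQRS":
        w = _arc_length_weights(pts, loop.fs)
        if w.sum() <= 0:
            raise DegenerateGeometryError("zero total arc length")
        candidate = (w[:, None] * pts).sum(axis=0) / w.sum()
    elif method == "eig1QRS":
        centered = pts - pts.mean(axis=0)
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        candidate = vt[0]
        mean_dir = pts.mean(axis=0)
        if np.linalg.norm(mean_dir) > 0 and float(candidate @ mean_dir) < 0:
            candidate = -candidate
    else:
        raise UsageError(
            f"unknown electrical method {method!r}; expected one of {ELECTRICAL_METHODS}"
        )

    nrm = np.linalg.norm(candidate)
    if nrm < 1e-12:
        raise DegenerateGeometryError(f"{method} direction has zero norm")
    return CardiacAxis(
        direction=candidate / nrm,
        origin=np.zeros(3),
        method=method,
        subject_id=loop.subject_id,
        frame="LPS",
    )


def load_ecg_table(path: str | Path, subject_id: str | None = None) -> MedianBeatECG:
    """Read a median-beat ECG from delimited text.

    Layout: comment header lines ``# fs=500``, ``# qrs_onset=..``,
    ``# qrs_offset=..`` followed by a CSV with one column per lead.
    """
    path = Path(path)
    meta: dict[str, float] = {}
    header_lines = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            header_lines += 1
            key, _, value = line[1:].strip().partition("=")
            meta[key.strip()] = float(value)
    required = {"fs", "qrs_onset", "qrs_offset"}
    if not required <= set(meta):
        raise FormatError(f"{path} header missing {sorted(required - set(meta))}")
    table = pd.read_csv(path, skiprows=header_lines)
    missing = [l for l in LEADS if l not in table.columns]
    if missing:
        raise FormatError(f"{path} missing lead columns {missing}")
    return MedianBeatECG(
        samples={l: table[l].to_numpy(dtype=float) for l in LEADS},
        fs=meta["fs"],
        qrs_onset=int(meta["qrs_onset"]),
        qrs_offset=int(meta["qrs_offset"]),
        subject_id=subject_id or path.stem,
    )


def save_ecg_table(ecg: MedianBeatECG, path: str | Path) -> Path:
    """Write a median-beat ECG in the format read by :func:`load_ecg_table`."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# fs={ecg.fs}\n")
        fh.write(f"# qrs_onset={ecg.qrs_onset}\n")
        fh.write(f"# qrs_offset={ecg.qrs_offset}\n")
        pd.DataFrame({l: ecg.samples[l] for l in LEADS}).to_csv(fh, index=False)
    return path
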