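"""Reading, writing and reducing 1D SAXS profiles and frame series.

Profiles are plain-text 2-3 column files (q, I[, sigma]) with '#' comments;
frame series are described by a CSV manifest with header ``time_s,path``.
q is carried in nm^-1 internally (q = (4*pi/lambda)*sin(theta), with
2*theta the scattering angle); Angstrom^-1 input is converted on read.

No interpolation is performed anywhere: buffer subtraction requires sample
and buffer to share a q grid, because resampling would silently correlate
the counting noise between neighbouring points.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScatteringFrame",
    "KratkyProfile",
    "SaxsFormatError",
    "GridMismatchError",
    "read_profile",
    "write_profile",
    "read_series",
    "subtract_buffer",
    "mask_q",
    "to_kratky",
    "from_kratky",
]

logger = logging.getLogger(__name__)

#: Instrument q window, nm^-1 (PILATUS at ~1 m, lambda = 0.1 nm).
DEFAULT_Q_WINDOW = (0.103, 3.26)


class SaxsFormatError(ValueError):
    """A profile or manifest file violates the expected plain-text format."""


class GridMismatchError(ValueError):
    """Two profiles that must share a q grid do not."""


@dataclass(frozen=True)
class ScatteringFrame:
    """One azimuthally averaged 1D SAXS profile.

    Attributes
    ----------
    q : ndarray
        Scattering-vector magnitudes, nm^-1, strictly increasing, > 0.
    intensity : ndarray
        Scattered intensity, arbitrary units (may be negative after buffer
        subtraction).
    sigma : ndarray or None
        Per-point 1-sigma uncertainties, same units as intensity.
    time : float
        Seconds since first injection.
    meta : dict
        Free-form metadata (wavelength_nm, detector distance, labels).
    """

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None
    time: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        q = np.asarray(self.q, dtype=float)
        i = np.asarray(self.intensity, dtype=float)
        object.__setattr__(self, "q", q)
        object.__setattr__(self, "intensity", i)
        if q.ndim != 1 or q.size == 0:
            raise SaxsFormatError("q must be a non-empty 1D array")
        if np.any(q <= 0) or np.any(np.diff(q) <= 0):
            raise SaxsFormatError("q must be strictly increasing and positive")
        if i.shape != q.shape:
            raise SaxsFormatError("intensity length does not match q")
        if self.sigma is not None:
            s = np.asarray(self.sigma, dtype=float)
            object.__setattr__(self, "sigma", s)
            if s.shape != q.shape:
                raise SaxsFormatError("sigma length does not match q")
            if np.any(s <= 0):
                raise SaxsFormatError("sigma must be positive where present")
        if self.time < 0:
            raise SaxsFormatError("time must be non-negative")

    def __len__(self) -> int:
        return self.q.size


@dataclass(frozen=True)
class KratkyProfile:
    """A profile in Kratky representation, y = q^2 * I(q)."""

    q: np.ndarray
    y: np.ndarray
    sigma_y: np.ndarray | None = None
    time: float = 0.0

    def __len__(self) -> int:
        return self.q.size


def to_kratky(frame: ScatteringFrame) -> KratkyProfile:
    """Kratky transform: y = q^2 * I, sigma_y = q^2 * sigma."""
    q2 = frame.q * frame.q
    sy = q2 * frame.sigma if frame.sigma is not None else None
    return KratkyProfile(q=frame.q, y=q2 * frame.intensity, sigma_y=sy, time=frame.time)


def from_kratky(profile: KratkyProfile, meta: dict | None = None) -> ScatteringFrame:
    """Invert the Kratky transform back to I(q); exact for q > 0."""
    q2 = profile.q * profile.q
    sig = profile.sigma_y / q2 if profile.sigma_y is not None else None
    return ScatteringFrame(
        q=profile.q, intensity=profile.y / q2, sigma=sig,
        time=profile.time, meta=dict(meta or {}),
    )


def _parse_columns(path: Path) -> tuple[list[np.ndarray], list[int]]:
    rows, linenos = [], []
    ncols = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace(",", " ").split()
        try:
            vals = [float(p) for p in parts]
        except ValueError as exc:
            raise SaxsFormatError(f"{path}:{lineno}: non-numeric field") from exc
        if len(vals) < 2:
            raise SaxsFormatError(f"{path}:{lineno}: need at least 2 columns")
        if ncols is None:
            ncols = len(vals)
        elif len(vals) != ncols:
            raise SaxsFormatError(f"{path}:{lineno}: inconsistent column count")
        rows.append(vals)
        linenos.append(lineno)
    if not rows:
        raise SaxsFormatError(f"{path}: no data rows")
    cols = [np.array(c) for c in zip(*rows)]
    return cols, linenos


def read_profile(
    path: str | Path,
    units: str = "nm",
    time: float = 0.0,
    meta: dict | None = None,
) -> ScatteringFrame:
    """Read a 2-3 column plain-text profile (q, I[, sigma]).

    Parameters
    ----------
    path : path
        Whitespace- or comma-separated text file; '#' starts a comment.
    units : {"nm", "angstrom"}
        Units of the q column. Angstrom^-1 values are multiplied by 10.
        Units are never guessed from the data.
    """
    path = Path(path)
    cols, linenos = _parse_columns(path)
    q = cols[0]
    if units == "angstrom":
        q = q * 10.0
    elif units != "nm":
        raise ValueError(f"unknown q units {units!r}; use 'nm' or 'angstrom'")
    bad = np.nonzero(np.diff(q) <= 0)[0]
    if bad.size:
        raise SaxsFormatError(
            f"{path}:{linenos[bad[0] + 1]}: q not strictly increasing"
        )
    sigma = cols[2] if len(cols) >= 3 else None
    return ScatteringFrame(
        q=q, intensity=cols[1], sigma=sigma, time=time, meta=dict(meta or {})
    )


def write_profile(frame: ScatteringFrame, path: str | Path) -> Path:
    """Write a profile as whitespace-separated text at full repr precision."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# time_s = {frame.time!r}\n")
        for key, val in sorted(frame.meta.items()):
            fh.write(f"# {key} = {val}\n")
        fh.write("# q_nm^-1 intensity" + (" sigma\n" if frame.sigma is not None else "\n"))
        for i in range(len(frame)):
            row = f"{float(frame.q[i])!r} {float(frame.intensity[i])!r}"
            if frame.sigma is not None:
                row += f" {float(frame.sigma[i])!r}"
            fh.write(row + "\n")
    return path


def read_series(manifest: str | Path, units: str = "nm") -> list[ScatteringFrame]:
    """Read a frame series from a ``time_s,path`` CSV manifest.

    Frames are returned sorted by time. Paths are resolved relative to the
    manifest location. A warning is logged when frame spacing deviates more
    than 10% from the modal interval (the nominal acquisition cadence).
    """
    manifest = Path(manifest)
    table = pd.read_csv(manifest)
    if not {"time_s", "path"}.issubset(table.columns):
        raise SaxsFormatError(f"{manifest}: manifest needs columns time_s,path")
    if table["time_s"].duplicated().any():
        raise SaxsFormatError(f"{manifest}: duplicate timestamps")
    table = table.sort_values("time_s")
    frames = []
    for _, row in table.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = manifest.parent / p
        if not p.exists():
            raise FileNotFoundError(f"{manifest}: missing profile {p}")
        frames.append(read_profile(p, units=units, time=float(row["time_s"])))
    times = np.array([f.time for f in frames])
    if len(times) > 2:
        dt = np.diff(times)
        rounded = np.round(dt, 6)
        vals, counts = np.unique(rounded, return_counts=True)
        modal = vals[np.argmax(counts)]
        if modal > 0 and np.any(np.abs(dt - modal) > 0.1 * modal):
            logger.warning(
                "frame spacing deviates >10%% from modal interval %.3g s", modal
            )
    return frames


def subtract_buffer(
    sample: ScatteringFrame,
    buffer: ScatteringFrame,
    scale: float = 1.0,
) -> ScatteringFrame:
    """Subtract a (scaled) buffer profile from a sample profile.

    The two profiles must share a q grid to 1e-9 relative tolerance; there
    is deliberately no interpolation fallback. Uncertainties combine in
    quadrature. Negative differences are retained (clipping would bias the
    Kratky-space constant) and their count is logged.
    """
    if scale < 0:
        raise ValueError("scale must be non-negative")
    if len(sample) != len(buffer) or not np.allclose(
        sample.q, buffer.q, rtol=1e-9, atol=0.0
    ):
        raise GridMismatchError("sample and buffer q grids differ; no interpolation")
    intensity = sample.intensity - scale * buffer.intensity
    sigma = None
    if sample.sigma is not None and buffer.sigma is not None:
        sigma = np.hypot(sample.sigma, scale * buffer.sigma)
    elif sample.sigma is not None:
        sigma = sample.sigma.copy()
    n_neg = int(np.sum(intensity < 0))
    if n_neg:
        logger.info("buffer subtraction produced %d negative intensities", n_neg)
    return replace(sample, intensity=intensity, sigma=sigma)


def mask_q(
    frame: ScatteringFrame,
    q_min: float = DEFAULT_Q_WINDOW[0],
    q_max: float = DEFAULT_Q_WINDOW[1],
) -> ScatteringFrame:
    """Restrict a frame to q_min <= q <= q_max (default: instrument window)."""
    if not q_min < q_max:
        raise ValueError("require q_min < q_max")
    keep = (frame.q >= q_min) & (frame.q <= q_max)
    if not keep.any():
        raise ValueError(f"no points in q window [{q_min}, {q_max}]")
    return replace(
        frame,
        q=frame.q[keep],
        intensity=frame.intensity[keep],
        sigma=frame.sigma[keep] if frame.sigma is not None else None,
    )
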