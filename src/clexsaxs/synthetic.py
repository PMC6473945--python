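"""Synthetic time-resolved SAXS frame series for pipeline validation.

Emulates the acquisition that the analysis assumes: frames every 5 s over
q in [0.103, 3.26] nm^-1, an underlying structure that evolves from single
alginate chains (cross-sectional radius ~0.2 nm) to a two-component
mixture of thickened chains (~0.9 nm) and Ca2+-crosslinked junction zones
(~2.5-3.0 nm), pH-dependent final weight fractions, a smooth buffer
background and Gaussian photon-counting-like noise.

Scenario presets encode the anchor values of the three pH conditions and
the slow-acidification (GDL) control; between anchors every quantity
follows a saturating-exponential interpolant, since only anchor values are
known, not functional forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .formfactor import BrokenRodParams, intensity_model
from .saxs_io import DEFAULT_Q_WINDOW, ScatteringFrame, write_profile

__all__ = [
    "ParameterTrajectory",
    "scenario",
    "SCENARIO_NAMES",
    "render_frames",
    "write_fixture",
    "DEFAULT_NOISE_LEVEL",
    "default_q_grid",
    "default_times",
    "buffer_background",
]

#: Gives the fully gelled (pH 7.0 endpoint) frame a peak Kratky
#: signal-to-noise ratio of ~30, typical of a synchrotron exposure.
DEFAULT_NOISE_LEVEL = 0.015

#: Time of the fully equilibrated "full gel" frame: 10 h.
FULL_GEL_TIME = 36000.0


def _sat_interp(anchors: tuple[tuple[float, float], ...], t: float) -> float:
    """Piecewise saturating-exponential interpolation through anchors.

    Within each anchor interval the value approaches the right anchor as
    1 - exp(-3*s) on the normalised abscissa s, rescaled to hit both
    anchors exactly; constant extrapolation outside the anchor range.
    """
    ts = [a[0] for a in anchors]
    vs = [a[1] for a in anchors]
    if t <= ts[0]:
        return vs[0]
    if t >= ts[-1]:
        return vs[-1]
    i = int(np.searchsorted(ts, t, side="right")) - 1
    s = (t - ts[i]) / (ts[i + 1] - ts[i])
    frac = -np.expm1(-3.0 * s) / -np.expm1(-3.0)
    return vs[i] + (vs[i + 1] - vs[i]) * frac


@dataclass(frozen=True)
class ParameterTrajectory:
    """Ground-truth broken-rod parameters as functions of reaction time.

    Anchor tables are ``((t_s, value), ...)`` pairs; the second component
    exists only from ``switch_time`` onwards (before that w2 = 0 and the
    structure is a single-chain population).
    """

    rc1_anchors: tuple[tuple[float, float], ...]
    rc2_anchors: tuple[tuple[float, float], ...]
    w2_anchors: tuple[tuple[float, float], ...]
    switch_time: float = 10.0
    amplitude_anchors: tuple[tuple[float, float], ...] = ((0.0, 1.0),)
    const_anchors: tuple[tuple[float, float], ...] = ((0.0, 0.01),)
    name: str = "custom"

    def rc1(self, t: float) -> float:
        return _sat_interp(self.rc1_anchors, t)

    def rc2(self, t: float) -> float:
        return _sat_interp(self.rc2_anchors, t)

    def w2(self, t: float) -> float:
        if t < self.switch_time:
            return 0.0
        return float(np.clip(_sat_interp(self.w2_anchors, t), 0.0, 1.0))

    def amplitude(self, t: float) -> float:
        return _sat_interp(self.amplitude_anchors, t)

    def const(self, t: float) -> float:
        return _sat_interp(self.const_anchors, t)

    def params_at(self, t: float) -> BrokenRodParams:
        """Broken-rod parameter set at time t (1 or 2 components)."""
        amp = self.amplitude(t)
        w2 = self.w2(t)
        if w2 <= 0.0:
            return BrokenRodParams(
                rc1=self.rc1(t), k1=amp, const=self.const(t), n_components=1
            )
        return BrokenRodParams(
            rc1=self.rc1(t),
            rc2=self.rc2(t),
            k1=amp * (1.0 - w2),
            k2=amp * w2,
            const=self.const(t),
            n_components=2,
        )


def _preset(name, rc1, rc2, w2, amplitude=((0.0, 1.0),), switch=10.0):
    return ParameterTrajectory(
        rc1_anchors=rc1, rc2_anchors=rc2, w2_anchors=w2,
        amplitude_anchors=amplitude, switch_time=switch, name=name,
    )


# Anchor values: single chains of radius 0.2 nm initially; junction zones
# of 2.6-3.0 nm discernible from 10 s; chains thickening to ~0.9 nm in the
# equilibrated gel; w2 ~60% at two minutes rising to ~80% at 10 h (pH 7.0);
# pH 7.4 plateaus near 60% with endpoint radii 0.93/2.9 nm; pH 8.0 is weak
# (rc2 ~2.5 nm) with non-monotone fractions; the GDL control matches the
# pH 7.0 endpoint. "pH8.0-alt" carries the alternative reading of the
# pH 8.0 fractions (w2 rising to 75% instead of halving to 25%).
_SCENARIOS: dict[str, ParameterTrajectory] = {
    "pH7.0": _preset(
        "pH7.0",
        rc1=((0.0, 0.2), (120.0, 0.7), (FULL_GEL_TIME, 0.9)),
        rc2=((10.0, 2.6), (120.0, 2.8), (FULL_GEL_TIME, 2.9)),
        w2=((10.0, 0.0), (120.0, 0.6), (FULL_GEL_TIME, 0.8)),
    ),
    "pH7.4": _preset(
        "pH7.4",
        rc1=((0.0, 0.2), (180.0, 0.7), (FULL_GEL_TIME, 0.93)),
        rc2=((10.0, 2.6), (180.0, 2.9), (FULL_GEL_TIME, 2.9)),
        w2=((10.0, 0.0), (180.0, 0.6), (FULL_GEL_TIME, 0.62)),
    ),
    "pH8.0": _preset(
        "pH8.0",
        rc1=((0.0, 0.2), (180.0, 0.6), (FULL_GEL_TIME, 0.8)),
        rc2=((10.0, 2.3), (180.0, 2.5), (FULL_GEL_TIME, 2.5)),
        w2=((10.0, 0.0), (180.0, 0.5), (FULL_GEL_TIME, 0.25)),
        amplitude=((0.0, 0.3),),
    ),
    "pH8.0-alt": _preset(
        "pH8.0-alt",
        rc1=((0.0, 0.2), (180.0, 0.6), (FULL_GEL_TIME, 0.8)),
        rc2=((10.0, 2.3), (180.0, 2.5), (FULL_GEL_TIME, 2.5)),
        w2=((10.0, 0.0), (180.0, 0.5), (FULL_GEL_TIME, 0.75)),
        amplitude=((0.0, 0.3),),
    ),
    "GDL-control": _preset(
        "GDL-control",
        rc1=((0.0, 0.2), (300.0, 0.7), (FULL_GEL_TIME, 0.9)),
        rc2=((10.0, 2.6), (300.0, 2.8), (FULL_GEL_TIME, 2.9)),
        w2=((10.0, 0.0), (300.0, 0.6), (FULL_GEL_TIME, 0.8)),
    ),
}

SCENARIO_NAMES = tuple(_SCENARIOS)


def scenario(name: str) -> ParameterTrajectory:
    """Return a named preset trajectory (deterministic)."""
    try:
        return _SCENARIOS[name]
    except KeyError:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(_SCENARIOS)}"
        ) from None


def default_q_grid(n: int = 120) -> np.ndarray:
    """Uniform q grid over the instrument window [0.103, 3.26] nm^-1."""
    return np.linspace(*DEFAULT_Q_WINDOW, n)


def default_times(n_frames: int = 30, interval: float = 5.0) -> np.ndarray:
    """Acquisition cadence: n_frames at the 5 s program interval, plus the
    fully equilibrated 10 h frame."""
    return np.append(np.arange(n_frames) * interval, FULL_GEL_TIME)


def buffer_background(q: np.ndarray) -> np.ndarray:
    """Smooth buffer scattering: low-q power law plus a flat term.

    Real buffer curves are not part of the model; this stand-in makes
    buffer subtraction a meaningful step of the synthetic pipeline.
    """
    return 0.05 + 0.005 * np.asarray(q, dtype=float) ** -1.5


def render_frames(
    traj: ParameterTrajectory,
    times,
    q_grid=None,
    noise_level: float = DEFAULT_NOISE_LEVEL,
    seed: int = 0,
) -> tuple[list[ScatteringFrame], ScatteringFrame]:
    """Render noisy sample frames plus one matched buffer frame.

    Sample intensity is ``intensity_model(params(t)) + background``; noise
    is independent Gaussian per point with variance proportional to the
    total (signal + background) intensity — the Gaussian limit of photon
    counting — scaled by ``noise_level``. The sigma column carries the true
    per-point standard deviation. Fully reproducible for a given seed.

    Returns
    -------
    (frames, buffer) : list of ScatteringFrame, ScatteringFrame
    """
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    bg = buffer_background(q)
    frames = []
    for t in np.asarray(times, dtype=float):
        mean = intensity_model(q, traj.params_at(t)) + bg
        sigma = noise_level * np.sqrt(mean)
        noisy = mean + rng.standard_normal(q.size) * sigma if noise_level else mean
        frames.append(
            ScatteringFrame(
                q=q, intensity=noisy,
                sigma=sigma if noise_level else None,
                time=float(t),
                meta={"wavelength_nm": 0.1, "scenario": traj.name},
            )
        )
    buf_sigma = noise_level * np.sqrt(bg)
    buf_int = bg + rng.standard_normal(q.size) * buf_sigma if noise_level else bg
    buffer = ScatteringFrame(
        q=q, intensity=buf_int,
        sigma=buf_sigma if noise_level else None,
        time=0.0, meta={"wavelength_nm": 0.1, "label": "buffer"},
    )
    return frames, buffer


def write_fixture(
    out_dir: str | Path,
    scenario_name: str = "pH7.0",
    seed: int = 0,
    times=None,
    q_grid=None,
    noise_level: float = DEFAULT_NOISE_LEVEL,
) -> Path:
    """Write a complete synthetic fixture and return the manifest path.

    Layout: ``profiles/frame_NNNN.dat``, ``buffer.dat``, ``manifest.csv``
    (``time_s,path``) and ``truth.csv`` with the ground-truth trajectory
    for recovery scoring.
    """
    out_dir = Path(out_dir)
    (out_dir / "profiles").mkdir(parents=True, exist_ok=True)
    traj = scenario(scenario_name)
    times = default_times() if times is None else np.asarray(times, dtype=float)
    frames, buffer = render_frames(
        traj, times, q_grid=q_grid, noise_level=noise_level, seed=seed
    )
    rows, truth = [], []
    for i, frame in enumerate(frames):
        rel = f"profiles/frame_{i:04d}.dat"
        write_profile(frame, out_dir / rel)
        rows.append({"time_s": frame.time, "path": rel})
        p = traj.params_at(frame.time)
        truth.append(
            {
                "time_s": frame.time,
                "n_comp": p.n_components,
                "rc1_nm": p.rc1,
                "rc2_nm": p.rc2 if p.n_components == 2 else np.nan,
                "w2": p.k2 / p.k_total if p.k_total > 0 else np.nan,
                "amplitude": p.k_total,
                "const": p.const,
            }
        )
    write_profile(buffer, out_dir / "buffer.dat")
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    pd.DataFrame(truth).to_csv(out_dir / "truth.csv", index=False)
    return manifest
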