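"""Synthetic 2-photon image stacks of axon segments and calibration beads.

The axon is modelled as a tube with Gaussian cross-section (FWHM equal to
the shaft diameter) following a smooth low-tortuosity planar curve; each
bouton is a Gaussian blob whose FWHM equals its ground-truth diameter and
whose emission peaks at ``bouton_brightness_factor`` times the shaft. The
microscope blur is a separable anisotropic Gaussian PSF, which lets the
renderer fold the optics in analytically (variances add), so measured
transverse widths obey the quadrature law FWHM_obs = sqrt(FWHM_obj^2 +
FWHM_psf^2) exactly — the property the bead-calibration chain is tested
against. Per-slice rigid jitter, across-stack drift, and Poisson/Gaussian
noise emulate acquisition artifacts within the study's quality gates.

Stacks are rendered as a tight region of interest around the traced axon;
the nominal field of view is carried as metadata (rendering a full
310-420 um field at 0.1 um/pixel would be ~10^9 voxels per stack for no
analytical benefit).
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage
from scipy.spatial import cKDTree

from .synthcohort import SegmentGroundTruth

__all__ = [
    "ImagingSpec",
    "RenderedStack",
    "make_trace",
    "render_segment",
    "render_bead",
    "write_stack",
    "read_stack",
    "write_swc",
    "read_swc",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class ImagingSpec:
    """Acquisition geometry, optics, photometry and motion model."""

    pixel_size_um: float = 0.1
    z_step_um: float = 1.0
    psf_fwhm_lateral_um: float = 0.4
    psf_fwhm_axial_um: float = 2.0
    axon_shaft_diameter_um: float = 0.6
    background_level: float = 10.0
    photon_scale: float = 100.0  # shaft peak intensity (counts) after blur
    bouton_brightness_factor: float = 2.5  # emission peak relative to shaft
    noise_model: str = "poisson+gaussian"  # poisson | gaussian | poisson+gaussian | none
    read_noise_sd: float = 2.0
    slow_drift_amplitude_px: float = 3.0
    fast_jitter_amplitude_px: float = 1.0
    fov_um: float | None = None  # nominal acquisition field; None -> tight ROI
    margin_um: float = 3.0
    z_halfextent_um: float = 3.0

    def validate(self) -> None:
        if self.psf_fwhm_lateral_um < 2.0 * self.pixel_size_um:
            raise ValueError("lateral PSF must span at least two pixels to be renderable")
        if not 0 <= self.slow_drift_amplitude_px < 5:
            raise ValueError("slow drift must stay below the 5-pixel quality gate")
        if not 0 <= self.fast_jitter_amplitude_px < 2:
            raise ValueError("fast jitter must stay below the 2-pixel quality gate")
        if self.noise_model not in ("poisson", "gaussian", "poisson+gaussian", "none"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.fov_um is not None and not 310 <= self.fov_um <= 420:
            raise ValueError("field of view outside the 310-420 um acquisition range")

    @property
    def sigma_psf_lateral(self) -> float:
        return self.psf_fwhm_lateral_um * FWHM_TO_SIGMA

    @property
    def sigma_psf_axial(self) -> float:
        return self.psf_fwhm_axial_um * FWHM_TO_SIGMA

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ImagingSpec":
        return cls(**d)


@dataclass
class RenderedStack:
    """Voxel data (z, y, x) plus the geometry needed to analyse it."""

    data: np.ndarray
    spec: ImagingSpec
    trace: np.ndarray  # (N, 3) backbone points, um, world frame
    origin_um: tuple[float, float]  # (y0, x0) of pixel [0, 0]
    z_positions_um: np.ndarray
    segment_id: str = "s0"
    day: int = 0
    seed: int = 0

    def um_to_px(self, x_um: np.ndarray, y_um: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        px = self.spec.pixel_size_um
        return (np.asarray(x_um) - self.origin_um[1]) / px, (
            np.asarray(y_um) - self.origin_um[0]
        ) / px

    def mip(self, z_center_um: float = 0.0, z_half_um: float = 2.0) -> np.ndarray:
        """Maximum-intensity projection over slices near the axon plane."""
        keep = np.abs(self.z_positions_um - z_center_um) <= z_half_um + 1e-9
        return self.data[keep].max(axis=0)


def make_trace(length_um: float, seed: int, step_um: float = 0.5) -> np.ndarray:
    """Smooth low-tortuosity planar backbone of the given arc length."""
    rng = np.random.default_rng(seed)
    amp = rng.uniform(0.02, 0.08)  # rad, heading oscillation
    period = rng.uniform(60.0, 120.0)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    s = np.arange(0.0, length_um + step_um / 2, step_um)
    theta = amp * np.sin(2.0 * np.pi * s / period + phase)
    x = np.concatenate([[0.0], np.cumsum(np.cos(theta[:-1]) * np.diff(s))])
    y = np.concatenate([[0.0], np.cumsum(np.sin(theta[:-1]) * np.diff(s))])
    return np.column_stack([x, y, np.zeros_like(x)])


def trace_seed(segment_id: str) -> int:
    """Stable per-segment geometry seed so all days share one frame."""
    return zlib.crc32(segment_id.encode()) & 0x7FFFFFFF


def _arc_coords(trace: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(np.diff(trace[:, :2], axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(d)])


def _interp_on_trace(trace: np.ndarray, arc_positions: np.ndarray) -> np.ndarray:
    s = _arc_coords(trace)
    x = np.interp(arc_positions, s, trace[:, 0])
    y = np.interp(arc_positions, s, trace[:, 1])
    z = np.interp(arc_positions, s, trace[:, 2])
    return np.column_stack([x, y, z])


def _apply_motion_and_noise(
    ideal: np.ndarray, spec: ImagingSpec, rng: np.random.Generator
) -> np.ndarray:
    nz = ideal.shape[0]
    out = ideal
    if spec.slow_drift_amplitude_px > 0 or spec.fast_jitter_amplitude_px > 0:
        out = np.empty_like(ideal)
        psi = rng.uniform(0, 2 * np.pi)
        span = spec.slow_drift_amplitude_px
        for k in range(nz):
            frac = k / max(nz - 1, 1) - 0.5
            drift = span * frac * np.array([np.sin(psi), np.cos(psi)])
            jitter = rng.uniform(
                -spec.fast_jitter_amplitude_px, spec.fast_jitter_amplitude_px, size=2
            )
            out[k] = ndimage.shift(ideal[k], drift + jitter, order=1, mode="nearest")
    if spec.noise_model in ("poisson", "poisson+gaussian"):
        out = rng.poisson(np.clip(out, 0.0, None)).astype(np.float64)
    if spec.noise_model in ("gaussian", "poisson+gaussian"):
        out = out + rng.normal(0.0, spec.read_noise_sd, size=out.shape)
    return np.asarray(out, dtype=np.float32)


def _z_positions(spec: ImagingSpec) -> np.ndarray:
    n = int(np.floor(spec.z_halfextent_um / spec.z_step_um))
    return np.arange(-n, n + 1) * spec.z_step_um


def _blob_amplitude(spec: ImagingSpec, diameter_um: float) -> float:
    """Post-blur peak of a bouton blob, relative units of shaft peak = 1.

    Amplitude attenuation per axis is sigma / sqrt(sigma^2 + sigma_psf^2);
    the tube attenuates only transversally (y and z for an axon along x).
    """
    st = spec.axon_shaft_diameter_um * FWHM_TO_SIGMA
    sb = diameter_um * FWHM_TO_SIGMA
    sl, sa = spec.sigma_psf_lateral, spec.sigma_psf_axial
    red_tube = (st / np.hypot(st, sl)) * (st / np.hypot(st, sa))
    red_blob = (sb / np.hypot(sb, sl)) ** 2 * (sb / np.hypot(sb, sa))
    return spec.bouton_brightness_factor * red_blob / red_tube


def render_segment(
    truth: SegmentGroundTruth,
    day: int,
    spec: ImagingSpec,
    seed: int = 0,
    trace: np.ndarray | None = None,
) -> RenderedStack:
    """Render one segment on one imaging day.

    Deterministic for a fixed seed. The backbone geometry is derived from
    the segment id so that every imaging day of a segment is rendered in the
    same frame (longitudinal alignment is assumed done upstream for real
    data; the synthetic renderer simply guarantees it).
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    if trace is None:
        trace = make_trace(truth.length, trace_seed(truth.segment_id))
    trace = np.asarray(trace, float)

    px = spec.pixel_size_um
    if spec.fov_um is None:
        x0 = trace[:, 0].min() - spec.margin_um
        x1 = trace[:, 0].max() + spec.margin_um
        y0 = trace[:, 1].min() - spec.margin_um
        y1 = trace[:, 1].max() + spec.margin_um
    else:
        cx, cy = trace[:, 0].mean(), trace[:, 1].mean()
        x0, x1 = cx - spec.fov_um / 2, cx + spec.fov_um / 2
        y0, y1 = cy - spec.fov_um / 2, cy + spec.fov_um / 2
    nx = int(np.ceil((x1 - x0) / px)) + 1
    ny = int(np.ceil((y1 - y0) / px)) + 1
    xs = x0 + np.arange(nx) * px
    ys = y0 + np.arange(ny) * px
    zs = _z_positions(spec)

    # lateral distance from every pixel to the backbone
    fine = _interp_on_trace(trace, np.arange(0.0, _arc_coords(trace)[-1] + 0.025, 0.05))
    tree = cKDTree(fine[:, :2])
    gx, gy = np.meshgrid(xs, ys)
    dist, _ = tree.query(np.column_stack([gx.ravel(), gy.ravel()]), workers=-1)
    dist = dist.reshape(ny, nx)

    st = spec.axon_shaft_diameter_um * FWHM_TO_SIGMA
    sig_lat_tube = float(np.hypot(st, spec.sigma_psf_lateral))
    sig_ax_tube = float(np.hypot(st, spec.sigma_psf_axial))
    shaft_lat = np.exp(-(dist**2) / (2.0 * sig_lat_tube**2))

    ideal = np.empty((len(zs), ny, nx), dtype=np.float64)
    z_axon = float(trace[:, 2].mean())
    for k, z in enumerate(zs):
        ideal[k] = (
            spec.photon_scale
            * shaft_lat
            * np.exp(-((z - z_axon) ** 2) / (2.0 * sig_ax_tube**2))
        )

    boutons = [b for b in truth.boutons if b.present_on(day)]
    centers = _interp_on_trace(trace, np.array([b.arc_position for b in boutons]))
    for b, (bx, by, bz) in zip(boutons, centers):
        if not (xs[0] <= bx <= xs[-1] and ys[0] <= by <= ys[-1]):
            raise ValueError(
                f"bouton {b.bouton_id} at ({bx:.1f}, {by:.1f}) um falls outside the volume"
            )
        sb = b.diameter * FWHM_TO_SIGMA
        sbl = float(np.hypot(sb, spec.sigma_psf_lateral))
        sba = float(np.hypot(sb, spec.sigma_psf_axial))
        amp = spec.photon_scale * _blob_amplitude(spec, b.diameter)
        half = 4.5 * sbl
        i0, i1 = np.searchsorted(xs, [bx - half, bx + half])
        j0, j1 = np.searchsorted(ys, [by - half, by + half])
        lat = np.exp(
            -((gx[j0:j1, i0:i1] - bx) ** 2 + (gy[j0:j1, i0:i1] - by) ** 2) / (2.0 * sbl**2)
        )
        # a varicosity is a local swelling of the axon, not a structure on
        # top of it: compose by envelope so the transverse profile through a
        # bouton is the bouton's own Gaussian
        for k, z in enumerate(zs):
            blob = amp * lat * np.exp(-((z - bz) ** 2) / (2.0 * sba**2))
            np.maximum(ideal[k, j0:j1, i0:i1], blob, out=ideal[k, j0:j1, i0:i1])

    ideal += spec.background_level
    data = _apply_motion_and_noise(ideal, spec, rng)
    return RenderedStack(
        data=data,
        spec=spec,
        trace=trace,
        origin_um=(float(y0), float(x0)),
        z_positions_um=zs,
        segment_id=truth.segment_id,
        day=int(day),
        seed=int(seed),
    )


def render_bead(
    spec: ImagingSpec,
    bead_diameter_um: float = 0.1,
    seed: int = 0,
    peak_intensity: float | None = None,
) -> RenderedStack:
    """Render a sub-resolution fluorescent bead at the volume centre.

    The measured lateral FWHM of the result is the quadrature sum of the
    bead diameter and the lateral PSF FWHM — the microscope resolving-power
    calibration.
    """
    spec.validate()
    if bead_diameter_um <= 0:
        raise ValueError("bead diameter must be positive")
    rng = np.random.default_rng(seed)
    half = 3.2
    px = spec.pixel_size_um
    n = int(round(2 * half / px)) + 1
    xs = -half + np.arange(n) * px
    zs = _z_positions(spec)
    sb = bead_diameter_um * FWHM_TO_SIGMA
    sbl = float(np.hypot(sb, spec.sigma_psf_lateral))
    sba = float(np.hypot(sb, spec.sigma_psf_axial))
    amp = 5.0 * spec.photon_scale if peak_intensity is None else peak_intensity
    gx, gy = np.meshgrid(xs, xs)
    lat = np.exp(-(gx**2 + gy**2) / (2.0 * sbl**2))
    ideal = np.stack(
        [amp * lat * np.exp(-(z**2) / (2.0 * sba**2)) for z in zs]
    ) + spec.background_level
    data = _apply_motion_and_noise(ideal, spec, rng)
    trace = np.array([[-half, 0.0, 0.0], [half, 0.0, 0.0]])
    return RenderedStack(
        data=data,
        spec=spec,
        trace=trace,
        origin_um=(-half, -half),
        z_positions_um=zs,
        segment_id="bead",
        day=0,
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# file formats


def write_stack(stack: RenderedStack, path) -> None:
    """Multi-page float32 TIFF; geometry and provenance in the description tag."""
    meta = {
        "spec": stack.spec.to_dict(),
        "origin_um": list(stack.origin_um),
        "z_positions_um": [float(z) for z in stack.z_positions_um],
        "trace_um": np.asarray(stack.trace, float).tolist(),
        "segment_id": stack.segment_id,
        "day": stack.day,
        "seed": stack.seed,
    }
    tifffile.imwrite(
        path,
        np.asarray(stack.data, np.float32),
        description=json.dumps(meta),
        resolution=(1.0 / stack.spec.pixel_size_um, 1.0 / stack.spec.pixel_size_um),
    )


def read_stack(path) -> RenderedStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        meta = json.loads(tf.pages[0].description)
    return RenderedStack(
        data=np.asarray(data, np.float32),
        spec=ImagingSpec.from_dict(meta["spec"]),
        trace=np.asarray(meta["trace_um"], float),
        origin_um=tuple(meta["origin_um"]),
        z_positions_um=np.asarray(meta["z_positions_um"], float),
        segment_id=meta["segment_id"],
        day=meta["day"],
        seed=meta["seed"],
    )


def write_swc(trace_um: np.ndarray, path, radius_um: float = 0.3) -> None:
    """Backbone as SWC (structure type 2, axon), one point per sample."""
    trace_um = np.asarray(trace_um, float)
    with open(path, "w") as fh:
        fh.write("# SWC axon backbone trace (um)\n")
        for i, (x, y, z) in enumerate(trace_um, start=1):
            parent = -1 if i == 1 else i - 1
            fh.write(f"{i} 2 {x:.4f} {y:.4f} {z:.4f} {radius_um:.3f} {parent}\n")


def read_swc(path) -> np.ndarray:
    pts = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            pts.append([float(parts[2]), float(parts[3]), float(parts[4])])
    if not pts:
        raise ValueError(f"no sample points in SWC file {path}")
    return np.asarray(pts, float)
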