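"""Synthetic longitudinal phantoms: ellipsoidal lesions with known
growth/shrinkage/appearance/disappearance trajectories, plus noisy
simulated readers and a degraded simulated segmenter.

Everything is driven by a single seeded generator, so phantoms are
bit-reproducible.  Lesions are rendered as digital ellipsoids (voxel
centers inside the analytic surface), which keeps the true equatorial
diameter analytic and lets diameter measurements be checked to within
one voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from lesiontrack.agreement import ReaderMeasurement
from lesiontrack.lesions import extract_lesions
from lesiontrack.volumes import ImageGrid, LabelVolume, write_label_volume

TRAJECTORY_KINDS = ("flat", "grow", "shrink", "vanish", "appear")


@dataclass(frozen=True)
class Trajectory:
    """Per-lesion size evolution: ``grow``/``shrink`` change the diameter
    by ``pct`` percent per study step (compounding); ``vanish``/``appear``
    toggle presence at ``event_study``."""

    kind: str
    pct: float = 0.0
    event_study: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TRAJECTORY_KINDS:
            raise ValueError(f"unknown trajectory kind {self.kind!r}")

    def diameter_at(self, d0: float, t: int) -> float:
        if self.kind == "flat":
            return d0
        if self.kind == "grow":
            return d0 * (1.0 + self.pct / 100.0) ** t
        if self.kind == "shrink":
            return d0 * (1.0 - self.pct / 100.0) ** t
        if self.kind == "vanish":
            return d0 if t < self.event_study else 0.0
        return d0 if t >= self.event_study else 0.0  # appear


@dataclass
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_patients: int = 1
    n_studies: int = 3
    n_lesions: int = 3
    diameter_range_mm: tuple[float, float] = (4.0, 12.0)
    trajectories: list[Trajectory] | None = None  # cycled over lesions; None = all flat
    axis_ratio_z: float = 1.0  # through-plane semi-axis relative to in-plane
    seed: int = 0

    def __post_init__(self) -> None:
        if not (3 <= self.n_studies <= 8):
            raise ValueError("n_studies must be between 3 and 8")
        if self.diameter_range_mm[0] <= 0:
            raise ValueError("diameters must be positive")


@dataclass
class TruthLesion:
    lesion_id: int
    center_mm: np.ndarray
    trajectory: Trajectory
    diameters_mm: list[float]  # per study; 0 = absent
    response_labels: list[str]  # per study


@dataclass
class PhantomTruth:
    grid: ImageGrid
    lesions: list[TruthLesion]
    n_studies: int
    seed: int


def _true_response_labels(diams: list[float], pd_pct: float = 20.0, pr_pct: float = -30.0) -> list[str]:
    """Reference labeling of a true diameter sequence, written directly
    from the threshold rules (kept separate from the response module so
    recovery tests compare two code paths)."""
    labels: list[str] = []
    first = next((i for i, d in enumerate(diams) if d > 0), None)
    if first is None:
        return ["NA"] * len(diams)
    baseline = diams[first]
    nadir = baseline
    in_cr = False
    for t, d in enumerate(diams):
        if t < first:
            labels.append("NA")
        elif t == first:
            labels.append("NA" if first == 0 else "NEW")
        elif d <= 0:
            labels.append("CR")
            in_cr = True
        elif in_cr:
            labels.append("PD")
        elif 100.0 * (d - nadir) / nadir > pd_pct:
            labels.append("PD")
        elif 100.0 * (d - baseline) / baseline <= pr_pct:
            labels.append("PR")
        else:
            labels.append("SD")
        if d > 0:
            nadir = min(nadir, d)
    return labels


def _render_ellipsoid(mask: np.ndarray, grid: ImageGrid, center_mm: np.ndarray,
                      diameter_mm: float, axis_ratio_z: float, value: int = 1) -> None:
    """Set voxels whose centers fall inside the ellipsoid (in-place)."""
    semi = np.array([diameter_mm / 2.0, diameter_mm / 2.0, diameter_mm / 2.0 * axis_ratio_z])
    spacing = np.asarray(grid.spacing)
    origin = grid.affine[:3, 3]
    lo = np.maximum(np.floor((center_mm - origin - semi) / spacing).astype(int), 0)
    hi = np.minimum(np.ceil((center_mm - origin + semi) / spacing).astype(int) + 1,
                    np.asarray(grid.shape))
    if np.any(lo >= hi):
        return
    xs, ys, zs = [np.arange(lo[a], hi[a]) * spacing[a] + origin[a] for a in range(3)]
    dx = (xs - center_mm[0]) / semi[0]
    dy = (ys - center_mm[1]) / semi[1]
    dz = (zs - center_mm[2]) / semi[2]
    inside = (dx[:, None, None] ** 2 + dy[None, :, None] ** 2 + dz[None, None, :] ** 2) <= 1.0
    sub = mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    sub[inside] = value


def generate_phantom(cfg: PhantomConfig, patient_index: int = 0) -> tuple[list[LabelVolume], PhantomTruth]:
    """Generate one patient's longitudinal series plus ground truth.

    Lesion centers are rejection-sampled so that every pair is separated
    by at least twice the maximum diameter any lesion ever reaches (no
    confluence); after 1000 failed attempts a RuntimeError is raised.
    """
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, patient_index]))
    grid = ImageGrid.from_spacing(cfg.shape, cfg.spacing)
    extent = np.asarray(cfg.shape) * np.asarray(cfg.spacing)

    trajectories = cfg.trajectories or [Trajectory("flat")]
    specs = []
    for i in range(cfg.n_lesions):
        d0 = float(rng.uniform(*cfg.diameter_range_mm))
        traj = trajectories[i % len(trajectories)]
        diams = [traj.diameter_at(d0, t) for t in range(cfg.n_studies)]
        specs.append((d0, traj, diams))

    max_d = max(max(diams) for _, _, diams in specs)
    min_sep = 2.0 * max_d
    margin = max_d / 2.0 + 1.0
    if np.any(extent - margin <= margin):
        raise RuntimeError(
            f"grid extent {tuple(extent)} mm too small for lesions up to {max_d:.1f} mm "
            "with the required separation")
    centers: list[np.ndarray] = []
    for _ in range(cfg.n_lesions):
        for attempt in range(1000):
            c = rng.uniform(margin, extent - margin)
            if all(np.linalg.norm(c - other) >= min_sep for other in centers):
                centers.append(c)
                break
        else:
            raise RuntimeError("could not place lesions with required separation after 1000 attempts")

    truth_lesions = [
        TruthLesion(lesion_id=i + 1, center_mm=centers[i], trajectory=traj,
                    diameters_mm=diams, response_labels=_true_response_labels(diams))
        for i, (_, traj, diams) in enumerate(specs)
    ]

    volumes = []
    pid = f"phantom{patient_index:03d}"
    for t in range(cfg.n_studies):
        mask = np.zeros(cfg.shape, dtype=np.int32)
        for tl in truth_lesions:
            d = tl.diameters_mm[t]
            if d > 0:
                _render_ellipsoid(mask, grid, tl.center_mm, d, cfg.axis_ratio_z)
        volumes.append(LabelVolume(grid=grid, data=mask, study_index=t, patient_id=pid))

    return volumes, PhantomTruth(grid=grid, lesions=truth_lesions, n_studies=cfg.n_studies, seed=cfg.seed)


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_reader(truth: PhantomTruth, detect_midpoint_mm: float, detect_slope: float,
                    noise_sd_mm: float, seed: int, reader_id: str = "R") -> list[ReaderMeasurement]:
    """Simulate a human reader over all (lesion, study) truth entries.

    Each present lesion is detected with probability
    logistic((d - midpoint)/slope); a midpoint <= 0 means a perfect
    detector.  Detected lesions get diameters = truth + Gaussian noise
    (clipped at 0).
    """
    if detect_slope <= 0 or noise_sd_mm < 0:
        raise ValueError("detect_slope must be positive and noise_sd_mm nonnegative")
    rng = np.random.default_rng(seed)
    out = []
    pid = "phantom000"
    for tl in truth.lesions:
        for t, d in enumerate(tl.diameters_mm):
            if d <= 0:
                continue
            p = 1.0 if detect_midpoint_mm <= 0 else _logistic((d - detect_midpoint_mm) / detect_slope)
            if rng.random() >= p:
                continue
            longest = max(0.0, d + rng.normal(0.0, noise_sd_mm)) if noise_sd_mm > 0 else d
            perp = max(0.0, d + rng.normal(0.0, noise_sd_mm)) if noise_sd_mm > 0 else d
            out.append(ReaderMeasurement(reader_id=reader_id, patient_id=pid, study_index=t,
                                         lesion_ref=tl.lesion_id, longest_mm=longest,
                                         perpendicular_mm=perp))
    return out


def simulate_segmenter(volumes: list[LabelVolume], truth: PhantomTruth,
                       small_miss_midpoint_mm: float = 0.0, boundary_jitter_vox: int = 0,
                       fp_rate_per_study: float = 0.0, seed: int = 0,
                       miss_slope_mm: float = 1.0) -> list[LabelVolume]:
    """Degrade phantom masks the way an imperfect segmenter would.

    Each connected lesion is dropped with size-dependent probability
    logistic((midpoint - d)/slope), where d is the sphere-equivalent
    diameter (midpoint 0 disables drops); kept lesions are eroded or
    dilated by a random amount up to ``boundary_jitter_vox``; a
    Poisson(``fp_rate_per_study``) number of spurious small blobs is
    added inside the central brain-box region.  With all parameters 0
    the output equals the input.
    """
    if small_miss_midpoint_mm < 0 or boundary_jitter_vox < 0 or fp_rate_per_study < 0:
        raise ValueError("degradation parameters must be nonnegative")
    rng = np.random.default_rng(seed)
    out_volumes = []
    for vol in volumes:
        out = np.zeros(vol.grid.shape, dtype=np.int32)
        for lesion in extract_lesions(vol, connectivity=26):
            d_eq = (6.0 * lesion.volume_mm3 / np.pi) ** (1.0 / 3.0)
            p_miss = 0.0 if small_miss_midpoint_mm <= 0 else _logistic((small_miss_midpoint_mm - d_eq) / miss_slope_mm)
            if rng.random() < p_miss:
                continue
            comp = np.zeros(vol.grid.shape, dtype=bool)
            comp[tuple(lesion.voxels.T)] = True
            if boundary_jitter_vox > 0:
                jitter = int(rng.integers(-boundary_jitter_vox, boundary_jitter_vox + 1))
                if jitter > 0:
                    comp = ndimage.binary_dilation(comp, iterations=jitter)
                elif jitter < 0:
                    eroded = ndimage.binary_erosion(comp, iterations=-jitter)
                    if eroded.any():  # never erase a lesion entirely by jitter
                        comp = eroded
            out[comp] = 1
        if fp_rate_per_study > 0:
            shape = np.asarray(vol.grid.shape)
            lo, hi = (0.1 * shape).astype(int), (0.9 * shape).astype(int)
            for _ in range(rng.poisson(fp_rate_per_study)):
                center_vox = rng.integers(lo, hi)
                center_mm = vol.grid.voxel_to_mm(center_vox)[0]
                radius_mm = float(rng.uniform(1.0, 2.5))
                _render_ellipsoid(out, vol.grid, center_mm, 2 * radius_mm, 1.0)
        out_volumes.append(LabelVolume(grid=vol.grid, data=out, study_index=vol.study_index,
                                       study_date=vol.study_date, patient_id=vol.patient_id))
    return out_volumes


def write_phantom(volumes: list[LabelVolume], truth: PhantomTruth, out_dir: str | Path) -> Path:
    """Write NIfTI masks, a truth table (CSV) and a manifest (JSON)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for vol in volumes:
        p = out_dir / f"study_{vol.study_index:02d}.nii.gz"
        write_label_volume(vol, p)
        paths.append(p.name)
    rows = []
    for tl in truth.lesions:
        for t in range(truth.n_studies):
            rows.append({"lesion_id": tl.lesion_id, "study_index": t,
                         "center_x_mm": tl.center_mm[0], "center_y_mm": tl.center_mm[1],
                         "center_z_mm": tl.center_mm[2], "trajectory": tl.trajectory.kind,
                         "true_diameter_mm": tl.diameters_mm[t],
                         "true_response": tl.response_labels[t]})
    pd.DataFrame(rows).to_csv(out_dir / "truth.csv", index=False)
    manifest = {"seed": truth.seed, "n_studies": truth.n_studies,
                "n_lesions": len(truth.lesions), "volumes": paths,
                "shape": list(truth.grid.shape), "spacing": list(truth.grid.spacing)}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out_dir
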