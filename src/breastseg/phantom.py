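"""Synthetic DCE-MRI-like phantoms with analytic ground truth.

The study data this package targets — subtraction dynamic contrast-enhanced
breast MRI — show the tumor as a hyperintense mass on a darker background,
occasionally with a hypointense cystic/necrotic core. The phantom generator
emulates exactly that statistical structure: a (optionally lobulated, rotated)
ellipsoidal lesion of known closed-form geometry, an optional concentric
hypointense core, additive Gaussian noise, and anisotropic voxel spacing.
Because the geometry is analytic, every downstream measurement (volume,
diameters, staging, cystic volume) can be checked against an exact oracle.

Voxel membership is decided by a voxel-center-inside test (no partial
volume), matching the discrete mask semantics used by all downstream shape
features. Lobulation is a low-order spherical-harmonic radial perturbation:
a voxel at normalized ellipsoidal radius rho belongs to the lesion iff
``rho <= 1 + amplitude * f(theta, phi)`` with ``max|f| = 1``, giving
realistic non-ellipsoidal shapes with controllable magnitude (closed-form
volume then no longer applies and analytic fields are reported as NaN).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation
from scipy.special import sph_harm_y

from .io import MANIFEST_COLUMNS, CohortManifest, write_mask, write_volume
from .quantify import StagingRules, classify_t_stage
from .volume import Mask3D, Volume3D

__all__ = [
    "CoreSpec",
    "PhantomSpec",
    "GroundTruthRecord",
    "generate_phantom",
    "analytic_geometry",
    "generate_cohort",
]

#: Default intensities on an arbitrary scanner-like scale: enhancing lesion
#: bright, fibroglandular background dark, necrotic core intermediate-dark.
DEFAULT_BACKGROUND = 50.0
DEFAULT_LESION = 300.0
DEFAULT_CORE = 100.0
DEFAULT_SPACING = (0.7, 0.7, 1.1)  # mm; anisotropic, thicker slices axially


@dataclass(frozen=True)
class CoreSpec:
    """Hypointense central core (cystic/necrotic change) of a lesion."""

    core_semi_axes_mm: tuple[float, float, float]
    core_intensity: float = DEFAULT_CORE


@dataclass(frozen=True)
class PhantomSpec:
    """Generative parameters of one phantom lesion.

    ``semi_axes_mm`` must be sorted descending (a >= b >= c); the lesion must
    fit inside the grid with at least one voxel of margin; the lesion must be
    brighter than the background and any core darker than the lesion rim.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING
    center_mm: tuple[float, float, float] | None = None
    semi_axes_mm: tuple[float, float, float] = (15.0, 12.0, 10.0)
    rotation: tuple[float, float, float] = (0.0, 0.0, 0.0)  # XYZ Euler, degrees
    lesion_intensity: float = DEFAULT_LESION
    background_intensity: float = DEFAULT_BACKGROUND
    noise_sd: float = 20.0
    lobulation_amplitude: float = 0.0
    core: CoreSpec | None = None
    seed: int = 0

    def __post_init__(self):
        if self.center_mm is None:
            c = tuple(
                (n - 1) * s / 2.0 for n, s in zip(self.grid_shape, self.spacing_mm)
            )
            object.__setattr__(self, "center_mm", c)
        self.validate()

    @property
    def rotation_matrix(self) -> np.ndarray:
        return Rotation.from_euler("xyz", self.rotation, degrees=True).as_matrix()

    def validate(self) -> None:
        a, b, c = self.semi_axes_mm
        if not (a >= b >= c > 0):
            raise ValueError(f"semi-axes must satisfy a >= b >= c > 0, got {self.semi_axes_mm}")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"non-positive spacing {self.spacing_mm}")
        if not 0.0 <= self.lobulation_amplitude <= 0.3:
            raise ValueError("lobulation_amplitude must lie in [0, 0.3]")
        if self.lesion_intensity <= self.background_intensity:
            raise ValueError("lesion_intensity must exceed background_intensity")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        # Support of the rotated (possibly inflated) ellipsoid along each world
        # axis; require >= 1 voxel margin inside the grid.
        R = self.rotation_matrix
        s = np.asarray(self.semi_axes_mm) * (1.0 + self.lobulation_amplitude)
        extent = np.sqrt((R**2) @ (s**2))
        lo = np.asarray(self.center_mm) - extent
        hi = np.asarray(self.center_mm) + extent
        spacing = np.asarray(self.spacing_mm)
        grid_hi = (np.asarray(self.grid_shape) - 1) * spacing
        if np.any(lo < spacing) or np.any(hi > grid_hi - spacing):
            raise ValueError(
                "lesion exceeds grid bounds (needs >= 1 voxel margin): "
                f"extent [{lo}, {hi}] vs grid [0, {grid_hi}] at spacing {tuple(spacing)}"
            )
        if self.core is not None:
            ca = np.asarray(self.core.core_semi_axes_mm)
            if np.any(ca <= 0):
                raise ValueError("core semi-axes must be positive")
            if self.core.core_intensity >= self.lesion_intensity:
                raise ValueError("core_intensity must be below lesion_intensity")
            # strict containment, also under the worst-case inward lobulation
            if np.any(ca >= np.asarray(self.semi_axes_mm) * (1.0 - self.lobulation_amplitude)):
                raise ValueError("core must lie strictly inside the (lobulated) lesion")


@dataclass(frozen=True)
class GroundTruthRecord:
    """Closed-form geometry of a phantom (the test oracle for measurements)."""

    analytic_volume_mm3: float
    analytic_max_diameter_mm: float
    t_stage_true: str
    core_volume_mm3: float = 0.0
    mask: Mask3D | None = None


def _ellipsoid_volume(semi_axes) -> float:
    a, b, c = semi_axes
    return 4.0 / 3.0 * np.pi * a * b * c


def _lobulation_field(spec: PhantomSpec, theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Random degree-2/3 spherical-harmonic perturbation, normalized to max|f|=1."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x10B]))
    terms = [(l, m) for l in (2, 3) for m in range(0, l + 1)]
    coeffs = rng.normal(size=len(terms))

    def evaluate(th, ph):
        f = np.zeros_like(th, dtype=float)
        for (l, m), w in zip(terms, coeffs):
            f += w * np.real(sph_harm_y(l, m, th, ph))
        return f

    # normalization constant from a fixed angular sample
    th_s, ph_s = np.meshgrid(
        np.linspace(0, np.pi, 64), np.linspace(0, 2 * np.pi, 128), indexing="ij"
    )
    scale = np.abs(evaluate(th_s, ph_s)).max()
    return evaluate(theta, phi) / max(scale, 1e-12)


def _membership(spec: PhantomSpec, semi_axes) -> np.ndarray:
    """Boolean voxel-center-inside mask for the (lobulated) rotated ellipsoid."""
    idx = np.indices(spec.grid_shape, dtype=float)
    coords = idx * np.asarray(spec.spacing_mm).reshape(3, 1, 1, 1)
    rel = coords - np.asarray(spec.center_mm).reshape(3, 1, 1, 1)
    R = spec.rotation_matrix
    local = np.tensordot(R.T, rel, axes=1)  # lesion frame
    u = local / np.asarray(semi_axes).reshape(3, 1, 1, 1)
    rho = np.sqrt((u**2).sum(axis=0))
    if spec.lobulation_amplitude == 0.0:
        return rho <= 1.0
    r = np.sqrt((local**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_theta = np.divide(local[2], r, out=np.zeros_like(r), where=r > 0)
        theta = np.arccos(np.clip(cos_theta, -1, 1))
        phi = np.arctan2(local[1], local[0])
    f = _lobulation_field(spec, theta, phi)
    return rho <= 1.0 + spec.lobulation_amplitude * f


def analytic_geometry(
    spec: PhantomSpec, staging: StagingRules | None = None
) -> GroundTruthRecord:
    """Exact ellipsoid geometry (volume, 2a diameter, core volume, T stage).

    Refuses lobulated specs: the perturbed shape has no closed form.
    """
    if spec.lobulation_amplitude != 0.0:
        raise ValueError("no closed-form geometry for a lobulated lesion")
    staging = staging or StagingRules()
    a = spec.semi_axes_mm[0]
    core_vol = (
        _ellipsoid_volume(spec.core.core_semi_axes_mm) if spec.core is not None else 0.0
    )
    return GroundTruthRecord(
        analytic_volume_mm3=_ellipsoid_volume(spec.semi_axes_mm),
        analytic_max_diameter_mm=2.0 * a,
        t_stage_true=classify_t_stage(2.0 * a, staging),
        core_volume_mm3=core_vol,
    )


def generate_phantom(
    spec: PhantomSpec, staging: StagingRules | None = None
) -> tuple[Volume3D, Mask3D, GroundTruthRecord]:
    """Render a phantom volume, its ground-truth mask, and the analytic record.

    The mask is the digitized lesion; the image is background plus lesion
    signal (core voxels carry the core intensity) plus iid Gaussian noise.
    Deterministic for a fixed ``spec.seed``.
    """
    spec.validate()
    staging = staging or StagingRules()
    inside = _membership(spec, spec.semi_axes_mm)
    image = np.full(spec.grid_shape, spec.background_intensity, dtype=np.float64)
    image[inside] = spec.lesion_intensity
    core_mask = None
    if spec.core is not None:
        core_spec = dataclasses.replace(spec, lobulation_amplitude=0.0, core=None)
        core_mask = _membership(core_spec, spec.core.core_semi_axes_mm)
        image[core_mask] = spec.core.core_intensity
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0x1F5]))
    if spec.noise_sd > 0:
        image += rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)

    vol = Volume3D(data=image.astype(np.float32), spacing_mm=spec.spacing_mm)
    mask = Mask3D(labels=inside.astype(np.uint8), spacing_mm=spec.spacing_mm)

    if spec.lobulation_amplitude == 0.0:
        record = dataclasses.replace(analytic_geometry(spec, staging), mask=mask)
    else:
        # nominal stage from the unperturbed 2a; exact closed forms unavailable
        record = GroundTruthRecord(
            analytic_volume_mm3=float("nan"),
            analytic_max_diameter_mm=float("nan"),
            t_stage_true=classify_t_stage(2.0 * spec.semi_axes_mm[0], staging),
            core_volume_mm3=(
                _ellipsoid_volume(spec.core.core_semi_axes_mm) if spec.core else 0.0
            ),
            mask=mask,
        )
    return vol, mask, record


def _stage_counts(n: int, stage_mix: tuple[float, float, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n cases over (T1, T2, T3)."""
    p = np.asarray(stage_mix, dtype=float)
    if p.min() < 0 or not np.isclose(p.sum(), 1.0):
        raise ValueError(f"stage_mix must be non-negative and sum to 1, got {stage_mix}")
    raw = n * p
    base = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - base))[: n - base.sum()]:
        base[i] += 1
    return dict(zip(("T1", "T2", "T3"), base.tolist()))


def generate_cohort(
    n: int,
    stage_mix: tuple[float, float, float] = (0.5, 0.4, 0.1),
    core_fraction: float = 0.0,
    seed: int = 0,
    out_dir: str | Path = "cohort",
    grid_shape: tuple[int, int, int] = (96, 96, 96),
    spacing_mm: tuple[float, float, float] = DEFAULT_SPACING,
    noise_sd: float = 20.0,
    staging: StagingRules | None = None,
) -> CohortManifest:
    """Simulate a stage-mixed cohort of phantoms and write it to disk.

    Writes ``n`` NIfTI image/mask pairs plus a CSV manifest recording paths,
    true semi-axes, analytic volume, true T stage and per-case seed. Stage
    counts follow ``stage_mix`` by largest-remainder rounding. Lesion
    diameters are drawn with a 2 mm guard away from the 20/50 mm staging
    boundaries (more than one voxel diagonal) so the true stage remains
    unambiguous after digitization. Sizes are
    additionally capped by what fits the grid with margin; a stage whose
    minimum size cannot fit raises.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    staging = staging or StagingRules()
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.write_text("")
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cohort output directory not writable: {out_dir}") from exc

    counts = _stage_counts(n, stage_mix)
    spacing = np.asarray(spacing_mm)
    # max semi-axis that fits the grid with a 2-voxel margin in the tightest axis
    grid_extent = (np.asarray(grid_shape) - 1) * spacing
    a_cap = float((grid_extent / 2 - 2 * spacing).min()) / 1.05  # slack for b,c rotation
    guard = 2.0  # mm clearance from the staging boundaries (> 1 voxel diagonal)
    ranges = {
        "T1": (8.0, min(staging.t1_max_mm - guard, 2 * a_cap)),
        "T2": (staging.t1_max_mm + guard, min(staging.t2_max_mm - guard, 2 * a_cap)),
        "T3": (staging.t2_max_mm + guard, min(staging.t2_max_mm * 1.3, 2 * a_cap)),
    }
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xC04]))
    rows, case = [], 0
    for stage in ("T1", "T2", "T3"):
        lo, hi = ranges[stage]
        if counts[stage] > 0 and hi <= lo:
            raise ValueError(
                f"stage {stage} lesions (diameter > {lo:.0f} mm) do not fit a "
                f"{tuple(grid_shape)} grid at spacing {tuple(spacing)}"
            )
        for _ in range(counts[stage]):
            for _attempt in range(50):
                d = rng.uniform(lo, hi)
                a = d / 2.0
                b = a * rng.uniform(0.6, 0.9)
                c = b * rng.uniform(0.6, 0.95)
                angles = tuple(rng.uniform(0, 180, size=3))
                has_core = rng.uniform() < core_fraction
                core = None
                if has_core:
                    f = rng.uniform(0.3, 0.55)
                    core = CoreSpec(core_semi_axes_mm=(a * f, b * f, c * f))
                case_seed = int(rng.integers(0, 2**31 - 1))
                try:
                    spec = PhantomSpec(
                        grid_shape=tuple(grid_shape),
                        spacing_mm=tuple(spacing_mm),
                        semi_axes_mm=(a, b, c),
                        rotation=angles,
                        noise_sd=noise_sd,
                        core=core,
                        seed=case_seed,
                    )
                except ValueError:
                    continue  # rotation pushed the lesion out of the grid; redraw
                break
            else:
                raise RuntimeError(f"could not place a {stage} lesion in the grid")
            vol, mask, record = generate_phantom(spec, staging)
            case_id = f"case_{case:03d}"
            image_path = out_dir / f"{case_id}_image.nii.gz"
            mask_path = out_dir / f"{case_id}_mask.nii.gz"
            write_volume(vol, image_path)
            write_mask(mask, mask_path)
            rows.append(
                {
                    "case_id": case_id,
                    "image_path": str(image_path),
                    "mask_path": str(mask_path),
                    "a_mm": a,
                    "b_mm": b,
                    "c_mm": c,
                    "volume_mm3": record.analytic_volume_mm3,
                    "t_stage": record.t_stage_true,
                    "core_volume_mm3": record.core_volume_mm3,
                    "seed": case_seed,
                }
            )
            case += 1
    manifest = CohortManifest(pd.DataFrame(rows, columns=MANIFEST_COLUMNS))
    manifest.to_csv(out_dir / "manifest.csv")
    return manifest
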