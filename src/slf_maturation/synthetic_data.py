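"""Synthetic phantoms emulating the study's data: ROI label maps, bundle
tractograms with known provenance, multi-shell DWI signals, and two-cohort
(neonate / adult) metric maps.

The phantom is schematic, not anatomical: each ROI is an axis-aligned box
(the mid-sagittal exclusion plane is a one-voxel slab), left/right ROI
pairs mirror each other across that plane, frontal ROIs sit anterior to
the AC coronal plane, parietal ROIs posterior to the PC plane, and the
posterior middle-frontal boxes (MFg-P) sit strictly between the two —
the geometry the SLF dissection recipes rely on.  Axes follow RAS:
+x right, +y anterior, +z superior.

Cohort generation uses a shared-factor model per subject: every tract
metric is an age trend plus a subject-level "maturation" factor (inducing
realistic cross-metric covariance) plus independent noise.  Defaults
emulate term neonates scanned at 37-44 weeks post-menstrual age against
adults aged 22-35 years, with NDI/FA rising and MD/RD falling over the
neonatal window, AD/ODI essentially flat, and large neonate-vs-adult
offsets in every metric except ODI; the SLF II offsets are the largest,
so the middle branch is the least mature in the synthetic ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from scipy.ndimage import binary_dilation

from .errors import LayoutError, SelectionError
from .io_formats import GradientScheme, Tractogram, VolumeImage
from .watson import dispersed_stick_attenuation, kappa_from_odi, watson_tau1

__all__ = [
    "ROI_NAMES",
    "METRICS",
    "BUNDLES",
    "PhantomLayout",
    "NoddiParams",
    "CohortSpec",
    "BundleComponent",
    "make_phantom",
    "simulate_bundle",
    "simulate_tractogram",
    "default_bundle_mix",
    "simulate_dwi",
    "default_cohort_spec",
    "simulate_cohort_tables",
    "simulate_cohorts",
    "bundle_corridor_mask",
    "dhcp_scheme",
]

ROI_NAMES = (
    "SFgL", "SFgR", "MFgL", "MFgR", "PrgL", "PrgR",
    "PaL", "PaR", "TeL", "TeR", "Midsag", "MFgL-P", "MFgR-P",
)

METRICS = ("NDI", "ODI", "FA", "MD", "AD", "RD")
BUNDLES = ("SLF_I", "SLF_II", "SLF_III")
HEMISPHERES = ("L", "R")


# ---------------------------------------------------------------------------
# Phantom layout


@dataclass
class PhantomLayout:
    """Schematic ROI layout: inclusive voxel-index boxes per ROI."""

    shape: tuple
    affine: np.ndarray
    boxes: dict  # name -> ((x0,x1),(y0,y1),(z0,z1)) inclusive
    label_ids: dict  # name -> positive int
    ac_index: int
    pc_index: int

    def centroid_world(self, name: str) -> np.ndarray:
        if name not in self.boxes:
            raise SelectionError(f"unknown ROI {name!r}")
        box = np.asarray(self.boxes[name], dtype=float)
        centre_vox = box.mean(axis=1)
        return centre_vox @ self.affine[:3, :3].T + self.affine[:3, 3]

    def label_volume(self) -> VolumeImage:
        data = np.zeros(self.shape, dtype=np.int16)
        for name, ((x0, x1), (y0, y1), (z0, z1)) in self.boxes.items():
            data[x0 : x1 + 1, y0 : y1 + 1, z0 : z1 + 1] = self.label_ids[name]
        return VolumeImage(data=data, affine=self.affine)


def _mirror_box(box, mid_x):
    (x0, x1), yb, zb = box
    return ((2 * mid_x - x1, 2 * mid_x - x0), yb, zb)


def make_phantom(
    shape: Sequence[int] = (48, 48, 48),
    voxel_size: float = 2.0,
    seed: int = 0,
) -> tuple[PhantomLayout, VolumeImage]:
    """Build the 13-ROI phantom and its integer label volume.

    The layout is deterministic given ``shape`` (``seed`` is accepted for
    interface symmetry with the other generators).  Requires at least 40
    voxels per axis and an even left-right dimension so that the
    mid-sagittal slab has an exact mirror plane.
    """
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise LayoutError("shape must be 3-D")
    if min(shape) < 40:
        raise LayoutError(f"shape {shape} too small: need >= 40 voxels per axis")
    nx, ny, nz = shape
    if nx % 2:
        raise LayoutError("left-right axis length must be even for mirror symmetry")
    mx, my, zc = nx // 2, ny // 2, nz // 2
    ac, pc = my + 4, my - 4

    frontal_x = (mx - 10, mx - 3)
    post_x = (mx - 12, mx - 3)
    left = {
        "SFgL": (frontal_x, (ac + 2, ac + 9), (zc + 6, zc + 13)),
        "MFgL": (frontal_x, (ac + 2, ac + 9), (zc - 3, zc + 3)),
        "PrgL": (frontal_x, (ac + 1, ac + 3), (zc - 12, zc - 6)),
        "PaL": (post_x, (pc - 9, pc - 2), (zc - 4, zc + 9)),
        "TeL": (post_x, (pc - 12, pc - 2), (1, zc - 15)),
        "MFgL-P": (frontal_x, (pc + 2, ac - 2), (zc - 8, zc + 3)),
    }
    boxes = dict(left)
    for name, box in left.items():
        right_name = name.replace("L", "R", 1) if "-" not in name else name.replace(
            "L-P", "R-P"
        )
        boxes[right_name] = _mirror_box(box, mx)
    boxes["Midsag"] = ((mx, mx), (0, ny - 1), (0, nz - 1))

    affine = np.diag([voxel_size] * 3 + [1.0])
    affine[:3, 3] = -voxel_size * np.array([mx, my, zc], dtype=float)

    label_ids = {name: i + 1 for i, name in enumerate(ROI_NAMES)}
    layout = PhantomLayout(
        shape=shape,
        affine=affine,
        boxes=boxes,
        label_ids=label_ids,
        ac_index=ac,
        pc_index=pc,
    )
    return layout, layout.label_volume()


# ---------------------------------------------------------------------------
# Bundle simulation


def _resample_spline(control: np.ndarray, step_mm: float) -> np.ndarray:
    """Interpolate control points with a natural cubic spline and sample at
    ~``step_mm`` spacing; the control points themselves are kept as vertices."""
    deltas = np.linalg.norm(np.diff(control, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(deltas)])
    if t[-1] <= 0:
        raise ValueError("degenerate control polygon")
    spline = CubicSpline(t, control, axis=0, bc_type="natural")
    n = max(int(np.ceil(t[-1] / step_mm)) + 1, 2)
    params = np.union1d(np.linspace(0.0, t[-1], n), t)
    return spline(params)


def simulate_bundle(
    layout: PhantomLayout,
    waypoints: Sequence[str],
    n: int = 100,
    jitter: float = 1.0,
    seed: int = 0,
    step_mm: float = 1.5,
    extend_mm: float = 6.0,
) -> Tractogram:
    """Generate ``n`` streamlines visiting the centroids of ``waypoints`` in
    order, smoothly interpolated, with Gaussian control-point jitter (mm SD).
    Every streamline has at least one vertex inside each waypoint ROI."""
    if n < 1:
        raise ValueError("n must be >= 1")
    for name in waypoints:
        if name not in layout.boxes:
            raise SelectionError(f"unknown ROI {name!r}")
    if len(waypoints) < 2:
        raise ValueError("need at least two waypoints")
    centroids = np.array([layout.centroid_world(w) for w in waypoints])
    # extend slightly beyond the terminal ROIs so endpoints are not exactly
    # at ROI centres (tractography streamlines overshoot their waypoints)
    d0 = centroids[0] - centroids[1]
    d1 = centroids[-1] - centroids[-2]
    d0 = d0 / max(np.linalg.norm(d0), 1e-9)
    d1 = d1 / max(np.linalg.norm(d1), 1e-9)
    anchors = np.vstack(
        [centroids[0] + extend_mm * d0, centroids, centroids[-1] + extend_mm * d1]
    )
    rng = np.random.default_rng(seed)
    streamlines = []
    for _ in range(n):
        control = anchors + rng.normal(scale=jitter, size=anchors.shape)
        streamlines.append(_resample_spline(control, step_mm))
    return Tractogram(streamlines=streamlines, header={"phantom": "bundle"})


@dataclass
class BundleComponent:
    name: str
    waypoints: tuple
    n: int
    contaminant: bool = False


def default_bundle_mix(
    protocol: str = "adult",
    n_per_bundle: int = 150,
    n_contaminant: int = 100,
) -> list:
    """Six SLF-like bundles plus a callosal and an arcuate contaminant.

    The callosal bundle satisfies the left SLF II inclusion pair but crosses
    the mid-sagittal plane; the arcuate bundle satisfies the left SLF III
    inclusion pair but projects into the temporal lobe — each is admitted by
    exactly one exclusion ROI, exercising both 'NOT' clauses.
    Under the neonatal protocol SLF II runs between the posterior and
    anterior middle-frontal boxes instead of reaching the parietal ROI.
    """
    if protocol not in ("adult", "neonate"):
        raise ValueError(f"unknown protocol {protocol!r}")
    slf2 = {
        "adult": {"L": ("PaL", "MFgL"), "R": ("PaR", "MFgR")},
        "neonate": {"L": ("MFgL-P", "MFgL"), "R": ("MFgR-P", "MFgR")},
    }[protocol]
    mix = [
        BundleComponent("SLF_I_L", ("PaL", "SFgL"), n_per_bundle),
        BundleComponent("SLF_I_R", ("PaR", "SFgR"), n_per_bundle),
        BundleComponent("SLF_II_L", slf2["L"], n_per_bundle),
        BundleComponent("SLF_II_R", slf2["R"], n_per_bundle),
        BundleComponent("SLF_III_L", ("PaL", "PrgL"), n_per_bundle),
        BundleComponent("SLF_III_R", ("PaR", "PrgR"), n_per_bundle),
        BundleComponent(
            "callosal", ("PaL", "MFgL", "MFgR"), n_contaminant, contaminant=True
        ),
        BundleComponent(
            "arcuate_L", ("PrgL", "PaL", "TeL"), n_contaminant, contaminant=True
        ),
    ]
    return mix


def simulate_tractogram(
    layout: PhantomLayout,
    bundle_mix: Sequence[BundleComponent] | None = None,
    seed: int = 0,
    jitter: float = 1.0,
) -> tuple[Tractogram, list]:
    """Concatenate the bundles of ``bundle_mix`` into one whole-phantom
    tractogram; returns the tractogram and a per-streamline provenance list
    (the generating bundle's name) for recovery testing."""
    if bundle_mix is None:
        bundle_mix = default_bundle_mix()
    if sum(c.n for c in bundle_mix) == 0:
        raise ValueError("bundle mix generates zero streamlines")
    streamlines: list = []
    provenance: list = []
    for i, comp in enumerate(bundle_mix):
        sub = simulate_bundle(
            layout,
            comp.waypoints,
            n=comp.n,
            jitter=jitter,
            seed=(seed * 1009 + i) % (2**31 - 1),
        )
        streamlines.extend(sub.streamlines)
        provenance.extend([comp.name] * comp.n)
    tractogram = Tractogram(streamlines=streamlines, header={"phantom": "mix"})
    return tractogram, provenance


# ---------------------------------------------------------------------------
# Multi-shell DWI simulation


def dhcp_scheme() -> GradientScheme:
    """A multi-shell scheme with the neonatal study's shell structure:
    b = 0 / 400 / 1000 / 2600 s/mm^2 with 20 / 64 / 88 / 128 directions
    (300 volumes), directions quasi-uniform on the sphere (Fibonacci
    spiral, azimuthally offset per shell)."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    bvals, bvecs = [], []
    for shell_idx, (b, n) in enumerate(((0, 20), (400, 64), (1000, 88), (2600, 128))):
        for k in range(n):
            bvals.append(float(b))
            if b == 0:
                bvecs.append([0.0, 0.0, 0.0])
            else:
                phi = golden * k + 2.0 * shell_idx
                z = 1.0 - (2.0 * k + 1.0) / n
                r = np.sqrt(max(0.0, 1.0 - z * z))
                bvecs.append([r * np.cos(phi), r * np.sin(phi), z])
    return GradientScheme(bvals=np.array(bvals), bvecs=np.array(bvecs))


@dataclass
class NoddiParams:
    """Per-voxel tissue parameters of the three-compartment model."""

    ndi: np.ndarray  # intra-neurite volume fraction in [0, 1]
    odi: np.ndarray  # orientation dispersion index in (0, 1]
    f_iso: np.ndarray  # free-water fraction in [0, 1]
    mu: np.ndarray  # mean neurite direction, unit vectors (..., 3)
    d_par: float = 1.7e-3  # intrinsic parallel diffusivity, mm^2/s
    d_iso: float = 3.0e-3  # free-water diffusivity, mm^2/s

    def __post_init__(self) -> None:
        self.ndi = np.asarray(self.ndi, dtype=float)
        self.odi = np.asarray(self.odi, dtype=float)
        self.f_iso = np.asarray(self.f_iso, dtype=float)
        self.mu = np.asarray(self.mu, dtype=float)
        if np.any(self.ndi < 0) or np.any(self.ndi > 1):
            raise ValueError("ndi must lie in [0, 1]")
        if np.any(self.f_iso < 0) or np.any(self.f_iso > 1):
            raise ValueError("f_iso must lie in [0, 1]")
        if np.any(self.odi <= 0) or np.any(self.odi > 1):
            raise ValueError("odi must lie in (0, 1]")
        if self.mu.shape[-1] != 3:
            raise ValueError("mu must have a trailing axis of length 3")
        if self.mu.shape[:-1] != self.ndi.shape:
            raise ValueError("mu grid does not match parameter grid")
        norms = np.linalg.norm(self.mu, axis=-1)
        if not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("mu must be unit-norm")

    @property
    def grid_shape(self) -> tuple:
        return self.ndi.shape


def noddi_signal(
    ndi: float,
    odi: float,
    f_iso: float,
    cos_angle: np.ndarray,
    bvals: np.ndarray,
    d_par: float = 1.7e-3,
    d_iso: float = 3.0e-3,
) -> np.ndarray:
    """Noise-free normalised signal S/S0 for one voxel.

    Intra-neurite: Watson-dispersed stick.  Extra-neurite: zeppelin whose
    tensor is the Watson average of an axially symmetric tensor with
    tortuosity d_perp = d_par * (1 - ndi).  Isotropic: free water.
    """
    kappa = float(kappa_from_odi(odi))
    bd = bvals * d_par
    a_intra = dispersed_stick_attenuation(bd, cos_angle, kappa)
    d_perp = d_par * (1.0 - ndi)
    tau1 = watson_tau1(kappa)
    d_ax = d_perp + (d_par - d_perp) * tau1
    d_rad = d_perp + (d_par - d_perp) * (1.0 - tau1) / 2.0
    a_extra = np.exp(-bvals * (d_rad + (d_ax - d_rad) * cos_angle**2))
    a_iso = np.exp(-bvals * d_iso)
    return (1.0 - f_iso) * (ndi * a_intra + (1.0 - ndi) * a_extra) + f_iso * a_iso


def simulate_dwi(
    params: NoddiParams,
    scheme: GradientScheme,
    snr: float | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Forward-simulate normalised multi-shell signals on a parameter grid.

    Returns an array of shape ``params.grid_shape + (n_volumes,)``.  With
    ``snr`` set, Rician noise is applied per channel (|S + complex Gaussian|)
    with sigma defined on the b=0 signal (S0 = 1)."""
    if len(scheme.b0_indices) < 1:
        raise ValueError("scheme needs at least one b=0 volume")
    grid = params.grid_shape
    ndi = params.ndi.ravel()
    odi = params.odi.ravel()
    f_iso = params.f_iso.ravel()
    mu = params.mu.reshape(-1, 3)
    nvol = len(scheme)
    out = np.empty((ndi.size, nvol), dtype=float)
    for v in range(ndi.size):
        cos_angle = scheme.bvecs @ mu[v]
        out[v] = noddi_signal(
            ndi[v], odi[v], f_iso[v], cos_angle, scheme.bvals,
            d_par=params.d_par, d_iso=params.d_iso,
        )
    if snr is not None:
        if snr <= 0:
            raise ValueError("snr must be positive")
        rng = np.random.default_rng(seed)
        sigma = 1.0 / snr
        out = np.abs(
            out
            + rng.normal(scale=sigma, size=out.shape)
            + 1j * rng.normal(scale=sigma, size=out.shape)
        )
    return out.reshape(grid + (nvol,))


# ---------------------------------------------------------------------------
# Cohort simulation


@dataclass
class CohortSpec:
    """Generative parameters for the two cohorts at tract-mean level.

    ``neonate_intercept`` and ``adult_mean`` give the per-bundle tract-mean
    value of each metric (neonates at the reference age); ``slope`` the
    neonatal change per week of post-menstrual age; ``factor_loading`` the
    per-metric weight on a shared per-subject maturation factor (this is
    what makes the six metrics covary); ``subject_sd`` the independent
    between-subject noise; ``hemi_sd`` the within-subject left/right
    fluctuation; ``voxel_sd`` the within-tract voxel noise used when
    painting metric maps.  Diffusivities are in mm^2/s; NDI/ODI/FA are
    dimensionless; ages in weeks (neonates) and years (adults).
    """

    n_neonates: int = 40
    n_adults: int = 40
    neonate_age_range: tuple = (37.0, 44.0)
    adult_age_range: tuple = (22.0, 35.0)
    age_distribution: str = "uniform"  # or "gaussian" (matched to 39.89 +/- 2.08)
    neonate_age_mean_sd: tuple = (39.89, 2.08)
    reference_age: float = 40.0
    neonate_intercept: dict = field(default_factory=dict)
    adult_mean: dict = field(default_factory=dict)
    slope: dict = field(default_factory=dict)
    factor_loading: dict = field(default_factory=dict)
    subject_sd: dict = field(default_factory=dict)
    hemi_sd: dict = field(default_factory=dict)
    voxel_sd: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.neonate_age_range
        if not (37.0 <= lo <= hi <= 44.0):
            raise ValueError("neonate ages must lie within 37-44 weeks PMA")
        lo, hi = self.adult_age_range
        if not (22.0 <= lo <= hi <= 35.0):
            raise ValueError("adult ages must lie within 22-35 years")
        for d in (self.subject_sd, self.hemi_sd, self.voxel_sd):
            if any(v < 0 for v in d.values()):
                raise ValueError("standard deviations must be >= 0")


#: adult tract-mean values per branch (plausible SLF magnitudes)
_ADULT_MEAN = {
    "SLF_I": dict(NDI=0.60, ODI=0.25, FA=0.45, MD=0.72e-3, AD=1.15e-3, RD=0.55e-3),
    "SLF_II": dict(NDI=0.62, ODI=0.26, FA=0.44, MD=0.70e-3, AD=1.13e-3, RD=0.54e-3),
    "SLF_III": dict(NDI=0.61, ODI=0.27, FA=0.46, MD=0.71e-3, AD=1.14e-3, RD=0.53e-3),
}

#: neonate-to-adult maturation span per metric (large for everything but ODI)
_MATURATION_SPAN = dict(
    NDI=0.37, ODI=0.02, FA=0.24, MD=-0.58e-3, AD=-0.45e-3, RD=-0.60e-3
)

#: fraction of the span still to travel at the reference age; the middle
#: branch lags roughly twice as far behind (in covariance-whitened units)
#: as the dorsal and ventral branches — the asynchrony the branch
#: comparison is designed to detect
_MATURATION_LAG = {"SLF_I": 0.55, "SLF_II": 1.0, "SLF_III": 0.6}


def default_cohort_spec(**overrides) -> CohortSpec:
    """The study-condition defaults: 40 + 40 subjects, SLF II least mature."""
    adult_mean = {b: dict(v) for b, v in _ADULT_MEAN.items()}
    neonate_intercept = {
        b: {
            m: adult_mean[b][m] - _MATURATION_LAG[b] * _MATURATION_SPAN[m]
            for m in METRICS
        }
        for b in BUNDLES
    }
    slope = dict(NDI=0.010, ODI=0.0, FA=0.007, MD=-0.020e-3, AD=-0.004e-3, RD=-0.025e-3)
    factor_loading = dict(
        NDI=0.018, ODI=0.008, FA=0.012, MD=-0.018e-3, AD=-0.015e-3, RD=-0.020e-3
    )
    subject_sd = dict(NDI=0.012, ODI=0.012, FA=0.010, MD=0.012e-3, AD=0.018e-3, RD=0.013e-3)
    hemi_sd = dict(NDI=0.004, ODI=0.004, FA=0.004, MD=0.004e-3, AD=0.006e-3, RD=0.005e-3)
    voxel_sd = dict(NDI=0.03, ODI=0.03, FA=0.03, MD=0.05e-3, AD=0.06e-3, RD=0.05e-3)
    defaults = dict(
        neonate_intercept=neonate_intercept,
        adult_mean=adult_mean,
        slope=slope,
        factor_loading=factor_loading,
        subject_sd=subject_sd,
        hemi_sd=hemi_sd,
        voxel_sd=voxel_sd,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


def _draw_ages(spec: CohortSpec, group: str, n: int, rng) -> np.ndarray:
    if group == "adult":
        lo, hi = spec.adult_age_range
        return rng.uniform(lo, hi, size=n)
    lo, hi = spec.neonate_age_range
    if spec.age_distribution == "gaussian":
        m, s = spec.neonate_age_mean_sd
        return np.clip(rng.normal(m, s, size=n), lo, hi)
    return rng.uniform(lo, hi, size=n)


def _subject_tract_values(spec: CohortSpec, group: str, age: float, rng) -> dict:
    """Latent per-hemisphere tract-mean values for one subject:
    {(bundle, metric, hemi): value}."""
    u = rng.normal()
    values = {}
    for bundle in BUNDLES:
        for metric in METRICS:
            if group == "neonate":
                base = spec.neonate_intercept[bundle][metric] + spec.slope[metric] * (
                    age - spec.reference_age
                )
            else:
                base = spec.adult_mean[bundle][metric]
            base += spec.factor_loading[metric] * u + rng.normal(
                scale=spec.subject_sd[metric]
            )
            for hemi in HEMISPHERES:
                values[(bundle, metric, hemi)] = base + rng.normal(
                    scale=spec.hemi_sd[metric]
                )
    return values


def simulate_cohort_tables(
    spec: CohortSpec | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw tract-mean cohort tables directly (no volumes): the fast path for
    statistical Monte-Carlo.  Returns (neonate, adult) wide DataFrames with
    columns ``{bundle}_{metric}_{L|R|LR}`` plus subject_id / group / age."""
    spec = spec or default_cohort_spec()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    frames = []
    for group, n in (("neonate", spec.n_neonates), ("adult", spec.n_adults)):
        ages = _draw_ages(spec, group, n, rng)
        rows = []
        for i in range(n):
            row = {
                "subject_id": f"{group}_{i:03d}",
                "group": group,
                "age": float(ages[i]),
            }
            vals = _subject_tract_values(spec, group, ages[i], rng)
            for bundle in BUNDLES:
                for metric in METRICS:
                    left = vals[(bundle, metric, "L")]
                    right = vals[(bundle, metric, "R")]
                    row[f"{bundle}_{metric}_L"] = left
                    row[f"{bundle}_{metric}_R"] = right
                    row[f"{bundle}_{metric}_LR"] = 0.5 * (left + right)
            rows.append(row)
        frames.append(pd.DataFrame(rows))
    return frames[0], frames[1]


# background (CSF-like) metric values outside all tract corridors
_BACKGROUND = dict(NDI=0.05, ODI=0.9, FA=0.05, MD=2.8e-3, AD=3.0e-3, RD=2.7e-3)


def bundle_corridor_mask(
    layout: PhantomLayout,
    waypoints: Sequence[str],
    radius_voxels: int = 4,
) -> np.ndarray:
    # radius must exceed the jittered vertex spread (~1.5 voxels) plus the
    # 1-voxel trilinear stencil, or edge vertices mix in background values
    # and induce a spurious, systematic lateralization
    """Binary mask of voxels within ``radius_voxels`` of the bundle's
    jitter-free centreline."""
    centreline = simulate_bundle(
        layout, waypoints, n=1, jitter=0.0, seed=0, step_mm=1.0
    ).streamlines[0]
    inv = np.linalg.inv(layout.affine)
    idx = np.floor(centreline @ inv[:3, :3].T + inv[:3, 3] + 0.5).astype(int)
    mask = np.zeros(layout.shape, dtype=bool)
    inside = np.all((idx >= 0) & (idx < np.array(layout.shape)), axis=1)
    idx = idx[inside]
    mask[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    return binary_dilation(mask, iterations=radius_voxels)


def simulate_cohorts(
    spec: CohortSpec | None = None,
    layout: PhantomLayout | None = None,
    seed: int | None = None,
    protocol_by_group: dict | None = None,
) -> Iterator[tuple[dict, dict]]:
    """Yield per-subject metric volumes for both cohorts.

    For each subject yields ``(subject_row, metric_volumes)`` where
    ``subject_row`` has subject_id / group / age and ``metric_volumes`` maps
    each of the six metric names to a :class:`VolumeImage`.  Voxels inside a
    bundle's corridor carry that subject's tract-level value for the bundle
    plus independent voxel noise; everything else is CSF-like background.
    """
    spec = spec or default_cohort_spec()
    if layout is None:
        layout, _ = make_phantom()
    protocol_by_group = protocol_by_group or {"neonate": "neonate", "adult": "adult"}
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    corridors = {}
    for group, protocol in protocol_by_group.items():
        comp_masks = {}
        for comp in default_bundle_mix(protocol):
            if comp.contaminant:
                continue
            bundle, hemi = comp.name.rsplit("_", 1)
            comp_masks[(bundle, hemi)] = bundle_corridor_mask(layout, comp.waypoints)
        corridors[group] = comp_masks

    for group, n in (("neonate", spec.n_neonates), ("adult", spec.n_adults)):
        ages = _draw_ages(spec, group, n, rng)
        for i in range(n):
            row = {
                "subject_id": f"{group}_{i:03d}",
                "group": group,
                "age": float(ages[i]),
            }
            vals = _subject_tract_values(spec, group, ages[i], rng)
            volumes = {}
            for metric in METRICS:
                data = np.full(layout.shape, _BACKGROUND[metric], dtype=float)
                for (bundle, hemi), mask in corridors[group].items():
                    noise = rng.normal(
                        scale=spec.voxel_sd[metric], size=int(mask.sum())
                    )
                    data[mask] = vals[(bundle, metric, hemi)] + noise
                volumes[metric] = VolumeImage(data=data, affine=layout.affine)
            yield row, volumes
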