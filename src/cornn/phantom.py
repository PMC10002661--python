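"""Synthetic fiber phantoms: self-contained subjects with known geometry.

A phantom subject carries everything the pipeline needs — an FOD grid built
from Watson kernels along analytic tube centerlines, a pseudo-structural
(T1w-like) image with tissue contrast, one-hot tissue masks, endpoint
parcels, context channels, and ground-truth bundle membership — on a small
isotropic grid (default 40^3 voxels at 2 mm).

Design notes
------------
Real anatomy is not translation-symmetric: the image content along a fiber
differs depending on where you are, which is exactly the cue a memory-based
propagator uses to keep its direction of travel.  An ideal homogeneous tube
would destroy that cue (forward and backward traversals would be
indistinguishable), so the phantoms modulate FOD amplitude and white-matter
intensity with (a) a monotone along-tract profile per bundle, emulating the
systematic along-tract microstructure gradients seen in tractometry, and
(b) a smooth multiplicative texture field with a component shared across
subjects (consistent anatomy) plus a smaller per-subject component.

Tissue layout: each tube is white matter (WM); 2-voxel-thick cortical-GM
caps close both ends of every bundle and double as endpoint parcels; a CSF
rim lines the volume boundary; the deep-GM channel exists (to honor the
4-channel tissue contract) but is empty in default phantoms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree

from .grids import ImageGrid
from .shbasis import N_COEFFS, project_kernel_batch

__all__ = [
    "FiberGeometry",
    "PhantomSubject",
    "make_phantom",
    "default_geometries",
    "make_default_subject",
    "normalize_to_brain_median",
    "build_feature_stack",
    "TISSUE_CGM",
    "TISSUE_DGM",
    "TISSUE_WM",
    "TISSUE_CSF",
]

# tissue channel order in every 4-channel mask grid
TISSUE_CGM, TISSUE_DGM, TISSUE_WM, TISSUE_CSF = 0, 1, 2, 3

CAP_EXTENSION_VOX = 2.0  # GM cap thickness along the fiber, voxels
CSF_RIM_VOX = 2  # CSF shell thickness at the volume boundary, voxels
TEXTURE_SIGMA_VOX = 2.0
# The modulation field has a fixed anatomical component shared by every
# subject (like real anatomy, which varies over space but is consistent
# across individuals) and a smaller per-subject random component.
TEXTURE_SHARED_AMPLITUDE = 0.3
TEXTURE_SUBJECT_AMPLITUDE = 0.08
_SHARED_FIELD_SEED = 1234509876
# Monotone along-tract amplitude profile (tractometry-style): real tracts
# show systematic along-tract microstructure gradients, and this is the
# cue that lets a memory-based propagator keep its direction of travel.
PROFILE_AMPLITUDE = 0.25


@dataclass
class FiberGeometry:
    """One analytic fiber bundle: a tube around a parametric centerline.

    kind 'straight' uses ``start``/``end`` (mm); kind 'arc' uses ``center``,
    ``radius_mm``, an orthonormal in-plane frame ``e1``/``e2`` and an angle
    range; kind 'crossing-pair' bundles two straight tubes (``start2``/
    ``end2``) that are expanded into two bundles at generation time.
    """

    kind: str
    tube_radius_mm: float = 6.0
    kappa: float = 15.0
    start: np.ndarray | None = None
    end: np.ndarray | None = None
    start2: np.ndarray | None = None
    end2: np.ndarray | None = None
    center: np.ndarray | None = None
    radius_mm: float | None = None
    e1: np.ndarray | None = None
    e2: np.ndarray | None = None
    angle_range: tuple[float, float] | None = None

    def sub_centerlines(self):
        """List of (point_fn, tangent_fn, length_mm) for each sub-bundle."""
        if self.kind == "straight":
            return [_segment(self.start, self.end)]
        if self.kind == "crossing-pair":
            return [_segment(self.start, self.end), _segment(self.start2, self.end2)]
        if self.kind == "arc":
            c = np.asarray(self.center, float)
            e1 = np.asarray(self.e1, float)
            e2 = np.asarray(self.e2, float)
            a0, a1 = self.angle_range
            r = float(self.radius_mm)

            def pt(t, a0=a0, a1=a1, c=c, e1=e1, e2=e2, r=r):
                a = a0 + np.asarray(t) * (a1 - a0)
                return c + r * (np.cos(a)[..., None] * e1 + np.sin(a)[..., None] * e2)

            def tan(t, a0=a0, a1=a1, e1=e1, e2=e2):
                a = a0 + np.asarray(t) * (a1 - a0)
                d = -np.sin(a)[..., None] * e1 + np.cos(a)[..., None] * e2
                return d * np.sign(a1 - a0)

            return [(pt, tan, abs(a1 - a0) * r)]
        raise ValueError(f"unknown geometry kind {self.kind!r}")

    def arc_length_mm(self) -> float:
        return self.sub_centerlines()[0][2]


def _segment(start, end):
    s = np.asarray(start, float)
    e = np.asarray(end, float)
    length = float(np.linalg.norm(e - s))
    d = (e - s) / length

    def pt(t, s=s, e=e):
        t = np.asarray(t)
        return s + t[..., None] * (e - s)

    def tan(t, d=d):
        t = np.asarray(t)
        return np.broadcast_to(d, t.shape + (3,)).copy()

    return pt, tan, length


@dataclass
class PhantomSubject:
    """A fully synthetic subject; all grids share one affine."""

    fod: ImageGrid  # C = 45
    t1w: ImageGrid  # C = 1, brain-median normalized
    tissue: ImageGrid  # C = 4, one-hot [cortical GM, deep GM, WM, CSF]
    parcellation: np.ndarray  # (X, Y, Z) int, endpoint parcels, 0 = none
    bundle_membership: np.ndarray  # (X, Y, Z, n_bundles) bool
    brain_mask: np.ndarray  # (X, Y, Z) bool
    context: ImageGrid  # feature stack from build_feature_stack
    geometries: list = field(default_factory=list)
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        return self.fod.affine

    @property
    def n_bundles(self) -> int:
        return self.bundle_membership.shape[3]

    def save(self, directory) -> None:
        import json
        from pathlib import Path

        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.fod.to_nifti(d / "fod.nii")
        self.t1w.to_nifti(d / "t1w.nii")
        self.tissue.to_nifti(d / "tissue.nii")
        self.context.to_nifti(d / "context.nii")
        ImageGrid(self.parcellation.astype(np.int16), self.affine).to_nifti(
            d / "parcellation.nii"
        )
        ImageGrid(self.bundle_membership.astype(np.int16), self.affine).to_nifti(
            d / "bundles.nii"
        )
        ImageGrid(self.brain_mask.astype(np.int16), self.affine).to_nifti(
            d / "brain_mask.nii"
        )
        manifest = {"seed": int(self.seed), "n_bundles": int(self.n_bundles)}
        (d / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory) -> "PhantomSubject":
        import json
        from pathlib import Path

        d = Path(directory)
        fod = ImageGrid.from_nifti(d / "fod.nii")
        manifest = json.loads((d / "manifest.json").read_text())
        return cls(
            fod=fod,
            t1w=ImageGrid.from_nifti(d / "t1w.nii"),
            tissue=ImageGrid.from_nifti(d / "tissue.nii"),
            parcellation=np.asarray(
                ImageGrid.from_nifti(d / "parcellation.nii").data[..., 0], dtype=np.int64
            ),
            bundle_membership=ImageGrid.from_nifti(d / "bundles.nii").data.astype(bool),
            brain_mask=ImageGrid.from_nifti(d / "brain_mask.nii").data[..., 0].astype(bool),
            context=ImageGrid.from_nifti(d / "context.nii"),
            seed=manifest["seed"],
        )


def _subvoxel_offsets() -> np.ndarray:
    """3x3x3 sub-voxel sample offsets in voxel units (27 samples)."""
    o = np.array([-1 / 3, 0.0, 1 / 3])
    return np.stack(np.meshgrid(o, o, o, indexing="ij"), axis=-1).reshape(-1, 3)


def make_phantom(
    geometries: list[FiberGeometry],
    grid_shape=(40, 40, 40),
    voxel_size: float = 2.0,
    seed: int = 0,
) -> PhantomSubject:
    """Build a complete synthetic subject from analytic fiber geometries.

    Per WM voxel the FOD is the partial-volume-weighted sum of Watson
    kernels about the local centerline tangents of every overlapping
    bundle, modulated by the subject's texture field.  Deterministic given
    ``seed``.
    """
    if not geometries:
        raise ValueError("need at least one geometry")
    if min(grid_shape) < 20:
        raise ValueError("grid_shape must be at least 20 voxels per axis")
    rng = np.random.default_rng(seed)
    dims = np.asarray(grid_shape, dtype=int)
    affine = np.diag([voxel_size] * 3 + [1.0])

    # flat arrays over all voxels
    ijk = np.stack(
        np.meshgrid(*[np.arange(n) for n in dims], indexing="ij"), axis=-1
    ).reshape(-1, 3)
    centers_mm = ijk * voxel_size  # affine is diagonal with zero offset
    sub = _subvoxel_offsets() * voxel_size  # (27, 3) mm
    n_vox = len(ijk)

    # expand crossing pairs into per-bundle centerlines
    lines = []
    for g in geometries:
        for pt, tan, length in g.sub_centerlines():
            lines.append((pt, tan, length, g))
    n_bundles = len(lines)

    weights = np.zeros((n_vox, n_bundles))
    cap_weights = np.zeros((n_vox, 2 * n_bundles))  # per bundle end
    tangents = np.zeros((n_vox, n_bundles, 3))
    t_par = np.zeros((n_vox, n_bundles))  # arclength parameter in [0, 1]
    for b, (pt, tan, length, g) in enumerate(lines):
        ext = CAP_EXTENSION_VOX * voxel_size / length  # cap extent in t units
        ts = np.linspace(-ext, 1.0 + ext, int(np.ceil(length / (0.25 * voxel_size))) + 1)
        cl = pt(ts)
        tree = cKDTree(cl)
        # candidate voxels: within tube radius + one voxel of the centerline
        d_c, idx_c = tree.query(centers_mm, workers=-1)
        cand = d_c <= g.tube_radius_mm + 2 * voxel_size
        pts = (centers_mm[cand][:, None, :] + sub[None, :, :]).reshape(-1, 3)
        d, idx = tree.query(pts, workers=-1)
        inside = (d <= g.tube_radius_mm).reshape(-1, 27)
        t_near = ts[idx].reshape(-1, 27)
        in_main = inside & (t_near >= 0) & (t_near <= 1)
        in_cap0 = inside & (t_near < 0)
        in_cap1 = inside & (t_near > 1)
        weights[cand, b] = in_main.mean(axis=1)
        cap_weights[cand, 2 * b] = in_cap0.mean(axis=1)
        cap_weights[cand, 2 * b + 1] = in_cap1.mean(axis=1)
        tangents[cand, b] = tan(np.clip(ts[idx_c[cand]], 0, 1))
        t_par[cand, b] = np.clip(ts[idx_c[cand]], 0, 1)

    # texture field shared by FOD amplitude and WM intensity: a fixed
    # "anatomical" component identical across subjects plus a per-subject
    # random component
    def _smooth_field(generator):
        f = gaussian_filter(
            generator.standard_normal(tuple(dims)), TEXTURE_SIGMA_VOX, mode="nearest"
        )
        return f / f.std()

    shared = _smooth_field(np.random.default_rng(_SHARED_FIELD_SEED))
    private = _smooth_field(rng)
    texture = np.clip(
        (1.0 + TEXTURE_SHARED_AMPLITUDE * shared)
        * (1.0 + TEXTURE_SUBJECT_AMPLITUDE * private),
        0.3,
        None,
    ).reshape(-1)

    # tissue assignment (priority: GM caps > WM > CSF rim)
    wm_total = weights.sum(axis=1)
    cap_total = cap_weights.sum(axis=1)
    wm = (wm_total > 0.05) & (cap_total <= wm_total)
    gm = (cap_total > 0.05) & ~wm
    on_rim = np.any((ijk < CSF_RIM_VOX) | (ijk >= dims - CSF_RIM_VOX), axis=1)
    csf = on_rim & ~wm & ~gm
    tissue = np.zeros((n_vox, 4))
    tissue[gm, TISSUE_CGM] = 1.0
    tissue[wm, TISSUE_WM] = 1.0
    tissue[csf, TISSUE_CSF] = 1.0
    # the brain is the union of the tissue classes; leaving it is a
    # stopping event for the anatomically constrained rules
    brain = wm | gm | csf

    # endpoint parcels: label 2b+1 / 2b+2 for the two ends of bundle b
    parcel = np.zeros(n_vox, dtype=np.int64)
    for c in range(2 * n_bundles):
        m = gm & (cap_weights[:, c] > 0.05)
        clash = m & (parcel > 0) & (parcel != c + 1)
        if np.any(clash):
            raise ValueError(
                f"endpoint parcels of different bundles overlap (cap {c + 1})"
            )
        parcel[m] = c + 1

    # FOD synthesis: batch-project Watson kernels at every (voxel, bundle);
    # each bundle carries a monotone along-tract amplitude profile
    profile = 1.0 + PROFILE_AMPLITUDE * (2.0 * t_par - 1.0)
    fod = np.zeros((n_vox, N_COEFFS))
    for b, (_, _, _, g) in enumerate(lines):
        m = wm & (weights[:, b] > 0)
        if not np.any(m):
            continue
        coeffs = project_kernel_batch(tangents[m, b], g.kappa)
        fod[m] += (weights[m, b] * texture[m] * profile[m, b])[:, None] * coeffs
    fod[~wm] = 0.0

    # pseudo-structural image: tissue contrasts + texture + smoothing + noise
    intensity = np.full(n_vox, 0.05)
    intensity = np.where(csf, 0.25, intensity)
    intensity = np.where(gm, 0.55, intensity)
    w_tot = weights.sum(axis=1)
    mean_profile = np.where(
        w_tot > 0, (weights * profile).sum(axis=1) / np.maximum(w_tot, 1e-12), 1.0
    )
    intensity = np.where(wm, texture * mean_profile, intensity)
    img = gaussian_filter(intensity.reshape(tuple(dims)), 1.0, mode="nearest")
    img += 0.02 * rng.standard_normal(img.shape)
    t1w = ImageGrid(img[..., None], affine)
    t1w = normalize_to_brain_median(t1w, brain.reshape(tuple(dims)))

    shape4 = tuple(dims)
    tissue_grid = ImageGrid(tissue.reshape(shape4 + (4,)), affine)
    fod_grid = ImageGrid(fod.reshape(shape4 + (N_COEFFS,)), affine)
    membership = (weights > 0.05).reshape(shape4 + (n_bundles,))
    parcel_grid = parcel.reshape(shape4)

    context = build_feature_stack(
        t1w,
        tissue_grid,
        parcel_grid,
        membership,
        region_channels=2 * n_bundles,
        bundle_channels=n_bundles,
    )
    return PhantomSubject(
        fod=fod_grid,
        t1w=t1w,
        tissue=tissue_grid,
        parcellation=parcel_grid,
        bundle_membership=membership,
        brain_mask=brain.reshape(shape4),
        context=context,
        geometries=geometries,
        seed=seed,
    )


def default_geometries(extent_mm: float = 80.0) -> list[FiberGeometry]:
    """Three bundles scaled to a cubic volume of the given extent: a
    90-degree crossing pair in the lower half and an arc in the upper
    half."""
    e = float(extent_mm)
    return [
        FiberGeometry(
            kind="crossing-pair",
            start=np.array([0.175 * e, 0.5 * e, 0.325 * e]),
            end=np.array([0.825 * e, 0.5 * e, 0.325 * e]),
            start2=np.array([0.5 * e, 0.175 * e, 0.325 * e]),
            end2=np.array([0.5 * e, 0.825 * e, 0.325 * e]),
        ),
        FiberGeometry(
            kind="arc",
            center=np.array([0.5 * e, 0.55 * e, 0.7 * e]),
            radius_mm=0.275 * e,
            e1=np.array([1.0, 0.0, 0.0]),
            e2=np.array([0.0, -1.0, 0.0]),
            angle_range=(np.deg2rad(20.0), np.deg2rad(160.0)),
        ),
    ]


def make_default_subject(
    seed: int = 0, grid_shape=(40, 40, 40), voxel_size: float = 2.0
) -> PhantomSubject:
    """Default desk-scale subject: three bundles scaled to the volume."""
    extent = grid_shape[0] * voxel_size
    return make_phantom(default_geometries(extent), grid_shape, voxel_size, seed)


def normalize_to_brain_median(image: ImageGrid, brain_mask: np.ndarray) -> ImageGrid:
    """Divide an intensity image by its median within the brain mask."""
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    med = np.median(image.data[mask])
    if med == 0:
        raise ValueError("median within brain mask is zero; cannot normalize")
    return image.with_data(image.data / med)


def build_feature_stack(
    t1w_like: ImageGrid,
    tissue_masks: ImageGrid,
    parcellation: np.ndarray,
    bundle_membership: np.ndarray,
    region_channels: int,
    bundle_channels: int,
) -> ImageGrid:
    """Stack the learning features: intensity, tissue, regions, bundles.

    Channel count = 1 + 4 + region_channels + bundle_channels; with the
    full anatomical-context configuration (46 regions, 72 bundles) this is
    123.  Declared channel counts may exceed the labels actually present;
    unused channels are zero-filled.  One-hot channels contain only {0, 1}.
    """
    if tissue_masks.n_channels != 4:
        raise ValueError("tissue_masks must have 4 channels")
    labels = np.asarray(parcellation)
    if labels.max() > region_channels:
        raise ValueError(
            f"parcel label {labels.max()} exceeds region_channels={region_channels}"
        )
    if bundle_membership.shape[3] > bundle_channels:
        raise ValueError(
            f"{bundle_membership.shape[3]} bundles exceed bundle_channels={bundle_channels}"
        )
    shape = t1w_like.shape
    out = np.zeros(shape + (1 + 4 + region_channels + bundle_channels,))
    out[..., 0] = t1w_like.data[..., 0]
    out[..., 1:5] = tissue_masks.data
    for r in range(1, region_channels + 1):
        out[..., 4 + r] = labels == r
    nb = bundle_membership.shape[3]
    out[..., 5 + region_channels : 5 + region_channels + nb] = bundle_membership
    return ImageGrid(out, t1w_like.affine.copy())
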