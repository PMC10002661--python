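"""Deterministic FOD-peak-following streamline propagation (the reference).

The propagation loop is the classic deterministic scheme: sample the FOD
grid at the current point (SAMP), pick the FOD peak best aligned with the
previous direction, and step x_{i+1} = x_i + gamma * d_i.  Seeds are tracked
bidirectionally (second pass along the antipode of the initial peak) and the
two halves are concatenated.  Anatomically constrained stopping rules, based
on the one-hot tissue masks, classify every new point as continue / accept /
reject.

Stopping rules (tissue lookup is nearest-voxel):

- inside WM with a valid peak: continue;
- entering cortical or deep GM: accept, keeping the entering point
  (cortical termination);
- entering CSF, leaving the brain mask, or leaving the grid: truncate at
  the last valid point; the finished streamline is then length-filtered;
- no FOD peak above the amplitude cutoff within the curvature limit:
  stop at the current point;
- exceeding the maximum length: stop.

A finished streamline is accepted iff its total length lies within
[min_length, max_length]; everything shorter or longer is rejected.

The tracker also produces training data: step labels in spherical
coordinates (theta, phi) and randomly ordered chunks of streamlines with
right-padded label arrays and validity masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import ImageGrid, samp, world_to_voxel
from .shbasis import best_aligned_peak_batch, extract_peaks_batch

__all__ = [
    "TrackerConfig",
    "Streamline",
    "Chunk",
    "propagate_reference",
    "step",
    "check_stopping",
    "seed_points",
    "track_reference",
    "make_labels",
    "angles_from_direction",
    "make_chunks",
]

# stopping codes
CONTINUE, STOP_KEEP, STOP_DROP, REJECT = 0, 1, 2, 3


@dataclass
class TrackerConfig:
    """Tracking parameters; defaults are conventional deterministic values."""

    step_gamma: float = 1.0  # mm
    max_angle_per_step: float = 45.0  # degrees
    fod_amp_cutoff: float = 0.1
    min_length: float = 10.0  # mm
    max_length: float = 200.0  # mm
    seeding_mode: str = "gmwm_interface"  # or "wm_random"
    n_streamlines: int = 1000
    seed: int = 0
    batch_size: int = 512
    max_seed_factor: float = 8.0  # seed budget = factor * n_streamlines

    def __post_init__(self):
        if self.step_gamma <= 0:
            raise ValueError("step_gamma must be positive")
        if not 0 < self.max_angle_per_step < 90:
            raise ValueError("max_angle_per_step must lie in (0, 90)")
        if self.min_length >= self.max_length:
            raise ValueError("min_length must be below max_length")


@dataclass
class Streamline:
    points: np.ndarray  # (n, 3) world mm, consecutive spacing = step_gamma
    status: str = "accepted"

    @property
    def length_mm(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    @property
    def span_mm(self) -> float:
        return float(np.linalg.norm(self.points[-1] - self.points[0]))


@dataclass
class Chunk:
    """Up to ``chunk_size`` streamlines with padded labels for training."""

    points: np.ndarray  # (n, L, 3) right-padded
    n_points: np.ndarray  # (n,)
    labels: np.ndarray  # (n, L-1, 2) theta/phi, right-padded
    valid: np.ndarray  # (n, L-1) bool

    @property
    def n_streamlines(self) -> int:
        return self.points.shape[0]


def step(x: np.ndarray, d: np.ndarray, gamma: float) -> np.ndarray:
    """Advance a point: x + gamma * d."""
    return np.asarray(x, float) + gamma * np.asarray(d, float)


def propagate_reference(fod: ImageGrid, x, prev_dir, cfg: TrackerConfig):
    """One deterministic propagation decision at a single point.

    Returns the sign-aligned best FOD peak direction, or ``None`` (the stop
    signal) when no peak clears the amplitude cutoff within the curvature
    limit.
    """
    vals, oob = samp(fod, np.asarray(x, float))
    if oob:
        return None
    dirs, amps, valid = best_aligned_peak_batch(
        vals[None, :], np.asarray(prev_dir, float)[None, :],
        cfg.max_angle_per_step, cfg.fod_amp_cutoff,
    )
    return dirs[0] if valid[0] else None


def _tissue_at(tissue: ImageGrid, points: np.ndarray):
    """Nearest-voxel one-hot tissue lookup; returns (B, 4) plus oob flags."""
    v = world_to_voxel(tissue, points)
    dims = np.asarray(tissue.shape)
    iv = np.rint(v).astype(np.int64)
    oob = np.any((iv < 0) | (iv >= dims), axis=1)
    iv = np.clip(iv, 0, dims - 1)
    return tissue.data[iv[:, 0], iv[:, 1], iv[:, 2]], oob, iv


def check_stopping(
    x_new: np.ndarray,
    tissue_masks: ImageGrid,
    length_so_far,
    cfg: TrackerConfig,
    brain_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Classify new point(s): continue / accept-stop / reject.

    ``length_so_far`` is the streamline length in mm including the step to
    ``x_new``.  Accept-stop comes in two flavors encoded internally: keep
    the entering point (GM termination, max-length cap) or drop it (CSF,
    brain exit, grid exit); rejection discards the whole streamline.
    Returns an int code array (CONTINUE / STOP_KEEP / STOP_DROP / REJECT).
    """
    pts = np.atleast_2d(np.asarray(x_new, float))
    length = np.atleast_1d(np.asarray(length_so_far, float))
    t, oob, iv = _tissue_at(tissue_masks, pts)
    cgm, dgm, wm, csf = t[:, 0] > 0.5, t[:, 1] > 0.5, t[:, 2] > 0.5, t[:, 3] > 0.5
    in_brain = np.ones(len(pts), dtype=bool)
    if brain_mask is not None:
        in_brain = brain_mask[iv[:, 0], iv[:, 1], iv[:, 2]] & ~oob
    else:
        in_brain = ~oob
    long_enough = length >= cfg.min_length
    code = np.full(len(pts), CONTINUE, dtype=np.int64)
    # leaving the brain or entering CSF: truncate; too-short fragments die
    bad = csf | ~in_brain
    code[bad & long_enough] = STOP_DROP
    code[bad & ~long_enough] = REJECT
    # GM entry: cortical termination, keep the point; the combined-length
    # filter (not this classifier) weeds out short GM-to-GM fragments
    gm_hit = (cgm | dgm) & ~bad
    code[gm_hit] = STOP_KEEP
    # max length cap
    code[(code == CONTINUE) & (length >= cfg.max_length)] = STOP_KEEP
    if np.asarray(x_new).ndim == 1:
        return code[0]
    return code


def seed_points(
    tissue_masks: ImageGrid, mode: str, n: int, seed: int
) -> np.ndarray:
    """Random seed points (world mm), uniform over the eligible voxel set.

    ``wm_random``: uniform over WM-mask voxel volumes.  ``gmwm_interface``:
    uniform over WM voxels 6-adjacent to a GM voxel.
    """
    wm = tissue_masks.data[..., 2] > 0.5
    gm = (tissue_masks.data[..., 0] > 0.5) | (tissue_masks.data[..., 1] > 0.5)
    if mode == "wm_random":
        eligible = wm
    elif mode == "gmwm_interface":
        adj = np.zeros_like(gm)
        for ax in range(3):
            for sh in (1, -1):
                adj |= np.roll(gm, sh, axis=ax)
        eligible = wm & adj
    else:
        raise ValueError(f"unknown seeding mode {mode!r}")
    idx = np.argwhere(eligible)
    if len(idx) == 0:
        raise ValueError(f"no eligible voxels for seeding mode {mode!r}")
    rng = np.random.default_rng(seed)
    chosen = idx[rng.integers(0, len(idx), size=n)]
    jitter = rng.uniform(-0.5, 0.5, size=(n, 3))
    vox = chosen + jitter
    return vox @ tissue_masks.affine[:3, :3].T + tissue_masks.affine[:3, 3]


def _track_half_batch(
    fod: ImageGrid,
    tissue: ImageGrid,
    brain_mask,
    starts: np.ndarray,
    dirs0: np.ndarray,
    base_length: np.ndarray,
    cfg: TrackerConfig,
    propagate,
):
    """Propagate one direction for a batch of seeds until all stop.

    ``propagate(points, prev_dirs, live)`` returns (dirs, valid) for the
    live subset.  Returns (list of per-streamline point arrays *excluding*
    the start point, rejected mask).
    """
    b = len(starts)
    max_steps = int(np.ceil(cfg.max_length / cfg.step_gamma)) + 2
    pts = np.zeros((b, max_steps, 3))
    n_pts = np.zeros(b, dtype=np.int64)
    cur = starts.copy()
    prev = dirs0.copy()
    length = base_length.copy()
    live = np.ones(b, dtype=bool)
    rejected = np.zeros(b, dtype=bool)
    while np.any(live):
        nxt = cur[live] + cfg.step_gamma * prev[live]
        length[live] += cfg.step_gamma
        code = check_stopping(nxt, tissue, length[live], cfg, brain_mask)
        li = np.nonzero(live)[0]
        keep = (code == CONTINUE) | (code == STOP_KEEP)
        lk = li[keep]
        pts[lk, n_pts[lk]] = nxt[keep]
        n_pts[lk] += 1
        rejected[li[code == REJECT]] = True
        cont = li[code == CONTINUE]
        live[:] = False
        if len(cont):
            cur[cont] = pts[cont, n_pts[cont] - 1]
            d, valid = propagate(cur[cont], prev[cont], cont)
            # no valid peak: stop here (length filter applied later)
            ok = cont[valid]
            prev[ok] = d[valid]
            live[ok] = True
    halves = [pts[i, : n_pts[i]] for i in range(b)]
    return halves, rejected, length


def track_reference(subject, cfg: TrackerConfig):
    """Bidirectional anatomically constrained deterministic tracking.

    Seeds per ``cfg.seeding_mode``; initial direction is the largest FOD
    peak at the seed, the second pass uses its antipode; each accepted
    streamline's point order is randomized (either orientation is equally
    valid training data).  Returns accepted :class:`Streamline` objects
    (at least ``cfg.n_streamlines`` unless the seed budget runs out).
    """
    fod, tissue, brain = subject.fod, subject.tissue, subject.brain_mask
    rng = np.random.default_rng(cfg.seed)
    accepted: list[Streamline] = []
    budget = int(cfg.max_seed_factor * cfg.n_streamlines)
    used = 0
    diag = {"rejected": 0, "no_first_peak": 0, "length_filtered": 0}

    def propagate(points, prev_dirs, _idx):
        vals, oob = samp(fod, points)
        dirs, amps, valid = best_aligned_peak_batch(
            vals, prev_dirs, cfg.max_angle_per_step, cfg.fod_amp_cutoff
        )
        valid &= ~oob
        return dirs, valid

    while len(accepted) < cfg.n_streamlines and used < budget:
        nb = min(cfg.batch_size, budget - used)
        seeds = seed_points(
            tissue, cfg.seeding_mode, nb, int(rng.integers(2**31))
        )
        used += nb
        vals, oob = samp(fod, seeds)
        peaks = extract_peaks_batch(vals, cfg.fod_amp_cutoff, max_peaks=1)
        has = np.array([len(p) > 0 for p in peaks]) & ~oob
        diag["no_first_peak"] += int((~has).sum())
        if not np.any(has):
            continue
        seeds = seeds[has]
        d0 = np.stack([p[0, :3] for p, h in zip(peaks, has) if h])
        half_a, rej_a, len_a = _track_half_batch(
            fod, tissue, brain, seeds, d0, np.zeros(len(seeds)), cfg, propagate
        )
        half_b, rej_b, _ = _track_half_batch(
            fod, tissue, brain, seeds, -d0, len_a, cfg, propagate
        )
        for i in range(len(seeds)):
            if rej_a[i] or rej_b[i]:
                diag["rejected"] += 1
                continue
            pts = np.concatenate(
                [half_a[i][::-1], seeds[i][None, :], half_b[i]], axis=0
            )
            length = cfg.step_gamma * (len(pts) - 1)
            if not (cfg.min_length <= length <= cfg.max_length):
                diag["length_filtered"] += 1
                continue
            if rng.random() < 0.5:
                pts = pts[::-1].copy()
            accepted.append(Streamline(points=pts))
            if len(accepted) >= cfg.n_streamlines:
                break
    if not accepted:
        raise RuntimeError(f"no streamlines accepted; diagnostics: {diag}")
    return accepted


def angles_from_direction(d: np.ndarray) -> np.ndarray:
    """Unit vector(s) -> (theta, phi); theta from +z, phi from +x, phi = 0
    at the poles."""
    single = np.asarray(d).ndim == 1
    d = np.atleast_2d(np.asarray(d, float))
    theta = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    at_pole = np.abs(d[:, 2]) >= 1.0 - 1e-12
    phi = np.where(at_pole, 0.0, np.arctan2(d[:, 1], d[:, 0]))
    out = np.stack([theta, phi], axis=1)
    return out[0] if single else out


def make_labels(s: Streamline) -> np.ndarray:
    """Per-step (theta, phi) labels; one fewer than the streamline's points."""
    pts = np.asarray(s.points if isinstance(s, Streamline) else s, float)
    if len(pts) < 2:
        raise ValueError("need at least 2 points for labels")
    steps = np.diff(pts, axis=0)
    norms = np.linalg.norm(steps, axis=1)
    if np.any(norms == 0):
        raise ValueError("duplicate consecutive points")
    return angles_from_direction(steps / norms[:, None])


def make_chunks(streamlines, chunk_size: int, seed: int = 0):
    """Randomly split streamlines into padded training chunks."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(streamlines))
    chunks = []
    for s0 in range(0, len(order), chunk_size):
        sel = order[s0 : s0 + chunk_size]
        group = [streamlines[i] for i in sel]
        lmax = max(len(s.points) for s in group)
        n = len(group)
        pts = np.zeros((n, lmax, 3))
        npts = np.zeros(n, dtype=np.int64)
        labels = np.zeros((n, lmax - 1, 2))
        valid = np.zeros((n, lmax - 1), dtype=bool)
        for i, s in enumerate(group):
            k = len(s.points)
            pts[i, :k] = s.points
            npts[i] = k
            labels[i, : k - 1] = make_labels(s)
            valid[i, : k - 1] = True
        chunks.append(Chunk(points=pts, n_points=npts, labels=labels, valid=valid))
    return chunks
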