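"""Batched bidirectional tracking with a trained propagator network.

The learned tracker mirrors the reference tracker's seeding and stopping
machinery but replaces peak-following with the network: at each point the
image grid (FOD grid for the teacher; the CONV-embedded feature grid for
the student, computed once per subject) is sampled with SAMP, the trunk
produces (theta, phi) and a new hidden state, and every live streamline in
the batch advances one step simultaneously.

White-matter seeding needs bidirectional tracking: after the first pass
stops, the streamline is flipped, a fresh forward pass over the reversed
point sequence (from a zero hidden state) rebuilds the memory, and tracking
continues out of the seed-side end.  Results are independent of the batch
size: every streamline's arithmetic involves only its own row.
"""

from __future__ import annotations

import numpy as np

from .cornn_models import StudentModel, PropagatorState, conv_embed, direction_from_angles
from .grids import ImageGrid, samp
from .reference_tracker import (
    CONTINUE,
    REJECT,
    STOP_DROP,
    STOP_KEEP,
    Streamline,
    TrackerConfig,
    check_stopping,
    seed_points,
)

__all__ = ["track_learned", "bidirectional_extend", "embed_for_model"]


def embed_for_model(model, subject) -> ImageGrid:
    """The grid a model propagates on: FODs for the teacher, CONV output
    for the student (computed once per subject)."""
    if isinstance(model, StudentModel):
        return conv_embed(model, subject.context)
    return subject.fod


def _masked_step(model, grid, points, state, active=None):
    """Sample + trunk step for a batch; rows outside ``active`` keep their
    state (used to right-align variable-length replay).

    Batches of fewer than four rows are zero-padded to four before the
    matrix products: BLAS's small-row kernels round differently from the
    blocked path, and tracking results must not depend on how many
    streamlines happen to be live (the batch-size-invariance contract).
    """
    n = len(points)
    pad = n < 4
    if pad:
        points = np.concatenate([points, np.repeat(points[-1:], 4 - n, axis=0)])
        state = PropagatorState(
            hidden=[
                np.concatenate([h, np.repeat(h[-1:], 4 - n, axis=0)])
                for h in state.hidden
            ]
        )
        if active is not None:
            active = np.concatenate([active, np.zeros(4 - n, dtype=bool)])
    vals, oob = samp(grid, points)
    angles, new_state = model.trunk_step(vals.astype(np.float32), state)
    if active is not None:
        keep = ~active
        for l in range(len(state.hidden)):
            new_state.hidden[l][keep] = state.hidden[l][keep]
    if pad:
        angles = angles[:n]
        new_state = new_state.select(np.arange(n))
        oob = oob[:n]
    return angles, new_state, oob


class _BatchHalfTracker:
    """Stateful half-tracking that keeps hidden states aligned with rows."""

    def __init__(self, model, grid, tissue, brain, cfg):
        self.model, self.grid = model, grid
        self.tissue, self.brain, self.cfg = tissue, brain, cfg

    def run(self, starts, states, dirs, base_len):
        cfg = self.cfg
        b = len(starts)
        max_steps = int(np.ceil(cfg.max_length / cfg.step_gamma)) + 2
        pts = np.zeros((b, max_steps, 3))
        n_pts = np.zeros(b, dtype=np.int64)
        rejected = np.zeros(b, dtype=bool)
        length = base_len.copy()
        rows = np.arange(b)  # global row of each live entry
        cur, d, state = starts.copy(), dirs.copy(), states
        while len(rows):
            nxt = cur + cfg.step_gamma * d
            length[rows] += cfg.step_gamma
            code = check_stopping(nxt, self.tissue, length[rows], cfg, self.brain)
            keep = (code == CONTINUE) | (code == STOP_KEEP)
            lk = rows[keep]
            pts[lk, n_pts[lk]] = nxt[keep]
            n_pts[lk] += 1
            rejected[rows[code == REJECT]] = True
            cont = code == CONTINUE
            rows = rows[cont]
            if not len(rows):
                break
            cur = nxt[cont]
            state = state.select(cont)
            angles, state, oob = _masked_step(self.model, self.grid, cur, state)
            d = direction_from_angles(angles[:, 0], angles[:, 1])
            if np.any(oob):
                ok = ~oob
                rows, cur, d = rows[ok], cur[ok], d[ok]
                state = state.select(ok)
        return [pts[i, : n_pts[i]] for i in range(b)], rejected, length


def _replay_states(model, grid, sequences, lengths):
    """Zero-state forward pass over right-aligned reversed sequences.

    ``sequences`` is (B, Lmax, 3) with each row's points occupying the last
    ``lengths[i]`` slots.  Returns the angles predicted at the final point
    and the hidden state after the full replay.
    """
    b, lmax, _ = sequences.shape
    state = PropagatorState.zeros(b)
    angles = np.zeros((b, 2), dtype=np.float32)
    for t in range(lmax):
        active = lengths > (lmax - 1 - t)
        if not np.any(active):
            continue
        a, state, _ = _masked_step(model, grid, sequences[:, t], state, active=active)
        angles[active] = a[active]
    return angles, state


def bidirectional_extend(model, grid, tissue, brain, first_half: np.ndarray, cfg):
    """Flip a tracked half, rebuild memory, and track the other way.

    ``first_half`` is an (n, 3) point array whose first point is the seed.
    Returns the combined points (far end -> seed -> extension).
    """
    rev = np.asarray(first_half, float)[::-1]
    b = _BatchHalfTracker(model, grid, tissue, brain, cfg)
    seq = rev[None, :, :]
    angles, state = _replay_states(model, grid, seq, np.array([len(rev)]))
    d = direction_from_angles(angles[:, 0], angles[:, 1])
    base = np.array([cfg.step_gamma * (len(rev) - 1)])
    halves, rejected, _ = b.run(rev[-1][None, :], state, d, base)
    return np.concatenate([rev, halves[0]], axis=0), bool(rejected[0])


def track_learned(model, subject, cfg: TrackerConfig, grid: ImageGrid | None = None):
    """Generate a tractogram with a trained model (teacher or student).

    Seeds in WM by default, tracks one direction from a zero hidden state,
    then flips and extends bidirectionally; batches continue until at least
    ``cfg.n_streamlines`` streamlines pass the length filter or the seed
    budget is exhausted.  Deterministic given (model, cfg).
    """
    if grid is None:
        grid = embed_for_model(model, subject)
    tissue, brain = subject.tissue, subject.brain_mask
    tracker = _BatchHalfTracker(model, grid, tissue, brain, cfg)
    accepted: list[Streamline] = []
    budget = int(cfg.max_seed_factor * cfg.n_streamlines)
    # the whole seed list is drawn once, so the tractogram is a pure
    # function of (model, config) and independent of the batch size
    seed_pool = seed_points(tissue, cfg.seeding_mode, budget, cfg.seed)
    used = 0
    reasons = {"rejected": 0, "length_filtered": 0}
    while len(accepted) < cfg.n_streamlines and used < budget:
        nb = min(cfg.batch_size, budget - used)
        seeds = seed_pool[used : used + nb]
        used += nb
        # first pass: direction predicted at the seed from a zero state
        state = PropagatorState.zeros(nb)
        angles, state, oob = _masked_step(model, grid, seeds, state)
        d0 = direction_from_angles(angles[:, 0], angles[:, 1])
        half_a, rej_a, len_a = tracker.run(seeds, state, d0, np.zeros(nb))
        # second pass: flip, replay, extend
        la = np.array([len(h) for h in half_a])
        lmax = int(la.max()) + 1
        seq = np.zeros((nb, lmax, 3))
        for i, h in enumerate(half_a):
            rev = np.concatenate([h[::-1], seeds[i][None, :]], axis=0)
            seq[i, lmax - len(rev) :] = rev
        angles_b, state_b = _replay_states(model, grid, seq, la + 1)
        d_b = direction_from_angles(angles_b[:, 0], angles_b[:, 1])
        half_b, rej_b, _ = tracker.run(
            seeds, state_b, d_b, cfg.step_gamma * la.astype(float)
        )
        for i in range(nb):
            if rej_a[i] or rej_b[i]:
                reasons["rejected"] += 1
                continue
            pts = np.concatenate(
                [half_a[i][::-1], seeds[i][None, :], half_b[i]], axis=0
            )
            length = cfg.step_gamma * (len(pts) - 1)
            if not (cfg.min_length <= length <= cfg.max_length):
                reasons["length_filtered"] += 1
                continue
            accepted.append(Streamline(points=pts))
            if len(accepted) >= cfg.n_streamlines:
                break
    if not accepted:
        raise RuntimeError(f"no streamlines accepted; rejection reasons: {reasons}")
    return accepted
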