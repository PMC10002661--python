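"""Teacher and student propagator networks (NumPy, hand-derived gradients).

Architecture (identical sequence trunk for both models):

- MLP: four blocks, each linear(512) -> batch-norm -> leaky ReLU (0.1),
  embedding the 45 sampled grid channels;
- GRU: two stacked gated-recurrent-unit layers, hidden width 512, carrying
  streamline memory;
- LIN: a linear map from the concatenated (MLP out, top GRU out) 1024-vector
  to the 2D output (theta, phi) of the next step direction.

The student adds a single 7x7x7 3D convolution (CONV) from the anatomical
feature stack to 45 channels — at 2 mm isotropic voxels a 1.4 cm receptive
field per axis — and reuses the teacher's GRU and LIN with frozen weights.
CONV output width 45 matches the MLP input width so the teacher's embedder
can supervise the student's via distillation.

All forward/backward passes are explicit NumPy; gradients are verified
against finite differences in the test suite.  Everything runs in float32.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np

from .grids import ImageGrid

__all__ = [
    "TeacherModel",
    "StudentModel",
    "PropagatorState",
    "direction_from_angles",
    "teacher_step",
    "conv_embed",
    "conv_patches",
    "transfer_and_freeze",
    "save_checkpoint",
    "load_checkpoint",
]

HIDDEN = 512
FOD_CHANNELS = 45
N_MLP_BLOCKS = 4
N_GRU_LAYERS = 2
CONV_KERNEL = 7
BN_EPS = 1e-5
BN_MOMENTUM = 0.1
LEAKY_SLOPE = 0.1
DTYPE = np.float32


def direction_from_angles(theta, phi) -> np.ndarray:
    """(theta, phi) -> unit vector (sin t cos p, sin t sin p, cos t)."""
    theta = np.asarray(theta, dtype=np.float64)
    phi = np.asarray(phi, dtype=np.float64)
    st = np.sin(theta)
    return np.stack([st * np.cos(phi), st * np.sin(phi), np.cos(theta)], axis=-1)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


# ---------------------------------------------------------------------------
# Parameter construction


def _linear_init(rng, fan_in, fan_out):
    bound = 1.0 / np.sqrt(fan_in)
    w = rng.uniform(-bound, bound, size=(fan_in, fan_out)).astype(DTYPE)
    b = rng.uniform(-bound, bound, size=fan_out).astype(DTYPE)
    return w, b


def _trunk_params(rng) -> dict:
    """MLP + GRU + LIN parameters (shared teacher/student trunk)."""
    p = {}
    widths = [FOD_CHANNELS] + [HIDDEN] * N_MLP_BLOCKS
    for i in range(N_MLP_BLOCKS):
        p[f"mlp{i}_W"], p[f"mlp{i}_b"] = _linear_init(rng, widths[i], widths[i + 1])
        p[f"mlp{i}_gamma"] = np.ones(HIDDEN, dtype=DTYPE)
        p[f"mlp{i}_beta"] = np.zeros(HIDDEN, dtype=DTYPE)
    for l in range(N_GRU_LAYERS):
        bound = 1.0 / np.sqrt(HIDDEN)
        p[f"gru{l}_Wih"] = rng.uniform(
            -bound, bound, size=(3 * HIDDEN, HIDDEN)
        ).astype(DTYPE)
        # orthogonal recurrent blocks and a positive update-gate bias: the
        # hidden state starts out persistent, which speeds up learning of
        # long-range streamline memory
        blocks = []
        for _ in range(3):
            q, _ = np.linalg.qr(rng.standard_normal((HIDDEN, HIDDEN)))
            blocks.append(q)
        p[f"gru{l}_Whh"] = np.concatenate(blocks, axis=0).astype(DTYPE)
        bih = np.zeros(3 * HIDDEN, dtype=DTYPE)
        bih[HIDDEN : 2 * HIDDEN] = 1.0
        p[f"gru{l}_bih"] = bih
        p[f"gru{l}_bhh"] = np.zeros(3 * HIDDEN, dtype=DTYPE)
    p["lin_W"], p["lin_b"] = _linear_init(rng, 2 * HIDDEN, 2)
    return p


def _trunk_param_count() -> int:
    """Closed-form parameter count of the trunk from the stated widths."""
    mlp = (FOD_CHANNELS * HIDDEN + HIDDEN) + 3 * (HIDDEN * HIDDEN + HIDDEN)
    mlp += N_MLP_BLOCKS * 2 * HIDDEN  # batch-norm affine
    gru = N_GRU_LAYERS * (2 * 3 * HIDDEN * HIDDEN + 2 * 3 * HIDDEN)
    lin = 2 * HIDDEN * 2 + 2
    return mlp + gru + lin


@dataclass
class _TrunkModel:
    """Shared MLP/GRU/LIN machinery; subclasses add their front end."""

    seed: int = 0
    params: dict = field(default_factory=dict)
    bn_running: dict = field(default_factory=dict)
    frozen: set = field(default_factory=set)

    def __post_init__(self):
        rng = np.random.default_rng(self.seed)
        if not self.params:
            self.params = self._init_params(rng)
        if not self.bn_running:
            for i in range(N_MLP_BLOCKS):
                self.bn_running[f"mlp{i}_mean"] = np.zeros(HIDDEN, dtype=DTYPE)
                self.bn_running[f"mlp{i}_var"] = np.ones(HIDDEN, dtype=DTYPE)
        got = sum(int(np.prod(v.shape)) for v in self.params.values())
        if got != self.expected_param_count():
            raise ValueError(
                f"parameter count {got} != expected {self.expected_param_count()}"
            )

    def _init_params(self, rng) -> dict:
        return _trunk_params(rng)

    def expected_param_count(self) -> int:
        return _trunk_param_count()

    # -- MLP ---------------------------------------------------------------
    def mlp_forward(self, x: np.ndarray, train: bool, cache: dict | None = None):
        """x (M, 45) -> (M, 512).  Training mode uses batch statistics and
        updates running averages; evaluation uses running averages."""
        h = x.astype(DTYPE)
        for i in range(N_MLP_BLOCKS):
            z = h @ self.params[f"mlp{i}_W"] + self.params[f"mlp{i}_b"]
            if train:
                mu = z.mean(axis=0)
                var = z.var(axis=0)
                m = z.shape[0]
                self.bn_running[f"mlp{i}_mean"] = (
                    (1 - BN_MOMENTUM) * self.bn_running[f"mlp{i}_mean"]
                    + BN_MOMENTUM * mu
                ).astype(DTYPE)
                unbiased = var * m / max(m - 1, 1)
                self.bn_running[f"mlp{i}_var"] = (
                    (1 - BN_MOMENTUM) * self.bn_running[f"mlp{i}_var"]
                    + BN_MOMENTUM * unbiased
                ).astype(DTYPE)
            else:
                mu = self.bn_running[f"mlp{i}_mean"]
                var = self.bn_running[f"mlp{i}_var"]
            inv = 1.0 / np.sqrt(var + BN_EPS)
            xhat = (z - mu) * inv
            y = self.params[f"mlp{i}_gamma"] * xhat + self.params[f"mlp{i}_beta"]
            out = np.where(y > 0, y, LEAKY_SLOPE * y)
            if cache is not None:
                cache[f"mlp{i}"] = (h, z, mu, inv, xhat, y)
            h = out.astype(DTYPE)
        return h

    def mlp_backward(self, d_out: np.ndarray, cache: dict, grads: dict, train: bool):
        """Backprop (M, 512) gradient through the MLP; returns d_input."""
        d = d_out.astype(DTYPE)
        for i in reversed(range(N_MLP_BLOCKS)):
            h, z, mu, inv, xhat, y = cache[f"mlp{i}"]
            d = np.where(y > 0, d, LEAKY_SLOPE * d)
            grads[f"mlp{i}_gamma"] = grads.get(f"mlp{i}_gamma", 0) + (d * xhat).sum(0)
            grads[f"mlp{i}_beta"] = grads.get(f"mlp{i}_beta", 0) + d.sum(0)
            dxhat = d * self.params[f"mlp{i}_gamma"]
            if train:
                m = z.shape[0]
                dz = (
                    dxhat - dxhat.mean(0) - xhat * (dxhat * xhat).mean(0)
                ) * inv
            else:
                dz = dxhat * inv
            grads[f"mlp{i}_W"] = grads.get(f"mlp{i}_W", 0) + h.T @ dz
            grads[f"mlp{i}_b"] = grads.get(f"mlp{i}_b", 0) + dz.sum(0)
            d = dz @ self.params[f"mlp{i}_W"].T
        return d

    # -- GRU ---------------------------------------------------------------
    def gru_cell(self, layer: int, x: np.ndarray, h: np.ndarray, cache=None):
        """One GRU step: x (B, 512), h (B, 512) -> h' (B, 512).

        Gate order (r, z, n); the hidden-side bias of the candidate gate
        sits inside the reset product, matching the common convention."""
        p = self.params
        gi = x @ p[f"gru{layer}_Wih"].T + p[f"gru{layer}_bih"]
        gh = h @ p[f"gru{layer}_Whh"].T + p[f"gru{layer}_bhh"]
        ir, iz, inn = np.split(gi, 3, axis=1)
        hr, hz, hn = np.split(gh, 3, axis=1)
        r = _sigmoid(ir + hr)
        z = _sigmoid(iz + hz)
        n = np.tanh(inn + r * hn)
        h_new = (1 - z) * n + z * h
        if cache is not None:
            cache.append((x, h, r, z, n, hn))
        return h_new.astype(DTYPE)

    def gru_cell_backward(self, layer: int, dh_new, cached, grads):
        """Backprop one GRU step; returns (d_x, d_h_prev)."""
        x, h, r, z, n, hn = cached
        p = self.params
        dn = dh_new * (1 - z)
        dz = dh_new * (h - n)
        dh = dh_new * z
        dan = dn * (1 - n * n)
        di_n = dan
        dr = dan * hn
        dhn = dan * r
        daz = dz * z * (1 - z)
        dar = dr * r * (1 - r)
        dgi = np.concatenate([dar, daz, di_n], axis=1).astype(DTYPE)
        dgh = np.concatenate([dar, daz, dhn], axis=1).astype(DTYPE)
        grads[f"gru{layer}_Wih"] = grads.get(f"gru{layer}_Wih", 0) + dgi.T @ x
        grads[f"gru{layer}_bih"] = grads.get(f"gru{layer}_bih", 0) + dgi.sum(0)
        grads[f"gru{layer}_Whh"] = grads.get(f"gru{layer}_Whh", 0) + dgh.T @ h
        grads[f"gru{layer}_bhh"] = grads.get(f"gru{layer}_bhh", 0) + dgh.sum(0)
        dx = dgi @ p[f"gru{layer}_Wih"]
        dh = dh + dgh @ p[f"gru{layer}_Whh"]
        return dx.astype(DTYPE), dh.astype(DTYPE)

    # -- full sequence pass ------------------------------------------------
    def forward_sequence(self, x: np.ndarray, valid: np.ndarray, train: bool):
        """x (N, L, 45), valid (N, L) -> preds (N, L, 2) plus a cache.

        The MLP runs on valid entries only (batch-norm statistics are taken
        over real, unpadded samples); the GRU runs across all steps, with
        padded inputs zero-filled — padding is on the right, so its hidden
        states never feed a valid step.  The input-side gate projections of
        each GRU layer are batched over all timesteps; only the hidden-side
        recurrence is sequential.
        """
        n, L, c = x.shape
        H = HIDDEN
        vi = np.nonzero(valid.reshape(-1))[0]
        flat = x.reshape(-1, c)[vi]
        cache = {"shape": (n, L), "vi": vi, "gru_layers": []}
        m = self.mlp_forward(flat, train, cache)
        mlp_out = np.zeros((n * L, H), dtype=DTYPE)
        mlp_out[vi] = m
        mlp_out = mlp_out.reshape(n, L, H)
        layer_in = mlp_out
        p = self.params
        for l in range(N_GRU_LAYERS):
            gi = (
                layer_in.reshape(-1, H) @ p[f"gru{l}_Wih"].T + p[f"gru{l}_bih"]
            ).reshape(n, L, 3 * H)
            R = np.empty((n, L, H), dtype=DTYPE)
            Z = np.empty((n, L, H), dtype=DTYPE)
            Nn = np.empty((n, L, H), dtype=DTYPE)
            HNpre = np.empty((n, L, H), dtype=DTYPE)
            Hprev = np.empty((n, L, H), dtype=DTYPE)
            Hout = np.empty((n, L, H), dtype=DTYPE)
            h = np.zeros((n, H), dtype=DTYPE)
            for t in range(L):
                gh = h @ p[f"gru{l}_Whh"].T + p[f"gru{l}_bhh"]
                r = _sigmoid(gi[:, t, :H] + gh[:, :H])
                z = _sigmoid(gi[:, t, H : 2 * H] + gh[:, H : 2 * H])
                hn = gh[:, 2 * H :]
                nn = np.tanh(gi[:, t, 2 * H :] + r * hn)
                Hprev[:, t] = h
                h = (1 - z) * nn + z * h
                R[:, t], Z[:, t], Nn[:, t], HNpre[:, t] = r, z, nn, hn
                Hout[:, t] = h
            cache["gru_layers"].append(
                {"x": layer_in, "R": R, "Z": Z, "N": Nn, "HN": HNpre, "Hprev": Hprev}
            )
            layer_in = Hout
        concat = np.concatenate([mlp_out, layer_in], axis=2)  # (N, L, 1024)
        preds = concat @ self.params["lin_W"] + self.params["lin_b"]
        cache["concat"] = concat
        cache["mlp_out"] = mlp_out
        return preds, cache

    def backward_sequence(
        self,
        d_preds: np.ndarray,
        cache: dict,
        train: bool = True,
        d_mlp_out_extra: np.ndarray | None = None,
    ):
        """Backprop through LIN, GRU (BPTT) and MLP.

        ``d_mlp_out_extra`` (N, L, 512) lets a distillation term inject
        gradient directly at the MLP output.  Returns (grads, d_x) where
        d_x is (N, L, 45) — the gradient at the sampled-feature input,
        which the student chains through SAMP into CONV.
        """
        n, L = cache["shape"]
        H = HIDDEN
        p = self.params
        grads: dict = {}
        d_preds = d_preds.astype(DTYPE)
        concat = cache["concat"]
        grads["lin_W"] = np.einsum("nlc,nlk->ck", concat, d_preds)
        grads["lin_b"] = d_preds.sum(axis=(0, 1))
        d_concat = d_preds @ self.params["lin_W"].T
        d_mlp_out = d_concat[:, :, :H].copy()
        dH = np.ascontiguousarray(d_concat[:, :, H:])  # grad w.r.t. top outputs
        if d_mlp_out_extra is not None:
            d_mlp_out += d_mlp_out_extra.astype(DTYPE)
        for l in reversed(range(N_GRU_LAYERS)):
            lay = cache["gru_layers"][l]
            dgi = np.empty((n, L, 3 * H), dtype=DTYPE)
            dgh = np.empty((n, L, 3 * H), dtype=DTYPE)
            dh_run = np.zeros((n, H), dtype=DTYPE)
            Whh = p[f"gru{l}_Whh"]
            for t in reversed(range(L)):
                dh = dH[:, t] + dh_run
                r, z, nn, hn = lay["R"][:, t], lay["Z"][:, t], lay["N"][:, t], lay["HN"][:, t]
                hprev = lay["Hprev"][:, t]
                dn = dh * (1 - z)
                dz = dh * (hprev - nn)
                dan = dn * (1 - nn * nn)
                dr = dan * hn
                dhn = dan * r
                daz = dz * z * (1 - z)
                dar = dr * r * (1 - r)
                dgi[:, t, :H] = dar
                dgi[:, t, H : 2 * H] = daz
                dgi[:, t, 2 * H :] = dan
                dgh[:, t, :H] = dar
                dgh[:, t, H : 2 * H] = daz
                dgh[:, t, 2 * H :] = dhn
                dh_run = dh * z + dgh[:, t] @ Whh
            dgi_f = dgi.reshape(-1, 3 * H)
            dgh_f = dgh.reshape(-1, 3 * H)
            x_f = lay["x"].reshape(-1, H)
            grads[f"gru{l}_Wih"] = dgi_f.T @ x_f
            grads[f"gru{l}_bih"] = dgi_f.sum(0)
            grads[f"gru{l}_Whh"] = dgh_f.T @ lay["Hprev"].reshape(-1, H)
            grads[f"gru{l}_bhh"] = dgh_f.sum(0)
            dH = (dgi_f @ p[f"gru{l}_Wih"]).reshape(n, L, H)
        d_gru_in = dH
        d_mlp_total = (d_mlp_out + d_gru_in).reshape(n * L, H)[cache["vi"]]
        d_flat = self.mlp_backward(d_mlp_total, cache, grads, train)
        d_x = np.zeros((n * L, d_flat.shape[1]), dtype=DTYPE)
        d_x[cache["vi"]] = d_flat
        return grads, d_x.reshape(n, L, -1)

    # -- single step (tracking) --------------------------------------------
    def trunk_step(self, features: np.ndarray, state: "PropagatorState"):
        """One evaluation-mode propagation step for a batch.

        features (B, 45) -> angles (B, 2) and the updated hidden state.
        """
        m = self.mlp_forward(features, train=False)
        h_new = []
        inp = m
        for l in range(N_GRU_LAYERS):
            hl = self.gru_cell(l, inp, state.hidden[l])
            h_new.append(hl)
            inp = hl
        concat = np.concatenate([m, h_new[-1]], axis=1)
        # the narrow (·, 1024) @ (1024, 2) product is computed as per-row
        # pairwise reductions: BLAS's narrow-output kernels round
        # differently for different row counts, which would break the
        # batch-size-invariance contract of batched tracking
        lin_w = self.params["lin_W"]
        angles = np.stack(
            [np.add.reduce(concat * lin_w[:, k][None, :], axis=1) for k in range(2)],
            axis=1,
        ) + self.params["lin_b"]
        return angles, PropagatorState(hidden=h_new)

    def trainable(self):
        return [k for k in self.params if k not in self.frozen]


@dataclass
class TeacherModel(_TrunkModel):
    """Propagator learning from FOD grids (45 input channels)."""


@dataclass
class StudentModel(_TrunkModel):
    """Propagator learning from structural features via a 7x7x7 CONV."""

    in_channels: int = 123

    def _init_params(self, rng) -> dict:
        p = _trunk_params(rng)
        fan_in = self.in_channels * CONV_KERNEL**3
        bound = 1.0 / np.sqrt(fan_in)
        p["conv_W"] = rng.uniform(
            -bound, bound, size=(fan_in, FOD_CHANNELS)
        ).astype(DTYPE)
        p["conv_b"] = rng.uniform(-bound, bound, size=FOD_CHANNELS).astype(DTYPE)
        return p

    def expected_param_count(self) -> int:
        k3 = CONV_KERNEL**3
        return _trunk_param_count() + self.in_channels * k3 * FOD_CHANNELS + FOD_CHANNELS

    @property
    def receptive_field_mm(self):
        """Per-axis receptive field of CONV at 2 mm voxels (= 14 mm)."""
        return CONV_KERNEL * 2.0


@dataclass
class PropagatorState:
    """Per-streamline GRU hidden state, one 512-vector per layer."""

    hidden: list  # N_GRU_LAYERS arrays of (B, 512)

    @classmethod
    def zeros(cls, batch: int) -> "PropagatorState":
        return cls(hidden=[np.zeros((batch, HIDDEN), dtype=DTYPE) for _ in range(N_GRU_LAYERS)])

    def select(self, mask) -> "PropagatorState":
        return PropagatorState(hidden=[h[mask] for h in self.hidden])


def teacher_step(model: _TrunkModel, fod_sample: np.ndarray, state: PropagatorState):
    """One propagation step: (theta, phi) and the new hidden state."""
    x = np.atleast_2d(np.asarray(fod_sample, dtype=DTYPE))
    if x.shape[1] != FOD_CHANNELS:
        raise ValueError(f"expected {FOD_CHANNELS} channels, got {x.shape[1]}")
    if state.hidden[0].shape[0] != x.shape[0]:
        raise ValueError("state batch size does not match input")
    angles, new_state = model.trunk_step(x, state)
    return angles, new_state


# ---------------------------------------------------------------------------
# Convolutional front end


def _pad_features(data: np.ndarray) -> np.ndarray:
    r = CONV_KERNEL // 2
    return np.pad(data, ((r, r), (r, r), (r, r), (0, 0)), mode="constant")


def _neighbor_offsets(dims_padded, n_channels) -> np.ndarray:
    """Flat offsets of the 7^3 window (x-fastest over dx, dy, dz) into a
    padded, channel-last flattened array."""
    px, py, pz = dims_padded
    offs = []
    for dx in range(CONV_KERNEL):
        for dy in range(CONV_KERNEL):
            for dz in range(CONV_KERNEL):
                offs.append(((dx * py + dy) * pz + dz) * n_channels)
    return np.asarray(offs, dtype=np.int64)


def conv_patches(features: ImageGrid, voxels: np.ndarray) -> np.ndarray:
    """im2col patches (V, 343 * C) at integer voxel coordinates.

    Patch layout is (dx, dy, dz, channel), matching ``conv_W``'s row order.
    Zero padding at the grid border.
    """
    data = np.ascontiguousarray(_pad_features(np.asarray(features.data, dtype=DTYPE)))
    dims_p = data.shape[:3]
    c = data.shape[3]
    flat = data.reshape(-1)
    v = np.asarray(voxels, dtype=np.int64)
    base = ((v[:, 0] * dims_p[1] + v[:, 1]) * dims_p[2] + v[:, 2]) * c
    offs = _neighbor_offsets(dims_p, c)
    idx = base[:, None] + offs[None, :]
    # gather whole channel runs: idx points at channel 0 of each tap
    out = flat[idx[:, :, None] + np.arange(c)[None, None, :]]
    return out.reshape(len(v), -1)


def conv_embed(model: StudentModel, features: ImageGrid, slab: int = 2) -> ImageGrid:
    """Full-grid CONV: features (X, Y, Z, C) -> learned 45-channel grid.

    Same-size zero padding; processed in z-slabs to bound memory.  Runs
    once per subject before tracking.
    """
    if features.n_channels != model.in_channels:
        raise ValueError(
            f"feature stack has {features.n_channels} channels; "
            f"model expects {model.in_channels}"
        )
    x, y, z = features.shape
    out = np.empty((x, y, z, FOD_CHANNELS), dtype=DTYPE)
    for x0 in range(0, x, slab):
        xs = np.arange(x0, min(x0 + slab, x))
        vox = np.stack(
            np.meshgrid(xs, np.arange(y), np.arange(z), indexing="ij"), axis=-1
        ).reshape(-1, 3)
        p = conv_patches(features, vox)
        out[xs[0] : xs[-1] + 1] = (
            p @ model.params["conv_W"] + model.params["conv_b"]
        ).reshape(len(xs), y, z, FOD_CHANNELS)
    return ImageGrid(out, features.affine.copy())


def transfer_and_freeze(teacher: TeacherModel, student: StudentModel) -> StudentModel:
    """Copy the teacher's GRU and LIN weights into the student and freeze
    them; subsequent training updates only CONV and the student MLP."""
    names = [k for k in teacher.params if k.startswith("gru") or k.startswith("lin")]
    for k in names:
        if teacher.params[k].shape != student.params[k].shape:
            raise ValueError(f"architecture mismatch for {k}")
        student.params[k] = teacher.params[k].copy()
    student.frozen = set(names)
    return student


# ---------------------------------------------------------------------------
# Checkpoints


def _arch_hash(model: _TrunkModel) -> str:
    desc = json.dumps(
        sorted((k, list(v.shape)) for k, v in model.params.items())
    )
    return hashlib.sha256(desc.encode()).hexdigest()[:16]


def save_checkpoint(model, path, epoch: int = 0, val_loss: float = float("nan")) -> None:
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays.update({f"bn_{k}": v for k, v in model.bn_running.items()})
    manifest = {
        "kind": type(model).__name__,
        "arch_hash": _arch_hash(model),
        "seed": int(model.seed),
        "epoch": int(epoch),
        "val_loss": float(val_loss),
        "frozen": sorted(model.frozen),
        "in_channels": int(getattr(model, "in_channels", FOD_CHANNELS)),
    }
    np.savez(path, manifest=json.dumps(manifest), **arrays)


def load_checkpoint(path):
    with np.load(path, allow_pickle=False) as z:
        manifest = json.loads(str(z["manifest"]))
        params = {k[6:]: z[k] for k in z.files if k.startswith("param_")}
        bn = {k[3:]: z[k] for k in z.files if k.startswith("bn_")}
    if manifest["kind"] == "StudentModel":
        model = StudentModel(
            seed=manifest["seed"],
            params=params,
            bn_running=bn,
            in_channels=manifest["in_channels"],
        )
    else:
        model = TeacherModel(seed=manifest["seed"], params=params, bn_running=bn)
    model.frozen = set(manifest["frozen"])
    if _arch_hash(model) != manifest["arch_hash"]:
        raise ValueError("checkpoint architecture hash mismatch")
    return model, manifest
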