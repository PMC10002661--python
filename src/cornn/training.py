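"""Teacher and student optimization: chunked cosine-loss training.

The supervision signal is the cosine similarity loss

    L_cos(z1, z2) = 1 - <z1, z2> / (|z1| |z2|),

applied between the predicted step direction (decoded from the network's
(theta, phi) output) and the reference step label, averaged over all valid
(unpadded) steps of a 1-chunk batch.  The student adds a distillation term:
the same cosine loss between its MLP embedding and the teacher's MLP
embedding of the true FOD sample at the same point, weighted by
``distill_weight``.

Optimization is Adam at a constant learning rate (default 0.001), batch
size 1 on the image level and one chunk of streamlines per step; one epoch
is one shuffled pass over all training chunks.  Training stops when the
validation loss has not improved for ``patience_epochs`` epochs, and the
parameters from the epoch with the lowest validation loss are returned.

A streamline of k points carries k - 1 step labels, so the prediction at a
streamline's last point is never supervised; point-validity masks gate the
MLP/batch-norm batch and label-validity masks gate the loss.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np

from .cornn_models import (
    DTYPE,
    FOD_CHANNELS,
    StudentModel,
    TeacherModel,
    conv_patches,
)
from .grids import samp_full

__all__ = [
    "TrainConfig",
    "SubjectData",
    "cosine_loss",
    "chunk_loss",
    "angles_loss_and_grad",
    "Adam",
    "prepare_teacher_data",
    "prepare_student_data",
    "train_teacher",
    "train_student",
]


@dataclass
class TrainConfig:
    learning_rate: float = 0.001  # constant; no schedule
    patience_epochs: int = 20
    max_epochs: int = 300
    chunk_size: int = 1000
    distill_weight: float = 1.0
    seed: int = 0

    def __post_init__(self):
        for name in ("learning_rate", "patience_epochs", "max_epochs", "chunk_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SubjectData:
    """A subject plus its reference streamline chunks (training unit)."""

    subject: object
    chunks: list


def cosine_loss(pred: np.ndarray, label: np.ndarray) -> np.ndarray:
    """1 - cos(angle between vectors); elementwise over the trailing axis."""
    p = np.asarray(pred, dtype=np.float64)
    l = np.asarray(label, dtype=np.float64)
    np_ = np.linalg.norm(p, axis=-1)
    nl = np.linalg.norm(l, axis=-1)
    if np.any(np_ == 0) or np.any(nl == 0):
        raise ValueError("cosine loss undefined for zero-norm vectors")
    return 1.0 - np.sum(p * l, axis=-1) / (np_ * nl)


def chunk_loss(preds: np.ndarray, labels: np.ndarray, valid: np.ndarray) -> float:
    """Mean cosine loss over valid steps; preds/labels are direction vectors."""
    v = np.asarray(valid, dtype=bool)
    if not v.any():
        raise ValueError("chunk has no valid steps")
    per = cosine_loss(preds[v], labels[v])
    return float(per.mean())


def angles_loss_and_grad(pred_angles, label_angles, label_valid):
    """Cosine loss directly in (theta, phi), plus its gradient.

    cos(angle) = sin tp sin tl cos(pp - pl) + cos tp cos tl; averaged over
    valid label steps, gradient zero at padding.
    """
    tp, pp = pred_angles[..., 0], pred_angles[..., 1]
    tl, pl = label_angles[..., 0], label_angles[..., 1]
    v = np.asarray(label_valid, dtype=bool)
    n = v.sum()
    dphi = pp - pl
    cosang = np.sin(tp) * np.sin(tl) * np.cos(dphi) + np.cos(tp) * np.cos(tl)
    loss = float((1.0 - cosang)[v].sum() / n)
    dtheta = -(np.cos(tp) * np.sin(tl) * np.cos(dphi) - np.sin(tp) * np.cos(tl))
    dphi_g = np.sin(tp) * np.sin(tl) * np.sin(dphi)
    grad = np.stack([dtheta, dphi_g], axis=-1) / n
    grad[~v] = 0.0
    return loss, grad.astype(DTYPE)


class Adam:
    """Standard Adam with bias correction; frozen parameters are skipped."""

    def __init__(self, model, lr: float, betas=(0.9, 0.999), eps: float = 1e-8):
        self.model = model
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in model.params.items()}
        self.v = {k: np.zeros_like(v) for k, v in model.params.items()}

    def step(self, grads: dict) -> None:
        self.t += 1
        for k in self.model.trainable():
            if k not in grads:
                continue
            g = np.asarray(grads[k], dtype=DTYPE)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            self.model.params[k] = (
                self.model.params[k] - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            ).astype(DTYPE)


# ---------------------------------------------------------------------------
# Data preparation (sampling geometry is fixed; computed once per corpus)


def _chunk_masks(ch):
    """Point-validity (n, L) and padded labels/label-validity (n, L, ...)."""
    n, L, _ = ch.points.shape
    pv = np.arange(L)[None, :] < ch.n_points[:, None]
    labels = np.zeros((n, L, 2))
    labels[:, : L - 1] = ch.labels
    lv = np.zeros((n, L), dtype=bool)
    lv[:, : L - 1] = ch.valid
    return pv, labels, lv


def prepare_teacher_data(data: SubjectData) -> list[dict]:
    """Sample the FOD grid at every chunk point; cache inputs and labels."""
    out = []
    fod = data.subject.fod
    for ch in data.chunks:
        n, L, _ = ch.points.shape
        pv, labels, lv = _chunk_masks(ch)
        res = samp_full(fod, ch.points.reshape(-1, 3))
        x = res["values"].reshape(n, L, FOD_CHANNELS).astype(DTYPE)
        x[~pv] = 0.0
        out.append({"x": x, "pv": pv, "labels": labels, "lv": lv})
    return out


def prepare_student_data(
    data: SubjectData, teacher: TeacherModel | None = None
) -> dict:
    """Per-subject cache for student training.

    The student's SAMP reads the CONV output grid, which changes with every
    update — but the streamline *points* are fixed.  So the trilinear corner
    indices and weights are precomputed per chunk, CONV is only ever
    evaluated on the union of corner voxels across the subject's chunks,
    and the im2col patches at those voxels are cached once per subject.
    Teacher MLP targets (evaluation mode, no gradient) are taken at the true
    FOD samples of the same points and stored at half precision.
    """
    subject = data.subject
    feat = subject.context
    dims = subject.fod.shape
    chunk_entries = []
    corner_sets = []
    for ch in data.chunks:
        res = samp_full(feat, ch.points.reshape(-1, 3))
        corner_sets.append(res["corner_indices"])
        pv, labels, lv = _chunk_masks(ch)
        entry = {
            "pv": pv,
            "labels": labels,
            "lv": lv,
            "weights": res["weights"].astype(DTYPE),
            "n": ch.points.shape[0],
            "L": ch.points.shape[1],
        }
        if teacher is not None:
            fres = samp_full(subject.fod, ch.points.reshape(-1, 3))
            x = fres["values"].astype(DTYPE)
            t_mlp = teacher.mlp_forward(x, train=False)
            t_mlp[~pv.reshape(-1)] = 0.0
            entry["teacher_mlp"] = t_mlp.astype(np.float16)
        chunk_entries.append(entry)
    uniq = np.unique(np.concatenate([c.ravel() for c in corner_sets]))
    lookup = np.zeros(int(uniq.max()) + 1, dtype=np.int64)
    lookup[uniq] = np.arange(len(uniq))
    for entry, corners in zip(chunk_entries, corner_sets):
        entry["corner_pos"] = lookup[corners]  # (NL, 8) into the voxel union
    vox = np.stack(np.unravel_index(uniq, dims), axis=1)
    patches = conv_patches(feat, vox)
    return {"patches": patches, "chunks": chunk_entries}


# ---------------------------------------------------------------------------
# Training loops


def _val_loss_teacher(model, val_sets) -> float:
    tot, n = 0.0, 0
    for chunks in val_sets:
        for ch in chunks:
            preds, _ = model.forward_sequence(ch["x"], ch["pv"], train=False)
            loss, _ = angles_loss_and_grad(preds, ch["labels"], ch["lv"])
            k = ch["lv"].sum()
            tot += loss * k
            n += k
    return tot / n


def _early_stop_loop(model, cfg, run_epoch, eval_val):
    """Shared epoch loop: best-checkpoint retention and patience stopping."""
    import logging

    log = logging.getLogger("cornn.training")
    history = []
    best = {"loss": np.inf, "params": None, "bn": None, "epoch": -1}
    for epoch in range(cfg.max_epochs):
        row = run_epoch(epoch)
        row.update(eval_val())
        row["epoch"] = epoch
        history.append(row)
        log.info(
            "epoch %d train %.4f val %.4f", epoch, row["train_loss"], row["val_loss"]
        )
        if row["val_loss"] < best["loss"]:
            best = {
                "loss": row["val_loss"],
                "params": copy.deepcopy(model.params),
                "bn": copy.deepcopy(model.bn_running),
                "epoch": epoch,
            }
        elif epoch - best["epoch"] >= cfg.patience_epochs:
            break
    model.params = best["params"]
    model.bn_running = best["bn"]
    return history


def train_teacher(model: TeacherModel, train_data, val_data, cfg: TrainConfig):
    """Optimize the teacher on reference chunks; returns (model, history).

    ``train_data`` / ``val_data`` are disjoint lists of :class:`SubjectData`.
    The returned model carries the parameters of the epoch with the lowest
    validation loss.
    """
    rng = np.random.default_rng(cfg.seed)
    train_sets = [prepare_teacher_data(d) for d in train_data]
    val_sets = [prepare_teacher_data(d) for d in val_data]
    pool = [(i, j) for i, s in enumerate(train_sets) for j in range(len(s))]
    opt = Adam(model, cfg.learning_rate)

    def run_epoch(epoch):
        ep_loss = []
        for k in rng.permutation(len(pool)):
            i, j = pool[k]
            ch = train_sets[i][j]
            preds, cache = model.forward_sequence(ch["x"], ch["pv"], train=True)
            loss, g = angles_loss_and_grad(preds, ch["labels"], ch["lv"])
            if not np.isfinite(loss):
                raise RuntimeError(f"training diverged at epoch {epoch} (loss={loss})")
            grads, _ = model.backward_sequence(g, cache, train=True)
            opt.step(grads)
            ep_loss.append(loss)
        return {"train_loss": float(np.mean(ep_loss))}

    history = _early_stop_loop(
        model, cfg, run_epoch, lambda: {"val_loss": _val_loss_teacher(model, val_sets)}
    )
    return model, history


def _student_forward(model, subj_set, ch, train: bool):
    """CONV at cached union voxels -> SAMP -> trunk."""
    conv_out = subj_set["patches"] @ model.params["conv_W"] + model.params["conv_b"]
    gathered = conv_out[ch["corner_pos"]]  # (NL, 8, 45)
    x = np.einsum("nkc,nk->nc", gathered, ch["weights"]).astype(DTYPE)
    n, L = ch["n"], ch["L"]
    x = x.reshape(n, L, FOD_CHANNELS)
    x[~ch["pv"]] = 0.0
    preds, seq_cache = model.forward_sequence(x, ch["pv"], train=train)
    return preds, seq_cache, conv_out


def _distill_loss_grad(student_mlp, teacher_mlp, mask_flat):
    """Mean cosine loss between embeddings + gradient w.r.t. the student's."""
    rows = np.nonzero(mask_flat)[0]
    a = student_mlp[rows].astype(np.float64)
    b = teacher_mlp[rows].astype(np.float64)
    n = len(rows)
    na = np.linalg.norm(a, axis=1, keepdims=True)
    nb = np.linalg.norm(b, axis=1, keepdims=True)
    na = np.where(na == 0, 1.0, na)
    nb = np.where(nb == 0, 1.0, nb)
    cos = np.sum(a * b, axis=1, keepdims=True) / (na * nb)
    loss = float((1.0 - cos).sum() / n)
    grad_rows = -(b / (na * nb) - cos * a / (na * na)) / n
    grad = np.zeros_like(student_mlp, dtype=DTYPE)
    grad[rows] = grad_rows.astype(DTYPE)
    return loss, grad


def _student_losses(model, subj_set, ch, train: bool, distill: bool):
    preds, cache, conv_out = _student_forward(model, subj_set, ch, train)
    loss, g = angles_loss_and_grad(preds, ch["labels"], ch["lv"])
    dl, dgrad = 0.0, None
    if distill and "teacher_mlp" in ch:
        s_mlp = cache["mlp_out"].reshape(-1, cache["mlp_out"].shape[-1])
        dl, dgrad = _distill_loss_grad(
            s_mlp, ch["teacher_mlp"].astype(DTYPE), ch["lv"].reshape(-1)
        )
    return preds, cache, conv_out, loss, g, dl, dgrad


def student_loss_and_grads(student, subj_set, ch, distill_weight: float):
    """One full student forward/backward on a chunk.

    Returns (total_loss, grads) with the CONV gradient assembled through
    the trilinear-sampling adjoint: the sampled-feature gradient is
    scattered onto the CONV output voxels with the cached corner weights,
    then contracted with the im2col patches.
    """
    n, L = ch["n"], ch["L"]
    preds, cache, conv_out, loss, g, dl, dgrad = _student_losses(
        student, subj_set, ch, train=True, distill=distill_weight != 0.0
    )
    total = loss + distill_weight * dl
    extra = (distill_weight * dgrad).reshape(n, L, -1) if dgrad is not None else None
    grads, d_x = student.backward_sequence(g, cache, train=True, d_mlp_out_extra=extra)
    d_x_flat = d_x.reshape(-1, FOD_CHANNELS)
    d_conv = np.zeros_like(conv_out)
    contrib = ch["weights"][:, :, None] * d_x_flat[:, None, :]
    np.add.at(d_conv, ch["corner_pos"].ravel(), contrib.reshape(-1, FOD_CHANNELS))
    grads["conv_W"] = subj_set["patches"].T @ d_conv
    grads["conv_b"] = d_conv.sum(0)
    return total, grads


def train_student(
    teacher: TeacherModel,
    student: StudentModel,
    train_data,
    val_data,
    cfg: TrainConfig,
):
    """Distill the student against labels and the teacher's MLP embedding.

    Total loss per chunk = label cosine loss + distill_weight * mean cosine
    loss between student and teacher MLP outputs over valid steps.  The
    student's GRU/LIN must already be frozen transfers from the teacher;
    gradients reach CONV through the trilinear-sampling adjoint.
    """
    if not any(k.startswith("gru") for k in student.frozen) or not any(
        k.startswith("lin") for k in student.frozen
    ):
        raise ValueError("student GRU/LIN must be frozen before training")
    rng = np.random.default_rng(cfg.seed)
    train_sets = [prepare_student_data(d, teacher) for d in train_data]
    val_sets = [prepare_student_data(d, teacher) for d in val_data]
    pool = [
        (i, j) for i, s in enumerate(train_sets) for j in range(len(s["chunks"]))
    ]
    opt = Adam(student, cfg.learning_rate)
    use_distill = cfg.distill_weight != 0.0

    def run_epoch(epoch):
        ep_loss = []
        for k in rng.permutation(len(pool)):
            i, j = pool[k]
            subj_set = train_sets[i]
            total, grads = student_loss_and_grads(
                student, subj_set, subj_set["chunks"][j], cfg.distill_weight
            )
            if not np.isfinite(total):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            opt.step(grads)
            ep_loss.append(total)
        return {"train_loss": float(np.mean(ep_loss))}

    def eval_val():
        lab_tot, dis_tot, n = 0.0, 0.0, 0
        for s in val_sets:
            for ch in s["chunks"]:
                _, _, _, loss, _, dl, _ = _student_losses(
                    student, s, ch, train=False, distill=use_distill
                )
                k = ch["lv"].sum()
                lab_tot += loss * k
                dis_tot += dl * k
                n += k
        return {
            "val_loss": (lab_tot + cfg.distill_weight * dis_tot) / n,
            "val_label_loss": lab_tot / n,
            "val_distill_loss": dis_tot / n,
        }

    history = _early_stop_loop(student, cfg, run_epoch, eval_val)
    return student, history
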