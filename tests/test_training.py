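"""Loss functions, optimizer contracts, and short training-loop behavior."""

import numpy as np
import pytest

from cornn.cornn_models import StudentModel, TeacherModel, transfer_and_freeze
from cornn.training import (
    Adam,
    SubjectData,
    TrainConfig,
    angles_loss_and_grad,
    chunk_loss,
    cosine_loss,
    prepare_teacher_data,
    train_student,
    train_teacher,
)


class TestCosineLoss:
    def test_identical_vectors(self, rng):
        v = rng.standard_normal(3)
        assert np.isclose(cosine_loss(v, v), 0.0)

    def test_orthogonal_vectors(self):
        assert np.isclose(cosine_loss([1.0, 0, 0], [0, 1.0, 0]), 1.0)

    def test_antiparallel_vectors(self):
        assert np.isclose(cosine_loss([1.0, 0, 0], [-2.0, 0, 0]), 2.0)

    def test_scale_invariance(self, rng):
        a, b = rng.standard_normal((2, 3))
        assert np.isclose(cosine_loss(a, b), cosine_loss(3 * a, 0.5 * b))

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_loss(np.zeros(3), np.ones(3))

    def test_range(self, rng):
        a = rng.standard_normal((100, 3))
        b = rng.standard_normal((100, 3))
        v = cosine_loss(a, b)
        assert (v >= 0).all() and (v <= 2).all()


class TestChunkLoss:
    def test_perfect_predictions(self, rng):
        labels = rng.standard_normal((4, 6, 3))
        valid = np.ones((4, 6), bool)
        assert abs(chunk_loss(labels, labels, valid)) < 1e-12

    def test_half_antiparallel_is_one(self):
        labels = np.tile([1.0, 0, 0], (2, 4, 1))
        preds = labels.copy()
        preds[1] *= -1
        valid = np.ones((2, 4), bool)
        assert np.isclose(chunk_loss(preds, labels, valid), 1.0)

    def test_padding_perturbation_is_ignored(self, rng):
        labels = rng.standard_normal((3, 5, 3))
        preds = labels.copy()
        valid = np.ones((3, 5), bool)
        valid[:, 3:] = False
        base = chunk_loss(preds, labels, valid)
        preds[:, 3:] = rng.standard_normal((3, 2, 3))
        assert chunk_loss(preds, labels, valid) == base

    def test_empty_mask_rejected(self, rng):
        with pytest.raises(ValueError):
            chunk_loss(np.ones((2, 2, 3)), np.ones((2, 2, 3)),
                       np.zeros((2, 2), bool))


class TestAnglesLoss:
    def test_matches_vector_cosine_loss(self, rng):
        from cornn.cornn_models import direction_from_angles

        pa = np.stack([rng.uniform(0, np.pi, (3, 4)),
                       rng.uniform(-np.pi, np.pi, (3, 4))], axis=-1)
        la = np.stack([rng.uniform(0, np.pi, (3, 4)),
                       rng.uniform(-np.pi, np.pi, (3, 4))], axis=-1)
        valid = rng.random((3, 4)) > 0.3
        loss, _ = angles_loss_and_grad(pa, la, valid)
        pv = direction_from_angles(pa[..., 0], pa[..., 1])
        lv = direction_from_angles(la[..., 0], la[..., 1])
        assert np.isclose(loss, chunk_loss(pv, lv, valid), atol=1e-12)

    def test_gradient_matches_finite_differences(self, rng):
        pa = np.stack([rng.uniform(0.3, np.pi - 0.3, (2, 3)),
                       rng.uniform(-2.0, 2.0, (2, 3))], axis=-1)
        la = np.stack([rng.uniform(0.3, np.pi - 0.3, (2, 3)),
                       rng.uniform(-2.0, 2.0, (2, 3))], axis=-1)
        valid = np.ones((2, 3), bool)
        _, g = angles_loss_and_grad(pa, la, valid)
        eps = 1e-6
        for idx in [(0, 0, 0), (1, 2, 1), (0, 1, 1)]:
            up, dn = pa.copy(), pa.copy()
            up[idx] += eps
            dn[idx] -= eps
            lp, _ = angles_loss_and_grad(up, la, valid)
            lm, _ = angles_loss_and_grad(dn, la, valid)
            assert np.isclose((lp - lm) / (2 * eps), g[idx], atol=1e-6)


class TestAdam:
    def test_frozen_parameters_never_move(self):
        t = TeacherModel(seed=0)
        s = StudentModel(seed=1, in_channels=5)
        s = transfer_and_freeze(t, s)
        opt = Adam(s, lr=0.1)
        before = {k: s.params[k].copy() for k in s.frozen}
        grads = {k: np.ones_like(v) for k, v in s.params.items()}
        for _ in range(3):
            opt.step(grads)
        for k in s.frozen:
            assert np.array_equal(s.params[k], before[k])
        assert not np.array_equal(s.params["conv_W"],
                                  StudentModel(seed=1, in_channels=5).params["conv_W"])

    def test_descends_a_quadratic(self):
        class Toy:
            params = {"w": np.array([5.0], dtype=np.float32)}

            def trainable(self):
                return ["w"]

        toy = Toy()
        opt = Adam(toy, lr=0.05)
        for _ in range(400):
            opt.step({"w": 2 * toy.params["w"]})
        assert abs(toy.params["w"][0]) < 0.1


class TestTrainConfig:
    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=0)

    def test_paper_values_are_defaults(self):
        cfg = TrainConfig()
        assert cfg.learning_rate == 0.001
        assert cfg.chunk_size == 1000
        assert cfg.distill_weight == 1.0


class TestTrainingLoops:
    """Short loops on the session corpus; behavioral contracts only."""

    def test_teacher_loss_trajectory_deterministic(self, subject, val_subject,
                                                   reference_chunks):
        tr = SubjectData(subject, reference_chunks[:1])
        va = SubjectData(val_subject, reference_chunks[1:2])
        cfg = TrainConfig(max_epochs=2, patience_epochs=5, seed=3)
        _, h1 = train_teacher(TeacherModel(seed=1), [tr], [va], cfg)
        _, h2 = train_teacher(TeacherModel(seed=1), [tr], [va], cfg)
        assert [r["train_loss"] for r in h1] == [r["train_loss"] for r in h2]
        assert [r["val_loss"] for r in h1] == [r["val_loss"] for r in h2]

    def test_teacher_loss_decreases(self, subject, val_subject, reference_chunks):
        tr = SubjectData(subject, reference_chunks[:2])
        va = SubjectData(val_subject, reference_chunks[2:3])
        cfg = TrainConfig(max_epochs=4, patience_epochs=10, seed=3)
        _, hist = train_teacher(TeacherModel(seed=1), [tr], [va], cfg)
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_best_checkpoint_is_min_val_loss(self, subject, val_subject,
                                             reference_chunks):
        tr = SubjectData(subject, reference_chunks[:1])
        va = SubjectData(val_subject, reference_chunks[1:2])
        cfg = TrainConfig(max_epochs=3, patience_epochs=10, seed=3)
        model, hist = train_teacher(TeacherModel(seed=1), [tr], [va], cfg)
        from cornn.training import _val_loss_teacher, prepare_teacher_data

        vl = _val_loss_teacher(model, [prepare_teacher_data(va)])
        assert np.isclose(vl, min(r["val_loss"] for r in hist), atol=1e-6)

    def test_student_frozen_params_bit_identical_after_training(
        self, subject, val_subject, reference_chunks
    ):
        teacher = TeacherModel(seed=1)
        student = StudentModel(seed=2, in_channels=subject.context.n_channels)
        student = transfer_and_freeze(teacher, student)
        frozen_before = {k: student.params[k].copy() for k in student.frozen}
        conv_before = student.params["conv_W"].copy()
        tr = SubjectData(subject, reference_chunks[:1])
        va = SubjectData(val_subject, reference_chunks[1:2])
        cfg = TrainConfig(max_epochs=2, patience_epochs=5, seed=3)
        student, hist = train_student(teacher, student, [tr], [va], cfg)
        for k in frozen_before:
            assert np.array_equal(student.params[k], frozen_before[k])
        assert not np.array_equal(student.params["conv_W"], conv_before)

    def test_student_requires_frozen_transfer(self, subject, val_subject,
                                              reference_chunks):
        teacher = TeacherModel(seed=1)
        student = StudentModel(seed=2, in_channels=subject.context.n_channels)
        tr = SubjectData(subject, reference_chunks[:1])
        va = SubjectData(val_subject, reference_chunks[1:2])
        with pytest.raises(ValueError, match="frozen"):
            train_student(teacher, student, [tr], [va],
                          TrainConfig(max_epochs=1, seed=0))

    def test_zero_distill_weight_reduces_to_label_loss(
        self, subject, val_subject, reference_chunks
    ):
        teacher = TeacherModel(seed=1)
        student = StudentModel(seed=2, in_channels=subject.context.n_channels)
        student = transfer_and_freeze(teacher, student)
        tr = SubjectData(subject, reference_chunks[:1])
        va = SubjectData(val_subject, reference_chunks[1:2])
        cfg = TrainConfig(max_epochs=1, patience_epochs=5, seed=3,
                          distill_weight=0.0)
        _, hist = train_student(teacher, student, [tr], [va], cfg)
        assert np.isclose(hist[0]["val_loss"], hist[0]["val_label_loss"])
        assert hist[0]["val_distill_loss"] == 0.0

    def test_conv_gradient_flows_through_samp_adjoint(self, subject,
                                                      reference_chunks):
        """End-to-end differentiability: the CONV weight gradient computed
        through the trilinear-sampling adjoint matches finite differences
        of the actual chunk loss."""
        import copy

        import cornn.cornn_models as cm
        from cornn.training import (
            _student_losses,
            prepare_student_data,
            student_loss_and_grads,
        )

        teacher = TeacherModel(seed=1)
        student = StudentModel(seed=2, in_channels=subject.context.n_channels)
        student = transfer_and_freeze(teacher, student)
        small = SubjectData(subject, reference_chunks[:1])
        subj_set = prepare_student_data(small, teacher)
        ch = subj_set["chunks"][0]
        # shrink the chunk for speed
        for key in ("pv", "labels", "lv"):
            ch[key] = ch[key][:8]
        ch["weights"] = ch["weights"].reshape(ch["n"], ch["L"], 8)[:8].reshape(-1, 8)
        ch["corner_pos"] = ch["corner_pos"].reshape(ch["n"], ch["L"], 8)[:8].reshape(-1, 8)
        ch["teacher_mlp"] = ch["teacher_mlp"].reshape(ch["n"], ch["L"], -1)[:8].reshape(-1, 512)
        ch["n"] = 8
        bn0 = copy.deepcopy(student.bn_running)
        total, grads = student_loss_and_grads(student, subj_set, ch, 1.0)
        student.bn_running = copy.deepcopy(bn0)
        rng = np.random.default_rng(0)
        v = rng.standard_normal(student.params["conv_W"].shape).astype(np.float32)
        v /= np.linalg.norm(v)
        eps = 1e-2
        orig = student.params["conv_W"].copy()

        def loss_at(w):
            student.params["conv_W"] = w
            student.bn_running = copy.deepcopy(bn0)
            _, _, _, loss, _, dl, _ = _student_losses(
                student, subj_set, ch, train=True, distill=True
            )
            return loss + dl

        lp = loss_at((orig + eps * v).astype(np.float32))
        lm = loss_at((orig - eps * v).astype(np.float32))
        student.params["conv_W"] = orig
        fd = (lp - lm) / (2 * eps)
        an = float((grads["conv_W"] * v).sum())
        assert abs(fd - an) < 0.05 * max(abs(fd), abs(an), 1e-3)

    def test_shuffled_labels_fail_to_learn(self, subject, val_subject,
                                           reference_chunks):
        """Negative control: label permutation destroys the signal."""
        import copy

        tr_chunks = [copy.deepcopy(reference_chunks[0])]
        rng = np.random.default_rng(0)
        c = tr_chunks[0]
        perm = rng.permutation(c.labels.reshape(-1, 2))
        c.labels = perm.reshape(c.labels.shape)
        tr = SubjectData(subject, tr_chunks)
        va = SubjectData(val_subject, reference_chunks[1:2])
        cfg = TrainConfig(max_epochs=3, patience_epochs=10, seed=3)
        _, hist = train_teacher(TeacherModel(seed=1), [tr], [va], cfg)
        assert min(r["val_loss"] for r in hist) > 0.5
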