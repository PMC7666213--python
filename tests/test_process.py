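"""Processing chain: rendering, RCC, picking, alignment, averaging."""

import numpy as np
import pandas as pd
import pytest

from barrelpaint import process
from barrelpaint.process import (
    align_rounds_coarse,
    align_rounds_fine,
    apply_round_shifts,
    average_particles,
    extract_pick_locs,
    joint_round_rotation,
    pick_particles,
    rcc_drift_correct,
    render_histogram,
    xcorr_shift,
)

from conftest import blinking_sites_table, make_table


class TestRender:
    def test_single_localization_single_bin(self):
        img = render_histogram(np.array([[5.0, 7.0]]), oversampling=10.0)
        assert img.data.sum() == 1.0
        assert np.count_nonzero(img.data) == 1

    def test_doubling_oversampling_preserves_total(self):
        rng = np.random.default_rng(0)
        locs = rng.uniform(0, 500, (5000, 2))
        bounds = ((0.0, 500.0), (0.0, 500.0))
        a = render_histogram(locs, 10.0, bounds=bounds)
        b = render_histogram(locs, 20.0, bounds=bounds)
        assert a.total == b.total == 5000
        assert b.data.size == pytest.approx(4 * a.data.size, rel=0.05)

    def test_uniform_input_poisson_like(self):
        rng = np.random.default_rng(1)
        locs = rng.uniform(0, 1000, (200_000, 2))
        img = render_histogram(locs, 10.0, bounds=((0.0, 1000.0), (0.0, 1000.0)))
        counts = img.data.ravel()
        assert abs(counts.var() / counts.mean() - 1.0) < 0.2

    def test_empty_input_warns(self):
        with pytest.warns(UserWarning):
            img = render_histogram(np.empty((0, 2)), 10.0)
        assert img.data.sum() == 0.0

    def test_invalid_oversampling(self):
        with pytest.raises(ValueError):
            render_histogram(np.array([[0.0, 0.0]]), 0.0)

    def test_xcorr_shift_matches_brute_force(self):
        """FFT cross-correlation peak equals the brute-force spatial
        correlation argmax on a small image pair."""
        rng = np.random.default_rng(2)
        a = rng.random((16, 16))
        b = np.roll(a, (3, -2), axis=(0, 1))
        (di, dj), score = xcorr_shift(b, a)
        assert round(di) == 3 and round(dj) == -2
        # brute force over integer shifts
        best = max(
            ((s0, s1, np.sum(np.roll(a, (s0, s1), axis=(0, 1)) * b))
             for s0 in range(-5, 6) for s1 in range(-5, 6)),
            key=lambda t: t[2],
        )
        assert (best[0], best[1]) == (3, -2)


def _drifting_table(n_frames=2000, rate=0.08, sigma=4.0, seed=0, drift=None):
    rng = np.random.default_rng(seed)
    sites = rng.uniform(200, 1800, (64, 2))
    frames, xs, ys = [], [], []
    for s in sites:
        fr = np.flatnonzero(rng.random(n_frames) < rate)
        xy = s + rng.normal(0, sigma, (len(fr), 2))
        frames.append(fr)
        xs.append(xy[:, 0])
        ys.append(xy[:, 1])
    frame = np.concatenate(frames)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if drift is not None:
        x = x + drift[0][frame]
        y = y + drift[1][frame]
    return make_table(frame, x, y, n_frames=n_frames)


class TestDriftCorrection:
    def test_zero_drift_recovers_near_zero(self):
        table = _drifting_table(seed=3)
        trace, corrected = rcc_drift_correct(table, 250, oversampling=20.0)
        bin_size = 100.0 / 20.0
        assert max(np.abs(trace.dx).max(), np.abs(trace.dy).max()) < bin_size
        assert len(corrected) == len(table)

    def test_linear_drift_recovered_within_10_percent_rms(self):
        n = 2000
        dx = 0.05 * np.arange(n)
        dy = -0.02 * np.arange(n)
        table = _drifting_table(n_frames=n, seed=4, drift=(dx, dy))
        trace, corrected = rcc_drift_correct(table, 250)
        rms_err = np.sqrt(np.mean((trace.dx - dx) ** 2 + (trace.dy - dy) ** 2))
        rms_truth = np.sqrt(np.mean(dx**2 + dy**2))
        assert rms_err < 0.10 * rms_truth
        assert len(corrected) == len(table)  # counts conserved

    def test_redundant_solution_beats_sequential_chain(self):
        """The least-squares solution over all pairs leaves smaller
        residuals on the pairwise measurements than integrating only
        consecutive-pair shifts."""
        n = 2000
        rng = np.random.default_rng(5)
        steps = rng.normal(0.0, 0.05, (n, 2))
        walk = np.cumsum(steps, axis=0)
        table = _drifting_table(n_frames=n, seed=5, drift=(walk[:, 0], walk[:, 1]))
        n_seg = 8
        L = n // n_seg
        bounds = ((table.df.x.min(), table.df.x.max()), (table.df.y.min(), table.df.y.max()))
        imgs = []
        for s in range(n_seg):
            m = (table.df.frame // L) == s
            imgs.append(render_histogram(table.df[m][["x", "y"]].to_numpy(), 20.0, bounds=bounds))
        pairs = [(i, j) for i in range(n_seg) for j in range(i + 1, n_seg)]
        meas = {}
        for i, j in pairs:
            (di, dj), _ = xcorr_shift(imgs[j].data, imgs[i].data)
            meas[(i, j)] = np.array([di, dj]) * imgs[0].bin_size
        # sequential: integrate consecutive shifts
        seq = np.zeros((n_seg, 2))
        for k in range(1, n_seg):
            seq[k] = seq[k - 1] + meas[(k - 1, k)]
        # redundant least squares
        A = np.zeros((len(pairs), n_seg - 1))
        m = np.zeros((len(pairs), 2))
        for k, (i, j) in enumerate(pairs):
            if j > 0:
                A[k, j - 1] += 1
            if i > 0:
                A[k, i - 1] -= 1
            m[k] = meas[(i, j)]
        sol, *_ = np.linalg.lstsq(A, m, rcond=None)
        red = np.vstack([[0, 0], sol])
        def residual(d):
            return np.sqrt(sum(
                np.sum((d[j] - d[i] - meas[(i, j)]) ** 2) for i, j in pairs
            ))
        assert residual(red) <= residual(seq) + 1e-9


class TestPicking:
    def test_single_particle_single_pick(self, monomer_field):
        spec, cfg, truth, table = monomer_field
        pose = truth.poses.iloc[0]
        center = np.array([pose.x, pose.y])
        xy = table.coords("xy")
        mask = np.linalg.norm(xy - center, axis=1) < 100.0
        sub = make_table(
            table.df.frame[mask].to_numpy(), xy[mask, 0], xy[mask, 1],
            n_frames=cfg.n_frames,
        )
        picks = pick_particles(sub, pick_radius=31.0, min_locs=30)
        assert len(picks) == 1
        assert picks[0].n_locs >= 0.99 * mask.sum()

    def test_min_locs_above_total_gives_no_picks(self, monomer_field):
        *_, table = monomer_field
        picks = pick_particles(table, 31.0, min_locs=len(table) + 1)
        assert picks == []

    def test_well_separated_particles_all_found(self, monomer_field):
        spec, cfg, truth, table = monomer_field
        picks = pick_particles(table, 31.0, min_locs=50)
        assert len(picks) == len(truth.poses)
        centers = np.array([p.center for p in picks])
        true_centers = truth.poses[["x", "y"]].to_numpy()
        d = np.linalg.norm(centers[:, None] - true_centers[None], axis=-1).min(axis=1)
        assert d.max() < 10.0

    def test_members_within_radius(self, monomer_field):
        *_, table = monomer_field
        picks = pick_particles(table, 31.0, min_locs=50)
        xy = table.coords("xy")
        for p in picks[:5]:
            r = np.linalg.norm(xy[p.indices] - np.array(p.center), axis=1)
            assert r.max() <= p.radius + 1e-9


class TestRoundAlignment:
    def test_identical_rounds_zero_shift(self):
        t = blinking_sites_table(4.0, seed=6, n_sites=20)
        shifts = align_rounds_coarse({"R1": t, "R2": t.copy()})
        assert abs(shifts["R2"].dx) < 1e-9 and abs(shifts["R2"].dy) < 1e-9

    def test_injected_offset_recovered(self):
        t = blinking_sites_table(4.0, seed=7, n_sites=30)
        t2 = t.copy()
        t2.df["x"] += 20.0
        shifts = align_rounds_coarse({"R1": t, "R2": t2}, oversampling=20.0)
        assert shifts["R2"].dx == pytest.approx(-20.0, abs=100.0 / 20.0)
        corrected = apply_round_shifts({"R1": t, "R2": t2}, shifts)
        assert len(corrected["R2"]) == len(t2)

    def test_antisymmetric_under_reference_swap(self):
        t = blinking_sites_table(4.0, seed=8, n_sites=30)
        t2 = t.copy()
        t2.df["x"] += 12.0
        t2.df["y"] -= 7.0
        f = align_rounds_coarse({"R1": t, "R2": t2}, reference="R1")
        b = align_rounds_coarse({"R1": t, "R2": t2}, reference="R2")
        assert f["R2"].dx == pytest.approx(-b["R1"].dx, abs=2.5)
        assert f["R2"].dy == pytest.approx(-b["R1"].dy, abs=2.5)

    def test_fine_alignment_identity_and_offset(self):
        rng = np.random.default_rng(9)
        marker = np.array([500.0, 500.0, 50.0])
        locs = marker + rng.normal(0, 4.0, (400, 3))
        t1 = make_table(np.arange(400), locs[:, 0], locs[:, 1], z=locs[:, 2])
        picks1 = pick_particles(t1, 40.0, 50)
        # identity
        fine = align_rounds_fine({"R1": t1, "R2": t1.copy()},
                                 {"R1": picks1, "R2": picks1})
        assert np.allclose([fine["R2"].dx, fine["R2"].dy, fine["R2"].dz], 0.0)
        # injected rigid offset (5, -3, 8)
        t2 = t1.copy()
        t2.df[["x", "y", "z"]] += np.array([5.0, -3.0, 8.0])
        picks2 = pick_particles(t2, 40.0, 50)
        fine = align_rounds_fine({"R1": t1, "R2": t2}, {"R1": picks1, "R2": picks2})
        tol = 3 * 4.0 / np.sqrt(400)
        assert fine["R2"].dx == pytest.approx(-5.0, abs=tol)
        assert fine["R2"].dy == pytest.approx(3.0, abs=tol)
        assert fine["R2"].dz == pytest.approx(-8.0, abs=tol)

    def test_fine_beats_coarse_residual(self):
        """Marker-based alignment leaves less inter-round marker
        misalignment than render cross-correlation alone."""
        rng = np.random.default_rng(10)
        markers = rng.uniform(200, 800, (3, 2))
        def round_table(offset, seed):
            rng_r = np.random.default_rng(seed)
            chunks = []
            for m in markers:
                pos = np.r_[m, 30.0] + offset
                chunks.append(pos + rng_r.normal(0, 4.0, (300, 3)))
            locs = np.vstack(chunks)
            return make_table(np.arange(len(locs)) % 500, locs[:, 0], locs[:, 1],
                              z=locs[:, 2], n_frames=500)
        t1 = round_table(np.zeros(3), 1)
        t2 = round_table(np.array([3.7, -2.2, 5.0]), 2)
        tables = {"R1": t1, "R2": t2}
        coarse = apply_round_shifts(tables, align_rounds_coarse(tables, oversampling=10.0))
        picks = {r: pick_particles(coarse[r], 40.0, 50) for r in tables}
        fine = apply_round_shifts(coarse, align_rounds_fine(coarse, picks))
        def marker_residual(tabs):
            res = 0.0
            for m in markers:
                coms = []
                for r in tabs:
                    xy = tabs[r].coords("xy")
                    sel = np.linalg.norm(xy - m, axis=1) < 50.0
                    coms.append(tabs[r].xyz[sel].mean(axis=0))
                res += np.linalg.norm(coms[0] - coms[1])
            return res
        assert marker_residual(fine) < marker_residual(coarse)

    def test_missing_marker_errors(self):
        t = blinking_sites_table(4.0, seed=11, n_sites=5)
        with pytest.raises(ValueError):
            align_rounds_fine({"R1": t, "R2": t.copy()}, {"R1": [], "R2": []})


class TestAveraging:
    def test_offset_particles_align_within_bin(self, ring_particles):
        p1, p2 = ring_particles[0], ring_particles[1] + np.array([10.0, 0.0, 0.0])
        out = average_particles([p1, p2], schedule=[("xy", 10.0)], n_iter=2)
        a, b = np.split(out.locs, [len(p1)])
        assert np.linalg.norm(a.mean(axis=0) - b.mean(axis=0)) < 100.0 / 10.0

    def test_particle_with_its_copy_identity(self, ring_particles):
        p = ring_particles[0]
        out = average_particles([p, p.copy()], schedule=[("xy", 10.0)], n_iter=1)
        for t in out.transforms:
            assert np.linalg.norm(t["shift"]) < 1e-9
            assert t["rotation"] == 0.0

    def test_objective_non_decreasing_and_counts_conserved(self, ring_particles):
        rng = np.random.default_rng(12)
        jittered = [p + np.r_[rng.uniform(-8, 8, 2), 0.0] for p in ring_particles]
        out = average_particles(jittered, schedule=[("xy", 10.0), ("xy", 20.0)], n_iter=3)
        assert len(out.locs) == sum(out.member_counts)
        per_step = {}
        for step, it, obj in out.objective_log:
            per_step.setdefault(step, []).append(obj)
        for objs in per_step.values():
            assert all(b >= a - 1e-9 for a, b in zip(objs, objs[1:]))

    def test_alignment_sharpens_blurred_ensemble(self, ring_particles):
        """Cross-correlation refinement undoes injected centring errors:
        the aligned sum's radial peak is narrower than the jittered pool's."""
        from barrelpaint.morphometry import radial_diameter

        rng = np.random.default_rng(13)
        jittered = [p + np.r_[rng.uniform(-8, 8, 2), 0.0] for p in ring_particles]
        naive = np.vstack(jittered)
        out = average_particles(jittered, schedule=[("xy", 10.0), ("xy", 20.0)], n_iter=3)
        before = radial_diameter(naive[:, :2]).dispersion
        after = radial_diameter(out.locs[:, :2]).dispersion
        assert after < before

    def test_transforms_are_rigid(self, ring_particles):
        out = average_particles(
            ring_particles[:4], schedule=[("xy", 10.0)], n_angles=8, n_iter=2
        )
        for original, moved in zip(ring_particles, np.split(out.locs, np.cumsum(out.member_counts))[:4]):
            d0 = np.linalg.norm(original[0] - original[-1])
            d1 = np.linalg.norm(moved[0] - moved[-1])
            assert d1 == pytest.approx(d0, rel=1e-9)

    def test_degenerate_particle_excluded(self, ring_particles):
        with pytest.warns(UserWarning):
            out = average_particles(
                [ring_particles[0], ring_particles[1], np.array([[0.0, 0.0, 0.0]])],
                schedule=[("xy", 10.0)], n_iter=1,
            )
        assert len(out.member_counts) == 2

    def test_fewer_than_two_particles_rejected(self, ring_particles):
        with pytest.raises(ValueError):
            average_particles([ring_particles[0]])


class TestJointRotation:
    @staticmethod
    def _l_shape():
        img = np.zeros((64, 64))
        img[18:46, 30:34] = 1.0
        img[18:22, 30:50] = 1.0
        return img

    def test_symmetric_input_returns_zero_by_tie_rule(self):
        disk = np.zeros((33, 33))
        yy, xx = np.mgrid[:33, :33]
        disk[(yy - 16) ** 2 + (xx - 16) ** 2 <= 100] = 1.0
        with pytest.warns(UserWarning, match="tie"):
            angle, _ = joint_round_rotation([disk], target=disk,
                                            angles_deg=[0.0, 90.0, 180.0, 270.0])
        assert angle == 0.0

    def test_rotation_recovered_within_grid_step(self):
        from scipy.ndimage import rotate

        pat = self._l_shape()
        rotated = rotate(pat, 30.0, reshape=False, order=1)
        angles = np.arange(0.0, 360.0, 2.0)
        best, matrix = joint_round_rotation([rotated], target=pat, angles_deg=angles)
        assert min(abs(best - 330.0), abs(best - 329.0), abs(best - 332.0)) <= 2.0
        # the returned angle maximizes the column sum by definition
        col = matrix.sum(axis=0)
        assert col[int(np.flatnonzero(angles == best)[0])] == col.max()
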