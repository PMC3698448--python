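"""End-to-end validation studies on the spherical phantom.

Each function recomputes one verifiable property of the pipeline from
scratch — exact sLORETA localization, agreement of the finite-difference
forward solver with the analytic sphere, closed-form component windows,
reference invariance, recovery of the planted condition orderings at the
scalp and ROI level, Type-I calibration of the multivariate test, the ROI
morphology oracles, the Wilks determinant identity, and seeded determinism.
They back both the acceptance test suite and ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np

from . import erp as E
from .forward import (
    build_source_space,
    leadfield_fdm,
    leadfield_sphere,
    rdm,
    _snap_electrodes,
)
from .inverse import cdr_series, peak_localization, sloreta_kernel
from .montage import make_montage
from .phantom import (
    make_design,
    make_phantom_head,
    make_source_model,
    simulate_experiment,
)
from .roi import build_roi, load_roi_definitions, roi_timecourse
from .stats import rm_wilks, wilks_manova

SHELLS = (92.0, 86.0, 80.0, 78.0)
SIGMAS = (0.33, 0.0042, 1.79, 0.33)


def _default_setup(spacing_mm: float = 4.0):
    tissue, atlas = make_phantom_head()
    montage = make_montage()
    src = build_source_space(tissue, spacing_mm, include_eyes=False)
    lf = leadfield_sphere(montage, src, SHELLS, SIGMAS)
    return tissue, atlas, montage, src, lf


# ---------------------------------------------------------------------------
# 1. sLORETA exact localization
# ---------------------------------------------------------------------------

def localization_study(n_cases: int = 50, seed: int = 0, spacing_mm: float = 8.0) -> dict:
    """Noiseless single-dipole simulations on the layered sphere phantom:
    count how often the standardized map peaks at the generating node."""
    _, _, _, src, lf = _default_setup(spacing_mm)
    kernel = sloreta_kernel(lf)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_cases):
        node = int(rng.integers(src.n_nodes))
        ori = rng.normal(size=3)
        ori /= np.linalg.norm(ori)
        d = lf.gain[:, node, :] @ ori
        wave = E.ERPWave({}, d[:, None], np.array([0.0]), list(lf.channels), "saccade", 1)
        cdr = cdr_series(wave, kernel)
        hits += peak_localization(cdr.values[:, 0]) == node
    return {"hits": int(hits), "n": n_cases, "n_nodes": src.n_nodes}


# ---------------------------------------------------------------------------
# 2. Forward oracle equivalence
# ---------------------------------------------------------------------------

def forward_oracle_study(
    voxel_size_mm: float = 3.0, n_nodes: int = 30, seed: int = 0
) -> dict:
    """Homogeneous-sphere phantom: finite-difference lead-field columns vs
    the analytic solution, as relative difference measures (RDM).

    Both engines see the same electrode set (positions snapped to scalp
    voxel centers) so the comparison isolates the solvers.
    """
    tissue, _ = make_phantom_head(
        voxel_size_mm=voxel_size_mm, with_eyes=False, with_air_cavity=False, roi_blobs={}
    )
    montage = make_montage()
    vox = _snap_electrodes(tissue, montage)
    m = montage.copy()
    m.positions = tissue.voxel_to_head(vox)
    src = build_source_space(tissue, 12.0, include_eyes=False)
    homog = {k: 0.33 for k in ("scalp", "skull", "csf", "gray", "white")}
    lf_f = leadfield_fdm(tissue, homog, m, src)
    lf_s = leadfield_sphere(m, src, SHELLS, (0.33,) * 4)
    rng = np.random.default_rng(seed)
    idx = rng.choice(src.n_nodes, min(n_nodes, src.n_nodes), replace=False)
    vals = np.array(
        [rdm(lf_f.gain[:, i, a], lf_s.gain[:, i, a]) for i in idx for a in range(3)]
    )
    return {
        "max_rdm": float(vals.max()),
        "mean_rdm": float(vals.mean()),
        "n_columns": int(vals.size),
        "voxel_size_mm": voxel_size_mm,
    }


# ---------------------------------------------------------------------------
# 3. Component-window closed forms
# ---------------------------------------------------------------------------

def component_closed_forms() -> dict:
    """Planted analytic waveforms through the component windows."""
    times_t = np.arange(-1100.0, 801.0, 4.0)
    ramp = np.where(times_t <= -1000, 0.0, np.where(times_t <= 0, -6 * (times_t + 1000) / 1000, -6.0))
    erp_t = E.ERPWave({}, ramp[None, :], times_t, ["ch"], "target", 1)
    negsw = E.measure_component(erp_t, "pretarget_neg_sw", "ch").value_uv

    A, sigma = 3.0, 5.0
    times_s = np.arange(-300.0, 101.0, 4.0)
    gauss = A * np.exp(-(times_s**2) / (2 * sigma**2))
    erp_s = E.ERPWave({}, gauss[None, :], times_s, ["ch"], "saccade", 1)
    spike = E.measure_component(erp_s, "spike", "ch").value_uv

    def g(t):
        return A * np.exp(-(t**2) / (2 * sigma**2))

    def win(lo, hi):  # independent longhand trapezoid mean on the samples
        ts = np.arange(lo, hi + 1, 4.0)
        return (g(ts[0]) / 2 + g(ts[1:-1]).sum() + g(ts[-1]) / 2) * 4.0 / (hi - lo)

    spike_oracle = win(-8.0, 8.0) - win(-24.0, -16.0)
    return {
        "negsw_ramp_uv": float(negsw),
        "negsw_error": float(abs(negsw - (-5.70))),
        "spike_uv": float(spike),
        "spike_oracle_error": float(abs(spike - spike_oracle)),
    }


# ---------------------------------------------------------------------------
# 4. Reference invariance
# ---------------------------------------------------------------------------

def reference_invariance_study(seed: int = 0, spacing_mm: float = 8.0) -> dict:
    _, _, _, src, lf = _default_setup(spacing_mm)
    kernel = sloreta_kernel(lf)
    rng = np.random.default_rng(seed)
    node = int(rng.integers(src.n_nodes))
    # a 100-nAm source puts the scalp pattern on a realistic microvolt scale
    d = (lf.gain[:, node, :] @ np.array([0.0, 0.0, 1.0])) * 100.0
    base = cdr_series(
        E.ERPWave({}, d[:, None], np.array([0.0]), list(lf.channels), "saccade", 1), kernel
    ).values
    worst = 0.0
    for c in (1.0, -250.0, 1e3):
        shifted = cdr_series(
            E.ERPWave({}, d[:, None] + c, np.array([0.0]), list(lf.channels), "saccade", 1),
            kernel,
        ).values
        worst = max(worst, float(np.abs(shifted - base).max() / base.max()))
    return {"max_rel_change": worst}


# ---------------------------------------------------------------------------
# 5. Parameter recovery and Type-I calibration
# ---------------------------------------------------------------------------

def recovery_study(n_seeds: int = 20, trials_per_cell: int = 40, seed0: int = 0) -> dict:
    """Recover the planted condition orderings, per seed, at both levels:

    scalp component measures (virtual-electrode groups) and ROI
    current-density series.  The presaccadic components are read at the
    ventral ACC (their planted source); the CNV orderings at the
    central-midline region carrying the CNV source.
    """
    tissue, atlas, montage, src, lf = _default_setup(4.0)
    spec = make_source_model(atlas, leadfield=lf, montage=montage)
    kernel = sloreta_kernel(lf)
    defs = {d.name: build_roi(atlas, d) for d in load_roi_definitions()}
    design = make_design(trials_per_cell=trials_per_cell, procedures=("mixed", "blocked"))
    h = atlas.voxel_size_mm

    names = [
        "erp_possw_anti_gt_pro", "erp_spike_pro_gt_anti",
        "erp_cnv_uncued_gt_cued", "erp_blocked_cnv_anti_gt_pro",
        "roi_possw_anti_gt_pro", "roi_spike_pro_gt_anti",
        "roi_cnv_uncued_gt_cued", "roi_blocked_cnv_anti_gt_pro",
        "vacc_dominates_midline_at_spike",
    ]
    counts = dict.fromkeys(names, 0)
    midline_other = ["orbital_frontal", "dorsal_acc", "posterior_cingulate"]

    def roi_window(cdr, roi, lo, hi):
        s = roi_timecourse(cdr, defs[roi], src, h, name=roi)
        sel = (cdr.times >= lo - 1e-9) & (cdr.times <= hi + 1e-9)
        return float(s.values[sel].mean())

    for k in range(n_seeds):
        raw, _, _ = simulate_experiment(
            tissue, atlas, montage, spec, design, lf, noise_sd=5.0,
            seed=(seed0 * 1000 + k) % (2**31 - 1),
        )
        sac = E.flip_lateral(
            E.rereference_average(E.reject_trials(E.segment_epochs(raw, "saccade"))), montage
        )
        tar = E.flip_lateral(
            E.rereference_average(E.reject_trials(E.segment_epochs(raw, "target"))), montage
        )
        del raw

        by_mov = E.compute_erp(sac, group_by=["movement"])
        by_cue = E.compute_erp(tar, group_by=["cue"])
        blocked = tar.subset((tar.trials["procedure"] == "blocked").to_numpy())
        by_mov_blocked = E.compute_erp(blocked, group_by=["movement"])

        def meas(erps, key, comp, group):
            return E.measure_component(erps[key], comp, group, montage).value_uv

        # scalp level (positive slow wave and spike are calibrated positive
        # at ParietalZ, the CNV negative at CentralZ)
        counts["erp_possw_anti_gt_pro"] += meas(by_mov, ("antisaccade",), "presaccadic_pos_sw", "ParietalZ") > meas(
            by_mov, ("prosaccade",), "presaccadic_pos_sw", "ParietalZ"
        )
        counts["erp_spike_pro_gt_anti"] += meas(by_mov, ("prosaccade",), "spike", "ParietalZ") > meas(
            by_mov, ("antisaccade",), "spike", "ParietalZ"
        )
        counts["erp_cnv_uncued_gt_cued"] += meas(by_cue, ("uncued",), "pretarget_neg_sw", "CentralZ") < meas(
            by_cue, ("cued",), "pretarget_neg_sw", "CentralZ"
        )
        counts["erp_blocked_cnv_anti_gt_pro"] += meas(
            by_mov_blocked, ("antisaccade",), "pretarget_neg_sw", "CentralZ"
        ) < meas(by_mov_blocked, ("prosaccade",), "pretarget_neg_sw", "CentralZ")

        # ROI level
        cdr_mov = {m: cdr_series(by_mov[(m,)], kernel) for m in ("prosaccade", "antisaccade")}
        counts["roi_possw_anti_gt_pro"] += roi_window(
            cdr_mov["antisaccade"], "ventral_acc", -50, -20
        ) > roi_window(cdr_mov["prosaccade"], "ventral_acc", -50, -20)
        spike_roi = {
            m: roi_window(c, "ventral_acc", -8, 8) - roi_window(c, "ventral_acc", -24, -16)
            for m, c in cdr_mov.items()
        }
        counts["roi_spike_pro_gt_anti"] += spike_roi["prosaccade"] > spike_roi["antisaccade"]

        cdr_cue = {c: cdr_series(by_cue[(c,)], kernel) for c in ("cued", "uncued")}
        cnv_roi = {
            c: roi_window(s, "dorsal_acc", -50, 0) - roi_window(s, "dorsal_acc", -1000, -950)
            for c, s in cdr_cue.items()
        }
        counts["roi_cnv_uncued_gt_cued"] += cnv_roi["uncued"] > cnv_roi["cued"]

        cdr_blk = {m: cdr_series(by_mov_blocked[(m,)], kernel) for m in ("prosaccade", "antisaccade")}
        cnv_blk = {
            m: roi_window(s, "dorsal_acc", -50, 0) - roi_window(s, "dorsal_acc", -1000, -950)
            for m, s in cdr_blk.items()
        }
        counts["roi_blocked_cnv_anti_gt_pro"] += cnv_blk["antisaccade"] > cnv_blk["prosaccade"]

        cdr_pro = cdr_mov["prosaccade"]
        i0 = int(np.argmin(np.abs(cdr_pro.times)))
        vacc = roi_timecourse(cdr_pro, defs["ventral_acc"], src, h).values[i0]
        others = [
            roi_timecourse(cdr_pro, defs[r], src, h).values[i0] for r in midline_other
        ]
        counts["vacc_dominates_midline_at_spike"] += bool(vacc > max(others))

    out = {k: int(v) for k, v in counts.items()}
    out["n_seeds"] = n_seeds
    out["min_recovered"] = int(min(counts.values()))
    return out


def headline_measures(seed: int = 0, n_sessions: int = 4, trials_per_cell: int = 40) -> dict:
    """Grand-average condition means under the default study conditions:
    saccade latencies per cue, the pretarget negative slow wave at CentralZ
    per cue (and per movement in blocked runs), and the presaccadic positive
    slow wave at ParietalZ per movement type."""
    import pandas as pd

    from .stats import latency_table

    tissue, atlas, montage, src, lf = _default_setup(4.0)
    spec = make_source_model(atlas, leadfield=lf, montage=montage)
    design = make_design(trials_per_cell=trials_per_cell, procedures=("mixed", "blocked"))

    acc: dict[str, list] = {}
    trial_tables = []
    for s in range(n_sessions):
        raw, trials, _ = simulate_experiment(
            tissue, atlas, montage, spec, design, lf, noise_sd=5.0,
            seed=(seed * 1000 + s) % (2**31 - 1),
        )
        trial_tables.append(trials)
        sac = E.rereference_average(E.reject_trials(E.segment_epochs(raw, "saccade")))
        tar = E.rereference_average(E.reject_trials(E.segment_epochs(raw, "target")))
        del raw
        by_cue = E.compute_erp(tar, group_by=["cue"])
        for cue in ("cued", "uncued"):
            acc.setdefault(f"cnv_centralz_{cue}_uv", []).append(
                E.measure_component(by_cue[(cue,)], "pretarget_neg_sw", "CentralZ", montage).value_uv
            )
        blocked = tar.subset((tar.trials["procedure"] == "blocked").to_numpy())
        by_mov_b = E.compute_erp(blocked, group_by=["movement"])
        for mov, tag in (("prosaccade", "pro"), ("antisaccade", "anti")):
            acc.setdefault(f"cnv_centralz_blocked_{tag}_uv", []).append(
                E.measure_component(by_mov_b[(mov,)], "pretarget_neg_sw", "CentralZ", montage).value_uv
            )
        by_mov = E.compute_erp(sac, group_by=["movement"])
        for mov, tag in (("prosaccade", "pro"), ("antisaccade", "anti")):
            acc.setdefault(f"possw_parietalz_{tag}_uv", []).append(
                E.measure_component(by_mov[(mov,)], "presaccadic_pos_sw", "ParietalZ", montage).value_uv
            )
            acc.setdefault(f"spike_parietalz_{tag}_uv", []).append(
                E.measure_component(by_mov[(mov,)], "spike", "ParietalZ", montage).value_uv
            )

    out = {k: float(np.mean(v)) for k, v in acc.items()}
    all_trials = pd.concat(trial_tables, ignore_index=True)
    mixed = all_trials[all_trials["procedure"] == "mixed"]
    cells = latency_table(mixed)["cells"].set_index(["cue", "movement"])
    for cue in ("cued", "uncued"):
        sub = mixed[(mixed["cue"] == cue) & (mixed["movement"] != "catch")
                    & ~mixed["error"] & ~mixed["blink"]]
        out[f"rt_{cue}_ms"] = float(sub["rt_ms"].mean())
    for mov, tag in (("prosaccade", "pro"), ("antisaccade", "anti")):
        out[f"rt_{tag}_ms"] = float(
            cells.xs(mov, level="movement")["mean"].mean()
        )
    out["n_trials"] = int(len(all_trials))
    return out


def manova_null_study(n_replicates: int = 2000, seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I error of the multivariate repeated-measures test under a
    Gaussian null (no condition effect, 12 sessions x 2 conditions x 4
    channels)."""
    rng = np.random.default_rng(seed)
    rej = 0
    for _ in range(n_replicates):
        data = rng.normal(size=(12, 2, 4))
        rej += rm_wilks(data, {"cond": [0, 1]})[0].p < alpha
    return {"false_positive_rate": rej / n_replicates, "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# 6. ROI morphology oracles
# ---------------------------------------------------------------------------

def roi_morphology_checks() -> dict:
    from .roi import ROIDefinition, dilate_mask
    from .volumes import LabelVolume

    mask = np.zeros((21, 21, 21), bool)
    mask[10, 10, 10] = True
    n_dilated = int(dilate_mask(mask, 3.0, 1.0).sum())

    grid = np.zeros((21, 21, 21), np.int16)
    grid[4, 10, 10] = 1
    grid[12, 10, 10] = 2
    affine = np.diag([1.0] * 4)
    affine[:3, 3] = -10.0
    atlas = LabelVolume(grid, 1.0, affine, {0: "background", 1: "ipl", 2: "spl"})
    recipe = [
        {"op": "union", "labels": ["ipl"]},
        {"op": "dilate", "mm": 4.0},
        {"op": "intersect", "with": [{"op": "union", "labels": ["spl"]}, {"op": "dilate", "mm": 4.0}]},
    ]
    ips = build_roi(atlas, ROIDefinition("ips", recipe))
    ips_vox = np.argwhere(ips).tolist()
    return {
        "dilate_3mm_voxels": n_dilated,
        "ips_overlap_voxels": int(ips.sum()),
        "ips_overlap_is_midpoint": ips_vox == [[8, 10, 10]],
    }


# ---------------------------------------------------------------------------
# 7. Wilks oracle
# ---------------------------------------------------------------------------

def wilks_oracle_study(n_fixtures: int = 100, seed: int = 0) -> dict:
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_fixtures):
        n = int(rng.integers(10, 18))
        p = int(rng.integers(1, 4))
        Y = rng.normal(size=(n, p))
        groups = rng.integers(0, 2, size=n)
        while len(set(groups)) < 2:
            groups = rng.integers(0, 2, size=n)
        res = wilks_manova(Y, groups)
        # determinant-ratio brute force
        E_mat = np.zeros((p, p))
        H_mat = np.zeros((p, p))
        grand = Y.mean(0)
        for lev in (0, 1):
            sub = Y[groups == lev]
            mu = sub.mean(0)
            for row in sub:
                d = (row - mu)[:, None]
                E_mat += d @ d.T
            dm = (mu - grand)[:, None]
            H_mat += len(sub) * dm @ dm.T
        lam = np.linalg.det(E_mat) / np.linalg.det(E_mat + H_mat)
        worst = max(worst, abs(res.wilks - lam))

    # one-variable case equals the univariate ANOVA F exactly
    y = rng.normal(size=14)
    g = np.array([0] * 7 + [1] * 7)
    res = wilks_manova(y[:, None], g)
    F, _ = sps.f_oneway(y[g == 0], y[g == 1])
    return {
        "max_abs_lambda_error": float(worst),
        "univariate_f_rel_error": float(abs(res.F - F) / F),
        "n_fixtures": n_fixtures,
    }


# ---------------------------------------------------------------------------
# 8. Determinism
# ---------------------------------------------------------------------------

def determinism_check(seed: int = 0) -> dict:
    from .erp import component_table

    tissue, atlas = make_phantom_head(voxel_size_mm=6.0)
    montage = make_montage()
    src = build_source_space(tissue, 6.0, include_eyes=False)
    lf = leadfield_sphere(montage, src, SHELLS, SIGMAS)
    spec = make_source_model(atlas, leadfield=lf, montage=montage)
    design = make_design(trials_per_cell=4, procedures=("mixed",))

    def run():
        raw, trials, _ = simulate_experiment(
            tissue, atlas, montage, spec, design, lf, noise_sd=5.0, seed=seed
        )
        ep = E.rereference_average(E.reject_trials(E.segment_epochs(raw, "saccade")))
        erps = E.compute_erp(ep, group_by=["cue", "movement"])
        table = component_table(erps, montage)
        return trials.to_csv(sep="\t", index=False), table.to_csv(sep="\t", index=False)

    t1, c1 = run()
    t2, c2 = run()
    return {
        "trials_identical": t1 == t2,
        "component_tables_identical": c1 == c2,
    }
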