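"""Phantom head, montage grouping, source model and experiment simulation."""

import numpy as np
import pandas as pd
import pytest

from presaccade.errors import (
    EmptyDesignError,
    InvalidGeometryError,
    InvalidMontageError,
    MisplacedROIError,
)
from presaccade.montage import Montage, make_montage
from presaccade.phantom import (
    DEFAULT_RT_MEANS_MS,
    SourceSpec,
    Dipole,
    make_design,
    make_phantom_head,
    make_source_model,
    raw_times,
    simulate_experiment,
)
from presaccade.volumes import TISSUE_IDS


def _lattice_band_counts(radii, voxel):
    """Independent enumeration oracle: loop over lattice points per band."""
    scalp, skull, csf, gray = radii
    half = int(np.ceil(scalp / voxel))
    counts = dict.fromkeys(["scalp", "skull", "csf", "gray"], 0)
    for i in range(-half, half + 1):
        for j in range(-half, half + 1):
            for k in range(-half, half + 1):
                r = voxel * np.sqrt(i * i + j * j + k * k)
                if r <= gray:
                    counts["gray"] += 1
                elif r <= csf:
                    counts["csf"] += 1
                elif r <= skull:
                    counts["skull"] += 1
                elif r <= scalp:
                    counts["scalp"] += 1
    return counts


def test_shell_voxel_counts_match_lattice_enumeration():
    radii = (92.0, 86.0, 80.0, 78.0)
    tissue, _ = make_phantom_head(
        radii, voxel_size_mm=8.0, white_core_radius_mm=1.0,
        with_eyes=False, with_air_cavity=False, roi_blobs={},
    )
    oracle = _lattice_band_counts(radii, 8.0)
    for name in ("scalp", "skull", "csf"):
        assert int((tissue.grid == TISSUE_IDS[name]).sum()) == oracle[name]
    n_gray_or_white = int(
        ((tissue.grid == TISSUE_IDS["gray"]) | (tissue.grid == TISSUE_IDS["white"])).sum()
    )
    assert n_gray_or_white == oracle["gray"]


def test_center_is_white_and_outside_is_background(phantom):
    tissue, _ = phantom
    center = tissue.head_to_voxel([[0.0, 0.0, 0.0]])[0].round().astype(int)
    assert tissue.grid[tuple(center)] == TISSUE_IDS["white"]
    # a voxel beyond the scalp radius (|r| ~ 94 mm) is background
    out = tissue.head_to_voxel([[60.0, 60.0, 40.0]])[0].round().astype(int)
    assert tissue.grid[tuple(out)] == TISSUE_IDS["background"]


def test_gray_and_eye_voxels_inside_scalp(phantom):
    tissue, _ = phantom
    mask = (tissue.grid == TISSUE_IDS["gray"]) | (tissue.grid == TISSUE_IDS["eye"])
    r = np.linalg.norm(tissue.voxel_centers(mask), axis=1)
    assert r.max() < 92.0


def test_non_decreasing_radii_rejected():
    with pytest.raises(InvalidGeometryError):
        make_phantom_head((92.0, 86.0, 86.0, 78.0))


def test_blob_outside_gray_rejected():
    blobs = {"bad": {"kind": "sphere", "center": (0.0, 0.0, 0.0), "radius": 5.0}}
    with pytest.raises(MisplacedROIError):
        make_phantom_head(roi_blobs=blobs)


# ---------------------------------------------------------------------------
# Montage
# ---------------------------------------------------------------------------

def test_virtual_groups_match_shipped_table(montage):
    assert montage.group_of("E55") == "CentralZ"
    assert montage.group_of("E61") == "ParietalZ"
    assert montage.group_channels("OccipitalZ") == ["E72", "E77", "E76"]
    assert len(montage.virtual_groups) == 20
    # a channel listed in no table row stays ungrouped
    assert montage.group_of("E1") is None


def test_montage_mirror_pairing(montage):
    # lateral groups pair member-by-member; midline channels are fixed points
    assert montage.mirror_partner("E52") == "E80"
    assert montage.mirror_partner("E80") == "E52"
    for ch in montage.group_channels("ParietalZ"):
        assert montage.mirror_partner(ch) == ch
    # layout is mirror symmetric in x
    for ch in montage.channels:
        i, j = montage.index(ch), montage.index(montage.mirror_partner(ch))
        np.testing.assert_allclose(
            montage.positions[i] * [-1, 1, 1], montage.positions[j], atol=1e-9
        )


def test_montage_too_few_channels_rejected():
    with pytest.raises(InvalidMontageError):
        make_montage(n_channels=64)


def test_montage_positions_on_scalp_sphere(montage):
    r = np.linalg.norm(montage.positions, axis=1)
    np.testing.assert_allclose(r, 92.0, rtol=1e-12)
    assert set(montage.fiducials) == {"nasion", "lpa", "rpa", "vertex"}


# ---------------------------------------------------------------------------
# Source model
# ---------------------------------------------------------------------------

def test_source_waveform_shapes(phantom):
    _, atlas = phantom
    spec = make_source_model(atlas)
    t = np.array([-1000.0, -500.0, 0.0])
    w = spec.waveform("pretarget_neg_sw", t)
    assert w[0] == 0.0 and w[2] == 1.0 and 0 < w[1] < 1
    # Gaussian pulse: value at -24 ms is exp(-24^2 / (2 sigma^2)) of the peak
    s = spec.components["spike"]["waveform"]["sigma_ms"]
    w = spec.waveform("spike", np.array([-24.0, 0.0]))
    assert w[1] == 1.0
    assert w[0] == pytest.approx(np.exp(-(24.0**2) / (2 * s**2)), abs=1e-12)


def test_default_gain_orderings(phantom):
    _, atlas = phantom
    spec = make_source_model(atlas)
    g = spec.condition_gain
    assert g("presaccadic_pos_sw", "cued", "antisaccade") > g(
        "presaccadic_pos_sw", "cued", "prosaccade"
    )
    assert g("spike", "cued", "prosaccade") > g("spike", "cued", "antisaccade")
    assert g("pretarget_neg_sw", "uncued", "prosaccade") > g(
        "pretarget_neg_sw", "cued", "prosaccade"
    )
    assert g("pretarget_neg_sw", "cued", "antisaccade", "blocked") > g(
        "pretarget_neg_sw", "cued", "prosaccade", "blocked"
    )


def test_calibrated_moments_hit_scalp_targets(phantom, montage, leadfield_coarse):
    from presaccade import erp as E

    _, atlas = phantom
    spec = make_source_model(atlas, leadfield=leadfield_coarse, montage=montage)
    # noiseless single-trial forward projection reproduces the target measure
    for cid, cfg in spec.components.items():
        dip = spec.dipole_for(cid)
        d = np.linalg.norm(leadfield_coarse.node_positions - dip.position_mm, axis=1)
        col = leadfield_coarse.gain[:, int(np.argmin(d)), :] @ dip.orientation
        times = (
            np.arange(-1100.0, 801.0, 4.0)
            if cfg["alignment"] == "target"
            else np.arange(-300.0, 101.0, 4.0)
        )
        wave = spec.waveform(cid, times) * spec.moments_nam[cid]
        erp = E.ERPWave({}, col[:, None] * wave[None, :], times,
                        list(leadfield_coarse.channels), cfg["alignment"], 1)
        got = E.measure_component(erp, cid, cfg["scalp_group"], montage).value_uv
        assert got == pytest.approx(cfg["target_scalp_uv"], rel=1e-9)


# ---------------------------------------------------------------------------
# Design and simulation
# ---------------------------------------------------------------------------

def test_mixed_design_composition():
    design = [{"procedure": "mixed", "cue": "cued", "n_trials": 60}]
    _, trials, _ = _simulate_tiny(design, seed=0)
    counts = trials["movement"].value_counts()
    assert counts["antisaccade"] == 24
    assert counts["prosaccade"] == 24
    assert counts["catch"] == 12
    # composition holds within every 5-trial sub-block
    for b in range(12):
        sub = trials.iloc[5 * b : 5 * b + 5]["movement"].value_counts()
        assert sub.get("antisaccade", 0) == 2
        assert sub.get("prosaccade", 0) == 2
        assert sub.get("catch", 0) == 1


def test_blocked_design_composition():
    design = [
        {"procedure": "blocked", "cue": "cued", "movement": "prosaccade", "n_trials": 20}
    ]
    _, trials, _ = _simulate_tiny(design, seed=1)
    for b in range(4):
        sub = trials.iloc[5 * b : 5 * b + 5]["movement"].value_counts()
        assert sub.get("prosaccade", 0) == 4
        assert sub.get("catch", 0) == 1


def test_empty_design_rejected():
    with pytest.raises(EmptyDesignError):
        _simulate_tiny([], seed=0)


def test_catch_trials_have_no_saccade():
    design = [{"procedure": "mixed", "cue": "uncued", "n_trials": 25}]
    _, trials, eog = _simulate_tiny(design, seed=2, eog_noise=0.0)
    catch = trials["movement"] == "catch"
    assert trials.loc[catch, "rt_ms"].isna().all()
    assert trials.loc[catch, "saccade_onset_s"].isna().all()
    # catch EOG carries no saccade step
    assert np.abs(eog[catch.to_numpy()]).max() < 1.0


def test_simulation_deterministic_under_seed():
    design = make_design(trials_per_cell=4, procedures=("mixed",))
    raw1, t1, e1 = _simulate_tiny(design, seed=33)
    raw2, t2, e2 = _simulate_tiny(design, seed=33)
    pd.testing.assert_frame_equal(t1, t2)
    assert np.array_equal(raw1.data, raw2.data)
    assert np.array_equal(e1, e2)


def test_noiseless_single_dipole_matches_leadfield_column():
    montage, lf, spec = _unit_setup()
    design = [{"procedure": "mixed", "cue": "cued", "n_trials": 5}]
    raw, trials, _ = simulate_experiment(
        None, None, montage, spec, design, lf, noise_sd=0.0, seed=4,
        error_rate=0.0, blink_rate=0.0,
    )
    # at target onset the CNV waveform is at its peak: scalp = column exactly
    i0 = int(np.argmin(np.abs(raw.times)))
    col = lf.gain[:, 0, :] @ spec.dipoles[0].orientation
    for t in range(len(trials)):
        np.testing.assert_allclose(raw.data[t, :, i0], col * 10.0, atol=1e-12)


def test_noiseless_superposition_of_two_dipoles():
    montage, lf, _ = _unit_setup()
    times = raw_times()

    def run(components):
        spec = _make_spec(components)
        design = [{"procedure": "mixed", "cue": "cued", "n_trials": 5}]
        raw, _, _ = simulate_experiment(
            None, None, montage, spec, design, lf, noise_sd=0.0, seed=5,
            error_rate=0.0, blink_rate=0.0,
        )
        return raw.data

    both = run(["a", "b"])
    only_a = run(["a"])
    only_b = run(["b"])
    np.testing.assert_allclose(both, only_a + only_b, atol=1e-12)


def test_rt_cued_mean_matches_configuration():
    """With the default RT model, 2000 cued trials reproduce the configured
    cued marginal mean (435.6 ms) within three standard errors."""
    montage, lf, spec = _unit_setup()
    design = [{"procedure": "mixed", "cue": "cued", "n_trials": 2500}]
    _, trials, _ = simulate_experiment(
        None, None, montage, spec, design, lf, noise_sd=0.0, seed=6,
        error_rate=0.0, blink_rate=0.0,
    )
    rt = trials.loc[trials["movement"] != "catch", "rt_ms"]
    assert len(rt) == 2000
    target = np.mean(
        [DEFAULT_RT_MEANS_MS[("cued", m)] for m in ("prosaccade", "antisaccade")]
    )
    se = rt.std(ddof=1) / np.sqrt(len(rt))
    assert abs(rt.mean() - target) < 3 * se


def test_error_trials_flip_saccade_direction():
    montage, lf, spec = _unit_setup()
    design = [{"procedure": "mixed", "cue": "cued", "n_trials": 200}]
    _, trials, _ = simulate_experiment(
        None, None, montage, spec, design, lf, noise_sd=0.0, seed=7,
        error_rate=0.5, blink_rate=0.0,
    )
    sacc = trials[trials["movement"] == "prosaccade"]
    ok = sacc[~sacc["error"]]
    bad = sacc[sacc["error"]]
    assert (ok["direction"] == ok["side"]).all()
    assert (bad["direction"] != bad["side"]).all()


# -- helpers ----------------------------------------------------------------

def _tiny_montage() -> Montage:
    return Montage(
        channels=["E1", "E2"],
        positions=np.array([[0.0, 0.0, 92.0], [0.0, 92.0, 0.0]]),
        fiducials={},
        virtual_groups={},
        mirror_map={"E1": "E1", "E2": "E2"},
    )


def _make_spec(component_ids) -> SourceSpec:
    comps = {}
    dipoles = []
    for k, cid in enumerate(component_ids):
        comps[cid] = {
            "alignment": "target",
            "waveform": {"kind": "ramp", "onset_ms": -1000.0, "peak_ms": 0.0, "resolve_ms": 200.0},
            "gains": {},
        }
        dipoles.append(Dipole(np.zeros(3), np.array([0.0, 0.0, 1.0]), cid))
    spec = SourceSpec(dipoles, comps)
    for cid in component_ids:
        spec.moments_nam[cid] = 10.0
    return spec


def _unit_setup():
    from presaccade.forward import LeadField

    montage = _tiny_montage()
    gain = np.array([[[0.1, 0.2, 0.3]], [[-0.1, 0.0, 0.4]]])  # (2 ch, 1 node, 3)
    lf = LeadField(gain, montage.channels, np.zeros((1, 3)), None, engine="test")
    return montage, lf, _make_spec(["a"])


def _simulate_tiny(design, seed, eog_noise=1.0):
    montage, lf, spec = _unit_setup()
    return simulate_experiment(
        None, None, montage, spec, design, lf, noise_sd=0.1, seed=seed,
        error_rate=0.0, blink_rate=0.0, eog_noise_sd=eog_noise,
    )
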