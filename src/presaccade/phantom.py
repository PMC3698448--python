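"""Phantom head, planted cortical sources, and simulated saccade experiments.

This module generates every input the analysis pipeline consumes:

* a concentric-shell spherical head phantom (scalp, skull, CSF, gray shell,
  white core, eyes, nasal air cavity) as labeled volumes, plus an atlas
  volume of named spherical ROI "blobs" planted in the gray shell;
* a dipole source model producing the three presaccadic ERP components —
  the pretarget negative slow wave (CNV), the presaccadic parietal positive
  slow wave, and the spike potential at saccade onset — with multiplicative
  condition gains (cue, movement type, procedure) whose default orderings
  follow the empirical phenomenology of cued/uncued pro- and antisaccade
  tasks;
* full simulated sessions: 250-Hz multichannel trials through a lead field,
  white sensor noise, lognormal reaction times with condition effects, a
  bipolar EOG channel with a step at saccade onset, and flagged error and
  blink trials.

The spherical geometry is deliberate: it admits an analytic forward solution
that serves as the oracle for the numerical solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ComponentConfigError,
    EmptyDesignError,
    InvalidGeometryError,
    MisplacedROIError,
)
from .montage import Montage
from .volumes import TISSUE_IDS, LabelVolume

# Sampling grid shared by the whole pipeline: 250 Hz.
DT_MS = 4.0
#: Raw per-trial records are stored target-locked on this window (ms).
RAW_WINDOW_MS = (-1104.0, 1004.0)

DEFAULT_SHELL_RADII_MM = (92.0, 86.0, 80.0, 78.0)
DEFAULT_WHITE_CORE_MM = 55.0

#: Named ROI blobs in the gray shell (radius band 55-78 mm).  Midline blobs
#: have no suffix; lateralized ones end in ``_left`` / ``_right``.
DEFAULT_ROI_BLOBS: dict[str, dict] = {
    "ventral_acc": {"kind": "sphere", "center": (0.0, 61.0, -19.3), "radius": 6.0},
    "orbital_frontal": {"kind": "sphere", "center": (0.0, 50.0, -40.0), "radius": 6.0},
    "dorsal_acc": {"kind": "sphere", "center": (0.0, 36.0, 53.0), "radius": 6.0},
    "posterior_cingulate": {"kind": "sphere", "center": (0.0, -45.0, 45.5), "radius": 6.0},
    "frontal_pole_left": {"kind": "sphere", "center": (-22.0, 57.0, 18.0), "radius": 6.0},
    "frontal_pole_right": {"kind": "sphere", "center": (22.0, 57.0, 18.0), "radius": 6.0},
    "superior_parietal_left": {"kind": "sphere", "center": (-33.0, -36.0, 42.0), "radius": 6.0},
    "superior_parietal_right": {"kind": "sphere", "center": (33.0, -36.0, 42.0), "radius": 6.0},
    "precentral_left": {"kind": "sphere", "center": (-45.0, 2.0, 45.5), "radius": 6.0},
    "precentral_right": {"kind": "sphere", "center": (45.0, 2.0, 45.5), "radius": 6.0},
}


def raw_times() -> np.ndarray:
    """Target-locked time axis of raw per-trial records (ms)."""
    lo, hi = RAW_WINDOW_MS
    return np.arange(lo, hi + DT_MS / 2, DT_MS)


# ---------------------------------------------------------------------------
# Phantom head
# ---------------------------------------------------------------------------

def make_phantom_head(
    shell_radii_mm: tuple[float, ...] = DEFAULT_SHELL_RADII_MM,
    voxel_size_mm: float = 4.0,
    roi_blobs: dict[str, dict] | None = None,
    white_core_radius_mm: float = DEFAULT_WHITE_CORE_MM,
    with_eyes: bool = True,
    with_air_cavity: bool = True,
    eye_radius_mm: float = 9.0,
) -> tuple[LabelVolume, LabelVolume]:
    """Build concentric-shell tissue labels and a matching atlas volume.

    ``shell_radii_mm`` are the outer radii of (scalp, skull, CSF, gray), in
    strictly decreasing order; the white core fills the center.  ROI blobs
    (named spheres or boxes) must lie entirely inside the gray shell.  The
    affine places the anterior commissure at the sphere center, RAS oriented.
    """
    radii = tuple(float(r) for r in shell_radii_mm)
    if len(radii) != 4:
        raise InvalidGeometryError("expected four shell radii (scalp, skull, CSF, gray)")
    seq = radii + (float(white_core_radius_mm),)
    if any(a <= b for a, b in zip(seq, seq[1:])) or seq[-1] <= 0:
        raise InvalidGeometryError(f"shell radii must strictly decrease: {seq}")
    scalp_r, skull_r, csf_r, gray_r = radii
    white_r = float(white_core_radius_mm)

    h = float(voxel_size_mm)
    half = int(math.ceil(scalp_r / h))
    n = 2 * half + 1
    affine = np.diag([h, h, h, 1.0])
    affine[:3, 3] = -half * h  # center voxel at the AC (origin)

    idx = np.arange(n)
    x = (idx - half) * h
    X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)

    grid = np.zeros((n, n, n), dtype=np.int16)
    grid[r <= scalp_r] = TISSUE_IDS["scalp"]
    grid[r <= skull_r] = TISSUE_IDS["skull"]
    grid[r <= csf_r] = TISSUE_IDS["csf"]
    grid[r <= gray_r] = TISSUE_IDS["gray"]
    grid[r <= white_r] = TISSUE_IDS["white"]

    if with_air_cavity:
        d = np.sqrt(X**2 + (Y - 64.0) ** 2 + (Z + 52.0) ** 2)
        grid[(d <= 7.0) & (grid > 0)] = TISSUE_IDS["air"]
    if with_eyes:
        for sx in (-1.0, 1.0):
            d = np.sqrt((X - sx * 28.0) ** 2 + (Y - 72.0) ** 2 + (Z + 20.0) ** 2)
            grid[(d <= eye_radius_mm) & (grid > 0)] = TISSUE_IDS["eye"]

    tissue = LabelVolume(grid, h, affine, dict_label_table())

    if roi_blobs is None:
        roi_blobs = DEFAULT_ROI_BLOBS
    atlas_grid = np.zeros_like(grid)
    table = {0: "background"}
    for lab, name in enumerate(sorted(roi_blobs), start=1):
        spec = roi_blobs[name]
        mask = _blob_mask(spec, X, Y, Z)
        if not mask.any():
            raise MisplacedROIError(f"ROI blob {name!r} contains no voxels")
        if np.any(grid[mask] != TISSUE_IDS["gray"]):
            raise MisplacedROIError(f"ROI blob {name!r} extends outside the gray shell")
        atlas_grid[mask] = lab
        table[lab] = name
    atlas = LabelVolume(atlas_grid, h, affine.copy(), table)
    return tissue, atlas


def dict_label_table() -> dict[int, str]:
    from .volumes import TISSUE_LABELS

    return dict(TISSUE_LABELS)


def _blob_mask(spec: dict, X: np.ndarray, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
    kind = spec.get("kind", "sphere")
    if kind == "sphere":
        cx, cy, cz = spec["center"]
        rr = float(spec["radius"])
        return (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2 <= rr**2
    if kind == "box":
        (x0, x1), (y0, y1), (z0, z1) = spec["bounds"]
        return (
            (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1) & (Z >= z0) & (Z <= z1)
        )
    raise MisplacedROIError(f"unknown blob kind {kind!r}")


# ---------------------------------------------------------------------------
# Source model
# ---------------------------------------------------------------------------

@dataclass
class Dipole:
    position_mm: np.ndarray
    orientation: np.ndarray
    component: str

    def __post_init__(self) -> None:
        self.position_mm = np.asarray(self.position_mm, dtype=float)
        o = np.asarray(self.orientation, dtype=float)
        nrm = np.linalg.norm(o)
        if not np.isfinite(nrm) or nrm == 0:
            raise ComponentConfigError("dipole orientation must be a nonzero vector")
        self.orientation = o / nrm


#: Default component recipe.  ``target_scalp_uv`` is the desired noiseless
#: component measure (at the named virtual-electrode group) for the baseline
#: condition; per-condition gains are ratios relative to that baseline.
DEFAULT_COMPONENTS: dict[str, dict] = {
    # Contingent negative variation: central-midline ramp over the pretarget
    # second, resolving shortly after target onset.  Larger when no spatial
    # cue was given; in blocked runs, larger for antisaccade blocks.
    "pretarget_neg_sw": {
        "roi": "dorsal_acc",
        "alignment": "target",
        "waveform": {"kind": "ramp", "onset_ms": -1000.0, "peak_ms": 0.0, "resolve_ms": 200.0},
        "orientation": "inward",
        "scalp_group": "CentralZ",
        "target_scalp_uv": -5.00,
        "gains": {
            "cue": {"cued": 1.0, "uncued": 5.65 / 5.00},
            "movement": {"prosaccade": 1.0, "antisaccade": 1.0, "catch": 1.0},
            "movement_when_blocked": {"prosaccade": 0.88, "antisaccade": 1.0, "catch": 1.0},
        },
    },
    # Presaccadic positive slow wave: ramps up from ~150 ms before saccade
    # onset; larger before antisaccades.
    "presaccadic_pos_sw": {
        "roi": "ventral_acc",
        "alignment": "saccade",
        "waveform": {"kind": "ramp", "onset_ms": -150.0, "peak_ms": -10.0, "resolve_ms": 60.0},
        "orientation": "outward",
        "scalp_group": "ParietalZ",
        "target_scalp_uv": 1.89,
        "gains": {
            "cue": {"cued": 1.0, "uncued": 1.0},
            "movement": {"prosaccade": 1.0, "antisaccade": 2.33 / 1.89, "catch": 1.0},
        },
    },
    # Spike potential: Gaussian pulse at saccade onset; larger before
    # prosaccades.
    "spike": {
        "roi": "ventral_acc",
        "alignment": "saccade",
        "waveform": {"kind": "gaussian", "center_ms": 0.0, "sigma_ms": 5.0},
        "orientation": "outward",
        "scalp_group": "ParietalZ",
        "target_scalp_uv": 3.0,
        "gains": {
            "cue": {"cued": 1.0, "uncued": 1.0},
            "movement": {"prosaccade": 1.0, "antisaccade": 2.0 / 3.0, "catch": 1.0},
        },
    },
}


@dataclass
class SourceSpec:
    """Planted dipoles, their waveforms, and condition gain tables."""

    dipoles: list[Dipole]
    components: dict[str, dict]
    moments_nam: dict[str, float] = field(default_factory=dict)

    def waveform(self, component: str, t_ms: np.ndarray) -> np.ndarray:
        """Unit-peak waveform of ``component`` on its own alignment axis."""
        cfg = self.components[component]["waveform"]
        t = np.asarray(t_ms, dtype=float)
        if cfg["kind"] == "ramp":
            onset, peak, resolve = cfg["onset_ms"], cfg["peak_ms"], cfg["resolve_ms"]
            rise = np.clip((t - onset) / (peak - onset), 0.0, 1.0)
            fall = np.where(t > peak, np.clip(1.0 - (t - peak) / resolve, 0.0, 1.0), 1.0)
            return rise * fall
        if cfg["kind"] == "gaussian":
            c, s = cfg["center_ms"], cfg["sigma_ms"]
            return np.exp(-((t - c) ** 2) / (2.0 * s**2))
        raise ComponentConfigError(f"unknown waveform kind {cfg['kind']!r}")

    def alignment(self, component: str) -> str:
        return self.components[component]["alignment"]

    def condition_gain(
        self,
        component: str,
        cue: str,
        movement: str,
        procedure: str = "mixed",
        side: str = "right",
    ) -> float:
        g = self.components[component]["gains"]
        val = g.get("cue", {}).get(cue, 1.0) * g.get("movement", {}).get(movement, 1.0)
        if procedure == "blocked" and "movement_when_blocked" in g:
            val *= g["movement_when_blocked"].get(movement, 1.0)
        val *= g.get("side", {}).get(side, 1.0)
        if val <= 0:
            raise ComponentConfigError(f"non-positive gain for {component}")
        return val

    def dipole_for(self, component: str) -> Dipole:
        for d in self.dipoles:
            if d.component == component:
                return d
        raise ComponentConfigError(f"no dipole for component {component!r}")


def make_source_model(
    atlas: LabelVolume,
    component_config: dict[str, dict] | None = None,
    leadfield=None,
    montage: Montage | None = None,
) -> SourceSpec:
    """Place one dipole per ERP component at the center of its atlas ROI.

    Orientation is radial ("outward" from the sphere center, or "inward").
    When a lead field and montage are supplied, each component's peak dipole
    moment (nAm) is calibrated so that the noiseless scalp component measure
    at its virtual-electrode group equals ``target_scalp_uv``; otherwise the
    configured ``moment_nam`` (default 100) is used directly.
    """
    components = component_config or DEFAULT_COMPONENTS
    names = {v: k for k, v in atlas.label_table.items()}
    dipoles = []
    for cid, cfg in components.items():
        roi = cfg["roi"]
        if roi not in names:
            raise ComponentConfigError(f"component {cid!r} references unknown ROI {roi!r}")
        mask = atlas.mask(roi)
        centers = atlas.voxel_centers(mask)
        centroid = centers.mean(axis=0)
        # node = ROI voxel nearest the centroid
        pos = centers[np.argmin(np.linalg.norm(centers - centroid, axis=1))]
        radial = pos / np.linalg.norm(pos)
        ori = -radial if cfg.get("orientation", "outward") == "inward" else radial
        dipoles.append(Dipole(pos, ori, cid))
    spec = SourceSpec(dipoles, {k: dict(v) for k, v in components.items()})
    for cid, cfg in components.items():
        spec.moments_nam[cid] = float(cfg.get("moment_nam", 100.0))
    if leadfield is not None and montage is not None:
        _calibrate_moments(spec, leadfield, montage)
    return spec


def _scalp_pattern(leadfield, dipole: Dipole) -> np.ndarray:
    """Lead-field column (uV per nAm) for a dipole, at its nearest node."""
    d = np.linalg.norm(leadfield.node_positions - dipole.position_mm, axis=1)
    node = int(np.argmin(d))
    return leadfield.gain[:, node, :] @ dipole.orientation


def _calibrate_moments(spec: SourceSpec, leadfield, montage: Montage) -> None:
    """Set peak moments so baseline-condition scalp measures hit their targets."""
    from . import erp as erp_mod

    for cid, cfg in spec.components.items():
        target = cfg.get("target_scalp_uv")
        group = cfg.get("scalp_group")
        if target is None or group is None:
            continue
        col = _scalp_pattern(leadfield, spec.dipole_for(cid))
        if cfg["alignment"] == "target":
            times = np.arange(erp_mod.TARGET_WINDOW_MS[0], erp_mod.TARGET_WINDOW_MS[1] + 1, DT_MS)
        else:
            times = np.arange(erp_mod.SACCADE_WINDOW_MS[0], erp_mod.SACCADE_WINDOW_MS[1] + 1, DT_MS)
        wave = spec.waveform(cid, times)
        template = erp_mod.ERPWave(
            condition={},
            data=col[:, None] * wave[None, :],
            times=times,
            channels=list(leadfield.channels),
            alignment=cfg["alignment"],
            n_trials=1,
        )
        per_nam = erp_mod.measure_component(template, cid, scope=group, montage=montage).value_uv
        if abs(per_nam) < 1e-12:
            raise ComponentConfigError(
                f"component {cid!r}: scalp measure per unit moment is zero; "
                "cannot calibrate"
            )
        spec.moments_nam[cid] = float(target / per_nam)


# ---------------------------------------------------------------------------
# Experiment design and simulation
# ---------------------------------------------------------------------------

#: Per-cell mean RTs (ms).  Marginals reproduce the cued/uncued means of the
#: mixed-choice experiment (435.6 / 473.0 ms) with a larger cue benefit for
#: antisaccades than prosaccades.
DEFAULT_RT_MEANS_MS: dict[tuple[str, str], float] = {
    ("cued", "prosaccade"): 409.6,
    ("cued", "antisaccade"): 461.6,
    ("uncued", "prosaccade"): 434.5,
    ("uncued", "antisaccade"): 511.5,
}
DEFAULT_RT_SD_MS = 90.0
#: Blocked runs are uniformly faster (preparatory set).
DEFAULT_BLOCKED_RT_SHIFT_MS = -30.0


def make_design(
    trials_per_cell: int = 40,
    procedures: tuple[str, ...] = ("mixed",),
    cues: tuple[str, ...] = ("cued", "uncued"),
) -> list[dict]:
    """Build a block list giving ``trials_per_cell`` saccade trials per
    (procedure, cue, movement) cell.

    Mixed blocks follow the 2 antisaccade : 2 prosaccade : 1 catch composition
    per 5-trial sub-block; blocked runs use 4 same-movement : 1 catch.
    """
    blocks: list[dict] = []
    for proc in procedures:
        for cue in cues:
            if proc == "mixed":
                n = int(np.ceil(trials_per_cell / 2)) * 5
                blocks.append({"procedure": proc, "cue": cue, "n_trials": n})
            else:
                n = int(np.ceil(trials_per_cell / 4)) * 5
                for mov in ("prosaccade", "antisaccade"):
                    blocks.append(
                        {"procedure": proc, "cue": cue, "movement": mov, "n_trials": n}
                    )
    return blocks


def _block_trials(block: dict, rng: np.random.Generator) -> list[str]:
    n = int(block["n_trials"])
    if n % 5:
        raise EmptyDesignError("block trial counts must be multiples of 5")
    out: list[str] = []
    for _ in range(n // 5):
        if block["procedure"] == "mixed":
            sub = ["antisaccade", "antisaccade", "prosaccade", "prosaccade", "catch"]
        else:
            sub = [block["movement"]] * 4 + ["catch"]
        out.extend(rng.permutation(sub).tolist())
    return out


def _rt_lognormal(mean_ms: float, sd_ms: float, rng: np.random.Generator) -> float:
    sigma2 = math.log(1.0 + (sd_ms / mean_ms) ** 2)
    mu = math.log(mean_ms) - sigma2 / 2.0
    return float(rng.lognormal(mu, math.sqrt(sigma2)))


def simulate_experiment(
    tissue: LabelVolume,
    atlas: LabelVolume,
    montage: Montage,
    source_spec: SourceSpec,
    design: list[dict],
    leadfield,
    noise_sd: float = 5.0,
    seed: int = 0,
    rt_means_ms: dict | None = None,
    rt_sd_ms: float = DEFAULT_RT_SD_MS,
    blocked_rt_shift_ms: float = DEFAULT_BLOCKED_RT_SHIFT_MS,
    error_rate: float = 0.03,
    blink_rate: float = 0.02,
    eog_amplitude_uv: float = 50.0,
    eog_noise_sd: float = 1.0,
):
    """Simulate a full session: raw per-trial records, trial table, EOG.

    Returns ``(raw, trials, eog)`` where ``raw`` is a target-locked
    :class:`~presaccade.erp.EpochSet` on the wide raw window, ``trials`` is
    the ground-truth trial table and ``eog`` is (n_trials, n_samples) in uV.
    Deterministic for a fixed seed.
    """
    from .erp import EpochSet  # deferred to avoid a circular import

    if not design or sum(int(b["n_trials"]) for b in design) == 0:
        raise EmptyDesignError("design contains no trials")
    if rt_means_ms is None:
        rt_means_ms = DEFAULT_RT_MEANS_MS

    rng = np.random.default_rng(seed)
    times = raw_times()
    nt = times.size
    n_ch = len(montage.channels)

    # per-component scalp patterns (uV per nAm) and alignments
    comp_cols = {
        d.component: _scalp_pattern(leadfield, d) for d in source_spec.dipoles
    }

    rows = []
    trial_idx = 0
    session_clock_s = 0.0
    for block in design:
        for movement in _block_trials(block, rng):
            cue = block["cue"]
            proc = block["procedure"]
            side = "left" if rng.random() < 0.5 else "right"
            is_catch = movement == "catch"
            error = (not is_catch) and (rng.random() < error_rate)
            blink = rng.random() < blink_rate
            if is_catch:
                rt = np.nan
            else:
                mean = rt_means_ms[(cue, movement)]
                if proc == "blocked":
                    mean = mean + blocked_rt_shift_ms
                rt = _rt_lognormal(mean, rt_sd_ms, rng)
                rt = float(np.clip(round(rt / DT_MS) * DT_MS, 152.0, 900.0))
            # intended saccade direction: toward target (pro) or mirror (anti)
            if is_catch:
                direction = None
            else:
                direction = side if movement == "prosaccade" else _other(side)
                if error:
                    direction = _other(direction)
            session_clock_s += 2.0  # pretarget interval
            target_onset_s = session_clock_s
            session_clock_s += 2.5 + rng.uniform(1.0, 3.0)  # target + ISI
            rows.append(
                {
                    "trial": trial_idx,
                    "procedure": proc,
                    "cue": cue,
                    "movement": movement,
                    "side": side,
                    "direction": direction,
                    "target_onset_s": round(target_onset_s, 4),
                    "rt_ms": rt,
                    "saccade_onset_s": (
                        round(target_onset_s + rt / 1000.0, 4) if not is_catch else np.nan
                    ),
                    "error": error,
                    "blink": blink,
                }
            )
            trial_idx += 1
    trials = pd.DataFrame(rows)

    n_trials = len(trials)
    data = np.empty((n_trials, n_ch, nt))
    eog = np.empty((n_trials, nt))
    frontal = np.asarray([p[1] > 40.0 and p[2] > -20.0 for p in montage.positions])

    for i, row in trials.iterrows():
        sig = rng.normal(0.0, noise_sd, size=(n_ch, nt))
        for cid, col in comp_cols.items():
            gain = source_spec.condition_gain(
                cid, row["cue"], row["movement"], row["procedure"], row["side"]
            )
            moment = source_spec.moments_nam[cid] * gain
            if source_spec.alignment(cid) == "target":
                w = source_spec.waveform(cid, times)
            else:
                if row["movement"] == "catch" or not np.isfinite(row["rt_ms"]):
                    continue
                w = source_spec.waveform(cid, times - row["rt_ms"])
            sig += col[:, None] * (moment * w)[None, :]
        tr_eog = rng.normal(0.0, eog_noise_sd, size=nt)
        if np.isfinite(row["rt_ms"]):
            sign = 1.0 if row["direction"] == "right" else -1.0
            tr_eog[times >= row["rt_ms"]] += sign * eog_amplitude_uv
        if row["blink"]:
            t0 = rng.uniform(-800.0, -300.0)
            pulse = (times >= t0) & (times < t0 + 200.0)
            sig[np.ix_(frontal, pulse)] += 100.0
            tr_eog[pulse] += 100.0
        data[i] = sig
        eog[i] = tr_eog

    raw = EpochSet(
        data=data,
        times=times,
        channels=list(montage.channels),
        trials=trials,
        alignment="raw",
    )
    return raw, trials, eog


def _other(side: str) -> str:
    return "left" if side == "right" else "right"
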