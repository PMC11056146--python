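"""Two-timepoint synthetic subjects for the WMH-trajectory analysis.

Each subject consists of pre-aligned baseline and 1-year volumes: ground-truth
tissue labels on a fine structural grid, a FLAIR-like scalar volume, diffusion
series (multishell at baseline, single-shell at follow-up) synthesized from
the Watson-NODDI forward model, SPGR/IR-SPGR volume sets for T1 mapping, and
the masks the downstream pipeline consumes (brain, white matter, stroke,
lesion-distribution prior).

Lesions are spheres placed inside the white-matter mask. Progression is grown
as one-voxel rims on existing lesions (plus a configurable fraction of de-novo
lesions); regression erodes one-voxel rims, reflecting that most incident WMH
change appears at the edge of existing lesions. Quantitative parameters are
assigned per longitudinal tissue class: every voxel of a class shares the
subject's class values (drawn once per subject around the population mean),
and the 1-year value is the baseline value plus the programmed class effect.
Within-mask variance in the fitted maps then comes from measurement noise,
which is the level the statistical battery operates on.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from wmhtraj.grid import Grid
from wmhtraj.qmri import (
    DiffusionScheme,
    NoddiParams,
    QT1Protocol,
    baseline_qt1_protocol,
    baseline_scheme,
    fit_dti_wls,
    followup_qt1_protocol,
    followup_scheme,
    ir_spgr_signal,
    noddi_forward,
    odi_to_kappa,
    spgr_signal,
)

LABELS = {"background": 0, "nonwm_brain": 1, "nawm": 2, "wmh": 3, "stroke": 4}
CHANGE_CLASSES = ("stable_nawm", "stable_wmh", "progressing_wmh", "regressing_wmh")
# codes of the voxelwise change-class truth map
CHANGE_CODES = {name: i + 1 for i, name in enumerate(CHANGE_CLASSES)}

#: generating parameters of each tissue class: (mean, SD) across subjects.
#: v_ic/odi/v_iso parameterize the diffusion signal, t1_s the relaxometry,
#: flair_c the FLAIR contrast in brain-SD units (applied while labeled WMH).
DEFAULT_CLASS_PARAMS: dict[str, dict[str, tuple[float, float]]] = {
    "stable_nawm": {
        "v_ic": (0.600, 0.020),
        "odi": (0.270, 0.015),
        "v_iso": (0.100, 0.010),
        "t1_s": (0.950, 0.030),
        "flair_c": (0.0, 0.0),
    },
    "progressing_wmh": {
        "v_ic": (0.497, 0.020),
        "odi": (0.242, 0.015),
        "v_iso": (0.117, 0.010),
        "t1_s": (1.008, 0.030),
        "flair_c": (3.0, 0.15),
    },
    "regressing_wmh": {
        "v_ic": (0.483, 0.020),
        "odi": (0.242, 0.015),
        "v_iso": (0.117, 0.010),
        "t1_s": (1.036, 0.030),
        "flair_c": (3.0, 0.15),
    },
    "stable_wmh": {
        "v_ic": (0.347, 0.020),
        "odi": (0.237, 0.015),
        "v_iso": (0.158, 0.010),
        "t1_s": (1.279, 0.030),
        "flair_c": (3.2, 0.15),
    },
    # surrounding tissue, fixed across the cohort
    "nonwm_brain": {
        "v_ic": (0.450, 0.0),
        "odi": (0.500, 0.0),
        "v_iso": (0.150, 0.0),
        "t1_s": (1.300, 0.0),
        "flair_c": (0.0, 0.0),
    },
    "stroke": {
        "v_ic": (0.250, 0.0),
        "odi": (0.400, 0.0),
        "v_iso": (0.350, 0.0),
        "t1_s": (1.500, 0.0),
        "flair_c": (2.5, 0.0),
    },
}

#: additive 1-year change of each generating parameter, per class. The induced
#: FA/MD changes (via the single-shell tensor fit of the class signal) carry
#: the observed longitudinal sign pattern: FA rises only where WMHs regress;
#: FA falls while MD and T1 rise where WMHs progress or persist; MD creeps up
#: in stable NAWM.
DEFAULT_LONGITUDINAL_EFFECTS: dict[str, dict[str, float]] = {
    "stable_nawm": {"v_ic": -0.004, "odi": 0.000, "v_iso": 0.001, "t1_s": 0.005},
    "progressing_wmh": {"v_ic": -0.030, "odi": 0.005, "v_iso": 0.040, "t1_s": 0.058},
    "regressing_wmh": {"v_ic": 0.020, "odi": -0.003, "v_iso": -0.008, "t1_s": -0.003},
    "stable_wmh": {"v_ic": -0.025, "odi": 0.003, "v_iso": 0.035, "t1_s": 0.049},
}

_PARAM_CLIP = {
    "v_ic": (0.01, 0.99),
    "odi": (0.02, 0.95),
    "v_iso": (0.0, 0.99),
    "t1_s": (0.3, 3.0),
    "flair_c": (0.0, 8.0),
}

FLAIR_MEAN = 100.0
S0_DWI = 1000.0
M0_QT1 = 1000.0


@dataclass
class PhantomSpec:
    """Study conditions of the synthetic cohort."""

    grid_shape_structural: tuple[int, int, int] = (48, 48, 48)
    voxel_mm_structural: tuple[float, float, float] = (1.0, 1.0, 1.0)
    grid_shape_diffusion: tuple[int, int, int] = (24, 24, 24)
    voxel_mm_diffusion: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_lesions: int = 20
    lesion_radius_range_mm: tuple[float, float] = (1.8, 3.5)
    fraction_progressing: float = 0.3
    fraction_regressing: float = 0.3
    fraction_de_novo: float = 0.1  # share of progression events appearing as new lesions
    progression_rim_vox: int = 1  # dilation depth of progression rims
    #: erosion depth of regression; 2 voxels makes regression events span
    #: robustly-detected interior tissue, not only the partial-volume edge
    regression_rim_vox: int = 2
    class_params: dict = field(default_factory=lambda: _copy_params(DEFAULT_CLASS_PARAMS))
    longitudinal_effects: dict = field(
        default_factory=lambda: _copy_effects(DEFAULT_LONGITUDINAL_EFFECTS)
    )
    snr: float = 30.0  # b=0 (or reference) signal over noise SD
    flair_smooth_sigma_vox: float = 0.5
    flair_gm_offset_noise_sd: float = 4.0  # GM-vs-WM FLAIR offset in noise-SD units
    seed: int = 0

    @property
    def structural_grid(self) -> Grid:
        return Grid(tuple(self.grid_shape_structural), tuple(self.voxel_mm_structural))

    @property
    def diffusion_grid(self) -> Grid:
        return Grid(tuple(self.grid_shape_diffusion), tuple(self.voxel_mm_diffusion))

    def validate(self) -> None:
        sg, dg = self.structural_grid, self.diffusion_grid
        if not sg.same_extent(dg):
            raise ValueError(
                f"structural and diffusion grids must cover the same physical extent: "
                f"{sg.extent_mm} vs {dg.extent_mm}"
            )
        if self.n_lesions < 0:
            raise ValueError("n_lesions must be >= 0")
        fp, fr = self.fraction_progressing, self.fraction_regressing
        if not (0 <= fp <= 1 and 0 <= fr <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if fp + fr > 1:
            raise ValueError("fraction_progressing + fraction_regressing must be <= 1")
        if self.n_lesions > 0 and fp + fr >= 1.0 and fr > 0:
            # regression only erodes rims so lesion cores persist, but a spec
            # with every lesion changing and nothing stable is rejected outright
            raise ValueError("fractions leave no stable WMH lesions")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        for cls, params in self.class_params.items():
            for p, (_, sd) in params.items():
                if sd < 0:
                    raise ValueError(f"negative SD for {cls}.{p}")
        if not (self.lesion_radius_range_mm[0] > 0
                and self.lesion_radius_range_mm[1] >= self.lesion_radius_range_mm[0]):
            raise ValueError("invalid lesion radius range")


def _copy_params(d):
    return {c: dict(p) for c, p in d.items()}


def _copy_effects(d):
    return {c: dict(p) for c, p in d.items()}


@dataclass
class SubjectPhantom:
    subject_id: str
    spec: PhantomSpec
    labels_bl: np.ndarray
    labels_fu: np.ndarray
    change_map: np.ndarray  # structural grid, CHANGE_CODES (0 = none)
    flair_bl: np.ndarray
    flair_fu: np.ndarray
    dwi_bl: np.ndarray
    scheme_bl: DiffusionScheme
    dwi_fu: np.ndarray
    scheme_fu: DiffusionScheme
    spgr_ir_bl: np.ndarray
    protocol_bl: QT1Protocol
    spgr_ir_fu: np.ndarray
    protocol_fu: QT1Protocol
    brain_mask: np.ndarray
    wm_mask: np.ndarray
    stroke_mask: np.ndarray
    template_prior: np.ndarray
    class_values: dict  # class -> param -> (bl, fu) subject-level truth
    truth: "object"  # tidy DataFrame: class x parameter x timepoint

    @property
    def wmh_bl(self) -> np.ndarray:
        return self.labels_bl == LABELS["wmh"]

    @property
    def wmh_fu(self) -> np.ndarray:
        return self.labels_fu == LABELS["wmh"]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def _ellipsoid(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = np.zeros(shape, dtype=float)
    for g, c, r in zip(grids, center, radii):
        acc = acc + ((g - c) / r) ** 2
    return acc <= 1.0


def _sphere(shape, center, radius_vox) -> np.ndarray:
    return _ellipsoid(shape, center, (radius_vox,) * 3)


def _base_anatomy(grid: Grid) -> tuple[np.ndarray, np.ndarray]:
    shape = grid.shape
    center = tuple((s - 1) / 2.0 for s in shape)
    brain = _ellipsoid(shape, center, tuple(0.45 * s for s in shape))
    wm = _ellipsoid(shape, center, tuple(0.33 * s for s in shape))
    return brain, wm & brain


# ---------------------------------------------------------------------------
# signal simulators
# ---------------------------------------------------------------------------


def simulate_dwi(
    param_maps: dict[str, np.ndarray],
    scheme: DiffusionScheme,
    snr: float,
    seed: int,
    s0: float = S0_DWI,
) -> np.ndarray:
    """Synthesize a 4-D diffusion series from per-voxel NODDI parameters.

    ``param_maps`` holds volumes ``v_ic``, ``odi``, ``v_iso`` (NaN outside the
    object) and optionally ``mu`` (a (3,) global fiber orientation; default z).
    The noise-free signal is the Watson-NODDI forward model scaled by ``s0``;
    noise is Rician: the magnitude of the signal plus complex Gaussian noise
    with SD = s0 / snr per channel. Voxels sharing identical parameters are
    grouped so the forward model runs once per distinct tissue state.
    """
    if snr <= 0 and not np.isinf(snr):
        raise ValueError("snr must be positive (np.inf disables noise)")
    v_ic = np.asarray(param_maps["v_ic"], dtype=float)
    odi = np.asarray(param_maps["odi"], dtype=float)
    v_iso = np.asarray(param_maps["v_iso"], dtype=float)
    mu = np.asarray(param_maps.get("mu", np.array([0.0, 0.0, 1.0])), dtype=float)
    shape = v_ic.shape
    n_vol = scheme.n_volumes
    signal = np.zeros(shape + (n_vol,), dtype=float)

    inside = np.isfinite(v_ic) & np.isfinite(odi) & np.isfinite(v_iso)
    if inside.any():
        stacked = np.column_stack(
            [np.round(v_ic[inside], 6), np.round(odi[inside], 6), np.round(v_iso[inside], 6)]
        )
        uniq, inv = np.unique(stacked, axis=0, return_inverse=True)
        sig_inside = np.empty((inside.sum(), n_vol))
        for u_i, (vic_u, odi_u, viso_u) in enumerate(uniq):
            p = NoddiParams(vic_u, viso_u, odi_to_kappa(max(odi_u, 1e-3)), mu)
            sig_inside[inv == u_i] = s0 * noddi_forward(p, scheme)
        signal[inside] = sig_inside

    if np.isinf(snr):
        return signal
    rng = np.random.default_rng(seed)
    sigma = s0 / snr
    real = signal + rng.normal(0.0, sigma, signal.shape)
    imag = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt(real * real + imag * imag)


def simulate_spgr_ir(
    t1_map: np.ndarray,
    m0_map: np.ndarray,
    b1_map: np.ndarray,
    protocol: QT1Protocol,
    snr: float,
    seed: int,
) -> np.ndarray:
    """SPGR + IR-SPGR volume set (last axis = protocol volumes), Gaussian noise.

    The noise SD is the largest in-object mean volume signal divided by snr.
    """
    if snr <= 0 and not np.isinf(snr):
        raise ValueError("snr must be positive (np.inf disables noise)")
    t1_ms = np.asarray(t1_map, dtype=float) * 1000.0
    m0 = np.asarray(m0_map, dtype=float)
    b1 = np.asarray(b1_map, dtype=float)
    inside = np.isfinite(t1_ms) & (t1_ms > 0) & (m0 > 0)
    vols = []
    for a in protocol.spgr_flip_angles_deg:
        v = np.zeros(t1_ms.shape)
        v[inside] = spgr_signal(t1_ms[inside], m0[inside], b1[inside], a, protocol.tr_ms)
        vols.append(v)
    for ti in protocol.ir_inversion_times_ms:
        v = np.zeros(t1_ms.shape)
        v[inside] = ir_spgr_signal(
            t1_ms[inside], m0[inside], b1[inside], protocol.ir_flip_angle_deg, ti
        )
        vols.append(v)
    data = np.stack(vols, axis=-1)
    if np.isinf(snr):
        return data
    ref = max(float(v[inside].mean()) for v in vols) if inside.any() else 1.0
    rng = np.random.default_rng(seed)
    return data + rng.normal(0.0, ref / snr, data.shape)


def simulate_flair(
    labels: np.ndarray,
    class_contrast: np.ndarray | dict,
    smooth_sigma: float,
    snr: float,
    seed: int,
    change_map: np.ndarray | None = None,
    gm_offset_noise_sd: float = 4.0,
) -> np.ndarray:
    """FLAIR-like scalar volume from a label map.

    The voxel noise SD is sigma_n = FLAIR_MEAN / snr. Non-WM brain tissue is
    offset from white matter by ``gm_offset_noise_sd`` noise SDs (cortical
    tissue is mildly hyperintense on FLAIR), so the brain-intensity SD - the
    reference of the segmentation threshold - is dominated by tissue contrast
    rather than noise, as on real images. WMH (and stroke) voxels sit at
    mu_brain + c * sd_brain where c is the class contrast in brain-SD units
    and (mu_brain, sd_brain) are the design (noise-free + noise variance)
    brain statistics. The noise-free field is optionally Gaussian-smoothed to
    emulate partial-volume edges before noise is added.
    """
    if snr <= 0:
        raise ValueError("snr must be positive (sigma would be degenerate)")
    labels = np.asarray(labels)
    sigma_n = FLAIR_MEAN / snr
    brain = labels != LABELS["background"]

    # offsets relative to the white-matter base; smoothing acts on these so
    # the brain/background edge does not bleed into the brain statistics
    field = np.zeros(labels.shape, dtype=float)
    field[labels == LABELS["nonwm_brain"]] += gm_offset_noise_sd * sigma_n

    # design brain statistics of the lesion-free volume (plus noise variance)
    n_brain = max(int(brain.sum()), 1)
    f_gm = float((labels == LABELS["nonwm_brain"]).sum()) / n_brain
    mu_brain = FLAIR_MEAN + f_gm * gm_offset_noise_sd * sigma_n
    sd_brain = math.sqrt(f_gm * (1.0 - f_gm) * (gm_offset_noise_sd * sigma_n) ** 2 + sigma_n**2)
    mu_offset = mu_brain - FLAIR_MEAN

    if isinstance(class_contrast, dict):
        c_map = np.full(labels.shape, np.nan)
        wmh = labels == LABELS["wmh"]
        if change_map is not None:
            for cls in ("stable_wmh", "progressing_wmh", "regressing_wmh"):
                sel = wmh & (change_map == CHANGE_CODES[cls])
                c_map[sel] = class_contrast.get(cls, 3.0)
            c_map[wmh & ~np.isfinite(c_map)] = class_contrast.get("stable_wmh", 3.0)
        else:
            c_map[wmh] = class_contrast.get("stable_wmh", 3.0)
        c_map[labels == LABELS["stroke"]] = class_contrast.get("stroke", 2.5)
    else:
        c_map = np.asarray(class_contrast, dtype=float)
        c_map = np.where(c_map != 0, c_map, np.nan)
    lesioned = np.isfinite(c_map)
    field[lesioned] = mu_offset + c_map[lesioned] * sd_brain

    if smooth_sigma > 0:
        field = ndimage.gaussian_filter(field, smooth_sigma)
    rng = np.random.default_rng(seed)
    return FLAIR_MEAN * brain + field + rng.normal(0.0, sigma_n, labels.shape)


# ---------------------------------------------------------------------------
# subject assembly
# ---------------------------------------------------------------------------


def _draw_class_values(spec: PhantomSpec, rng: np.random.Generator) -> dict:
    """Per-subject class parameter values at both timepoints."""
    values: dict[str, dict[str, tuple[float, float]]] = {}
    for cls, params in spec.class_params.items():
        effects = spec.longitudinal_effects.get(cls, {})
        values[cls] = {}
        for p, (mean, sd) in params.items():
            lo, hi = _PARAM_CLIP[p]
            bl = float(np.clip(rng.normal(mean, sd) if sd > 0 else mean, lo, hi))
            fu = float(np.clip(bl + effects.get(p, 0.0), lo, hi))
            values[cls][p] = (bl, fu)
    return values


def _nn_indices(src_grid: Grid, dst_grid: Grid) -> tuple[np.ndarray, ...]:
    idx = []
    for ax in range(3):
        centers = dst_grid.centers_mm(ax)
        coord = centers / src_grid.voxel_mm[ax] - 0.5
        j = np.ceil(coord - 0.5).astype(int)  # nearest center, ties to lower index
        idx.append(np.clip(j, 0, src_grid.shape[ax] - 1))
    return np.ix_(*idx)


def _class_field(
    region_codes: np.ndarray,
    class_values: dict,
    param: str,
    tp: int,
) -> np.ndarray:
    """Map the region-code volume to per-voxel parameter values (NaN outside)."""
    out = np.full(region_codes.shape, np.nan)
    for cls, code in _REGION_CODES.items():
        sel = region_codes == code
        if sel.any():
            out[sel] = class_values[cls][param][tp]
    return out


_REGION_CODES = {
    "stable_nawm": 1,
    "stable_wmh": 2,
    "progressing_wmh": 3,
    "regressing_wmh": 4,
    "nonwm_brain": 5,
    "stroke": 6,
}


def _region_code_volume(change_map: np.ndarray, labels_bl: np.ndarray) -> np.ndarray:
    """Tissue-state codes covering the whole brain (change classes + other)."""
    codes = np.zeros(change_map.shape, dtype=np.int8)
    for cls in CHANGE_CLASSES:
        codes[change_map == CHANGE_CODES[cls]] = _REGION_CODES[cls]
    codes[(labels_bl == LABELS["nonwm_brain"]) & (codes == 0)] = _REGION_CODES["nonwm_brain"]
    codes[labels_bl == LABELS["stroke"]] = _REGION_CODES["stroke"]
    # any WM voxel not assigned to a change class (shouldn't happen) -> stable NAWM
    codes[(labels_bl == LABELS["nawm"]) & (codes == 0)] = _REGION_CODES["stable_nawm"]
    codes[(labels_bl == LABELS["wmh"]) & (codes == 0)] = _REGION_CODES["stable_wmh"]
    return codes


def effective_dti_truth(class_values: dict, cls: str, tp: int) -> tuple[float, float]:
    """Ground-truth FA/MD of one class: the noise-free single-shell tensor fit.

    The diffusion signal is generated by the Watson-NODDI model, so the FA/MD
    "truth" is defined as what the iterative-WLS tensor fit returns on the
    noise-free class signal over the b in {0, 1000} subset - a deterministic
    function of the class parameters.
    """
    scheme = followup_scheme()
    p = NoddiParams(
        class_values[cls]["v_ic"][tp],
        class_values[cls]["v_iso"][tp],
        odi_to_kappa(class_values[cls]["odi"][tp]),
        np.array([0.0, 0.0, 1.0]),
    )
    sig = S0_DWI * noddi_forward(p, scheme)
    fit = fit_dti_wls(sig, scheme)
    return fit.fa, fit.md


def make_subject_phantom(spec: PhantomSpec, subject_seed: int, subject_id: str | None = None) -> SubjectPhantom:
    """Generate one two-timepoint subject; deterministic given (spec, seed)."""
    import pandas as pd

    spec.validate()
    rng = np.random.default_rng(int(subject_seed))
    sgrid, dgrid = spec.structural_grid, spec.diffusion_grid
    shape = sgrid.shape
    brain, wm = _base_anatomy(sgrid)

    # stroke lesion: one small sphere inside eroded WM
    wm_core = ndimage.binary_erosion(wm, iterations=3)
    core_idx = np.argwhere(wm_core)
    stroke = np.zeros(shape, dtype=bool)
    if core_idx.size:
        c = core_idx[rng.integers(len(core_idx))]
        stroke = _sphere(shape, c, 3.0 / spec.voxel_mm_structural[0]) & wm

    # lesions
    wmh_bl = np.zeros(shape, dtype=bool)
    lesion_masks: list[np.ndarray] = []
    vox = spec.voxel_mm_structural[0]
    for _ in range(spec.n_lesions):
        r_mm = rng.uniform(*spec.lesion_radius_range_mm)
        c = core_idx[rng.integers(len(core_idx))] if core_idx.size else None
        if c is None:
            break
        les = _sphere(shape, c, r_mm / vox) & wm & ~stroke
        if les.sum() < 5:
            continue
        lesion_masks.append(les)
        wmh_bl |= les

    n_les = len(lesion_masks)
    order = rng.permutation(n_les)
    n_prog = min(n_les, max(1, round(spec.fraction_progressing * n_les))) if (
        spec.fraction_progressing > 0 and n_les
    ) else 0
    n_regr = min(n_les - n_prog, max(1, round(spec.fraction_regressing * n_les))) if (
        spec.fraction_regressing > 0 and n_les
    ) else 0
    prog_ids = order[:n_prog].tolist()
    regr_ids = order[n_prog : n_prog + n_regr].tolist()

    struct6 = ndimage.generate_binary_structure(3, 1)
    wmh_fu = wmh_bl.copy()
    progressing = np.zeros(shape, dtype=bool)
    regressing = np.zeros(shape, dtype=bool)
    n_de_novo = int(round(spec.fraction_de_novo * n_prog))
    for i in (prog_ids[: n_prog - n_de_novo] if n_de_novo else prog_ids):
        les = lesion_masks[i]
        rim = (
            ndimage.binary_dilation(les, struct6, iterations=spec.progression_rim_vox)
            & wm & ~wmh_bl & ~stroke
        )
        progressing |= rim
    if n_de_novo:
        for _ in range(n_de_novo):
            r_mm = max(2.0, spec.lesion_radius_range_mm[0])
            c = core_idx[rng.integers(len(core_idx))]
            les = _sphere(shape, c, r_mm / vox) & wm & ~wmh_bl & ~stroke
            if les.sum() >= 5:
                progressing |= les
    for i in regr_ids:
        les = lesion_masks[i]
        core = ndimage.binary_erosion(les, struct6, iterations=spec.regression_rim_vox)
        rim = les & ~core
        regressing |= rim
        wmh_fu &= ~rim
    wmh_fu |= progressing
    regressing &= ~progressing  # disjointness safeguard

    labels_bl = np.zeros(shape, dtype=np.int8)
    labels_bl[brain] = LABELS["nonwm_brain"]
    labels_bl[wm] = LABELS["nawm"]
    labels_bl[wmh_bl] = LABELS["wmh"]
    labels_bl[stroke] = LABELS["stroke"]

    labels_fu = np.zeros(shape, dtype=np.int8)
    labels_fu[brain] = LABELS["nonwm_brain"]
    labels_fu[wm] = LABELS["nawm"]
    labels_fu[wmh_fu] = LABELS["wmh"]
    labels_fu[stroke] = LABELS["stroke"]

    nawm_bl = labels_bl == LABELS["nawm"]
    nawm_fu = labels_fu == LABELS["nawm"]
    change_map = np.zeros(shape, dtype=np.int8)
    change_map[nawm_bl & nawm_fu] = CHANGE_CODES["stable_nawm"]
    change_map[(labels_bl == LABELS["wmh"]) & (labels_fu == LABELS["wmh"])] = CHANGE_CODES[
        "stable_wmh"
    ]
    change_map[nawm_bl & (labels_fu == LABELS["wmh"])] = CHANGE_CODES["progressing_wmh"]
    change_map[(labels_bl == LABELS["wmh"]) & nawm_fu] = CHANGE_CODES["regressing_wmh"]

    if spec.n_lesions > 0 and n_les > 0:
        for cls in CHANGE_CLASSES:
            if spec.fraction_progressing == 0 and cls == "progressing_wmh":
                continue
            if spec.fraction_regressing == 0 and cls == "regressing_wmh":
                continue
            if not (change_map == CHANGE_CODES[cls]).any():
                raise RuntimeError(f"phantom produced an empty {cls} class; adjust the spec")

    class_values = _draw_class_values(spec, rng)
    region_codes = _region_code_volume(change_map, labels_bl)
    region_codes_d = region_codes[_nn_indices(sgrid, dgrid)]

    # diffusion series (params live on the diffusion grid)
    dwi = {}
    schemes = {"bl": baseline_scheme(), "fu": followup_scheme()}
    for tp_i, tp in enumerate(("bl", "fu")):
        maps = {
            p: _class_field(region_codes_d, class_values, p, tp_i)
            for p in ("v_ic", "odi", "v_iso")
        }
        dwi[tp] = simulate_dwi(maps, schemes[tp], spec.snr, seed=int(rng.integers(2**31)))

    # QT1 series (structural grid)
    b1_map = np.full(shape, np.nan)
    ramp = 0.9 + 0.2 * (np.arange(shape[0]) / max(shape[0] - 1, 1))
    b1_full = np.broadcast_to(ramp[:, None, None], shape)
    protocols = {"bl": baseline_qt1_protocol(), "fu": followup_qt1_protocol()}
    spgr = {}
    for tp_i, tp in enumerate(("bl", "fu")):
        t1 = _class_field(region_codes, class_values, "t1_s", tp_i)
        m0 = np.where(np.isfinite(t1), M0_QT1, np.nan)
        b1_map = np.where(np.isfinite(t1), b1_full, np.nan)
        spgr[tp] = simulate_spgr_ir(
            t1, m0, b1_map, protocols[tp], spec.snr, seed=int(rng.integers(2**31))
        )

    contrast = {
        cls: class_values[cls]["flair_c"][0] for cls in CHANGE_CLASSES
    }
    contrast["stroke"] = class_values["stroke"]["flair_c"][0]
    flair_bl = simulate_flair(
        labels_bl, contrast, spec.flair_smooth_sigma_vox, spec.snr,
        seed=int(rng.integers(2**31)), change_map=change_map,
        gm_offset_noise_sd=spec.flair_gm_offset_noise_sd,
    )
    flair_fu = simulate_flair(
        labels_fu, contrast, spec.flair_smooth_sigma_vox, spec.snr,
        seed=int(rng.integers(2**31)), change_map=change_map,
        gm_offset_noise_sd=spec.flair_gm_offset_noise_sd,
    )

    prior = ndimage.gaussian_filter(
        ndimage.binary_dilation(wm, struct6, iterations=2).astype(float), 1.0
    )
    prior = np.clip(prior / max(prior.max(), 1e-12), 0.0, 1.0)

    # tidy ground-truth table
    rows = []
    sid = subject_id or f"sub-{int(subject_seed)}"
    for cls in CHANGE_CLASSES:
        for tp_i, tp in enumerate(("bl", "fu")):
            fa, md = effective_dti_truth(class_values, cls, tp_i)
            rows.extend(
                [
                    (sid, cls, "fa", tp, fa),
                    (sid, cls, "md", tp, md * 1e3),
                    (sid, cls, "t1", tp, class_values[cls]["t1_s"][tp_i]),
                    (sid, cls, "ndi", tp, class_values[cls]["v_ic"][tp_i]),
                    (sid, cls, "odi", tp, class_values[cls]["odi"][tp_i]),
                    (sid, cls, "fwf", tp, class_values[cls]["v_iso"][tp_i]),
                ]
            )
    truth = pd.DataFrame(rows, columns=["subject", "class", "parameter", "timepoint", "true_mean"])

    return SubjectPhantom(
        subject_id=sid,
        spec=spec,
        labels_bl=labels_bl,
        labels_fu=labels_fu,
        change_map=change_map,
        flair_bl=flair_bl,
        flair_fu=flair_fu,
        dwi_bl=dwi["bl"],
        scheme_bl=schemes["bl"],
        dwi_fu=dwi["fu"],
        scheme_fu=schemes["fu"],
        spgr_ir_bl=spgr["bl"],
        protocol_bl=protocols["bl"],
        spgr_ir_fu=spgr["fu"],
        protocol_fu=protocols["fu"],
        brain_mask=brain,
        wm_mask=wm,
        stroke_mask=stroke,
        template_prior=prior,
        class_values=class_values,
        truth=truth,
    )


def make_cohort(n_subjects: int, spec: PhantomSpec, seed: int):
    """Reproducible cohort: per-subject seeds derived from the master seed."""
    import pandas as pd

    if n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    spec.validate()
    seeds = subject_seeds(n_subjects, seed)
    subjects = [
        make_subject_phantom(spec, int(s), subject_id=f"sub-{i:03d}")
        for i, s in enumerate(seeds)
    ]
    truth = pd.concat([s.truth for s in subjects], ignore_index=True)
    return subjects, truth


def subject_seeds(n_subjects: int, master_seed: int) -> np.ndarray:
    """Deterministic per-subject integer seeds (< 2^31)."""
    ss = np.random.SeedSequence(int(master_seed))
    return ss.generate_state(n_subjects, dtype=np.uint32).astype(np.int64) % (2**31)
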