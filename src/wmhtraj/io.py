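"""File I/O: NIfTI-1 volumes, FSL-dialect gradient tables, protocol JSON."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from wmhtraj.grid import Grid
from wmhtraj.qmri import DiffusionScheme, QT1Protocol


def save_nifti(volume: np.ndarray, voxel_mm, path) -> None:
    vol = np.asarray(volume)
    if vol.dtype == bool:
        vol = vol.astype(np.uint8)
    affine = np.diag(list(voxel_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol, affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, Grid]:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    zooms = img.header.get_zooms()[:3]
    return vol, Grid(tuple(vol.shape[:3]), tuple(float(z) for z in zooms))


def save_scheme(scheme: DiffusionScheme, bval_path, bvec_path) -> None:
    """FSL dialect: one row of b-values; three rows of direction components."""
    np.savetxt(str(bval_path), scheme.bvals[None, :], fmt="%.1f")
    np.savetxt(str(bvec_path), scheme.bvecs.T, fmt="%.6f")


def load_scheme(bval_path, bvec_path) -> DiffusionScheme:
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    return DiffusionScheme(bvals, bvecs)


def save_protocol(protocol: QT1Protocol, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "spgr_flip_angles_deg": list(protocol.spgr_flip_angles_deg),
                "ir_inversion_times_ms": list(protocol.ir_inversion_times_ms),
                "tr_ms": protocol.tr_ms,
                "ir_flip_angle_deg": protocol.ir_flip_angle_deg,
            },
            indent=2,
        )
    )


def load_protocol(path) -> QT1Protocol:
    d = json.loads(Path(path).read_text())
    return QT1Protocol(
        tuple(d["spgr_flip_angles_deg"]),
        tuple(d["ir_inversion_times_ms"]),
        d.get("tr_ms", 8.0),
        d.get("ir_flip_angle_deg", 5.0),
    )


def write_subject(subject, out_dir) -> Path:
    """Persist one phantom subject: NIfTI volumes, gradient tables, truth CSV."""
    out = Path(out_dir) / subject.subject_id
    out.mkdir(parents=True, exist_ok=True)
    svox = subject.spec.voxel_mm_structural
    dvox = subject.spec.voxel_mm_diffusion
    for name, vol, vox in [
        ("labels_bl", subject.labels_bl, svox),
        ("labels_fu", subject.labels_fu, svox),
        ("change_map", subject.change_map, svox),
        ("flair_bl", subject.flair_bl, svox),
        ("flair_fu", subject.flair_fu, svox),
        ("brain_mask", subject.brain_mask, svox),
        ("wm_mask", subject.wm_mask, svox),
        ("stroke_mask", subject.stroke_mask, svox),
        ("template_prior", subject.template_prior, svox),
        ("dwi_bl", subject.dwi_bl, dvox),
        ("dwi_fu", subject.dwi_fu, dvox),
        ("qt1_bl", subject.spgr_ir_bl, svox),
        ("qt1_fu", subject.spgr_ir_fu, svox),
    ]:
        save_nifti(vol, vox, out / f"{name}.nii.gz")
    save_scheme(subject.scheme_bl, out / "dwi_bl.bval", out / "dwi_bl.bvec")
    save_scheme(subject.scheme_fu, out / "dwi_fu.bval", out / "dwi_fu.bvec")
    save_protocol(subject.protocol_bl, out / "qt1_bl.json")
    save_protocol(subject.protocol_fu, out / "qt1_fu.json")
    subject.truth.to_csv(out / "truth.csv", index=False)
    return out
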