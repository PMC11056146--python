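"""End-to-end orchestration: phantom -> fitting -> segmentation -> change
masks -> statistics.

``run_subject`` executes every stage for one synthetic subject and returns its
per-class mean tissue signatures at both timepoints; ``run_cohort`` assembles
the cohort table and runs the full statistical battery (cross-sectional
repeated-measures ANOVAs with Tukey post hocs, longitudinal paired t tests
with a single 12-test Holm family), mirroring the structure of the published
analysis. NODDI parameters are analyzed at baseline only: the 1-year visit
has no multishell acquisition.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from wmhtraj import change_masks as cm
from wmhtraj import qmri, stats
from wmhtraj.phantom import (
    CHANGE_CLASSES,
    PhantomSpec,
    SubjectPhantom,
    make_subject_phantom,
    subject_seeds,
)
from wmhtraj.segmentation import SegmentationConfig, derive_nawm, segment_wmh

LONGITUDINAL_PARAMS = ("fa", "md", "t1")
BASELINE_ONLY_PARAMS = ("ndi", "odi", "fwf")

#: change directions of the published 1-year pattern: FA rises only in
#: regressing WMHs; FA falls and MD/T1 rise in progressing and stable WMHs;
#: MD rises in stable NAWM.
EXPECTED_SIGN_PATTERN: dict[tuple[str, str], int] = {
    ("fa", "regressing_wmh"): +1,
    ("fa", "progressing_wmh"): -1,
    ("fa", "stable_wmh"): -1,
    ("md", "progressing_wmh"): +1,
    ("md", "stable_wmh"): +1,
    ("md", "stable_nawm"): +1,
    ("t1", "progressing_wmh"): +1,
    ("t1", "stable_wmh"): +1,
}


@dataclass
class RunConfig:
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    n_subjects: int = 20
    master_seed: int = 0
    parameters: tuple[str, ...] = ("fa", "md", "t1")
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    min_cluster: int = 5
    connectivity: int = 26
    noddi_max_voxels_per_class: int = 60  # class means estimated on a capped subsample
    alpha: float = 0.05
    out_dir: Path | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        phantom = PhantomSpec(**raw.pop("phantom", {}))
        seg = SegmentationConfig(**raw.pop("segmentation", {}))
        if "parameters" in raw:
            raw["parameters"] = tuple(raw["parameters"])
        if "out_dir" in raw and raw["out_dir"] is not None:
            raw["out_dir"] = Path(raw["out_dir"])
        return cls(phantom=phantom, segmentation=seg, **raw)

    def validate(self) -> None:
        self.phantom.validate()
        known = set(LONGITUDINAL_PARAMS) | set(BASELINE_ONLY_PARAMS)
        unknown = set(self.parameters) - known
        if unknown:
            raise ValueError(f"unknown parameters: {sorted(unknown)}")


@dataclass
class SubjectMeasures:
    subject_id: str
    rows: pd.DataFrame  # subject, parameter, class, timepoint, value
    volumes_ml: dict[str, float]
    qc: dict


class StageError(RuntimeError):
    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed for subject '{subject}': {cause}")
        self.stage = stage
        self.subject = subject


def _derive_masks(subject: SubjectPhantom, config: RunConfig):
    """Segmentation + four-class mask derivation on the structural grid."""
    seg = {}
    for tp, flair in (("bl", subject.flair_bl), ("fu", subject.flair_fu)):
        wmh = segment_wmh(flair, subject.brain_mask, subject.template_prior, config.segmentation)
        wmh &= ~subject.stroke_mask  # stroke lesions excluded from WMH masks
        seg[tp] = {
            "wmh": wmh,
            "nawm": derive_nawm(subject.wm_mask, wmh, subject.stroke_mask),
        }
    masks = cm.change_classes(
        seg["bl"]["nawm"], seg["bl"]["wmh"], seg["fu"]["nawm"], seg["fu"]["wmh"]
    )
    volumes = cm.class_volumes(masks, subject.spec.voxel_mm_structural)
    filtered = masks.map_masks(
        lambda m: cm.filter_small_clusters(m, config.min_cluster, config.connectivity)
    )
    filtered.provenance.update(
        {"min_cluster": config.min_cluster, "connectivity": config.connectivity}
    )
    return seg, masks, volumes, filtered


def _cap_mask(mask: np.ndarray, cap: int, rng: np.random.Generator) -> np.ndarray:
    if cap <= 0 or mask.sum() <= cap:
        return mask
    idx = np.argwhere(mask)
    keep = idx[rng.choice(len(idx), size=cap, replace=False)]
    out = np.zeros_like(mask)
    out[tuple(keep.T)] = True
    return out


def run_subject(config: RunConfig, subject_seed: int, subject_id: str | None = None) -> SubjectMeasures:
    """All stages for one subject; deterministic given (config, seed)."""
    config.validate()
    sid = subject_id or f"sub-{int(subject_seed)}"
    try:
        subject = make_subject_phantom(config.phantom, subject_seed, subject_id=sid)
    except Exception as e:  # noqa: BLE001
        raise StageError("phantom", sid, e) from e

    try:
        seg, masks, volumes, filtered = _derive_masks(subject, config)
    except Exception as e:  # noqa: BLE001
        raise StageError("segmentation", sid, e) from e

    sgrid = config.phantom.structural_grid
    dgrid = config.phantom.diffusion_grid
    masks_struct = filtered.as_dict()
    masks_diff = {
        name: cm.resample_nn(m, sgrid, dgrid) for name, m in masks_struct.items()
    }

    rows: list[tuple] = []
    qc: dict = {"empty_classes": []}
    want = set(config.parameters)

    # diffusion: FA/MD at both timepoints on the single-shell subsets
    if want & {"fa", "md"}:
        try:
            union_d = np.zeros(dgrid.shape, dtype=bool)
            for m in masks_diff.values():
                union_d |= m
            for tp, data, scheme in (
                ("bl", subject.dwi_bl, subject.scheme_bl),
                ("fu", subject.dwi_fu, subject.scheme_fu),
            ):
                maps = qmri.fit_dti_volume(data, scheme, union_d)
                for param in ("fa", "md"):
                    if param not in want:
                        continue
                    cmeans = stats.class_means(maps[param], masks_diff, maps["converged"])
                    scale = 1e3 if param == "md" else 1.0
                    for cls, v in cmeans.items():
                        rows.append((sid, param, cls, tp, v * scale))
        except Exception as e:  # noqa: BLE001
            raise StageError("dti", sid, e) from e

    # quantitative T1 at both timepoints on the structural grid
    if "t1" in want:
        try:
            union_s = np.zeros(sgrid.shape, dtype=bool)
            for m in masks_struct.values():
                union_s |= m
            b1_bl = None
            for tp, data, protocol in (
                ("bl", subject.spgr_ir_bl, subject.protocol_bl),
                ("fu", subject.spgr_ir_fu, subject.protocol_fu),
            ):
                # the shortened 1-year protocol does not identify B1 on its
                # own; reuse the baseline HIFI estimate at follow-up
                t1maps = qmri.fit_despot1_volume(
                    data, protocol, union_s, b1_fixed=b1_bl if tp == "fu" else None
                )
                if tp == "bl":
                    b1_bl = t1maps["b1"]
                cmeans = stats.class_means(t1maps["t1_s"], masks_struct, t1maps["converged"])
                for cls, v in cmeans.items():
                    rows.append((sid, "t1", cls, tp, v))
        except Exception as e:  # noqa: BLE001
            raise StageError("qt1", sid, e) from e

    # NODDI at baseline only (no 1-year multishell acquisition)
    if want & set(BASELINE_ONLY_PARAMS):
        try:
            rng = np.random.default_rng(int(subject_seed) + 7)
            fit_mask = np.zeros(dgrid.shape, dtype=bool)
            capped = {
                name: _cap_mask(m, config.noddi_max_voxels_per_class, rng)
                for name, m in masks_diff.items()
            }
            for m in capped.values():
                fit_mask |= m
            nmaps = qmri.fit_noddi_volume(subject.dwi_bl, subject.scheme_bl, fit_mask)
            for param in BASELINE_ONLY_PARAMS:
                if param not in want:
                    continue
                cmeans = stats.class_means(nmaps[param], capped, nmaps["converged"])
                for cls, v in cmeans.items():
                    rows.append((sid, param, cls, "bl", v))
        except Exception as e:  # noqa: BLE001
            raise StageError("noddi", sid, e) from e

    df = pd.DataFrame(rows, columns=["subject", "parameter", "class", "timepoint", "value"])
    for cls in CHANGE_CLASSES:
        if not masks_struct[cls].any():
            qc["empty_classes"].append(cls)
    qc["seg_wmh_voxels_bl"] = int(seg["bl"]["wmh"].sum())
    qc["seg_wmh_voxels_fu"] = int(seg["fu"]["wmh"].sum())

    if config.out_dir is not None:
        out = Path(config.out_dir) / "subjects"
        out.mkdir(parents=True, exist_ok=True)
        from wmhtraj.io import save_nifti

        sub_out = out / sid
        sub_out.mkdir(exist_ok=True)
        for tp in ("bl", "fu"):
            save_nifti(seg[tp]["wmh"], sgrid.voxel_mm, sub_out / f"wmh_{tp}.nii.gz")
        for name, m in masks_struct.items():
            save_nifti(m, sgrid.voxel_mm, sub_out / f"class_{name}.nii.gz")
        df.to_csv(sub_out / "measures.csv", index=False)

    return SubjectMeasures(subject_id=sid, rows=df, volumes_ml=volumes, qc=qc)


def _complete_case_matrix(
    cohort: pd.DataFrame, parameter: str, timepoint: str
) -> tuple[np.ndarray, list[str]]:
    sub = cohort[(cohort["parameter"] == parameter) & (cohort["timepoint"] == timepoint)]
    wide = sub.pivot_table(index="subject", columns="class", values="value")
    wide = wide.reindex(columns=list(CHANGE_CLASSES)).dropna()
    return wide.to_numpy(), list(wide.index)


def run_cohort(config: RunConfig):
    """Full synthetic-cohort replication run.

    Returns (cohort_table, results dict); writes result tables, the volumes
    CSV, the sign-pattern verdict and a provenance log when out_dir is set.
    """
    config.validate()
    if config.n_subjects < 2:
        raise ValueError("cohort size must be >= 2")
    seeds = subject_seeds(config.n_subjects, config.master_seed)
    measures = [
        run_subject(config, int(s), subject_id=f"sub-{i:03d}") for i, s in enumerate(seeds)
    ]
    cohort = pd.concat([m.rows for m in measures], ignore_index=True)
    volumes = pd.DataFrame(
        [{"subject": m.subject_id, **m.volumes_ml} for m in measures]
    )
    results = run_stats_battery(cohort, config)
    if config.out_dir is not None:
        report_tables(cohort, volumes, results, config)
    return cohort, results


def run_stats_battery(cohort: pd.DataFrame, config: RunConfig) -> dict:
    """Cross-sectional ANOVAs + Tukey post hocs and the Holm-corrected
    longitudinal paired t tests over a long-format cohort table."""
    results: dict = {"cross_sectional": {}, "paired": {}, "skipped": []}
    for param in config.parameters:
        tps = ("bl", "fu") if param in LONGITUDINAL_PARAMS else ("bl",)
        for tp in tps:
            data, subs = _complete_case_matrix(cohort, param, tp)
            if len(subs) < 2:
                results["skipped"].append(f"{param}/{tp}: <2 complete cases")
                continue
            anova = stats.rm_anova_gg(data)
            tukey = stats.tukey_pairwise(data, labels=list(CHANGE_CLASSES), alpha=config.alpha)
            results["cross_sectional"][f"{param}_{tp}"] = {
                "n": len(subs),
                "anova": anova,
                "tukey": tukey,
            }

    # longitudinal paired t tests: one Holm family across all 12 tests
    paired_rows: dict[str, list[stats.PairedTestRow]] = {}
    flat: list[stats.PairedTestRow] = []
    for param in [p for p in config.parameters if p in LONGITUDINAL_PARAMS]:
        bl, subs_bl = _complete_case_matrix(cohort, param, "bl")
        fu, subs_fu = _complete_case_matrix(cohort, param, "fu")
        common = sorted(set(subs_bl) & set(subs_fu))
        if len(common) < 2:
            results["skipped"].append(f"{param}/paired: <2 complete cases")
            continue
        bl = bl[[subs_bl.index(s) for s in common]]
        fu = fu[[subs_fu.index(s) for s in common]]
        rows = stats.paired_tests(bl, fu, labels=list(CHANGE_CLASSES))
        paired_rows[param] = rows
        flat.extend(rows)
    if flat:
        adj = stats.holm_adjust([r.p_raw for r in flat])
        for r, a in zip(flat, adj):
            r.p_holm = float(a)
    results["paired"] = paired_rows
    results["sign_pattern"] = stats.sign_pattern_summary(
        paired_rows, EXPECTED_SIGN_PATTERN, alpha=config.alpha
    )
    return results


def report_tables(cohort: pd.DataFrame, volumes: pd.DataFrame, results: dict, config: RunConfig):
    """Write the cross-sectional / longitudinal result tables and run summary."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.to_csv(out / "cohort_table.csv", index=False)
    volumes.to_csv(out / "class_volumes_ml.csv", index=False)
    for key, res in results["cross_sectional"].items():
        rows = [
            {
                "comparison": f"{c.pair[0]} - {c.pair[1]}",
                "estimate": c.estimate,
                "ci_low": c.ci_low,
                "ci_high": c.ci_high,
                "p_adj": c.p_adj,
            }
            for c in res["tukey"]
        ]
        pd.DataFrame(rows).to_csv(out / f"tukey_{key}.csv", index=False)
    paired = []
    for param, rows in results["paired"].items():
        for r in rows:
            paired.append(
                {
                    "parameter": param,
                    "class": r.label,
                    "estimate": r.estimate,
                    "ci_low": r.ci_low,
                    "ci_high": r.ci_high,
                    "p_raw": r.p_raw,
                    "p_holm": r.p_holm,
                    "n": r.n,
                }
            )
    pd.DataFrame(paired).to_csv(out / "paired_tests.csv", index=False)

    summary = {
        "config": {
            "n_subjects": config.n_subjects,
            "master_seed": config.master_seed,
            "parameters": list(config.parameters),
            "phantom": {
                k: v
                for k, v in dataclasses.asdict(config.phantom).items()
                if k not in ("class_params", "longitudinal_effects")
            },
        },
        "anova": {
            key: {
                "F": res["anova"].f,
                "df1": res["anova"].df1,
                "df2": res["anova"].df2,
                "epsilon": res["anova"].epsilon,
                "p": res["anova"].p,
                "n": res["n"],
            }
            for key, res in results["cross_sectional"].items()
        },
        "sign_pattern": results["sign_pattern"],
        "skipped": results["skipped"],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
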