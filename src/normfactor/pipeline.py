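"""End-to-end orchestration: normative scoring -> signed NMF -> reporting.

Stages communicate only through files under the output directory, so any
stage can be deleted and rerun in isolation; every stage derives its own
seed from the single global seed via ``stage_seed``, and a JSON manifest
records the config and per-stage wall times.  Defaults follow the
reference protocol: K searched in 2..10 with 100
restarts, 1000 permutations, 100 subsamples of 90% of patients, FDR q = 0.05
and a top-5% voxel fraction for display/annotation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import bridge as br
from . import clinical as cl
from . import factors as fm
from . import io as io_core
from . import normative as nm
from . import robustness as rb
from . import significance as sg
from . import transfer as tr
from ._utils import stage_seed

log = logging.getLogger("normfactor.pipeline")

STAGES = (
    "normative",
    "factors",
    "significance",
    "robustness",
    "transfer",
    "bridge",
    "clinical",
    "annotation",
)


@dataclass
class RunConfig:
    input_dir: str  # cohort fixture: images/, mask.nii.gz, subjects.tsv
    output_dir: str
    validation_dir: str | None = None  # optional second cohort for transfer
    term_maps: str | None = None  # optional TSV voxels x terms
    # normative
    gp_restarts: int = 3
    cv_folds: int = 10
    # factor model
    k_min: int = 2
    k_max: int = 10
    n_runs: int = 100
    # significance
    n_perm: int = 1000
    n_runs_null: int = 20
    # robustness
    subsample_fraction: float = 0.9
    n_repeats: int = 100
    # thresholds
    fdr_q: float = 0.05
    top_fraction: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.k_max < self.k_min:
            raise ValueError("k_max must be >= k_min")
        if self.n_runs < 2 or self.n_perm < 1 or self.n_repeats < 1:
            raise ValueError("n_runs >= 2, n_perm >= 1, n_repeats >= 1 required")
        if not (0.0 < self.subsample_fraction <= 1.0):
            raise ValueError("subsample_fraction must be in (0, 1]")
        if not (0.0 < self.top_fraction < 1.0):
            raise ValueError("top_fraction must be in (0, 1)")
        if not Path(self.input_dir).exists():
            raise FileNotFoundError(self.input_dir)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _cohort_paths(root: str | Path):
    root = Path(root)
    return sorted((root / "images").glob("*.nii*")), root / "mask.nii.gz", root / "subjects.tsv"


def _load(root: str | Path):
    return io_core.load_cohort(*_cohort_paths(root))


def _stage_normative(cfg: RunConfig, out: Path) -> None:
    gmv, space, table = _load(cfg.input_dir)
    ctrl = (table["group"] == "control").to_numpy()
    seed = stage_seed(cfg.seed, "normative")
    fit = nm.fit_normative(gmv[ctrl], table.loc[ctrl], n_restarts=cfg.gp_restarts, seed=seed)
    dev = nm.score_deviations(fit, gmv[~ctrl], table.loc[~ctrl], provenance="pipeline")
    parts = nm.split_signed(dev)
    np.savez(
        out / "deviations.npz",
        Z=dev.Z,
        D_pos=parts.D_pos,
        D_neg=parts.D_neg,
        patient_ids=table.loc[~ctrl, "subject_id"].to_numpy(str),
    )
    if cfg.cv_folds > 1:
        cv = nm.crossvalidate(gmv[ctrl], table.loc[ctrl], k_folds=cfg.cv_folds, seed=seed,
                              n_restarts=cfg.gp_restarts)
        pd.DataFrame({"smse": cv.smse}).to_csv(out / "normative_cv.tsv", sep="\t", index=False)
        io_core.write_manifest(cv.summary(), out / "normative_cv.json")


def _read_dev(out: Path):
    z = np.load(out / "deviations.npz", allow_pickle=False)
    return z["D_pos"], z["D_neg"], [str(s) for s in z["patient_ids"]]


def _stage_factors(cfg: RunConfig, out: Path) -> None:
    D_pos, D_neg, ids = _read_dev(out)
    _imgs, mask_p, _tab = _cohort_paths(cfg.input_dir)
    space = io_core.load_mask(mask_p)
    for sign, D in (("positive", D_pos), ("negative", D_neg)):
        seed = stage_seed(cfg.seed, f"factors_{sign[:3]}")
        k_opt, profile, runs = fm.select_k(
            D, k_min=cfg.k_min, k_max=cfg.k_max, n_runs=cfg.n_runs, seed=seed
        )
        H, W = fm.consensus_factors(runs, sign_part=sign, subject_ids=ids)
        ve = fm.variance_explained(D, H)
        np.savez(out / f"factors_{sign}.npz", H=H.H, W=W.W, k_opt=k_opt, r2=ve.r_squared)
        io_core.save_factor_maps(
            H.H, space, out / "factor_maps", prefix=f"{sign}_factor",
            top_fraction=cfg.top_fraction,
        )
        io_core.save_matrix_tsv(
            np.column_stack([W.W, ve.r_squared]),
            ids,
            [f"{sign[0].upper()}W{j + 1}" for j in range(k_opt)] + ["variance_explained"],
            out / f"composition_{sign}.tsv",
        )
        pd.DataFrame(
            {"k": list(profile.stability_by_k()), "stability": list(profile.stability_by_k().values())}
        ).to_csv(out / f"stability_{sign}.tsv", sep="\t", index=False)
        log.info("factors[%s]: k_opt=%d", sign, k_opt)


def _stage_significance(cfg: RunConfig, out: Path) -> None:
    D_pos, D_neg, _ids = _read_dev(out)
    res = {}
    for sign, D in (("positive", D_pos), ("negative", D_neg)):
        k_opt = int(np.load(out / f"factors_{sign}.npz")["k_opt"])
        seed = stage_seed(cfg.seed, f"significance_{sign[:3]}")
        pr = sg.permutation_test(
            D, k_opt, n_perm=cfg.n_perm, n_runs_null=cfg.n_runs_null, seed=seed
        )
        res[sign] = {
            "observed_stability": pr.observed_stability,
            "stability_p": pr.stability_p,
            "n_perm": pr.n_perm,
            "n_runs_null": pr.n_runs_null,
            "r2_significant_fraction": float(np.mean(pr.r2_p_fdr < cfg.fdr_q)),
        }
        pd.DataFrame(
            {"r2": pr.observed_r2, "p": pr.r2_p, "p_fdr": pr.r2_p_fdr}
        ).to_csv(out / f"significance_{sign}.tsv", sep="\t", index=False)
    io_core.write_manifest(res, out / "significance.json")


def _stage_robustness(cfg: RunConfig, out: Path) -> None:
    D_pos, D_neg, _ids = _read_dev(out)
    res = {}
    for sign, D in (("positive", D_pos), ("negative", D_neg)):
        z = np.load(out / f"factors_{sign}.npz")
        seed = stage_seed(cfg.seed, f"robustness_{sign[:3]}")
        rep = rb.subsample_robustness(
            D, z["H"], z["W"], int(z["k_opt"]), fraction=cfg.subsample_fraction,
            n_repeats=cfg.n_repeats, seed=seed,
        )
        res[sign] = rep.summary()
        pd.DataFrame(
            np.column_stack([rep.h_spearman, rep.w_spearman]),
            columns=[f"h_rho_{j + 1}" for j in range(rep.h_spearman.shape[1])]
            + [f"w_rho_{j + 1}" for j in range(rep.w_spearman.shape[1])],
        ).to_csv(out / f"robustness_{sign}.tsv", sep="\t", index=False)
    io_core.write_manifest(res, out / "robustness.json")


def _stage_transfer(cfg: RunConfig, out: Path) -> None:
    if cfg.validation_dir is None:
        log.info("transfer: no validation cohort configured; skipped")
        return
    gmv, _space, table = _load(cfg.validation_dir)
    ctrl = (table["group"] == "control").to_numpy()
    seed = stage_seed(cfg.seed, "transfer")
    fit = nm.fit_normative(gmv[ctrl], table.loc[ctrl], n_restarts=cfg.gp_restarts, seed=seed)
    dev = nm.score_deviations(fit, gmv[~ctrl], table.loc[~ctrl], provenance="validation")
    parts = nm.split_signed(dev)
    res = {}
    for sign, D_new in (("positive", parts.D_pos), ("negative", parts.D_neg)):
        z = np.load(out / f"factors_{sign}.npz")
        W_pred = tr.predict_composition(z["H"], D_new)
        ev = tr.evaluate_transfer(
            W_pred, D_new, int(z["k_opt"]), seed=seed, H_discovery=z["H"]
        )
        res[sign] = {
            "spearman_r": ev.spearman_r.tolist(),
            "spearman_p": ev.spearman_p.tolist(),
            "h_match_corr": ev.h_match_corr,
        }
        io_core.save_matrix_tsv(
            W_pred, table.loc[~ctrl, "subject_id"],
            [f"pred_{sign[0].upper()}W{j + 1}" for j in range(W_pred.shape[1])],
            out / f"transfer_predicted_{sign}.tsv",
        )
    io_core.write_manifest(res, out / "transfer.json")


def _stage_bridge(cfg: RunConfig, out: Path) -> None:
    gmv, space, table = _load(cfg.input_dir)
    gm = br.grouplevel_tmap(gmv, table, q=cfg.fdr_q)
    io_core.save_image(gm.t, space, out / "group_tmap.nii.gz")
    io_core.save_image(-np.log10(np.maximum(gm.p, 1e-300)), space, out / "group_neglog10p.nii.gz")
    zp = np.load(out / "factors_positive.npz")
    zn = np.load(out / "factors_negative.npz")
    fit = br.regress_tmap_on_factors(gm, zp["H"], zn["H"])
    seed = stage_seed(cfg.seed, "bridge")
    W_all = np.hstack([zp["W"], zn["W"]])
    coords, avg_idx = br.embed_compositions(W_all, fit.coefficients, seed=seed)
    io_core.write_manifest(
        {
            "coefficients": fit.coefficients.tolist(),
            "r_squared": fit.r_squared,
            "f_statistic": fit.f_statistic,
            "p_value": fit.p_value,
            "fdr_significant_voxels": int(gm.fdr_mask.sum()),
        },
        out / "bridge.json",
    )
    rows = ["patient"] * (coords.shape[0] - (avg_idx is not None))
    if avg_idx is not None:
        rows.append("average_patient")
    pd.DataFrame({"x": coords[:, 0], "y": coords[:, 1], "role": rows}).to_csv(
        out / "embedding.tsv", sep="\t", index=False
    )


def _stage_clinical(cfg: RunConfig, out: Path) -> None:
    _gmv, _space, table = _load(cfg.input_dir)
    patients = table[table["group"] == "patient"].reset_index(drop=True)
    zp = np.load(out / "factors_positive.npz")
    zn = np.load(out / "factors_negative.npz")
    W_all = np.hstack([zp["W"], zn["W"]])
    names = [f"PW{j + 1}" for j in range(zp["W"].shape[1])] + [
        f"NW{j + 1}" for j in range(zn["W"].shape[1])
    ]
    assoc = cl.associate_clinical(W_all, patients, factor_names=names)
    assoc.table.to_csv(out / "clinical_associations.tsv", sep="\t", index=False)
    cl.onset_contrast(W_all, patients, factor_names=names).table.to_csv(
        out / "onset_contrast.tsv", sep="\t", index=False
    )
    cl.sex_contrast(W_all, patients, factor_names=names).table.to_csv(
        out / "sex_contrast.tsv", sep="\t", index=False
    )


def _stage_annotation(cfg: RunConfig, out: Path) -> None:
    if cfg.term_maps is None:
        log.info("annotation: no term maps configured; skipped")
        return
    tm = pd.read_csv(cfg.term_maps, sep="\t")
    term_set = ann.TermMapSet(values=tm.to_numpy(float), terms=list(tm.columns))
    seed = stage_seed(cfg.seed, "annotation")
    for sign in ("positive", "negative"):
        H = np.load(out / f"factors_{sign}.npz")["H"]
        for j, rep in ann.annotate_factors(
            H, term_set, fraction=cfg.top_fraction, n_perm=cfg.n_perm, seed=seed
        ).items():
            rep.to_csv(out / f"annotation_{sign}_{j + 1}.tsv", sep="\t", index=False)


_STAGE_FUNCS = {
    "normative": _stage_normative,
    "factors": _stage_factors,
    "significance": _stage_significance,
    "robustness": _stage_robustness,
    "transfer": _stage_transfer,
    "bridge": _stage_bridge,
    "clinical": _stage_clinical,
    "annotation": _stage_annotation,
}


def run_pipeline(config: RunConfig, stages: tuple[str, ...] = STAGES) -> Path:
    """Run the requested stages in order; returns the output directory.

    A failing stage aborts the run, leaving a ``FAILED_<stage>`` marker so
    partial results are recognizable; rerunning with the same config and the
    remaining stages resumes from the serialized outputs.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()[:16]
    manifest: dict = {"config": cfg_dict, "config_hash": cfg_hash, "stages": {}}
    for stage in stages:
        if stage not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {stage!r}")
        t0 = time.perf_counter()
        log.info("stage %s: start", stage)
        try:
            _STAGE_FUNCS[stage](config, out)
        except Exception:
            (out / f"FAILED_{stage}").write_text("stage failed; partial results\n")
            io_core.write_manifest(manifest, out / "manifest.json")
            log.exception("stage %s failed", stage)
            raise
        manifest["stages"][stage] = {"seconds": round(time.perf_counter() - t0, 3)}
        log.info("stage %s: done (%.1fs)", stage, manifest["stages"][stage]["seconds"])
    import importlib.metadata as _md

    try:
        manifest["version"] = _md.version("normfactor")
    except _md.PackageNotFoundError:  # pragma: no cover
        manifest["version"] = "unknown"
    io_core.write_manifest(manifest, out / "manifest.json")
    return out
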