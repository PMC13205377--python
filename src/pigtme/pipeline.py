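"""Experiment orchestration: configuration, I/O adapters, seeded end-to-end runs.

``run_experiment`` chains the whole analysis: simulate a cohort (genotypes,
scale BW with fixed effects, ventral clearance), produce image-derived
biometric features (rendered depth videos for a configurable subset of
animals, the closed-form feature-space mode for the rest), fit the BW
regressions, compute trait measurement error, and run the genetic stages
(MAF filter, GRM, REML heritability for scale BW / image BW / TME, GWAS on
all three, top-marker agreement counts), assembling everything into a
:class:`~pigtme.tme.TmeReport`.  Everything is deterministic given the
experiment seed; intermediate artifacts are persisted as plain CSV/TSV/JSON
when an output directory is set.

The I/O adapters read and write the documented plain-text layouts:
genotype tables (CSV, one marker column per SNP, 0/1/2 codes), phenotype
tables (CSV, one row per animal x time point), per-video frame directories
(PNG pseudo-color image plus same-stem CSV distance map in meters).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import bwreg, quantgen, segment, simdata, tme

__all__ = [
    "ExperimentConfig",
    "run_experiment",
    "write_genotypes_csv",
    "read_genotypes_csv",
    "write_phenotypes_csv",
    "read_phenotypes_csv",
    "write_video_dir",
    "read_video_dir",
    "write_vc_json",
    "write_gwas_tsv",
]

log = logging.getLogger("pigtme")

FEATURE_COLUMNS = ["dorsal_length", "abdominal_width", "height", "volume"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# I/O adapters


def write_genotypes_csv(geno: simdata.GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(geno.codes, index=geno.animal_ids, columns=geno.marker_ids)
    df.index.name = "animal_id"
    df.to_csv(path)


def read_genotypes_csv(path: str | Path) -> simdata.GenotypeMatrix:
    df = pd.read_csv(path, index_col="animal_id")
    codes = df.to_numpy()
    bad = ~np.isin(codes, (0, 1, 2))
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"invalid genotype code {codes[r, c]!r} for animal {df.index[r]!r}, "
            f"marker {df.columns[c]!r}"
        )
    return simdata.GenotypeMatrix(
        codes=codes.astype(np.int8),
        animal_ids=[str(a) for a in df.index],
        marker_ids=[str(m) for m in df.columns],
    )


def write_phenotypes_csv(pheno: pd.DataFrame, path: str | Path) -> None:
    pheno.to_csv(path, index=False)


def read_phenotypes_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _read_distance_csv(path: Path) -> np.ndarray:
    try:
        return np.loadtxt(path, delimiter=",", dtype=np.float64, ndmin=2)
    except ValueError:
        # locate the offending cell for the error message
        for r, line in enumerate(path.read_text().splitlines()):
            for c, cell in enumerate(line.split(",")):
                try:
                    float(cell)
                except ValueError:
                    raise ValueError(
                        f"{path.name}: non-numeric cell {cell!r} at row {r}, col {c}"
                    ) from None
        raise


def write_video_dir(video: simdata.DepthVideo, out_dir: str | Path, stem: str = "frame") -> None:
    """One PNG pseudo-color image plus one same-stem CSV distance map per frame."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for fr in video.frames:
        name = f"{stem}_{fr.frame_index:04d}"
        Image.fromarray(fr.color_image).save(out / f"{name}.png")
        np.savetxt(out / f"{name}.csv", fr.distance_map, delimiter=",", fmt="%.6f")


def read_video_dir(in_dir: str | Path, stem: str = "frame") -> simdata.DepthVideo:
    """Read a frame directory back; rejects PNG/CSV shape mismatches by name."""
    d = Path(in_dir)
    frames = []
    pngs = sorted(d.glob(f"{stem}_*.png"))
    if not pngs:
        raise FileNotFoundError(f"no '{stem}_*.png' frames in {d}")
    for png in pngs:
        csv = png.with_suffix(".csv")
        if not csv.exists():
            raise FileNotFoundError(f"distance map {csv.name} missing for {png.name}")
        color = np.asarray(Image.open(png).convert("RGB"))
        dist = _read_distance_csv(csv)
        if color.shape[:2] != dist.shape:
            raise ValueError(
                f"frame {png.stem}: PNG shape {color.shape[:2]} != CSV shape {dist.shape}"
            )
        idx = int(png.stem.rsplit("_", 1)[1])
        frames.append(simdata.DepthFrame(distance_map=dist, color_image=color, frame_index=idx))
    return simdata.DepthVideo(frames=frames)


def write_vc_json(vcs: dict[str, quantgen.VarianceComponents], path: str | Path) -> None:
    out = {
        key: {
            "sigma2_u": vc.sigma2_u,
            "sigma2_e": vc.sigma2_e,
            "h2": vc.h2,
            "se_h2": vc.se_h2,
            "loglik": vc.loglik,
            "boundary": vc.boundary,
        }
        for key, vc in vcs.items()
    }
    Path(path).write_text(json.dumps(out, indent=2) + "\n")


def write_gwas_tsv(res: quantgen.GWASResult, path: str | Path) -> None:
    res.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# experiment configuration and runner


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    sim: simdata.SimConfig
    methods: list[str] = field(default_factory=lambda: ["ols", "rf"])
    scenario: str = "random"  # or "genetic_clearance"
    time_points: list[str] = field(default_factory=lambda: ["T2"])
    n_rendered: int = 0
    train_frac: float = 0.8
    maf_threshold: float = 0.05
    k_top: int = 10
    k_ref: int = 100
    out_dir: str | None = None
    # resume: read features_{tp}.csv from this directory instead of
    # simulating/rendering them (the other stages re-run identically)
    features_dir: str | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("random", "genetic_clearance"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        bad = [m for m in self.methods if m not in ("ols", "rf", "volumetric")]
        if bad:
            raise ValueError(f"unknown method(s) {bad}")
        for tp in self.time_points:
            if tp not in simdata.TIME_POINT_MEAN_BW:
                raise ValueError(f"unknown time point {tp!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        raw = yaml.safe_load(Path(path).read_text())
        sim_raw = raw.pop("sim", {})
        fe = sim_raw.pop("fixed_effects", None)
        if fe is not None:
            sim_raw["fixed_effects"] = simdata.FixedEffectSpec(**fe)
        if "image_shape" in sim_raw:
            sim_raw["image_shape"] = tuple(sim_raw["image_shape"])
        return cls(sim=simdata.SimConfig(**sim_raw), **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["sim"]["image_shape"] = list(d["sim"]["image_shape"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _scenario_sim_config(config: ExperimentConfig) -> simdata.SimConfig:
    """Clearance heritability is forced to 0 under the random-error scenario."""
    if config.scenario == "random":
        return replace(config.sim, h2_clearance=0.0)
    if config.sim.h2_clearance == 0.0:
        return replace(config.sim, h2_clearance=0.5)
    return config.sim


def _cohort_features(
    geno: simdata.GenotypeMatrix,
    bw: np.ndarray,
    clearance: np.ndarray,
    cfg: simdata.SimConfig,
    n_rendered: int,
    rng: np.random.Generator,
    shape_dev: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Image-derived features: rendered+segmented subset, feature-space rest."""
    if shape_dev is None:
        shape_dev = np.zeros((len(bw), 2))
    feats = simdata.simulate_features(bw, clearance, cfg, rng, shape_dev=shape_dev)
    drops = []
    for i in range(min(n_rendered, len(bw))):
        shape = simdata.shape_from_weight(
            float(bw[i]), cfg, clearance=float(clearance[i]), shape_dev=tuple(shape_dev[i])
        )
        video = simdata.render_depth_video(shape, cfg, rng)
        agg, table = segment.process_video(
            video, camera_height=cfg.camera_height, trim_ratio=cfg.trim_ratio
        )
        feats.iloc[i] = [agg.dorsal_length, agg.abdominal_width, agg.height, agg.volume]
        n_drop = int((table["status"] != "ok").sum())
        drops.append({"animal_id": geno.animal_ids[i], "frames": len(table), "dropped": n_drop})
    return feats, pd.DataFrame(drops, columns=["animal_id", "frames", "dropped"])


def _fit_reference_model(
    cfg: simdata.SimConfig,
    method: str,
    mean_bw: float,
    sd_bw: float,
    rng: np.random.Generator,
) -> tuple[bwreg.RegressionModel, bwreg.FitMetrics]:
    """Calibrate a BW regressor on a reference cohort without clearance genetics.

    The vision system's regression is trained once, on a population whose
    ventral clearance varies only environmentally — the constant-clearance
    assumption under which depth-based volumetrics are calibrated.  Applying
    that model to a study cohort that segregates clearance-raising variants
    is exactly how a heritable clearance turns into a systematic, heritable
    measurement error.
    """
    n = cfg.n_individuals
    bw = rng.normal(mean_bw, sd_bw, size=n)
    bw = np.maximum(bw, 1.0)
    clearance = np.maximum(
        cfg.clearance_baseline + rng.normal(0.0, cfg.sd_clearance, size=n), 0.0
    )
    dev = rng.normal(0.0, cfg.shape_sd, size=(n, 2))
    feats = simdata.simulate_features(bw, clearance, cfg, rng, shape_dev=dev)
    if method == "ols":
        model = bwreg.fit_ols(feats, bw)
    else:
        model = bwreg.fit_rf(feats, bw, seed=cfg.seed)
    metrics = bwreg.evaluate(bw, model.predict(feats))
    return model, metrics


def run_experiment(config: ExperimentConfig) -> tme.TmeReport:
    """Run the full seeded experiment and assemble the comparison report."""
    cfg = _scenario_sim_config(config)
    out = Path(config.out_dir) if config.out_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(cfg.seed)
    rngs = {
        name: np.random.default_rng(s)
        for name, s in zip(
            ("geno", "trait", "clearance", "shape", "features", "reference"), ss.spawn(6)
        )
    }
    shape_dev = simdata.simulate_shape_deviations(cfg, rngs["shape"])

    stage = "simulate_genotypes"
    try:
        geno = simdata.simulate_genotypes(cfg, rngs["geno"])
        log.info("stage=%s n=%d m=%d seed=%d", stage, geno.n, geno.m, cfg.seed)

        stage = "quantgen_setup"
        fgeno = quantgen.maf_filter(geno, config.maf_threshold)
        _, G = quantgen.build_grm(fgeno)
        log.info("stage=%s markers_kept=%d of %d", stage, fgeno.m, geno.m)

        arch = None
        per_animal, fit_rows, h2_rows, agree_rows = [], [], [], []
        vcs: dict[str, quantgen.VarianceComponents] = {}
        for tp in config.time_points:
            stage = f"simulate_trait[{tp}]"
            if arch is None:
                arch, pheno = simdata.simulate_trait(
                    geno, cfg, rngs["trait"], time_point=tp,
                    mean_bw=simdata.TIME_POINT_MEAN_BW[tp],
                )
                stage = "simulate_clearance"
                c_arch, clearance = simdata.simulate_clearance(
                    geno, cfg, rngs["clearance"], exclude_qtl=arch.qtl_indices
                )
            else:
                # same QTL and breeding values at every visit; fresh residuals
                _, pheno = simdata.simulate_trait(
                    geno, cfg, rngs["trait"], time_point=tp,
                    mean_bw=simdata.TIME_POINT_MEAN_BW[tp],
                )
                pheno["scale_bw"] += arch.breeding_values - pheno["true_bv"]
                pheno["true_bv"] = arch.breeding_values
            y = pheno["scale_bw"].to_numpy()

            stage = f"features[{tp}]"
            if config.features_dir is not None:
                stored = pd.read_csv(Path(config.features_dir) / f"features_{tp}.csv")
                if list(stored["animal_id"]) != geno.animal_ids:
                    raise ValueError(f"persisted features for {tp} do not match cohort")
                feats = stored[FEATURE_COLUMNS].copy()
            else:
                feats, drop_log = _cohort_features(
                    geno, y, clearance, cfg, config.n_rendered, rngs["features"],
                    shape_dev=shape_dev,
                )
                if len(drop_log):
                    log.info("stage=%s rendered=%d dropped_frames=%d", stage,
                             len(drop_log), int(drop_log["dropped"].sum()))
            if out is not None:
                feats.assign(animal_id=geno.animal_ids).to_csv(
                    out / f"features_{tp}.csv", index=False
                )

            stage = f"reml[{tp}:scale]"
            X = simdata.design_matrix(pheno)
            vc_scale = quantgen.reml_fit(y, X, G)
            vcs[f"{tp}:scale_bw"] = vc_scale
            gwas_scale = quantgen.gwas_scan(y, X, fgeno, G, vc_scale)
            if out is not None:
                write_gwas_tsv(gwas_scale, out / f"gwas_{tp}_scale.tsv")

            for method in config.methods:
                stage = f"bwreg[{tp}:{method}]"
                if method == "volumetric":
                    model = bwreg.volumetric_model(*simdata.volumetric_calibration(cfg))
                    image_bw = model.predict(feats[["volume"]])
                    m_te = bwreg.evaluate(y, image_bw)
                    m_tr = m_te  # no statistical training step
                else:
                    model, m_tr = _fit_reference_model(
                        cfg, method, float(y.mean()), float(y.std()), rngs["reference"]
                    )
                    image_bw = model.predict(feats)
                    m_te = bwreg.evaluate(y, image_bw)
                fit_rows.append(
                    {"time_point": tp, "method": method,
                     "r2_train": m_tr.r2, "mape_train": m_tr.mape,
                     "r2_test": m_te.r2, "mape_test": m_te.mape,
                     "n_train": m_tr.n, "n_test": m_te.n}
                )
                tme_v = tme.compute_tme(y, image_bw)
                per_animal.append(
                    pd.DataFrame(
                        {"animal_id": geno.animal_ids, "time_point": tp,
                         "method": method, "scale_bw": y, "image_bw": image_bw}
                    )
                )
                if out is not None:
                    pd.DataFrame(
                        {"animal_id": geno.animal_ids, "time_point": tp,
                         "method": method, "image_bw": image_bw}
                    ).to_csv(out / f"predictions_{tp}_{method}.csv", index=False)

                stage = f"reml[{tp}:{method}]"
                vc_img = quantgen.reml_fit(image_bw, X, G)
                vc_tme = quantgen.reml_fit(tme_v, X, G)
                vcs[f"{tp}:{method}:image_bw"] = vc_img
                vcs[f"{tp}:{method}:tme"] = vc_tme
                h2_rows.append(
                    {"time_point": tp, "method": method,
                     "h2_bw": vc_scale.h2, "se_bw": vc_scale.se_h2,
                     "h2_cv": vc_img.h2, "se_cv": vc_img.se_h2,
                     "h2_tme": vc_tme.h2, "se_tme": vc_tme.se_h2}
                )

                stage = f"gwas[{tp}:{method}]"
                gwas_img = quantgen.gwas_scan(image_bw, X, fgeno, G, vc_img)
                gwas_tme = quantgen.gwas_scan(tme_v, X, fgeno, G, vc_tme)
                agree_rows.append(
                    {"time_point": tp, "method": method,
                     "agreement": tme.topk_agreement(gwas_scale, gwas_img,
                                                     config.k_top, config.k_ref),
                     "tme_overlap": tme.topk_agreement(gwas_scale, gwas_tme,
                                                       config.k_top, config.k_ref),
                     "k_top": config.k_top, "k_ref": config.k_ref}
                )
                if out is not None:
                    write_gwas_tsv(gwas_img, out / f"gwas_{tp}_{method}_image.tsv")
                    write_gwas_tsv(gwas_tme, out / f"gwas_{tp}_{method}_tme.tsv")
            if out is not None:
                write_phenotypes_csv(pheno, out / f"phenotypes_{tp}.csv")
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    stage = "assemble_report"
    report = tme.assemble_report(
        pd.concat(per_animal, ignore_index=True),
        fit_metrics=pd.DataFrame(fit_rows),
        heritability=pd.DataFrame(h2_rows),
        agreement=pd.DataFrame(agree_rows),
    )
    if out is not None:
        write_vc_json(vcs, out / "vc.json")
        report.write(out / "report")
    log.info("stage=done time_points=%d methods=%d", len(config.time_points),
             len(config.methods))
    return report
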