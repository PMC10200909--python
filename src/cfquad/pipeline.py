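"""Pipeline orchestration: simulate -> extract -> differential -> train ->
evaluate, with config serialization, provenance headers and logging.

Every data artifact (TSV matrix, differential table, JSON report) carries a
provenance header with the package version, the run seed and a hash of the
canonical config, so reruns are attributable and — logs aside, which carry
wall-clock timings — byte-identical for identical config + inputs.
"""

from __future__ import annotations

import dataclasses
import glob
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .classify import choose_cutoff, evaluate, fit_stacked
from .cna import call_significant_bins, cna_matrix, cna_zscores
from .fragments import read_fragment_table, read_manifest
from .fragmentomics import em_differential, em_matrix, flen_distribution_test, flen_matrix
from .genome import apply_blacklist, build_genome_model, compute_bin_gc, read_chrom_sizes
from .methylation import gwm_density_shift, gwm_matrix
from .simulate import cohort_spec, generate_cohort

log = logging.getLogger("cfquad")

FEATURE_FILES = {"GWM": "gwm.tsv", "CNA": "cna.tsv", "EM": "em.tsv", "Flen": "flen.tsv"}


@dataclass
class RunConfig:
    outdir: str
    seed: int = 0
    preset: str = "breast"
    n_cancer: int = 30
    n_control: int = 30
    fragments_per_sample: int = 200_000
    tumor_fraction: float | None = None
    bin_size: int = 50_000
    alpha: float = 0.05
    min_specificity: float = 0.90
    validation_fraction: float = 0.33
    chrom_sizes: str | None = None
    blacklist: str | None = None
    reference: str | None = None
    fragments_dir: str | None = None
    manifest: str | None = None
    include_flen_model: bool = False
    naive_stacking: bool = False
    features: tuple = ("GWM", "CNA", "EM", "Flen")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["features"] = list(d["features"])
        return d

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded, so two
        runs of one config into different directories hash alike)."""
        d = self.to_dict()
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    return (
        f"# cfquad v{__version__} seed={config.seed} "
        f"config={config.config_hash()}"
    )


def write_matrix(df: pd.DataFrame, path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config) + "\n")
        df.to_csv(fh, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    return df


def write_json(obj, path, config: RunConfig) -> None:
    payload = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.config_hash(),
        },
        **obj,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=float)


def setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "pipeline.log"),
    ):
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(handler)


def build_model_from_config(config: RunConfig):
    if config.chrom_sizes:
        model = build_genome_model(read_chrom_sizes(config.chrom_sizes),
                                   config.bin_size)
    else:
        from .simulate import default_genome

        model = default_genome(bin_size=config.bin_size)
    if config.blacklist:
        model = apply_blacklist(model, config.blacklist)
        log.info("blacklist applied: %d of %d bins retained",
                 model.retained.sum(), model.n_bins)
    if config.reference:
        model = compute_bin_gc(model, config.reference)
    return model


def load_fragments(config: RunConfig, model) -> dict[str, pd.DataFrame]:
    frames = {}
    paths = sorted(glob.glob(str(Path(config.fragments_dir) / "*.fragments.tsv*")))
    if not paths:
        raise FileNotFoundError(f"no fragment tables under {config.fragments_dir}")
    for path in paths:
        report = read_fragment_table(path, model)
        for err in report.errors:
            log.warning("%s: %s", path, err)
        if len(report.frame):
            frames[report.frame["sample_id"].iloc[0]] = report.frame
    return frames


def extract_features(
    frames: dict[str, pd.DataFrame], model, config: RunConfig, outdir: Path
) -> dict[str, pd.DataFrame]:
    features = {}
    if "GWM" in config.features:
        features["GWM"] = gwm_matrix(frames, model)
    if "CNA" in config.features:
        features["CNA"] = cna_matrix(frames, model)
    if "EM" in config.features:
        features["EM"] = em_matrix(frames)
    if "Flen" in config.features:
        features["Flen"] = flen_matrix(frames)
    outdir.mkdir(parents=True, exist_ok=True)
    for fam, mat in features.items():
        write_matrix(mat, outdir / FEATURE_FILES[fam], config)
        log.info("feature %s: %d samples x %d features", fam, *mat.shape)
    return features


def _split(features, manifest):
    cancer_ids = manifest.loc[manifest["label"] == "cancer", "sample_id"]
    control_ids = manifest.loc[manifest["label"] == "control", "sample_id"]
    return {
        fam: (mat.loc[mat.index.isin(cancer_ids)],
              mat.loc[mat.index.isin(control_ids)])
        for fam, mat in features.items()
    }


def run_differential(features, manifest, config: RunConfig, outdir: Path) -> dict:
    outdir.mkdir(parents=True, exist_ok=True)
    split = _split(features, manifest)
    results = {}
    if "CNA" in features:
        cancer, control = split["CNA"]
        table = call_significant_bins(cancer, control, alpha=config.alpha)
        z = cna_zscores(cancer, control)
        table["z_group_mean"] = z.loc["mean"].to_numpy()
        with open(outdir / "cna_differential.tsv", "w") as fh:
            fh.write(_provenance(config) + "\n")
            table.to_csv(fh, sep="\t", index=False)
        results["cna_significant"] = {
            "increase": int((table["category"] == "increase").sum()),
            "decrease": int((table["category"] == "decrease").sum()),
        }
    if "EM" in features:
        cancer, control = split["EM"]
        table = em_differential(cancer, control, alpha=config.alpha)
        with open(outdir / "em_differential.tsv", "w") as fh:
            fh.write(_provenance(config) + "\n")
            table.to_csv(fh, sep="\t", index=False)
        results["em_significant"] = {
            "increase": int((table["category"] == "increase").sum()),
            "decrease": int((table["category"] == "decrease").sum()),
        }
    if "GWM" in features:
        cancer, control = split["GWM"]
        res, direction = gwm_density_shift(cancer, control)
        results["gwm_shift"] = {
            "ks_statistic": res.statistic, "p": res.pvalue, "direction": direction,
        }
    if "Flen" in features:
        cancer, control = split["Flen"]
        res, med_a, med_b = flen_distribution_test(cancer, control)
        results["flen_shift"] = {
            "ks_statistic": res.statistic, "p": res.pvalue,
            "median_cancer": med_a, "median_control": med_b,
        }
    write_json(results, outdir / "differential_summary.json", config)
    return results


def train_model(features, manifest, config: RunConfig):
    """Fit the stacked model on the discovery cohort only and freeze the
    specificity-anchored cutoff. Validation rows never enter training."""
    disc = manifest[manifest["cohort"] == "discovery"]
    families = [f for f in ("GWM", "CNA", "EM") if f in features]
    if config.include_flen_model and "Flen" in features:
        families.append("Flen")
    train_feats = {
        fam: features[fam].loc[features[fam].index.isin(disc["sample_id"])]
        for fam in families
    }
    order = train_feats[families[0]].index
    y = disc.set_index("sample_id").loc[order, "label"]
    model = fit_stacked(
        train_feats, y, seed=config.seed,
        naive_stacking=config.naive_stacking,
    )
    scores = model.predict_proba(train_feats)
    model.cutoff = choose_cutoff(scores, y, config.min_specificity)
    model.min_specificity = config.min_specificity
    return model, list(order)


def run_pipeline(config: RunConfig) -> dict:
    """End-to-end run; returns the evaluation report. Any stage failure
    aborts with the stage name in the raised error."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    setup_logging(outdir)
    with open(outdir / "config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2, sort_keys=True)

    stage = "simulate"
    try:
        t0 = time.time()
        if config.fragments_dir is None:
            spec = cohort_spec(
                preset=config.preset, n_cancer=config.n_cancer,
                n_control=config.n_control,
                fragments_per_sample=config.fragments_per_sample,
                tumor_fraction_mean=config.tumor_fraction, seed=config.seed,
            )
            result = generate_cohort(spec, outdir=outdir / "cohort")
            frames, manifest = result.frames, result.manifest
            model = spec.genome
            # deterministic discovery/validation split by sample order
            n_val = int(round(len(manifest) * config.validation_fraction))
            val_ids = set(
                manifest.groupby("label")["sample_id"]
                .apply(lambda s: s.iloc[: max(1, int(round(len(s) * config.validation_fraction)))])
                .explode()
            ) if n_val else set()
            manifest = manifest.copy()
            manifest.loc[manifest["sample_id"].isin(val_ids), "cohort"] = "validation"
            manifest.to_csv(outdir / "cohort" / "manifest.tsv", sep="\t", index=False)
        else:
            model = build_model_from_config(config)
            frames = load_fragments(config, model)
            manifest = read_manifest(config.manifest)
        log.info("stage %s done in %.1fs (%d samples)", stage,
                 time.time() - t0, len(frames))

        stage = "extract"
        t0 = time.time()
        features = extract_features(frames, model, config, outdir / "features")
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "differential"
        t0 = time.time()
        disc_manifest = manifest[manifest["cohort"] == "discovery"]
        disc_features = {
            fam: mat.loc[mat.index.isin(disc_manifest["sample_id"])]
            for fam, mat in features.items()
        }
        run_differential(disc_features, disc_manifest, config, outdir / "differential")
        log.info("stage %s done in %.1fs", stage, time.time() - t0)

        stage = "train"
        t0 = time.time()
        stacked, train_ids = train_model(features, manifest, config)
        save_model(stacked, outdir / "model")
        log.info("stage %s done in %.1fs (cutoff %.4f)", stage,
                 time.time() - t0, stacked.cutoff)

        stage = "evaluate"
        t0 = time.time()
        val_manifest = manifest[manifest["cohort"] == "validation"]
        if len(val_manifest) and val_manifest["label"].nunique() == 2:
            eval_feats = {
                fam: features[fam].loc[
                    features[fam].index.isin(val_manifest["sample_id"])
                ]
                for fam in stacked.families
            }
            report = evaluate(stacked, eval_feats, val_manifest,
                              train_sample_ids=train_ids)
        else:
            eval_feats = {
                fam: features[fam].loc[features[fam].index.isin(train_ids)]
                for fam in stacked.families
            }
            report = evaluate(stacked, eval_feats, manifest,
                              allow_train_overlap=True, train_sample_ids=train_ids)
        write_json(report, outdir / "report.json", config)
        log.info("stage %s done in %.1fs (AUC %.3f)", stage,
                 time.time() - t0, report["auc"])
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc


def save_model(model, outdir: Path) -> None:
    import pickle

    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "model.pkl", "wb") as fh:
        pickle.dump(model, fh, protocol=4)
    summary = {
        "families": model.families,
        "algorithms": {f: m.algorithm for f, m in model.base_models.items()},
        "cv_auc": {f: m.cv_auc for f, m in model.base_models.items()},
        "n_selected_features": {
            f: len(m.feature_names) for f, m in model.base_models.items()
        },
        "cutoff": model.cutoff,
        "min_specificity": model.min_specificity,
        "seed": model.seed,
        "meta": model.meta,
    }
    with open(outdir / "model.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)


def load_model(path: Path):
    import pickle

    path = Path(path)
    if path.is_dir():
        path = path / "model.pkl"
    with open(path, "rb") as fh:
        return pickle.load(fh)
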