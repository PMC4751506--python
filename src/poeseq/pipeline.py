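"""End-to-end orchestration: simulate/read -> normalize -> DE -> parental
classification -> strain comparison -> imprinting screen -> phenotype stats.

Every run writes its stage outputs as TSV plus a JSON manifest echoing the
configuration, input checksums, per-stage row counts and filter exclusion
tallies.  Runs are deterministic given the seed; by default no wall-clock
timestamp is recorded so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import io as pio
from .datatypes import DEThresholds, ScreenThresholds, ValidationError
from .de import call_de, diet_contrasts
from .normalize import normalize, replicate_correlation
from .parental import classify_parental, marker_report, strain_comparison
from .phenotype import (
    direction_chisq,
    expressed_imprinted,
    hfd_shift,
    weight_correlation,
)
from .screen import annotate_known, filter_snps, screen_mild, screen_strict
from .simulate import StudyDesign, TruthConfig, simulate_study

__version__ = "0.1.0"


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and cause."""


@dataclass
class SimulateConfig:
    n_genes: int = 2000
    replicates_per_cell: int = 3
    snps_per_gene: int = 5
    depth: float = 50.0
    overdispersion_rho: float = 0.02


@dataclass
class PipelineConfig:
    """Everything a run needs; see ``PipelineConfig.from_yaml``."""

    seed: int = 0
    simulate: SimulateConfig | None = field(default_factory=SimulateConfig)
    counts_path: str | None = None
    meta_path: str | None = None
    allelic_path: str | None = None
    annotation_path: str | None = None
    de_thresholds: DEThresholds = field(default_factory=DEThresholds)
    strain_fold_min: float = 5.0
    screen_thresholds: ScreenThresholds = field(default_factory=ScreenThresholds)
    test_variant: str = "moderated"
    fold_basis: str = "linear"
    bh_correct: bool = False
    min_mean_count: float = 5.0
    markers: tuple[str, ...] = ()
    record_timestamp: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        if "seed" in raw:
            cfg.seed = int(raw["seed"])
        if raw.get("simulate") is not None:
            cfg.simulate = SimulateConfig(**raw["simulate"])
        elif "inputs" in raw:
            cfg.simulate = None
        inputs = raw.get("inputs", {})
        cfg.counts_path = inputs.get("counts")
        cfg.meta_path = inputs.get("meta")
        cfg.allelic_path = inputs.get("allelic")
        cfg.annotation_path = inputs.get("annotation")
        if "de" in raw:
            cfg.de_thresholds = DEThresholds(**raw["de"])
        cfg.strain_fold_min = float(raw.get("strain_fold_min", cfg.strain_fold_min))
        if "screen" in raw:
            cfg.screen_thresholds = ScreenThresholds(**raw["screen"])
        flags = raw.get("flags", {})
        cfg.test_variant = flags.get("test_variant", cfg.test_variant)
        cfg.fold_basis = flags.get("fold_basis", cfg.fold_basis)
        cfg.bh_correct = bool(flags.get("bh_correct", cfg.bh_correct))
        cfg.min_mean_count = float(flags.get("min_mean_count", cfg.min_mean_count))
        cfg.markers = tuple(raw.get("markers", ()))
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stage(manifest: dict, name: str):
    class _Ctx:
        def __enter__(self):
            manifest["stages"][name] = {"status": "running"}
            return manifest["stages"][name]

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                manifest["stages"][name]["status"] = "failed"
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            manifest["stages"][name]["status"] = "ok"

    return _Ctx()


def run_pipeline(config: PipelineConfig, outdir, seed: int | None = None) -> dict:
    """Execute every stage and write all outputs plus ``manifest.json``."""
    out = pio.ensure_dir(outdir)
    seed = config.seed if seed is None else seed
    manifest: dict = {
        "tool": "poeseq",
        "version": __version__,
        "seed": seed,
        "config": _config_echo(config),
        "inputs": {},
        "stages": {},
        "timestamp": datetime.now(timezone.utc).isoformat()
        if config.record_timestamp
        else None,
    }

    with _stage(manifest, "load") as st:
        if config.simulate is not None:
            sim = config.simulate
            design = StudyDesign(
                replicates_per_cell=sim.replicates_per_cell, n_genes=sim.n_genes
            )
            study = simulate_study(
                design,
                seed=seed,
                snps_per_gene=sim.snps_per_gene,
                depth=sim.depth,
                overdispersion_rho=sim.overdispersion_rho,
            )
            counts, meta, allelic = study.counts, study.meta, study.allelic
            annotation = _truth_annotation(study.truth)
            pio.write_count_matrix(counts, out / "counts.tsv")
            pio.write_sample_meta(meta, out / "sample_meta.tsv")
            pio.write_allelic_table(allelic, out / "allelic_counts.tsv")
            pio.write_truth(study.truth, out / "truth.tsv")
            pio.write_annotation(annotation, out / "imprint_annotation.tsv")
            for f in ("counts.tsv", "sample_meta.tsv", "allelic_counts.tsv"):
                manifest["inputs"][f] = _sha256(out / f)
        else:
            if not (config.counts_path and config.meta_path):
                raise ValidationError("counts and meta inputs are required")
            counts = pio.read_count_matrix(config.counts_path)
            meta = pio.read_sample_meta(config.meta_path)
            allelic = (
                pio.read_allelic_table(config.allelic_path, meta)
                if config.allelic_path
                else None
            )
            annotation = (
                pio.read_annotation(config.annotation_path)
                if config.annotation_path
                else None
            )
            for key in ("counts_path", "meta_path", "allelic_path", "annotation_path"):
                p = getattr(config, key)
                if p:
                    manifest["inputs"][key] = _sha256(Path(p))
        st["n_genes"] = int(counts.shape[0])
        st["n_samples"] = int(counts.shape[1])

    with _stage(manifest, "normalize") as st:
        norm = normalize(counts)
        norm.values.rename_axis("gene_id").to_csv(out / "normalized_log2.tsv", sep="\t")
        pd.DataFrame(
            {"tmm_factor": norm.factors, "library_size": norm.library_sizes}
        ).rename_axis("sample_id").to_csv(out / "normalization_report.tsv", sep="\t")
        rep = replicate_correlation(norm, meta)
        rep.to_csv(out / "replicate_correlation.tsv", sep="\t", index=False)
        st["n_groups"] = int(rep["group"].nunique())

    with _stage(manifest, "de") as st:
        contrasts = diet_contrasts(
            norm, meta, thresholds=config.de_thresholds, test=config.test_variant
        )
        st["contrasts"] = {}
        for geno, res in contrasts.items():
            pio.write_de_table(res, out / f"de_{geno}_HFD-vs-Con.tsv")
            st["contrasts"][geno] = {
                "up": int(len(res.up)),
                "down": int(len(res.down)),
            }

    with _stage(manifest, "parental") as st:
        categories = classify_parental(contrasts)
        categories.rename_axis("gene_id").to_csv(out / "parental_categories.tsv", sep="\t")
        st["category_counts"] = categories.value_counts().to_dict()

    with _stage(manifest, "strain_compare") as st:
        thr5 = DEThresholds(
            p_max=config.de_thresholds.p_max, fold_min=config.strain_fold_min
        )
        de_con = call_de(
            norm, meta,
            {"genotype": "PWK", "diet": "Con"}, {"genotype": "B6", "diet": "Con"},
            thresholds=thr5, label="PWK-Con-vs-B6-Con", test=config.test_variant,
        )
        de_hfd = call_de(
            norm, meta,
            {"genotype": "PWK", "diet": "HFD"}, {"genotype": "B6", "diet": "Con"},
            thresholds=thr5, label="PWK-HFD-vs-B6-Con", test=config.test_variant,
        )
        venn = strain_comparison(de_con, de_hfd)
        membership = pd.DataFrame(
            {name: counts.index.isin(idx) for name, idx in venn.items()},
            index=counts.index,
        )
        membership.rename_axis("gene_id").to_csv(out / "strain_comparison.tsv", sep="\t")
        st["set_sizes"] = {k: int(len(v)) for k, v in venn.items()}
        if config.markers:
            rep = marker_report(norm, meta, config.markers, test=config.test_variant)
            rep.to_csv(out / "marker_report.tsv", sep="\t")

    with _stage(manifest, "imprint_screen") as st:
        if allelic is None:
            st["skipped"] = "no allelic table provided"
        else:
            filtered, excl = filter_snps(allelic, config.screen_thresholds)
            st["snps_input"] = int(len(allelic.snps))
            st["snps_retained"] = int(len(filtered.snps))
            st["excluded"] = excl
            assert st["snps_input"] == st["snps_retained"] + sum(excl.values())
            for mode, fn in (("strict", screen_strict), ("mild", screen_mild)):
                res = fn(filtered, config.screen_thresholds)
                cand = res.candidates
                if annotation is not None and len(cand):
                    cand, summary = annotate_known(
                        cand, annotation.to_frame("status")
                    )
                    st[f"{mode}_known_summary"] = summary
                cand.to_csv(out / f"screen_{mode}_candidates.tsv", sep="\t", index=False)
                st[f"{mode}_candidates"] = int(len(cand))

    with _stage(manifest, "imprint_stats") as st:
        if annotation is None:
            st["skipped"] = "no imprint annotation provided"
        elif "body_weight_g" not in meta.columns or meta["body_weight_g"].isna().any():
            raise ValidationError(
                "imprint-stats requires body_weight_g for every sample"
            )
        else:
            status, missing = expressed_imprinted(
                counts, annotation, config.min_mean_count
            )
            st["n_expressed_imprinted"] = int(len(status))
            st["n_annotation_missing"] = len(missing)
            corr, summary = weight_correlation(
                norm, meta["body_weight_g"], status
            )
            corr.to_csv(out / "weight_correlation.tsv", sep="\t")
            summary.to_csv(out / "weight_correlation_summary.tsv", sep="\t", index=False)
            shifts = hfd_shift(norm, meta, "B6", status)
            shifts.to_csv(out / "hfd_shift_B6.tsv", sep="\t")
            tests = {}
            for s in ("PEG", "MEG"):
                try:
                    tests[s] = direction_chisq(shifts, s)
                except ValidationError as err:
                    tests[s] = {"status": s, "error": str(err)}
            st["direction_tests"] = tests
            st["note"] = (
                "direction test is a 1-df goodness-of-fit on the down/up split "
                "of significantly shifted genes (50:50 null)"
            )

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _truth_annotation(truth: pd.DataFrame) -> pd.Series:
    """PEG/MEG annotation implied by the simulation ground truth."""
    state = truth["imprint_state"]
    status = pd.Series("none", index=truth.index)
    status[state.str.startswith("PEG")] = "PEG"
    status[state.str.startswith("MEG")] = "MEG"
    return status[status != "none"].rename("status")


def _config_echo(config: PipelineConfig) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj

    return {
        f.name: enc(getattr(config, f.name)) for f in dataclasses.fields(config)
    }
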