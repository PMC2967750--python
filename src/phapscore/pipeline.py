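"""End-to-end orchestration: filter genes -> prune -> map -> score ->
associate -> extreme-dose screen -> classify, from one config, with a run
manifest recording every parameter and per-stage counts."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from .association import (
    run_gene_association,
    run_snp_association,
    write_association,
)
from .classification import (
    empirical_significance,
    evaluate_gene_classifier,
    write_roc,
)
from .extreme_dose import dichotomize, discover_features, write_ttest_table
from .gene_mapping import assign_snps, write_map
from .genotype_io import (
    read_dosage_table,
    read_gene_intervals,
    read_gene_list,
    read_overrides,
    read_phenotypes,
    read_vcf,
)
from .ld_prune import prune
from .phap_scoring import (
    estimate_frequencies,
    score_matrix,
    write_frequencies,
    write_scores,
)

logger = logging.getLogger(__name__)

STAGES = (
    "load", "prune", "map", "score", "associate", "extremes", "classify",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and partial outputs."""


@dataclass
class RunConfig:
    genotypes: str = ""
    genotype_format: str = "vcf"  # or "dosage"
    variant_metadata: str | None = None
    bed: str = ""
    phenotypes: str = ""
    gene_list: str = ""
    overrides: str | None = None
    out_dir: str = "phapscore_run"
    freq_mode: str = "genotype"
    max_r2: float = 0.2
    window_bp: int = 5000
    alpha: float = 0.05
    low_threshold: float = 3.0
    high_threshold: float = 7.0
    folds: int = 10
    null_reps: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def validate(self) -> None:
        problems = []
        for name in ("genotypes", "bed", "phenotypes", "gene_list"):
            value = getattr(self, name)
            if not value:
                problems.append(f"{name} is required")
            elif not Path(value).exists():
                problems.append(f"{name} path does not exist: {value}")
        if self.overrides and not Path(self.overrides).exists():
            problems.append(f"overrides path does not exist: {self.overrides}")
        if self.genotype_format not in ("vcf", "dosage"):
            problems.append(f"genotype_format must be vcf|dosage, got {self.genotype_format}")
        if self.freq_mode not in ("genotype", "allele"):
            problems.append(f"freq_mode must be genotype|allele, got {self.freq_mode}")
        if not 0.0 <= self.max_r2 <= 1.0:
            problems.append(f"max_r2 must be in [0, 1], got {self.max_r2}")
        if self.window_bp < 0:
            problems.append(f"window_bp must be >= 0, got {self.window_bp}")
        if not 0.0 < self.alpha < 1.0:
            problems.append(f"alpha must be in (0, 1), got {self.alpha}")
        if self.low_threshold <= 0 or self.high_threshold <= 0:
            problems.append("dose thresholds must be > 0")
        if self.folds < 2:
            problems.append(f"folds must be >= 2, got {self.folds}")
        if self.null_reps < 1:
            problems.append(f"null_reps must be >= 1, got {self.null_reps}")
        if problems:
            raise ValueError("invalid run config: " + "; ".join(problems))


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages; returns the run directory.

    Every stage output is persisted; any stage error aborts with the stage
    name and a pointer to the partial outputs already written.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("phapscore")
    root.addHandler(handler)
    root.setLevel(logging.INFO)

    manifest: dict[str, Any] = {
        "version": __version__,
        "parameters": dataclasses.asdict(config),
        "stages": {},
    }
    stage = "load"
    try:
        # ---- load ----------------------------------------------------
        genes = read_gene_intervals(config.bed)
        candidates = read_gene_list(config.gene_list, [g.symbol for g in genes])
        candidate_genes = [g for g in genes if g.symbol in set(candidates)]
        if config.genotype_format == "vcf":
            matrix = read_vcf(config.genotypes)
        else:
            matrix = read_dosage_table(config.genotypes, config.variant_metadata)
        phenotypes = read_phenotypes(
            config.phenotypes, known_samples=matrix.sample_ids, allow_extra=True
        )
        overrides = (
            read_overrides(config.overrides, [g.symbol for g in genes])
            if config.overrides
            else []
        )
        manifest["stages"]["load"] = {
            "n_samples": matrix.n_samples,
            "n_variants": matrix.n_variants,
            "n_annotation_genes": len(genes),
            "n_candidate_genes": len(candidate_genes),
            "n_phenotyped": len(phenotypes.doses),
        }

        # ---- prune ---------------------------------------------------
        stage = "prune"
        prune_result = prune(matrix, max_r2=config.max_r2)
        with open(out / "kept_variants.tsv", "w") as fh:
            fh.write("variant_id\n")
            for vid in prune_result.kept_variant_ids:
                fh.write(vid + "\n")
        with open(out / "dropped_variants.tsv", "w") as fh:
            fh.write("dropped_id\tblocking_kept_id\tr2\n")
            for did, bid, r2 in prune_result.dropped:
                fh.write(f"{did}\t{bid}\t{r2:.10g}\n")
        pruned = matrix.subset_variants(prune_result.kept_variant_ids)
        manifest["stages"]["prune"] = {
            "max_r2": config.max_r2,
            "snps_in": matrix.n_variants,
            "snps_kept": pruned.n_variants,
        }

        # ---- map -----------------------------------------------------
        stage = "map"
        snp_map = assign_snps(
            pruned.variants, candidate_genes,
            window_bp=config.window_bp, overrides=overrides,
        )
        write_map(snp_map, out / "snp_gene_map.tsv")
        manifest["stages"]["map"] = {
            "window_bp": config.window_bp,
            "genes_mapped": len(snp_map.gene_symbols),
            "snps_mapped": len(snp_map.variant_ids),
            "n_overrides": len(overrides),
        }

        # ---- score ---------------------------------------------------
        stage = "score"
        freqs = estimate_frequencies(pruned)
        write_frequencies(freqs, out / "frequencies.tsv")
        gsm = score_matrix(pruned, snp_map, freqs, mode=config.freq_mode)
        write_scores(gsm, out / "gene_scores.tsv")
        manifest["stages"]["score"] = {
            "freq_mode": config.freq_mode,
            "n_gene_scores_per_patient": len(gsm.gene_symbols),
        }

        # ---- associate -----------------------------------------------
        stage = "associate"
        snp_table = run_snp_association(
            pruned, phenotypes, snp_map.variant_ids, alpha=config.alpha
        )
        write_association(snp_table, out / "snp_association.tsv")
        gene_table = run_gene_association(gsm, phenotypes, alpha=config.alpha)
        write_association(gene_table, out / "gene_association.tsv")
        manifest["stages"]["associate"] = {
            "snp_m": snp_table.attrs["m"],
            "snp_threshold": snp_table.attrs["threshold"],
            "gene_m": gene_table.attrs["m"],
            "gene_threshold": gene_table.attrs["threshold"],
            "snp_significant": int(snp_table["significant_after_correction"].sum()),
            "gene_significant": int(gene_table["significant_after_correction"].sum()),
        }

        # ---- extremes ------------------------------------------------
        stage = "extremes"
        feature_sets: dict[str, dict[str, list[str]]] = {}
        labels_by_dir = {}
        for direction, threshold in (
            ("low", config.low_threshold), ("high", config.high_threshold)
        ):
            labels = dichotomize(phenotypes, threshold, direction)
            labels_by_dir[direction] = labels
            strict, nominal, table = discover_features(gsm, labels, alpha=config.alpha)
            write_ttest_table(table, out / f"ttest_{direction}.tsv")
            feature_sets[direction] = {"strict": strict, "nominal": nominal}
            manifest["stages"].setdefault("extremes", {})[direction] = {
                "threshold": threshold,
                "n_positive": labels.n_positive,
                "n_negative": labels.n_negative,
                "m": table.attrs["m"],
                "n_strict": len(strict),
                "n_nominal": len(nominal),
            }

        # ---- classify ------------------------------------------------
        stage = "classify"
        summary_rows = []
        for direction in ("low", "high"):
            labels = labels_by_dir[direction]
            y = labels.vector_for(gsm.sample_ids) if all(
                s in labels.labels for s in gsm.sample_ids
            ) else None
            if y is None:
                samples = [s for s in gsm.sample_ids if s in labels.labels]
                raise PipelineError(
                    f"classify: {len(gsm.sample_ids) - len(samples)} scored "
                    "samples lack phenotypes"
                )
            for which in ("strict", "nominal"):
                genes_used = feature_sets[direction][which]
                if not genes_used:
                    logger.warning(
                        "%s/%s classifier skipped: empty feature set", direction, which
                    )
                    summary_rows.append(
                        dict(direction=direction, feature_set=which,
                             n_features=0, auroc=float("nan"),
                             empirical_p=float("nan"), status="skipped")
                    )
                    continue
                ev = evaluate_gene_classifier(
                    gsm, genes_used, y, k=config.folds, seed=config.seed
                )
                ev.empirical_p = empirical_significance(
                    ev.auroc, gsm, gsm.gene_symbols, len(genes_used), y,
                    B=config.null_reps, seed=config.seed, k=config.folds,
                )
                write_roc(ev.roc_points, out / f"roc_{direction}_{which}.tsv")
                summary_rows.append(
                    dict(direction=direction, feature_set=which,
                         n_features=len(genes_used), auroc=ev.auroc,
                         empirical_p=ev.empirical_p, status="ok")
                )
        with open(out / "classification_summary.tsv", "w") as fh:
            fh.write("direction\tfeature_set\tn_features\tauroc\tempirical_p\tstatus\n")
            for r in summary_rows:
                fh.write(
                    f"{r['direction']}\t{r['feature_set']}\t{r['n_features']}\t"
                    f"{r['auroc']:.10g}\t{r['empirical_p']:.10g}\t{r['status']}\n"
                )
        manifest["stages"]["classify"] = {
            "folds": config.folds,
            "null_reps": config.null_reps,
            "seed": config.seed,
            "results": summary_rows,
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(
            f"stage '{stage}' failed: {exc}; partial outputs in {out}"
        ) from exc
    finally:
        root.removeHandler(handler)
        handler.close()

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete; outputs in %s", out)
    return out
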