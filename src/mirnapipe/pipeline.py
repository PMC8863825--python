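"""End-to-end orchestration: simulate → quantify → filter/normalize →
differential expression → correlation → PCA, with per-stage artifacts, a
hash manifest and a consolidated JSON summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexp, normalize, pca, pheno, quantify
from .reference import PrecursorSet
from .simulate import SimDesign, generate_reference, simulate_counts, write_fastq

__all__ = ["PipelineConfig", "ConfigError", "run_pipeline", "detection_summary"]

log = logging.getLogger("mirnapipe")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 1 at the CLI)."""


@dataclass
class PipelineConfig:
    out_dir: str = "mirnapipe_out"
    # real-data inputs (ignored in simulation mode)
    fastq_dir: str | None = None
    fasta: str | None = None
    gff: str | None = None
    sample_table: str | None = None
    # analysis parameters
    adapter: str = SimDesign.adapter
    max_mismatches: int = 1
    min_read_len: int = 15
    min_norm_count: float = 10.0
    min_sample_frac: float = 0.7
    filter_scope: str = "all"
    fdr_threshold: float = 0.05
    logcpm_prior: float = 2.0
    run_correlation: bool = True
    run_pca: bool = True
    seed: int = 1
    # optional simulation block: presence switches to simulation mode
    simulation: dict | None = field(default=None)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ConfigError("fdr_threshold must lie in (0, 1)")
        if self.simulation is None:
            for name in ("fastq_dir", "fasta", "gff", "sample_table"):
                value = getattr(self, name)
                if value is None:
                    raise ConfigError(f"missing required path: {name}")
                if not Path(value).exists():
                    raise ConfigError(f"{name} does not exist: {value}")

    def design(self) -> SimDesign:
        block = dict(self.simulation or {})
        block.setdefault("seed", self.seed)
        block.setdefault("adapter", self.adapter)
        for key in ("group_sizes", "lib_size_range", "baseline_logmean_range"):
            if key in block and isinstance(block[key], (list, tuple)):
                # pyyaml reads "3.0e4" (no signed exponent) as a string
                cast = int if key == "group_sizes" else float
                block[key] = tuple(cast(v) for v in block[key])
        try:
            return SimDesign(**block)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid simulation block: {exc}") from exc


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> Path:
    df.to_csv(path, sep="\t", **kwargs)
    return path


def detection_summary(counts: pd.DataFrame) -> dict:
    """Detection and median-expression histograms over annotated miRNAs.

    ``detected_in_n_samples``: for each annotated mature miRNA the number
    of samples with a nonzero count, binned over 0..n_samples.
    ``median_cpm_log10_hist``: histogram of log10 median CPM per miRNA,
    zero-median miRNAs excluded.
    """
    n_samples = counts.shape[1]
    detected = (counts > 0).sum(axis=1)
    bins = np.bincount(detected.to_numpy(), minlength=n_samples + 1)
    cpm = counts / counts.sum(axis=0) * 1e6
    med = cpm.median(axis=1)
    med = med[med > 0]
    edges = np.arange(-2.0, 6.5, 0.5)
    hist, _ = np.histogram(np.log10(med), bins=edges)
    return {
        "n_mirna": int(counts.shape[0]),
        "n_samples": int(n_samples),
        "detected_in_n_samples": bins.tolist(),
        "median_cpm_log10_edges": edges.tolist(),
        "median_cpm_log10_hist": hist.tolist(),
    }


def run_pipeline(config: PipelineConfig, make_figures: bool = True) -> dict:
    """Execute the full workflow; returns the consolidated summary dict.

    Simulation mode (a ``simulation`` block present) generates reference,
    reads, phenotypes and ground truth in ``out_dir/sim`` and then runs the
    same downstream path a real dataset would take.  Identical config and
    seed produce identical artifact hashes.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []
    summary: dict = {"mode": "simulation" if config.simulation is not None else "real"}

    def record(stage: str, params: dict, paths: list[Path]) -> None:
        manifest.append(
            {
                "stage": stage,
                "parameters": params,
                "outputs": {p.name: _sha256(p) for p in sorted(paths)},
            }
        )

    # -- stage: inputs ---------------------------------------------------
    if config.simulation is not None:
        design = config.design()
        sim_dir = out / "sim"
        sim_dir.mkdir(exist_ok=True)
        reference = generate_reference(design)
        fasta = sim_dir / "precursors.fa"
        gff = sim_dir / "precursors.gff3"
        reference.to_fasta(fasta)
        reference.to_gff3(gff)
        truth, pheno_df = simulate_counts(design, reference)
        fastq_paths = write_fastq(truth, reference, design, sim_dir / "fastq")
        groups = design.sample_groups()
        samples_path = _write_tsv(groups.to_frame(), sim_dir / "samples.tsv")
        pheno_path = _write_tsv(pheno_df, sim_dir / "phenotypes.tsv")
        truth_path = sim_dir / "ground_truth.json"
        truth_path.write_text(
            json.dumps(
                {
                    "true_counts": truth.true_counts.to_dict(orient="split"),
                    "true_logfc": truth.true_logfc.to_dict(orient="split"),
                    "pheno_signs": truth.pheno_signs,
                    "lib_sizes": truth.lib_sizes.to_dict(),
                },
                default=str,
            )
        )
        record(
            "simulate",
            {k: str(v) for k, v in asdict(design).items()},
            [fasta, gff, samples_path, pheno_path, truth_path, *fastq_paths.values()],
        )
        adapter = design.adapter
    else:
        fasta, gff = Path(config.fasta), Path(config.gff)
        reference = PrecursorSet.from_files(fasta, gff)
        table = pd.read_csv(config.sample_table, sep="\t", index_col=0)
        if "group" not in table.columns:
            raise ConfigError("sample table needs a 'group' column")
        groups = table["group"]
        pheno_df = table
        fastq_dir = Path(config.fastq_dir)
        fastq_paths = {}
        for sample in groups.index:
            path = fastq_dir / f"{sample}.fastq.gz"
            if not path.exists():
                path = fastq_dir / f"{sample}.fastq"
            if not path.exists():
                raise ConfigError(f"no FASTQ found for sample {sample!r}")
            fastq_paths[sample] = path
        adapter = config.adapter

    # -- stage: quantify -------------------------------------------------
    log.info("quantifying %d samples", len(fastq_paths))
    counts, qcs = quantify.quantify_samples(
        fastq_paths,
        reference,
        adapter,
        max_mismatches=config.max_mismatches,
        min_len=config.min_read_len,
    )
    counts_path = _write_tsv(counts, out / "counts.tsv")
    qc_path = out / "quantify_qc.json"
    quantify.write_qc(qcs, qc_path)
    det = detection_summary(counts)
    det_path = out / "detection_summary.json"
    det_path.write_text(json.dumps(det, indent=2) + "\n")
    record(
        "quantify",
        {"adapter": adapter, "max_mismatches": config.max_mismatches},
        [counts_path, qc_path, det_path],
    )
    summary["samples"] = len(fastq_paths)
    summary["annotated_matures"] = int(counts.shape[0])
    summary["reads_mapped"] = {q["sample"]: q["reads_mapped"] for q in qcs}

    # -- stage: filter + normalize --------------------------------------
    spec = normalize.FilterSpec(
        min_norm_count=config.min_norm_count,
        min_sample_frac=config.min_sample_frac,
        scope=config.filter_scope,
    )
    retained = normalize.filter_expressed(counts, groups, spec)
    filtered = counts.loc[retained]
    factors = normalize.tmm_factors(filtered)
    logcpm = normalize.log_cpm(filtered, factors, prior=config.logcpm_prior)
    filt_path = _write_tsv(filtered, out / "filtered_counts.tsv")
    logcpm_path = _write_tsv(logcpm, out / "logcpm.tsv")
    factors_path = out / "norm_factors.json"
    factors_path.write_text(
        json.dumps(
            {
                "tmm_factors": factors.factors.round(10).to_dict(),
                "lib_sizes": factors.lib_sizes.to_dict(),
                "retained": len(retained),
                "removed": int(counts.shape[0] - len(retained)),
            },
            indent=2,
        )
    )
    record(
        "normalize",
        {"min_norm_count": spec.min_norm_count, "min_sample_frac": spec.min_sample_frac,
         "scope": spec.scope},
        [filt_path, logcpm_path, factors_path],
    )
    summary["filtered_mirnas"] = len(retained)

    # -- stage: differential expression ---------------------------------
    dispersion = diffexp.estimate_common_dispersion(filtered, groups, factors)
    results, union = diffexp.run_all_comparisons(
        filtered, groups, factors, dispersion, config.fdr_threshold
    )
    de_paths = []
    for label, res in results.items():
        de_paths.append(_write_tsv(res, out / f"de_{label}.tsv"))
    union_path = out / "de_union.tsv"
    pd.Series(union, name="mirna").to_csv(union_path, sep="\t", index=False)
    de_paths.append(union_path)
    record(
        "diffexp",
        {"dispersion": dispersion.phi, "fdr_threshold": config.fdr_threshold},
        de_paths,
    )
    summary["dispersion"] = dispersion.phi
    summary["de_per_comparison"] = {
        label: int((res["FDR"] <= config.fdr_threshold).sum())
        for label, res in results.items()
    }
    summary["de_union_size"] = len(union)
    if not union:
        summary["note"] = "no discoveries at the FDR threshold"

    # -- stage: correlation ---------------------------------------------
    if config.run_correlation and union:
        corr = pheno.spearman_matrix(logcpm.loc[union], pheno_df)
        corr = pheno.block_order(corr)
        corr_path = _write_tsv(corr.ordered(), out / "spearman.tsv")
        paths = [corr_path]
        if make_figures:
            from . import plots

            paths.append(plots.correlation_heatmap(corr, out / "spearman_heatmap.png"))
        record("correlate", {"mirnas": len(union)}, paths)

    # -- stage: PCA ------------------------------------------------------
    if config.run_pca and union:
        matrix = pca.build_feature_matrix(logcpm.loc[union], pheno_df)
        result = pca.run_pca(matrix)
        sep = pca.group_separation(result.scores, groups)
        mirna_only = None
        if len(union) >= 2:
            mirna_only = pca.run_pca(
                pca.build_feature_matrix(logcpm.loc[union], pheno_df.iloc[:, :0])
            )
        paths = [
            _write_tsv(result.scores, out / "pca_scores.tsv"),
            _write_tsv(result.loadings, out / "pca_loadings.tsv"),
            _write_tsv(result.contributions, out / "pca_contributions.tsv"),
        ]
        pca_summary = {
            "variance_fractions": result.variance_fractions.round(12).tolist(),
            "variance_fractions_mirna_only": (
                mirna_only.variance_fractions.round(12).tolist()
                if mirna_only is not None
                else None
            ),
            "separation": sep,
            "top_contributors": list(
                pca.top_contributors(result, k=30).index
            ),
        }
        pca_path = out / "pca_summary.json"
        pca_path.write_text(json.dumps(pca_summary, indent=2) + "\n")
        paths.append(pca_path)
        if make_figures:
            from . import plots

            paths.append(
                plots.pca_biplot(result, groups, out / "pca_biplot.png")
            )
        record("pca", {"features": matrix.shape[1]}, paths)
        summary["pc_variance_fractions"] = pca_summary["variance_fractions"][:2]
        summary["pc1_threshold_accuracy"] = sep["threshold_accuracy"]

    summary["detection"] = det
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2) + "\n")
    return summary
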