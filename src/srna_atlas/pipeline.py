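"""End-to-end pipeline: coverage -> calls -> counts -> DE -> comparative.

The pipeline chains every stage of the package in the order a discovery
study runs them: build (or simulate) per-sample coverage, pool it, call
intergenic transcripts, count reads per call per sample, compute MEVs,
normalize with TMM, test every requested pairwise contrast with the NB
exact test, and derive the comparative layer (overlap matrix, z-scores,
clustering, PCA, pattern groups).  Every run writes its resolved
configuration and a manifest with stage-by-stage record counts next to
the outputs, and no stage mutates its inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import comparative, coverage, diffexpr, discovery, io, quantify, synthetic
from .errors import DataError, PipelineError

logger = logging.getLogger("srna_atlas")


def _require_known_keys(mapping: Mapping[str, Any], allowed: set[str], where: str) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        raise DataError(f"unknown config keys in {where}: {sorted(unknown)}")


@dataclass
class SyntheticConfig:
    genome_length: int = synthetic.DEFAULT_GENOME_LENGTH
    n_genes: int = synthetic.DEFAULT_N_GENES
    n_srna: int = synthetic.DEFAULT_N_SRNA
    n_utr: int = synthetic.DEFAULT_N_UTR
    conditions: list[str] = field(default_factory=lambda: list(synthetic.DEFAULT_CONDITIONS))
    replicates: int = synthetic.DEFAULT_REPLICATES
    dispersion: float = synthetic.DEFAULT_DISPERSION
    de_fraction: float = 0.3
    read_length: int = synthetic.DEFAULT_READ_LENGTH
    noise_depth: float = synthetic.DEFAULT_NOISE_DEPTH


@dataclass
class InputConfig:
    """Paths to real inputs (alternative to simulation)."""

    annotation: str = ""
    reads: str = ""
    samples: str = ""
    genome_length: int = 0


@dataclass
class DEConfig:
    alpha: float = diffexpr.DEFAULT_ALPHA
    logratio_trim: float = diffexpr.DEFAULT_LOGRATIO_TRIM
    abundance_trim: float = diffexpr.DEFAULT_ABUNDANCE_TRIM
    prior_replicates: float = diffexpr.DEFAULT_PRIOR_REPLICATES
    prior_count: float = diffexpr.DEFAULT_PRIOR_COUNT
    contrasts: list[list[str]] | None = None  # default: all condition pairs


@dataclass
class ComparativeConfig:
    pseudocount: float = 1.0
    min_conditions: int = 2
    mev_threshold: float = 1.0


@dataclass
class PipelineConfig:
    """Validated top-level configuration.

    Unknown keys anywhere in the document are rejected so typos fail
    loudly instead of silently falling back to defaults.
    """

    output_dir: str = "srna_atlas_out"
    seed: int = 0
    synthetic: SyntheticConfig | None = None
    inputs: InputConfig | None = None
    caller: discovery.CallerParams = field(default_factory=discovery.CallerParams)
    de: DEConfig = field(default_factory=DEConfig)
    comparative: ComparativeConfig = field(default_factory=ComparativeConfig)

    @classmethod
    def from_dict(cls, raw: Mapping[str, Any]) -> "PipelineConfig":
        _require_known_keys(
            raw, {"output_dir", "seed", "synthetic", "inputs", "caller", "de", "comparative"},
            "top level",
        )
        cfg = cls()
        cfg.output_dir = str(raw.get("output_dir", cfg.output_dir))
        cfg.seed = int(raw.get("seed", cfg.seed))
        for name, klass, target in (
            ("synthetic", SyntheticConfig, "synthetic"),
            ("inputs", InputConfig, "inputs"),
            ("de", DEConfig, "de"),
            ("comparative", ComparativeConfig, "comparative"),
        ):
            if name in raw and raw[name] is not None:
                section = raw[name]
                _require_known_keys(section, {f.name for f in dataclasses.fields(klass)}, name)
                setattr(cfg, target, klass(**section))
        if "caller" in raw and raw["caller"] is not None:
            section = raw["caller"]
            _require_known_keys(
                section, {f.name for f in dataclasses.fields(discovery.CallerParams)}, "caller"
            )
            cfg.caller = discovery.CallerParams(**section)
        if cfg.synthetic is None and cfg.inputs is None:
            cfg.synthetic = SyntheticConfig()
        if cfg.synthetic is not None and cfg.inputs is not None:
            raise DataError("config must specify either 'synthetic' or 'inputs', not both")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {
            "output_dir": self.output_dir,
            "seed": self.seed,
            "caller": dataclasses.asdict(self.caller),
            "de": dataclasses.asdict(self.de),
            "comparative": dataclasses.asdict(self.comparative),
        }
        if self.synthetic is not None:
            out["synthetic"] = dataclasses.asdict(self.synthetic)
        if self.inputs is not None:
            out["inputs"] = dataclasses.asdict(self.inputs)
        return out


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
                raise PipelineError(name, exc) from exc

        return run

    return wrap


def run_pipeline(config: PipelineConfig | Mapping[str, Any] | str | Path) -> Path:
    """Run every stage and write all artifacts under ``config.output_dir``.

    Returns the output directory.  Reproducible: rerunning with the same
    config and seed produces byte-identical tables.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_dict(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"stages": {}, "seed": config.seed}

    # --- stage: inputs (simulate or load)
    @_stage("inputs")
    def load_inputs():
        if config.synthetic is not None:
            sc = config.synthetic
            truth, counts, tracks, reads = synthetic.default_experiment(
                seed=config.seed,
                genome_length=sc.genome_length,
                n_genes=sc.n_genes,
                n_srna=sc.n_srna,
                n_utr=sc.n_utr,
                conditions=sc.conditions,
                replicates=sc.replicates,
                dispersion=sc.dispersion,
                de_fraction=sc.de_fraction,
                read_length=sc.read_length,
                noise_depth=sc.noise_depth,
            )
            genes = truth.gene_likes()
            samples = counts.samples
            io.write_gff3(io.annotation_to_records(truth.genes, truth.planted), out / "truth.gff3")
            io.write_bed(reads, out / "reads.bed")
            io.write_sample_sheet(samples, out / "samples.tsv")
            return genes, reads, samples, truth.genome_length, tracks
        ic = config.inputs
        assert ic is not None
        genes = io.records_to_genes(io.read_gff3(ic.annotation))
        reads = io.read_bed(ic.reads)
        samples = io.read_sample_sheet(ic.samples)
        length = ic.genome_length or int(reads["end"].max())
        tracks = {
            s: coverage.pileup(reads[reads["sample"] == s], length, sample_ids=[s])
            for s in samples.index
        }
        return genes, reads, samples, length, tracks

    genes, reads, samples, genome_length, tracks = load_inputs()
    manifest["stages"]["inputs"] = {"samples": len(samples), "reads": int(len(reads))}

    # --- stage: coverage
    @_stage("coverage")
    def build_coverage():
        pooled = coverage.pool(list(tracks.values()))
        io.write_bedgraph(pooled, out / "pooled")
        return pooled

    pooled = build_coverage()
    manifest["stages"]["coverage"] = {"total_depth": pooled.total()}

    # --- stage: discovery
    @_stage("discovery")
    def discover():
        result = discovery.call_transcripts(pooled, genes, config.caller)
        io.write_gff3(io.calls_to_records(result.calls), out / "calls.gff3")
        io.write_table(io.calls_to_frame(result.calls), out / "calls.tsv")
        return result

    called = discover()
    manifest["stages"]["discovery"] = called.funnel
    for stage, count in called.funnel.items():
        logger.info("discovery funnel: %s = %d", stage, count)

    # --- stage: quantify
    @_stage("quantify")
    def quantify_stage():
        cm = quantify.count_reads(reads, called.calls, samples)
        mevs = quantify.mev_table(cm)
        io.write_counts(cm, out / "counts.tsv")
        io.write_table(mevs, out / "mev.tsv")
        return cm, mevs

    cm, mevs = quantify_stage()
    manifest["stages"]["quantify"] = {
        "features": len(cm.features),
        "assigned_reads": int(cm.counts.to_numpy().sum()),
    }

    # --- stage: differential expression
    @_stage("diffexpr")
    def de_stage():
        if len(cm.features) < 2 or cm.counts.to_numpy().sum() == 0:
            return None, {}
        factors = diffexpr.tmm_factors(
            cm, logratio_trim=config.de.logratio_trim, abundance_trim=config.de.abundance_trim
        )
        io.write_table(factors.factors.to_frame("tmm_factor"), out / "factors.tsv", "sample")
        contrasts = config.de.contrasts or [
            [a, b] for a, b in combinations(cm.conditions, 2)
        ]
        results: dict[str, diffexpr.DEResult] = {}
        for a, b in contrasts:
            res = diffexpr.de_test(
                cm, (a, b), alpha=config.de.alpha, factors=factors,
                prior_replicates=config.de.prior_replicates,
                prior_count=config.de.prior_count,
            )
            name = f"{a}_vs_{b}"
            io.write_table(res.table, out / f"de_{name}.tsv")
            results[name] = res
        return factors, results

    factors, de_results = de_stage()
    manifest["stages"]["diffexpr"] = {
        name: int((res.table["qvalue"] < res.alpha).sum()) for name, res in de_results.items()
    }

    # --- stage: comparative
    @_stage("comparative")
    def comparative_stage():
        if not de_results:
            return
        de_sets = {name: res.directions() for name, res in de_results.items()}
        ov = comparative.overlap_matrix(de_sets)
        io.write_table(ov.counts, out / "overlap_counts.tsv", "condition")
        io.write_table(ov.relative, out / "overlap_relative.tsv", "condition")

        eff = factors.effective_sizes()
        norm = cm.counts / eff * factors.reference_effective_size()
        logexpr = np.log2(norm + config.comparative.pseudocount)
        z, dropped = comparative.zscore_matrix(logexpr)
        io.write_table(z, out / "zscores.tsv")
        if z.shape[0] >= 2 and z.shape[1] >= 2:
            clust = comparative.pearson_cluster(z, axis="columns")
            (out / "samples.nwk").write_text(clust.newick() + "\n")
        averaged = logexpr.T.groupby(cm.samples["condition"]).mean().T
        if averaged.shape[1] >= 2:
            p = comparative.pca(averaged)
            io.write_table(p.scores, out / "pca_scores.tsv", "condition")
            io.write_table(
                p.variance_fraction.to_frame("variance_fraction"), out / "pca_variance.tsv",
                "component",
            )
        max_mev = mevs.drop(columns="cumulative").max(axis=1)
        patterns = comparative.pattern_groups(
            de_sets, max_mev,
            min_conditions=config.comparative.min_conditions,
            mev_threshold=config.comparative.mev_threshold,
        )
        io.write_table(patterns, out / "patterns.tsv")

    comparative_stage()
    manifest["stages"]["comparative"] = {"contrasts": len(de_results)}

    resolved = yaml.safe_dump(config.to_dict(), sort_keys=True)
    (out / "config.resolved.yaml").write_text(resolved)
    manifest["config_sha256"] = hashlib.sha256(resolved.encode()).hexdigest()
    try:
        from importlib.metadata import version

        manifest["versions"] = {
            "srna-atlas": version("srna-atlas"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        }
    except Exception:  # pragma: no cover - metadata missing in odd installs
        pass
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
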