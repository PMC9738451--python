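"""End-to-end orchestration: filter -> DE -> binarize -> curate -> enrich -> ORA.

Every stage writes its artifact into the run directory and the run
closes with a manifest recording parameters, the seed, and SHA-256
checksums of every input and output, so a rerun with the same config
and inputs is verifiably identical.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from regenatlas import io as raio
from regenatlas.de import FilterConfig, filter_genes, run_all_pairwise
from regenatlas.enrichment import curate_geneset, enrichment_curve, ora_test
from regenatlas.patterns import binarize_all

logger = logging.getLogger(__name__)

__version__ = "0.1.0"


@dataclass
class PipelineConfig:
    """Everything needed to reproduce one pipeline run."""

    counts_path: str
    design_path: str
    gmt_path: str | None = None
    mapping_path: str | None = None
    filter: FilterConfig = field(default_factory=FilterConfig)
    fdr_threshold: float = 0.05
    comparison_mode: str = "pairs"
    scoring_mode: str = "labelwise"
    tie_break: str = "min_ones_lex"
    ci_level: str = "sd1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fdr_threshold < 1:
            raise ValueError("fdr_threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "filter" in raw and isinstance(raw["filter"], dict):
            raw["filter"] = FilterConfig(**raw["filter"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["filter"] = {"min_count": self.filter.min_count,
                       "min_samples": self.filter.min_samples}
        return d


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> Path:
    """Execute all stages and return the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: dict[str, dict] = {}

    def record(stage: str, paths: list[Path]) -> None:
        stages[stage] = {p.name: _sha256(p) for p in paths}

    counts = raio.read_counts(config.counts_path, config.design_path)
    design = counts.timepoint_design()

    # 1. filter
    try:
        filtered = filter_genes(counts, config.filter)
        if len(filtered.counts) == 0:
            raise ValueError("no genes survive filtering")
        path = out / "filtered_counts.tsv"
        raio.write_counts(filtered, path)
        record("filter", [path])
        logger.info("filter: %d -> %d genes", len(counts.counts), len(filtered.counts))

        # 2. pairwise DE over all comparisons
        de_results = run_all_pairwise(
            filtered, mode=config.comparison_mode, fdr_threshold=config.fdr_threshold
        )
        de_dir = out / "de"
        de_dir.mkdir(exist_ok=True)
        de_paths = []
        for res in de_results:
            p = de_dir / f"{res.comparison.name}.tsv"
            raio.write_de_table(res, p)
            de_paths.append(p)
        record("de", de_paths)

        # 3. binarize
        matrix = binarize_all(
            de_results,
            design,
            mode=config.scoring_mode,
            fdr_threshold=config.fdr_threshold,
            tie_break=config.tie_break,
        )
        bm_path = out / "binary_matrix.tsv"
        prov_path = out / "binary_matrix.provenance.json"
        raio.write_binary_matrix(matrix, bm_path, prov_path)
        record("binarize", [bm_path, prov_path])

        # 4-6. gene-set stages (optional: need a GMT)
        curves_path = out / "enrichment_curves.tsv"
        ora_path = out / "ora.tsv"
        if config.gmt_path is not None:
            raw_sets = raio.read_gmt(config.gmt_path)
            if config.mapping_path is not None:
                homology = raio.read_mapping(config.mapping_path)
                curated = [
                    curate_geneset(
                        sorted(gs.members), homology, name=gs.name,
                        description=gs.description,
                    )
                    for gs in raw_sets
                ]
            else:
                curated = raw_sets  # sets already keyed by species gene ids
            nonempty = [gs for gs in curated if gs.members & matrix.universe]
            skipped = len(curated) - len(nonempty)
            if skipped:
                logger.warning(
                    "enrich: %d sets empty after curation/intersection", skipped
                )
            curated_path = out / "curated_sets.gmt"
            raio.write_gmt(nonempty, curated_path)
            record("curate", [curated_path])

            curves = [
                enrichment_curve(matrix, gs, level=config.ci_level) for gs in nonempty
            ]
            raio.write_curves(curves, curves_path)
            record("enrich", [curves_path])

            dynamic = set(
                matrix.values.index[(matrix.values == 1).any(axis=1)]
            )
            ora = ora_test(
                dynamic, matrix.universe, nonempty,
                fdr_threshold=config.fdr_threshold,
            )
            raio.write_ora(ora, ora_path)
            record("ora", [ora_path])
        else:
            raio.write_curves([], curves_path)
            record("enrich", [curves_path])
            logger.info("no gene sets supplied; enrichment reports zero sets")
    except Exception as exc:
        done = ", ".join(stages) or "none"
        raise RuntimeError(
            f"pipeline aborted after stages [{done}]: {exc}"
        ) from exc

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "inputs": {
            Path(p).name: _sha256(Path(p))
            for p in [
                config.counts_path,
                config.design_path,
                config.gmt_path,
                config.mapping_path,
            ]
            if p is not None
        },
        "stages": stages,
    }
    raio.write_manifest(manifest, out / "manifest.json")
    return out
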