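"""End-to-end pipeline: cohort in, feature table / reduction / comparison out.

`run_pipeline` is the library entry point the CLI wraps. All artifacts are
plain text (CSV, JSON, Markdown) and byte-identical across reruns with the
same config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cohort import (
    DEFAULT_ALPHA,
    DEFAULT_THRESHOLD,
    ComparisonReport,
    ReductionReport,
    build_feature_table,
    compare_groups,
    reduce_redundancy,
)
from .glcm import DEFAULT_DISTANCES, DEFAULT_N_LEVELS
from .haralick import DEFAULT_LOG_BASE
from .io import VolumeWithMask, read_volume_with_mask
from .synthetic import CohortSpec, make_cohort

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "load_cohort_dir"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Analysis settings; defaults reproduce the reference protocol
    (128 gray levels, distances 1-5, |rho| cutoff 0.9, alpha 0.05)."""

    n_levels: int = DEFAULT_N_LEVELS
    distances: tuple[int, ...] = DEFAULT_DISTANCES
    log_base: str | float = DEFAULT_LOG_BASE
    threshold: float = DEFAULT_THRESHOLD
    reference: str | None = None  # None -> middle distance
    alpha: float = DEFAULT_ALPHA
    holm: bool = False
    seed: int = 0

    def to_json(self) -> str:
        d = asdict(self)
        d["distances"] = list(self.distances)
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["distances"] = tuple(d["distances"])
        return cls(**d)


@dataclass
class PipelineResult:
    feature_table: pd.DataFrame
    reduction: ReductionReport
    comparison: ComparisonReport
    outdir: Path | None = None


def load_cohort_dir(indir: str | Path) -> list[VolumeWithMask]:
    """Load a cohort from a directory holding a manifest.csv.

    The manifest needs columns ``volume``, ``mask`` and ``group`` indexed by
    subject_id (as written by :func:`voitex.synthetic.write_cohort`).
    """
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.csv", index_col="subject_id")
    cohort = []
    for subject_id, row in manifest.iterrows():
        cohort.append(
            read_volume_with_mask(
                indir / row["volume"],
                indir / row["mask"],
                subject_id=str(subject_id),
                group_label=row.get("group"),
            )
        )
    return cohort


def _write_outputs(result: PipelineResult, config: PipelineConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    result.feature_table.to_csv(outdir / "features.csv", float_format="%.12g")
    red = result.reduction
    (outdir / "reduction.json").write_text(json.dumps(red.to_dict(), indent=1) + "\n")
    corr_dir = outdir / "correlations"
    corr_dir.mkdir(exist_ok=True)
    for param, mat in red.between_distance_rho.items():
        mat.to_csv(corr_dir / f"between_distance_{param}.csv", float_format="%.12g")
    red.within_distance_rho.to_csv(
        corr_dir / f"within_{red.reference_distance}.csv", float_format="%.12g"
    )
    result.comparison.table.to_csv(
        outdir / "comparison.csv", index=False, float_format="%.12g"
    )
    (outdir / "comparison.md").write_text(result.comparison.to_markdown())
    log_lines = [
        f"voitex {__version__}",
        "config: " + config.to_json().replace("\n", " "),
        f"subjects: {len(result.feature_table)}",
        f"reference_distance: {red.reference_distance}",
        f"retained: {','.join(red.retained)}",
        f"excluded: {','.join(red.excluded_names)}",
    ]
    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")


def run_pipeline(
    config: PipelineConfig,
    inputs: list[VolumeWithMask] | CohortSpec,
    outdir: str | Path | None = None,
) -> PipelineResult:
    """Run extraction, reduction and comparison; optionally write artifacts.

    ``inputs`` is either a loaded cohort or a :class:`CohortSpec` to
    simulate (seeded from ``config.seed``). On a stage failure with
    ``outdir`` set, partial outputs are preserved next to a ``FAILED``
    marker naming the stage.
    """
    outdir = Path(outdir) if outdir is not None else None
    stage = "simulate"
    try:
        if isinstance(inputs, CohortSpec):
            from dataclasses import replace

            cohort, _ = make_cohort(replace(inputs, master_seed=config.seed))
        else:
            cohort = inputs
        stage = "extract"
        ft = build_feature_table(
            cohort,
            n_levels=config.n_levels,
            distances=config.distances,
            log_base=config.log_base,
        )
        stage = "reduce"
        if len(config.distances) > 1:
            reduction = reduce_redundancy(
                ft, threshold=config.threshold, reference=config.reference
            )
        else:
            logger.info("single distance: between-distance screening skipped")
            from .cohort import reduce_between_parameters

            ref = "q1"
            cols = [c for c in ft.columns if c.endswith(f"@{ref}")]
            reduction = reduce_between_parameters(ft[cols], threshold=config.threshold)
            reduction.reference_distance = ref
        stage = "compare"
        comparison = compare_groups(
            ft, reduction, alpha=config.alpha, holm=config.holm
        )
        result = PipelineResult(ft, reduction, comparison, outdir)
        if outdir is not None:
            stage = "write"
            _write_outputs(result, config, outdir)
        return result
    except Exception as exc:
        if outdir is not None:
            outdir.mkdir(parents=True, exist_ok=True)
            (outdir / "FAILED").write_text(f"stage: {stage}\n{exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
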