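"""End-to-end driver: phantoms -> segmentations -> features -> ICC -> correlation.

``run_experiment`` reproduces the full synthetic study: a seeded phantom
suite is segmented with the four individual methods plus the majority-vote
consensus under both initial-mask styles, the 107-feature catalog is
extracted for every variant and for the ground truth, ICC(2,1) tables are
computed for the robustness designs (between masks, among methods) and the
accuracy design (versus ground truth), and Spearman correlation matrices are
compared across settings.  Everything derives deterministically from the
master seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .consensus import conseg
from .correlation import CorrelationMatrix, compare_matrices, reference_order, spearman_matrix
from .features import ExtractionConfig, extract_all
from .grids import BinaryMask
from .phantom import PhantomCase, SuiteConfig, generate_suite
from .reliability import (
    ALL_METHODS,
    DesignSpec,
    IccSummary,
    run_design,
    stable_features,
    summarize,
)
from .segment import APParams, MASACParams, STParams, run_all

__all__ = ["RunConfig", "ExperimentReport", "run_experiment", "build_feature_table"]

logger = logging.getLogger(__name__)

MASK_STYLES = ("rectangular", "irregular")


@dataclass
class RunConfig:
    """Serializable configuration for one full experiment run."""

    suite: SuiteConfig = field(default_factory=SuiteConfig)
    fraction: float = 0.41
    st: STParams = field(default_factory=STParams)
    ap: APParams = field(default_factory=APParams)
    masac: MASACParams = field(default_factory=MASACParams)
    vote_threshold: int | None = None
    extraction: ExtractionConfig = field(default_factory=ExtractionConfig)
    designs: tuple[str, ...] = ("between_masks", "among_methods", "vs_ground_truth")
    seed: int = 0
    out_dir: str | Path | None = None


@dataclass
class ExperimentReport:
    """Bundle of everything one run produces."""

    feature_table: pd.DataFrame
    icc_tables: dict[str, pd.DataFrame]
    summaries: dict[str, IccSummary]
    stable_robustness: list[str]
    stable_all: list[str]
    correlation: dict[str, CorrelationMatrix]
    matrix_similarity: float | None
    seg_stats: pd.DataFrame
    config: RunConfig

    @property
    def stable_fraction(self) -> float:
        return len(self.stable_all) / 107.0


def _segment_case(case: PhantomCase, cfg: RunConfig, case_idx: int):
    """All five segmentations under both mask styles for one case."""
    out = {}
    for s_idx, style in enumerate(MASK_STYLES):
        init = case.rect_mask if style == "rectangular" else case.irreg_mask
        seed = int(
            np.random.default_rng([cfg.seed, 7, case_idx, s_idx]).integers(0, 2**31 - 1)
        )
        individual = run_all(
            case.image,
            init,
            fraction=cfg.fraction,
            st_params=cfg.st,
            ap_params=cfg.ap,
            masac_params=cfg.masac,
            seed=seed,
            mask_style=style,
        )
        fused = conseg(
            case.image,
            init,
            vote_threshold=cfg.vote_threshold,
            individual=individual,
            mask_style=style,
        )
        for name, res in {**individual, "ConSeg": fused}.items():
            out[(name, style)] = res
    return out


def build_feature_table(cases: list[PhantomCase], cfg: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every case and extract features for all variants plus GT.

    Returns the feature table (one row per case x method x mask style, plus a
    GT row per case) and a per-variant segmentation statistics table
    (volume in cm^3 and SUVmax).
    """
    rows = []
    stats = []
    failures: list[dict] = []
    for idx, case in enumerate(cases):
        try:
            segs = _segment_case(case, cfg, idx)
        except Exception as exc:  # noqa: BLE001 - a failed case is recorded, not fatal
            logger.error("case %s failed during segmentation: %s", case.case_id, exc)
            failures.append({"case": case.case_id, "stage": "segmentation", "error": str(exc)})
            continue
        variants: dict[tuple[str, str], BinaryMask] = {
            key: res.mask for key, res in segs.items()
        }
        variants[("GT", "GT")] = case.gt_mask
        for (method, style), mask in variants.items():
            try:
                fv = extract_all(case.image, mask, cfg.extraction)
            except Exception as exc:  # noqa: BLE001
                logger.error(
                    "feature extraction failed for %s/%s/%s: %s",
                    case.case_id, method, style, exc,
                )
                failures.append(
                    {
                        "case": case.case_id,
                        "stage": "features",
                        "method": method,
                        "mask_style": style,
                        "error": str(exc),
                    }
                )
                continue
            row = {"case": case.case_id, "method": method, "mask_style": style}
            row.update(fv.values)
            rows.append(row)
            stats.append(
                {
                    "case": case.case_id,
                    "method": method,
                    "mask_style": style,
                    "volume_cm3": mask.volume_cm3,
                    "suv_max": float(case.image.data[mask.data].max()),
                }
            )
        if cfg.out_dir is not None:
            _write_case(case, segs, cfg)
    if not rows:
        raise RuntimeError(f"every case failed: {failures}")
    if failures and cfg.out_dir is not None:
        from . import io

        Path(cfg.out_dir).mkdir(parents=True, exist_ok=True)
        io.dump_json(failures, Path(cfg.out_dir) / "failures.json")
    table = pd.DataFrame(rows)
    table.attrs["failures"] = failures
    return table, pd.DataFrame(stats)


def _write_case(case: PhantomCase, segs, cfg: RunConfig) -> None:
    from . import io

    d = Path(cfg.out_dir) / case.case_id
    d.mkdir(parents=True, exist_ok=True)
    io.write_volume(case.image, d / "image.nii.gz")
    io.write_volume(case.gt_mask, d / "gt.nii.gz")
    io.write_volume(case.rect_mask, d / "rect_mask.nii.gz")
    io.write_volume(case.irreg_mask, d / "irreg_mask.nii.gz")
    for (method, style), res in segs.items():
        io.write_volume(res.mask, d / f"seg_{method}_{style}.nii.gz")
    io.dump_json(case.provenance, d / "provenance.json")


def compute_icc_tables(
    table: pd.DataFrame, designs: tuple[str, ...]
) -> dict[str, pd.DataFrame]:
    """All design/subgroup ICC tables the run requests, keyed by a stable name."""
    out: dict[str, pd.DataFrame] = {}
    if "between_masks" in designs:
        for m in ALL_METHODS:
            out[f"between_masks:{m}"] = run_design(table, DesignSpec("between_masks", method=m))
    if "among_methods" in designs:
        for s in MASK_STYLES:
            out[f"among_methods:{s}"] = run_design(
                table, DesignSpec("among_methods", mask_style=s)
            )
    if "vs_ground_truth" in designs and (table["method"] == "GT").any():
        for m in ALL_METHODS:
            for s in MASK_STYLES:
                out[f"vs_gt:{m}:{s}"] = run_design(
                    table, DesignSpec("vs_ground_truth", method=m, mask_style=s)
                )
    return out


def run_experiment(cfg: RunConfig | None = None) -> ExperimentReport:
    """Run the complete synthetic experiment; see the module docstring."""
    cfg = cfg or RunConfig()
    logger.info("generating %d-case suite (seed %d)", cfg.suite.n_cases, cfg.seed)
    cases = generate_suite(cfg.suite, cfg.seed)
    table, seg_stats = build_feature_table(cases, cfg)

    icc_tables = compute_icc_tables(table, cfg.designs)
    summaries = {k: summarize(v) for k, v in icc_tables.items()}

    robustness_keys = [
        k for k in icc_tables if k.startswith(("between_masks", "among_methods"))
    ]
    stable_rob = (
        stable_features({k: icc_tables[k] for k in robustness_keys})
        if robustness_keys
        else []
    )
    stable_all = stable_features(icc_tables) if icc_tables else []

    correlation: dict[str, CorrelationMatrix] = {}
    similarity = None
    n_cases = table["case"].nunique()
    if n_cases >= 3:
        for style in MASK_STYLES:
            sub = table[(table["method"] == "ConSeg") & (table["mask_style"] == style)]
            correlation[f"ConSeg:{style}"] = spearman_matrix(sub)
        order = reference_order(correlation["ConSeg:irregular"])
        correlation = {k: v.reordered(order) for k, v in correlation.items()}
        similarity = compare_matrices(
            correlation["ConSeg:rectangular"], correlation["ConSeg:irregular"]
        )

    report = ExperimentReport(
        feature_table=table,
        icc_tables=icc_tables,
        summaries=summaries,
        stable_robustness=stable_rob,
        stable_all=stable_all,
        correlation=correlation,
        matrix_similarity=similarity,
        seg_stats=seg_stats,
        config=cfg,
    )
    if cfg.out_dir is not None:
        _write_report(report)
    return report


def _write_report(report: ExperimentReport) -> None:
    from . import io

    d = Path(report.config.out_dir)
    d.mkdir(parents=True, exist_ok=True)
    report.feature_table.to_csv(d / "features.csv", index=False, float_format="%.12g")
    report.seg_stats.to_csv(d / "seg_stats.csv", index=False, float_format="%.12g")
    for key, tab in report.icc_tables.items():
        tab.to_csv(d / f"icc_{key.replace(':', '_')}.csv", float_format="%.12g")
    summary = {
        "summaries": {
            k: {
                "counts": s.counts,
                "median_icc": s.median_icc,
                "n_features": s.n_features,
                "n_negative_excluded": s.n_negative_excluded,
                "n_invalid_excluded": s.n_invalid_excluded,
            }
            for k, s in report.summaries.items()
        },
        "stable_robustness": report.stable_robustness,
        "stable_all": report.stable_all,
        "stable_all_percent": 100.0 * report.stable_fraction,
        "matrix_similarity": report.matrix_similarity,
        "seed": report.config.seed,
    }
    io.dump_json(summary, d / "summary.json")
    for key, m in report.correlation.items():
        m.matrix.to_csv(d / f"spearman_{key.replace(':', '_')}.csv", float_format="%.12g")
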