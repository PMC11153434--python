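"""ICC(2,1) reliability analysis of radiomic features.

The agreement statistic is the single-measure, absolute-agreement intraclass
correlation under a two-way random-effects model:

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

where MSR, MSC and MSE are the subject, rater and residual mean squares of
the two-way ANOVA decomposition of an n-subjects x k-raters matrix.  Values
are categorized by absolute value as excellent (>= 0.9), good (0.75-0.89),
moderate (0.5-0.74) or poor (< 0.5).  Negative ICCs (small-sample artefacts)
are retained and flagged in per-feature output, but excluded from the
category-count summaries with the excluded fraction reported.

Three comparison designs are supported on a feature table:

* ``between_masks``   -- raters are the two initial-mask styles, for one method (k=2)
* ``among_methods``   -- raters are the four individual methods, for one mask style (k=4)
* ``vs_ground_truth`` -- raters are a segmentation variant and the ground truth (k=2)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ICCResult",
    "DesignSpec",
    "icc_a1",
    "categorize_icc",
    "run_design",
    "summarize",
    "stable_features",
    "IccSummary",
    "INDIVIDUAL_METHODS",
    "CATEGORY_ORDER",
]

INDIVIDUAL_METHODS = ("MASAC", "AP", "ST", "41MAX")
ALL_METHODS = INDIVIDUAL_METHODS + ("ConSeg",)
CATEGORY_ORDER = ("excellent", "good", "moderate", "poor")


@dataclass(frozen=True)
class ICCResult:
    """One ICC(2,1) estimate with its ANOVA mean squares and category."""

    icc: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    category: str
    negative_flag: bool
    valid: bool = True


@dataclass(frozen=True)
class DesignSpec:
    """A comparison design over the feature table."""

    design: str  # between_masks | among_methods | vs_ground_truth
    method: str | None = None
    mask_style: str | None = None

    def __post_init__(self) -> None:
        if self.design not in ("between_masks", "among_methods", "vs_ground_truth"):
            raise ValueError(f"unknown design {self.design!r}")


def icc_a1(values: np.ndarray) -> ICCResult:
    """ICC(2,1): two-way random effects, single measurement, absolute agreement."""
    m = np.asarray(values, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("measurement matrix must be 2-D (subjects x raters)")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValueError("measurement matrix contains non-finite values")

    grand = m.mean()
    row_means = m.mean(axis=1)
    col_means = m.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((m - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err, 0.0) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom == 0:  # constant matrix: 0/0, undefined
        return ICCResult(np.nan, msr, msc, mse, "undefined", False, valid=False)
    icc = (msr - mse) / denom
    return ICCResult(
        icc=float(icc),
        ms_rows=float(msr),
        ms_cols=float(msc),
        ms_error=float(mse),
        category=categorize_icc(icc),
        negative_flag=bool(icc < 0),
    )


def categorize_icc(icc: float) -> str:
    """Category from |ICC|: >= 0.9 excellent, [0.75, 0.9) good, [0.5, 0.75)
    moderate, < 0.5 poor."""
    if not np.isfinite(icc):
        raise ValueError("ICC must be finite")
    a = abs(icc)
    if a >= 0.9:
        return "excellent"
    if a >= 0.75:
        return "good"
    if a >= 0.5:
        return "moderate"
    return "poor"


def _rater_frames(table: pd.DataFrame, spec: DesignSpec) -> dict[str, pd.DataFrame]:
    """Per-rater feature frames indexed by case, per the design."""

    def sel(method: str, mask_style: str | None) -> pd.DataFrame:
        q = table["method"] == method
        if mask_style is not None:
            q &= table["mask_style"] == mask_style
        sub = table.loc[q]
        if sub.empty:
            raise KeyError(
                f"feature table has no rows for method={method!r}, mask_style={mask_style!r}"
            )
        return sub.set_index("case")

    if spec.design == "between_masks":
        if spec.method is None:
            raise ValueError("between_masks needs a method")
        return {
            "rectangular": sel(spec.method, "rectangular"),
            "irregular": sel(spec.method, "irregular"),
        }
    if spec.design == "among_methods":
        if spec.mask_style is None:
            raise ValueError("among_methods needs a mask_style")
        return {m: sel(m, spec.mask_style) for m in INDIVIDUAL_METHODS}
    # vs_ground_truth
    if spec.method is None or spec.mask_style is None:
        raise ValueError("vs_ground_truth needs a method and a mask_style")
    return {"segmentation": sel(spec.method, spec.mask_style), "GT": sel("GT", None)}


def run_design(
    table: pd.DataFrame,
    spec: DesignSpec,
    feature_cols: list[str] | None = None,
) -> pd.DataFrame:
    """Compute one ICC per feature for the given design.

    ``table`` must have columns ``case``, ``method``, ``mask_style`` plus one
    column per feature.  Features invalid (NaN) in any cell are excluded and
    counted in ``result.attrs['n_excluded_invalid']``.  Negative ICCs are
    retained with ``negative`` set.
    """
    for col in ("case", "method", "mask_style"):
        if col not in table.columns:
            raise KeyError(f"feature table is missing the {col!r} column")
    if feature_cols is None:
        feature_cols = [c for c in table.columns if c not in ("case", "method", "mask_style")]

    raters = _rater_frames(table, spec)
    cases = sorted(set.intersection(*(set(f.index) for f in raters.values())))
    if len(cases) < 2:
        raise ValueError("need at least 2 common subjects across raters")

    rows = []
    n_excluded = 0
    for feat in feature_cols:
        m = np.column_stack([raters[r].loc[cases, feat].to_numpy() for r in raters])
        if not np.all(np.isfinite(m)):
            n_excluded += 1
            continue
        res = icc_a1(m)
        rows.append(
            {
                "feature": feat,
                "icc": res.icc,
                "ms_rows": res.ms_rows,
                "ms_cols": res.ms_cols,
                "ms_error": res.ms_error,
                "category": res.category,
                "negative": res.negative_flag,
                "valid": res.valid,
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    out.attrs["design"] = spec
    out.attrs["n_subjects"] = len(cases)
    out.attrs["n_raters"] = len(raters)
    out.attrs["n_excluded_invalid"] = n_excluded
    return out


@dataclass
class IccSummary:
    """Category counts, median ICC and exclusion accounting for one design."""

    counts: dict[str, int]
    median_icc: float
    n_features: int
    n_negative_excluded: int
    n_invalid_excluded: int

    @property
    def negative_fraction(self) -> float:
        tot = self.n_features + self.n_negative_excluded
        return self.n_negative_excluded / tot if tot else 0.0


def summarize(icc_table: pd.DataFrame) -> IccSummary:
    """Summarize a per-feature ICC table.

    Negative and undefined ICCs are excluded from the category counts and the
    median, with the excluded counts reported.
    """
    if icc_table.empty:
        raise ValueError("empty ICC table")
    ok = icc_table[icc_table["valid"] & ~icc_table["negative"]]
    counts = {c: int((ok["category"] == c).sum()) for c in CATEGORY_ORDER}
    return IccSummary(
        counts=counts,
        median_icc=float(ok["icc"].median()) if len(ok) else np.nan,
        n_features=len(ok),
        n_negative_excluded=int(icc_table["negative"].sum()),
        n_invalid_excluded=int((~icc_table["valid"]).sum())
        + int(icc_table.attrs.get("n_excluded_invalid", 0)),
    )


def stable_features(
    icc_tables: dict[str, pd.DataFrame],
    threshold: float = 0.75,
) -> list[str]:
    """Features whose ICC meets ``threshold`` in every supplied design table.

    This mirrors the selection of segmentation- and mask-independent features:
    a feature qualifies only if it is defined and at or above the threshold in
    all tables.
    """
    if not icc_tables:
        raise ValueError("no ICC tables supplied")
    sets = []
    for tab in icc_tables.values():
        ok = tab[tab["valid"] & (tab["icc"] >= threshold)]
        sets.append(set(ok.index))
    common = set.intersection(*sets)
    any_table = next(iter(icc_tables.values()))
    return [f for f in any_table.index if f in common]
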