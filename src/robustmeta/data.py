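"""Study-level data model and delimited-text I/O.

A meta-analysis here is a set of K study-level summary results: a point
estimate per study with its standard error. Ratio measures (odds ratios,
risk ratios) are always carried on the natural-log scale internally; the
``measure`` tag only governs how results are reported back (exponentiation
of point estimates and interval bounds).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


class Measure(str, enum.Enum):
    """Effect-measure scale of a study set.

    ``MD`` is an (additive) mean difference; ``LOG_OR`` and ``LOG_RR`` are
    log odds/risk ratios. All computation happens on the additive scale;
    the measure controls only back-transformation for reporting.
    """

    MD = "md"
    LOG_OR = "logor"
    LOG_RR = "logrr"

    @property
    def is_ratio(self) -> bool:
        return self in (Measure.LOG_OR, Measure.LOG_RR)

    @classmethod
    def coerce(cls, value: "Measure | str") -> "Measure":
        if isinstance(value, Measure):
            return value
        return cls(str(value).lower().replace("_", ""))


class ValidationError(ValueError):
    """Raised when study-level input fails an invariant."""


@dataclass(frozen=True)
class StudySet:
    """K study-level effect estimates with standard errors.

    Parameters
    ----------
    estimates : array-like of float
        Effect estimates on the analysis (additive) scale.
    std_errors : array-like of float
        Standard errors, strictly positive, same length.
    labels : sequence of str, optional
        Study identifiers; defaults to ``study_1 .. study_K``.
    measure : Measure
        Reporting scale; computation is always additive.
    sizes : array-like of int, optional
        Per-study sample sizes (present for simulated data).
    """

    estimates: np.ndarray
    std_errors: np.ndarray
    labels: tuple[str, ...] = ()
    measure: Measure = Measure.MD
    sizes: np.ndarray | None = None

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=float)
        se = np.asarray(self.std_errors, dtype=float)
        object.__setattr__(self, "estimates", est)
        object.__setattr__(self, "std_errors", se)
        object.__setattr__(self, "measure", Measure.coerce(self.measure))
        if est.ndim != 1 or se.ndim != 1:
            raise ValidationError("estimates and std_errors must be 1-D")
        if est.size < 1:
            raise ValidationError("a study set needs at least one study")
        if est.size != se.size:
            raise ValidationError(
                f"length mismatch: {est.size} estimates vs {se.size} standard errors"
            )
        if not np.all(np.isfinite(est)):
            bad = int(np.flatnonzero(~np.isfinite(est))[0])
            raise ValidationError(f"non-finite estimate in row {bad + 1}")
        if not np.all(np.isfinite(se) & (se > 0)):
            bad = int(np.flatnonzero(~(np.isfinite(se) & (se > 0)))[0])
            raise ValidationError(
                f"standard error must be finite and > 0 (row {bad + 1}: {se[bad]!r})"
            )
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"study_{i + 1}" for i in range(est.size))
            )
        elif len(self.labels) != est.size:
            raise ValidationError("labels length does not match estimates")
        else:
            object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if self.sizes is not None:
            n = np.asarray(self.sizes, dtype=int)
            if n.size != est.size:
                raise ValidationError("sizes length does not match estimates")
            if np.any(n <= 0):
                raise ValidationError("study sizes must be positive")
            object.__setattr__(self, "sizes", n)

    @property
    def k(self) -> int:
        """Number of studies."""
        return int(self.estimates.size)

    def weights(self) -> np.ndarray:
        """Standardized inverse-variance weights w_j = σ_j⁻² / Σ σ⁻²."""
        w = self.std_errors**-2.0
        return w / w.sum()

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "study": list(self.labels),
                "estimate": self.estimates,
                "se": self.std_errors,
            }
        )
        if self.sizes is not None:
            df["n"] = self.sizes
        return df

    def to_csv(self, path, delimiter: str = ",") -> None:
        """Write the study set with round-trippable float precision."""
        self.to_frame().to_csv(path, index=False, sep=delimiter,
                               float_format=lambda v: repr(float(v)))


@dataclass
class EstimateResult:
    """A pooled effect estimate with its uncertainty.

    All values are on the analysis (additive) scale; use
    :func:`write_results` or ``report_scale()`` for ratio-scale reporting.
    ``extras`` carries method-specific metadata such as the kernel
    bandwidth (MBE) or the imputed-study count (trim-and-fill).
    """

    method: str
    estimate: float
    std_error: float
    ci_low: float
    ci_high: float
    alpha: float = 0.05
    n_boot: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.std_error < 0:
            raise ValidationError("std_error must be >= 0")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValidationError("CI must bracket the point estimate")

    def report_scale(self, measure: Measure) -> tuple[float, float, float]:
        """(estimate, ci_low, ci_high) on the reporting scale."""
        measure = Measure.coerce(measure)
        if measure.is_ratio:
            return (
                math.exp(self.estimate),
                math.exp(self.ci_low),
                math.exp(self.ci_high),
            )
        return (self.estimate, self.ci_low, self.ci_high)


def read_study_set(
    path,
    measure: Measure | str = Measure.MD,
    *,
    delimiter: str = ",",
    label_col: str = "study",
    estimate_col: str = "estimate",
    se_col: str = "se",
    ratio_ci_cols: tuple[str, str, str] | None = None,
) -> StudySet:
    """Read study-level summary data from a delimited text file.

    The file must have a header. By default columns ``study``, ``estimate``,
    ``se`` are used, with the estimate already on the analysis scale.
    For ratio measures, ``ratio_ci_cols=(ratio, lo, hi)`` names columns
    holding the ratio-scale point estimate and its 95% CI bounds; these are
    converted as β̂ = log(ratio), σ = (log hi − log lo) / (2 z_0.975).
    """
    measure = Measure.coerce(measure)
    try:
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"empty input file: {path}") from exc
    if df.empty:
        raise ValidationError(f"no data rows in {path}")

    if ratio_ci_cols is not None:
        if not measure.is_ratio:
            raise ValidationError("ratio_ci_cols requires a ratio measure")
        rcol, locol, hicol = ratio_ci_cols
        for c in (rcol, locol, hicol):
            if c not in df.columns:
                raise ValidationError(f"missing column {c!r} in {path}")
        ratio = pd.to_numeric(df[rcol], errors="coerce")
        lo = pd.to_numeric(df[locol], errors="coerce")
        hi = pd.to_numeric(df[hicol], errors="coerce")
        if ratio.isna().any() or lo.isna().any() or hi.isna().any():
            bad = int(ratio.isna().idxmax() if ratio.isna().any() else lo.isna().idxmax())
            raise ValidationError(f"non-numeric ratio/CI value in row {bad + 1}")
        if (ratio <= 0).any() or (lo <= 0).any() or (hi <= 0).any():
            raise ValidationError("ratio-scale values must be positive")
        z = stats.norm.ppf(0.975)
        est = np.log(ratio.to_numpy())
        se = (np.log(hi.to_numpy()) - np.log(lo.to_numpy())) / (2.0 * z)
    else:
        for c in (estimate_col, se_col):
            if c not in df.columns:
                raise ValidationError(f"missing column {c!r} in {path}")
        est_s = pd.to_numeric(df[estimate_col], errors="coerce")
        se_s = pd.to_numeric(df[se_col], errors="coerce")
        if est_s.isna().any():
            bad = int(np.flatnonzero(est_s.isna())[0])
            raise ValidationError(f"missing/non-numeric estimate in row {bad + 1}")
        if se_s.isna().any():
            bad = int(np.flatnonzero(se_s.isna())[0])
            raise ValidationError(f"missing/non-numeric standard error in row {bad + 1}")
        est = est_s.to_numpy(dtype=float)
        se = se_s.to_numpy(dtype=float)
    if np.any(se <= 0):
        bad = int(np.flatnonzero(se <= 0)[0])
        raise ValidationError(f"standard error must be > 0 (row {bad + 1})")

    labels = (
        tuple(str(x) for x in df[label_col])
        if label_col in df.columns
        else ()
    )
    return StudySet(estimates=est, std_errors=se, labels=labels, measure=measure)


def results_frame(
    results: Sequence[EstimateResult],
    diagnostics=None,
    measure: Measure | str = Measure.MD,
) -> pd.DataFrame:
    """Tabulate pooled results; ratio measures get exponentiated columns."""
    if not results:
        raise ValidationError("no results to write")
    measure = Measure.coerce(measure)
    rows = []
    for r in results:
        row = {
            "method": r.method,
            "estimate": r.estimate,
            "se": r.std_error,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "alpha": r.alpha,
            "n_boot": r.n_boot,
        }
        if measure.is_ratio:
            rep, lo, hi = r.report_scale(measure)
            row["reported_estimate"] = rep
            row["reported_ci_low"] = lo
            row["reported_ci_high"] = hi
        rows.append(row)
    df = pd.DataFrame(rows)
    if diagnostics is not None:
        for key in ("Q", "i_squared", "tau2", "gamma", "gamma_p"):
            val = getattr(diagnostics, key, None)
            df[key] = val if val is not None else np.nan
    return df


def write_results(
    results: Sequence[EstimateResult],
    diagnostics,
    measure: Measure | str,
    path,
) -> None:
    """Write a results table (CSV). See :func:`results_frame`."""
    results_frame(results, diagnostics, measure).to_csv(path, index=False)


def funnel_coordinates(data: StudySet) -> pd.DataFrame:
    """Per-study funnel-plot coordinates: estimate, SE and precision 1/σ."""
    return pd.DataFrame(
        {
            "study": list(data.labels),
            "estimate": data.estimates,
            "std_error": data.std_errors,
            "precision": 1.0 / data.std_errors,
        }
    )


def plot_funnel(data: StudySet, path=None, ax=None):
    """Funnel scatter with the SE axis inverted (precise studies on top)."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(data.estimates, data.std_errors, s=18, alpha=0.8, edgecolor="none")
    ax.invert_yaxis()
    ax.set_xlabel("effect estimate")
    ax.set_ylabel("standard error")
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
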