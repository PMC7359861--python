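"""Model/Results interface for robust meta-analysis.

``MetaAnalysis`` wraps a :class:`~robustmeta.data.StudySet` the way a
statsmodels model wraps its data: construct from arrays, a DataFrame or a
CSV file, then ``fit()`` to obtain a :class:`MetaAnalysisResults` holding
the pooled estimates from the requested estimators, their uncertainties,
heterogeneity/asymmetry diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from . import comparators, estimators
from .data import (
    EstimateResult,
    Measure,
    StudySet,
    funnel_coordinates,
    plot_funnel,
    read_study_set,
    results_frame,
)

ALL_METHODS = (
    "weighted_mean",
    "regression_extrapolation",
    "trim_and_fill",
    "weighted_median",
    "mbe",
)

_BOOT_METHODS = frozenset({"weighted_median", "mbe"})


class MetaAnalysis:
    """A meta-analysis of K study-level effect estimates.

    Parameters
    ----------
    estimates, std_errors : array-like
        Study effect estimates (analysis scale) and standard errors.
    labels : sequence of str, optional
    measure : {"md", "logor", "logrr"}
        Reporting scale; ratio measures are exponentiated in summaries.

    Examples
    --------
    >>> ma = MetaAnalysis([0.1, 0.3, 0.8, 0.2], [0.1, 0.15, 0.4, 0.12])
    >>> res = ma.fit(seed=7, n_boot=2000)
    >>> float(round(res.results["weighted_median"].estimate, 3))
    0.171
    """

    def __init__(
        self,
        estimates,
        std_errors,
        labels: Sequence[str] = (),
        measure: Measure | str = Measure.MD,
        sizes=None,
    ) -> None:
        self.data = StudySet(
            estimates=np.asarray(estimates, float),
            std_errors=np.asarray(std_errors, float),
            labels=tuple(labels),
            measure=Measure.coerce(measure),
            sizes=sizes,
        )

    @classmethod
    def from_study_set(cls, data: StudySet) -> "MetaAnalysis":
        obj = cls.__new__(cls)
        obj.data = data
        return obj

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        estimate_col: str = "estimate",
        se_col: str = "se",
        label_col: str = "study",
        measure: Measure | str = Measure.MD,
    ) -> "MetaAnalysis":
        labels = (
            tuple(str(x) for x in df[label_col]) if label_col in df.columns else ()
        )
        return cls(
            df[estimate_col].to_numpy(float),
            df[se_col].to_numpy(float),
            labels=labels,
            measure=measure,
        )

    @classmethod
    def from_csv(cls, path, measure: Measure | str = Measure.MD, **kwargs):
        return cls.from_study_set(read_study_set(path, measure, **kwargs))

    @property
    def k(self) -> int:
        return self.data.k

    def diagnostics(self) -> comparators.DiagnosticsResult:
        """Q, I², τ² and (K ≥ 3, unequal SEs) the Egger test."""
        return comparators.heterogeneity(self.data)

    def funnel_coordinates(self) -> pd.DataFrame:
        return funnel_coordinates(self.data)

    def plot_funnel(self, path=None, ax=None):
        return plot_funnel(self.data, path=path, ax=ax)

    def fit(
        self,
        methods: Sequence[str] = ALL_METHODS,
        n_boot: int = 10_000,
        seed: int | None = None,
        alpha: float = 0.05,
        side: str = "auto",
        truncate_phi: bool = False,
        bandwidth_multiplier: float = 1.0,
    ) -> "MetaAnalysisResults":
        """Fit the requested pooled estimators.

        ``seed`` is required when any bootstrap-based estimator
        (weighted_median, mbe) is selected. Estimators needing K ≥ 3
        (Egger-based and trim-and-fill) are skipped with a warning entry
        when the study set is too small.
        """
        unknown = set(methods) - set(ALL_METHODS)
        if unknown:
            raise ValueError(f"unknown methods: {sorted(unknown)}")
        if _BOOT_METHODS & set(methods) and seed is None and self.k > 1:
            raise ValueError(
                "seed is required for bootstrap-based estimators "
                "(weighted_median, mbe)"
            )
        boot = estimators.BootstrapSpec(n_boot=n_boot, seed=seed or 0)
        results: dict[str, EstimateResult] = {}
        warnings: list[str] = []
        for m in methods:
            if m in ("regression_extrapolation", "trim_and_fill") and self.k < 3:
                warnings.append(f"{m}: skipped (needs at least 3 studies)")
                continue
            if m == "weighted_mean":
                results[m] = estimators.weighted_mean(self.data, alpha=alpha)
            elif m == "weighted_median":
                results[m] = estimators.weighted_median(self.data, boot, alpha=alpha)
            elif m == "mbe":
                results[m] = estimators.mode_based_estimate(
                    self.data, boot, alpha=alpha,
                    bandwidth_multiplier=bandwidth_multiplier,
                )
            elif m == "regression_extrapolation":
                results[m] = comparators.regression_extrapolation(
                    self.data, alpha=alpha, truncate_phi=truncate_phi
                )
            elif m == "trim_and_fill":
                tf = comparators.trim_and_fill(self.data, side=side, alpha=alpha)
                results[m] = tf.pooled
        diag = None
        if self.k >= 2:
            diag = comparators.heterogeneity(self.data)
        else:
            warnings.append("diagnostics: skipped (needs at least 2 studies)")
        return MetaAnalysisResults(self, results, diag, warnings)


class MetaAnalysisResults:
    """Pooled estimates, diagnostics and reporting for a fitted model."""

    def __init__(self, model, results, diagnostics, warnings=()):
        self.model = model
        self.results: dict[str, EstimateResult] = results
        self.diagnostics = diagnostics
        self.warnings = list(warnings)

    @property
    def measure(self) -> Measure:
        return self.model.data.measure

    def to_frame(self) -> pd.DataFrame:
        return results_frame(
            list(self.results.values()), self.diagnostics, self.measure
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def summary(self) -> str:
        """Human-readable grid: one row per estimator, plus diagnostics."""
        ratio = self.measure.is_ratio
        lines = [f"Meta-analysis of K = {self.model.k} studies "
                 f"({self.measure.value})", "-" * 64]
        header = f"{'estimator':<28}{'estimate':>10}{'95% CI':>22}"
        lines.append(header)
        for name, r in self.results.items():
            est, lo, hi = r.report_scale(self.measure) if ratio else (
                r.estimate, r.ci_low, r.ci_high
            )
            lines.append(f"{name:<28}{est:>10.3f}{f'({lo:.3f}; {hi:.3f})':>22}")
        d = self.diagnostics
        if d is not None:
            lines.append("-" * 64)
            lines.append(
                f"Q = {d.Q:.2f}   I^2 = {d.i_squared:.1f}%   tau^2 = {d.tau2:.4f}"
            )
            if d.gamma is not None:
                lines.append(
                    f"Egger gamma = {d.gamma:.2f} (SE {d.gamma_se:.2f}, "
                    f"p = {d.gamma_p:.3g})"
                )
        for w in self.warnings:
            lines.append(f"note: {w}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<MetaAnalysisResults: {sorted(self.results)}>"
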