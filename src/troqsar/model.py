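"""Model/Results interface over the TRO screening pipeline.

``TROQSAR`` is built from compound records (or a DataFrame/CSV in the
standard schema), holds the screening settings, and ``fit()`` runs the
full procedure — TRO evaluation, MOA classification, class-based
screening, and the before/after baseline regressions — returning a
``TROQSARResults`` object with the fitted lines, the improvement
figures, per-record dispositions, a text ``summary()`` and a scatter
``plot()``.

Example
-------
>>> from troqsar import TROQSAR, load_table2_fixture
>>> res = TROQSAR(load_table2_fixture()).fit()
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .core import ClassThresholds, CompoundRecord, MOAClass, TROConvention
from .exceptions import NotFittedError
from .regression import QSARModel
from .screening import DEFAULT_RETAIN, ScreeningReport, compare_fit

__all__ = ["TROQSAR", "TROQSARResults"]


class TROQSAR:
    """A TRO-screened baseline-toxicity QSAR model.

    Parameters
    ----------
    records : sequence of CompoundRecord
    thresholds : ClassThresholds, optional
        log-TRO class boundaries (default 1 and 3).
    convention : TROConvention
        'absolute' (default) or 'signed' log TRO.
    retain : iterable of MOAClass
        Classes kept in the screened training set (default: narcosis).
    dedupe : bool
        Drop repeated CAS numbers, keeping the first occurrence.
    """

    def __init__(
        self,
        records: Sequence[CompoundRecord],
        *,
        thresholds: Optional[ClassThresholds] = None,
        convention: TROConvention = TROConvention.ABSOLUTE,
        retain: Iterable[MOAClass] = DEFAULT_RETAIN,
        dedupe: bool = True,
    ) -> None:
        self.records = list(records)
        self.thresholds = thresholds or ClassThresholds()
        self.convention = TROConvention(convention)
        self.retain = frozenset(MOAClass(c) for c in retain)
        self.dedupe = bool(dedupe)

    @classmethod
    def from_dataframe(cls, df, **kwargs) -> "TROQSAR":
        """Build from a DataFrame in the compound-table schema."""
        from .io import records_from_dataframe

        records, report = records_from_dataframe(df)
        model = cls(records, **kwargs)
        model.parse_report = report
        return model

    @classmethod
    def from_csv(cls, path, **kwargs) -> "TROQSAR":
        from .io import read_compounds_csv

        records, report = read_compounds_csv(path)
        model = cls(records, **kwargs)
        model.parse_report = report
        return model

    def fit(self) -> "TROQSARResults":
        """Run screening and both regressions."""
        report = compare_fit(
            self.records,
            thresholds=self.thresholds,
            retain=self.retain,
            convention=self.convention,
            dedupe=self.dedupe,
        )
        return TROQSARResults(self, report)


class TROQSARResults:
    """Results of a fitted :class:`TROQSAR` model."""

    def __init__(self, model: TROQSAR, report: ScreeningReport) -> None:
        self.model = model
        self.report = report

    # -- statsmodels-style accessors ------------------------------------
    @property
    def model_initial(self) -> QSARModel:
        return self.report.model_initial

    @property
    def model_screened(self) -> QSARModel:
        return self.report.model_screened

    @property
    def improvement(self):
        return self.report.improvement

    @property
    def retained(self):
        return self.report.retained

    @property
    def excluded(self):
        return self.report.excluded

    def predict(self, log_kow) -> np.ndarray:
        """Predict log LC50 (mg/L) from log KOW with the screened model."""
        if self.model_screened is None:
            raise NotFittedError("no screened model available")
        x = np.asarray(log_kow, dtype=float)
        return self.model_screened.intercept + self.model_screened.slope * x

    def save(self, path, format: str = "json") -> None:
        from .io import write_report

        write_report(self.report, path, format=format)

    def summary(self) -> str:
        """Text summary of the screening and the two fits."""
        rep = self.report
        imp = rep.improvement
        width = 78
        lines = []
        lines.append("TRO-screened baseline QSAR (log LC50 ~ log KOW)".center(width))
        lines.append("=" * width)
        n_total = len(rep.retained) + len(rep.excluded)
        n_dup = sum(1 for e in rep.excluded if e.reason == "DUPLICATE")
        n_unc = sum(1 for e in rep.excluded if e.reason == "UNCLASSIFIED")
        lines.append(
            f"Records: {n_total}   duplicates removed: {n_dup}   "
            f"unclassified: {n_unc}"
        )
        lines.append(
            f"Retained classes: {', '.join(sorted(c.value.lower() for c in rep.retain))}"
            f"   convention: {rep.convention.value}"
            f"   thresholds: |log TRO| < {rep.thresholds.narcosis_upper}"
            f" / >= {rep.thresholds.reactive_lower}"
        )
        lines.append("-" * width)
        lines.append(
            f"{'':12s}{'n':>5s}{'slope':>12s}{'intercept':>12s}{'R2':>10s}{'SDEP':>10s}"
        )
        for label, m in (("Initial", rep.model_initial), ("Screened", rep.model_screened)):
            lines.append(
                f"{label:12s}{m.n:>5d}{m.slope:>12.4f}{m.intercept:>12.4f}"
                f"{m.r_squared:>10.4f}{m.sdep:>10.4f}"
            )
        lines.append("-" * width)
        lines.append(
            f"R2 gain: {imp.r2_improved - imp.r2_initial:+.4f}   "
            f"as-defined (initial denom.): {imp.pct_initial_denominator:+.2f}%   "
            f"as-reported (improved denom.): {imp.pct_improved_denominator:+.2f}%"
        )
        moa_excl = [
            e for e in rep.excluded if e.reason == "MOA_CLASS_NOT_RETAINED"
        ]
        if moa_excl:
            names = ", ".join(
                f"{e.record.abbreviation or e.record.name} ({e.tro.moa.value.lower()})"
                for e in moa_excl
            )
            lines.append(f"Excluded by MOA class: {names}")
        warn = set(rep.model_initial.warnings) | set(rep.model_screened.warnings)
        if warn:
            lines.append(f"Warnings: {', '.join(sorted(warn))}")
        lines.append("=" * width)
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of log LC50 vs log KOW with the two fitted lines."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6.5, 4.5))
        rep = self.report

        def xy(items):
            pts = [
                (it.record.log_kow, it.record.endpoints.resolved_log_lc50())
                for it in items
                if it.record.log_kow is not None
                and it.record.endpoints.resolved_log_lc50() is not None
            ]
            return (np.array([p[0] for p in pts]), np.array([p[1] for p in pts]))

        xr, yr = xy(rep.retained)
        xe, ye = xy([e for e in rep.excluded if e.reason == "MOA_CLASS_NOT_RETAINED"])
        ax.scatter(xr, yr, label="retained", color="tab:blue", zorder=3)
        if xe.size:
            ax.scatter(xe, ye, label="excluded (MOA)", color="tab:red", marker="x", zorder=3)
        xs = np.linspace(
            min(np.concatenate([xr, xe]) if xe.size else xr),
            max(np.concatenate([xr, xe]) if xe.size else xr),
            50,
        )
        mi, ms = rep.model_initial, rep.model_screened
        ax.plot(xs, mi.intercept + mi.slope * xs, "--", color="gray",
                label=f"initial (R$^2$={mi.r_squared:.2f})")
        ax.plot(xs, ms.intercept + ms.slope * xs, "-", color="tab:blue",
                label=f"screened (R$^2$={ms.r_squared:.2f})")
        ax.set_xlabel("log $K_{OW}$")
        ax.set_ylabel("log LC$_{50}$ (mg/L)")
        ax.legend()
        return ax
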