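"""End-to-end TRO screening of a QSAR training set.

Every record is evaluated for TRO and mode of action; records outside
the retained MOA classes (by default narcosis only, the class for which
the single-descriptor log KOW model is appropriate) are excluded, the
baseline model is fitted before and after screening, and the two fits
are compared.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Set, Tuple

from .core import (
    ClassThresholds,
    CompoundRecord,
    MOAClass,
    TROConvention,
    TROResult,
    evaluate_record,
)
from .exceptions import InvalidInputError, TroqsarError
from .regression import ImprovementResult, QSARModel, fit_linear_qsar, improvement_percent

__all__ = [
    "ExclusionReason",
    "ScreenedRecord",
    "ScreeningReport",
    "DEFAULT_RETAIN",
    "screen",
    "compare_fit",
    "select_descriptor_tier",
]

DEFAULT_RETAIN = frozenset({MOAClass.NARCOSIS})


class ExclusionReason:
    MOA_CLASS_NOT_RETAINED = "MOA_CLASS_NOT_RETAINED"
    UNCLASSIFIED = "UNCLASSIFIED"
    DUPLICATE = "DUPLICATE"


@dataclass(frozen=True)
class ScreenedRecord:
    """A record with its TRO evaluation and, when excluded, the reason."""

    record: CompoundRecord
    tro: TROResult
    reason: Optional[str] = None


@dataclass
class ScreeningReport:
    """Before/after comparison of the baseline QSAR fit.

    ``model_initial`` is fitted on every TRO-computable (deduplicated)
    record; ``model_screened`` on the retained MOA classes only.
    """

    model_initial: QSARModel
    model_screened: QSARModel
    retained: List[ScreenedRecord]
    excluded: List[ScreenedRecord]
    improvement: ImprovementResult
    thresholds: ClassThresholds = field(default_factory=ClassThresholds)
    convention: TROConvention = TROConvention.ABSOLUTE
    retain: frozenset = DEFAULT_RETAIN

    def to_dict(self) -> dict:
        def entry(item: ScreenedRecord) -> dict:
            rec, tro = item.record, item.tro
            out = {
                "name": rec.name,
                "cas": rec.cas,
                "abbreviation": rec.abbreviation,
                "log_kow": rec.log_kow,
                "log_lc50": rec.endpoints.resolved_log_lc50(),
                "log_noec": rec.endpoints.resolved_log_noec(),
                "log_tro_signed": tro.log_tro_signed,
                "log_tro_abs": tro.log_tro_abs,
                "moa": tro.moa.value,
                "flags": sorted(f.value for f in tro.flags),
            }
            if item.reason is not None:
                out["reason"] = item.reason
            return out

        return {
            "settings": {
                "thresholds": {
                    "narcosis_upper": self.thresholds.narcosis_upper,
                    "reactive_lower": self.thresholds.reactive_lower,
                },
                "convention": self.convention.value,
                "retain": sorted(c.value for c in self.retain),
            },
            "model_initial": self.model_initial.to_dict(),
            "model_screened": self.model_screened.to_dict(),
            "improvement": self.improvement.to_dict(),
            "retained": [entry(r) for r in self.retained],
            "excluded": [entry(r) for r in self.excluded],
        }


def screen(
    records: Sequence[CompoundRecord],
    thresholds: Optional[ClassThresholds] = None,
    retain: Iterable[MOAClass] = DEFAULT_RETAIN,
    convention: TROConvention = TROConvention.ABSOLUTE,
    dedupe: bool = True,
) -> Tuple[List[ScreenedRecord], List[ScreenedRecord]]:
    """Partition records into (retained, excluded) by MOA class.

    With ``dedupe`` on, records sharing a CAS number keep only the first
    occurrence (later ones excluded with reason DUPLICATE). Input order
    is preserved in both outputs. Records whose endpoints cannot yield a
    TRO are excluded as UNCLASSIFIED, never dropped silently.
    """
    records = list(records)
    if not records:
        raise InvalidInputError("screen requires at least one record")
    thresholds = thresholds or ClassThresholds()
    retain_set: Set[MOAClass] = {MOAClass(c) for c in retain}

    retained: List[ScreenedRecord] = []
    excluded: List[ScreenedRecord] = []
    seen_cas: Set[str] = set()
    for record in records:
        tro = evaluate_record(record, thresholds, convention)
        if dedupe and record.cas is not None:
            if record.cas in seen_cas:
                excluded.append(ScreenedRecord(record, tro, ExclusionReason.DUPLICATE))
                continue
            seen_cas.add(record.cas)
        if tro.moa is MOAClass.UNCLASSIFIED:
            excluded.append(ScreenedRecord(record, tro, ExclusionReason.UNCLASSIFIED))
        elif tro.moa not in retain_set:
            excluded.append(
                ScreenedRecord(record, tro, ExclusionReason.MOA_CLASS_NOT_RETAINED)
            )
        else:
            retained.append(ScreenedRecord(record, tro))
    return retained, excluded


def _fit_stage(items: Sequence[ScreenedRecord], stage: str) -> QSARModel:
    xs, ys = [], []
    for item in items:
        if item.record.log_kow is None:
            continue
        y = item.record.endpoints.resolved_log_lc50()
        if y is None:
            continue
        xs.append(item.record.log_kow)
        ys.append(y)
    try:
        return fit_linear_qsar(xs, ys)
    except TroqsarError as exc:
        raise type(exc)(f"{stage} fit failed: {exc}") from exc


def compare_fit(
    records: Sequence[CompoundRecord],
    thresholds: Optional[ClassThresholds] = None,
    retain: Iterable[MOAClass] = DEFAULT_RETAIN,
    convention: TROConvention = TROConvention.ABSOLUTE,
    dedupe: bool = True,
) -> ScreeningReport:
    """Fit the baseline model with and without TRO screening.

    The initial ("without TRO") model uses all TRO-computable records
    after deduplication, including transition/reactive ones; the screened
    model uses the retained classes only.
    """
    thresholds = thresholds or ClassThresholds()
    convention = TROConvention(convention)
    retain_set = frozenset(MOAClass(c) for c in retain)
    retained, excluded = screen(records, thresholds, retain_set, convention, dedupe)

    computable = [
        item
        for item in retained + excluded
        if item.reason not in (ExclusionReason.DUPLICATE, ExclusionReason.UNCLASSIFIED)
    ]
    model_initial = _fit_stage(computable, "initial (unscreened)")
    model_screened = _fit_stage(retained, "screened")
    improvement = improvement_percent(
        model_initial.r_squared, model_screened.r_squared
    ) if model_initial.r_squared > 0 and model_screened.r_squared > 0 else ImprovementResult(
        model_initial.r_squared, model_screened.r_squared, float("nan"), float("nan")
    )
    return ScreeningReport(
        model_initial=model_initial,
        model_screened=model_screened,
        retained=retained,
        excluded=excluded,
        improvement=improvement,
        thresholds=thresholds,
        convention=convention,
        retain=retain_set,
    )


@dataclass(frozen=True)
class DescriptorTier:
    """Recommended descriptor tier for a MOA class."""

    tier: str
    fittable_here: bool
    note: str = ""


_TIERS = {
    MOAClass.NARCOSIS: DescriptorTier(
        "2D: log KOW",
        True,
        "baseline toxicity is well predicted by hydrophobicity alone",
    ),
    MOAClass.TRANSITION: DescriptorTier(
        "2D with caution",
        True,
        "mixed mode of action; a correction method is deferred to future work",
    ),
    MOAClass.REACTIVE: DescriptorTier(
        "3D/quantum descriptors",
        False,
        "excess toxicity requires quantum-chemical descriptors; "
        "not fittable by this package",
    ),
    MOAClass.UNCLASSIFIED: DescriptorTier(
        "insufficient data",
        False,
        "endpoints do not determine a TRO",
    ),
}


def select_descriptor_tier(moa: MOAClass) -> DescriptorTier:
    """Descriptor-tier recommendation for a classified compound."""
    return _TIERS[MOAClass(moa)]
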