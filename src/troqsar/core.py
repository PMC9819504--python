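"""Domain model for the toxicity rank order (TRO) statistic.

The TRO of a compound is the ratio of its acute toxicity endpoint (LC50,
the concentration lethal to 50% of exposed organisms) to its chronic
endpoint (NOEC, the highest tested concentration without observed effect).
Worked with in base-10 log space,

    log TRO = log10(LC50) - log10(NOEC),

the statistic separates modes of toxic action: baseline (narcosis)
compounds show little acute/chronic separation, while reactive compounds —
whose toxicity is driven by specific covalent or receptor interactions
rather than accumulation — show a large separation. The class boundaries
used here are |log TRO| < 1 for narcosis, 1 <= |log TRO| < 3 for the
transition regime, and |log TRO| >= 3 for reactive compounds.

All concentrations are mg/L; the ratio itself is unit-free, but the two
endpoints must share units (a caller responsibility — see the I/O module
contract).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

from .exceptions import InvalidInputError

__all__ = [
    "MOAClass",
    "TROConvention",
    "QCFlag",
    "ClassThresholds",
    "ToxicityEndpoints",
    "CompoundRecord",
    "TROResult",
    "compute_log_tro",
    "compute_log_tro_from_concentrations",
    "classify_moa",
    "evaluate_record",
]

_CAS_PATTERN = re.compile(r"^\d{1,7}-\d{2}-\d$")

#: Tolerance for agreement between a concentration and its supplied log.
LOG_CONC_AGREEMENT_TOL = 1e-6


class MOAClass(str, Enum):
    """Mode-of-action class assigned from |log TRO|."""

    NARCOSIS = "NARCOSIS"
    TRANSITION = "TRANSITION"
    REACTIVE = "REACTIVE"
    UNCLASSIFIED = "UNCLASSIFIED"

    @property
    def severity(self) -> Optional[int]:
        """Ordinal class index (narcosis 0 .. reactive 2); None if unclassified."""
        order = {"NARCOSIS": 0, "TRANSITION": 1, "REACTIVE": 2}
        return order.get(self.value)


class TROConvention(str, Enum):
    """Sign convention for log TRO.

    ``ABSOLUTE`` reports |log LC50 - log NOEC| (reproduces published
    tables, where NOEC occasionally exceeds LC50); ``SIGNED`` keeps the
    raw difference.
    """

    ABSOLUTE = "absolute"
    SIGNED = "signed"


class QCFlag(str, Enum):
    """Quality-control flags attached to a TRO evaluation."""

    MISSING_ENDPOINT = "MISSING_ENDPOINT"
    NOEC_EXCEEDS_LC50 = "NOEC_EXCEEDS_LC50"
    CONFLICTING_ENDPOINT = "CONFLICTING_ENDPOINT"


@dataclass(frozen=True)
class ClassThresholds:
    """log-TRO boundaries of the mode-of-action partition.

    Intervals are half-open: narcosis [0, narcosis_upper), transition
    [narcosis_upper, reactive_lower), reactive [reactive_lower, inf).
    """

    narcosis_upper: float = 1.0
    reactive_lower: float = 3.0

    def __post_init__(self) -> None:
        if not (0 < self.narcosis_upper < self.reactive_lower):
            raise InvalidInputError(
                "thresholds must satisfy 0 < narcosis_upper < reactive_lower; "
                f"got narcosis_upper={self.narcosis_upper}, "
                f"reactive_lower={self.reactive_lower}"
            )


def _check_finite(value: float, name: str) -> float:
    try:
        value = float(value)
    except (TypeError, ValueError) as exc:
        raise InvalidInputError(f"{name} is not a number: {value!r}") from exc
    if not math.isfinite(value):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    return value


@dataclass(frozen=True)
class ToxicityEndpoints:
    """Acute (LC50) and chronic (NOEC) endpoints, as concentrations (mg/L)
    and/or their base-10 logs.

    Either member of each pair may be given; when both are given they must
    agree to within ``LOG_CONC_AGREEMENT_TOL`` in log space, otherwise the
    log value takes precedence and evaluation raises a
    ``CONFLICTING_ENDPOINT`` flag.
    """

    lc50: Optional[float] = None
    log_lc50: Optional[float] = None
    noec: Optional[float] = None
    log_noec: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("lc50", "noec"):
            value = getattr(self, name)
            if value is None:
                continue
            value = _check_finite(value, name)
            if value <= 0:
                raise InvalidInputError(
                    f"{name} must be a strictly positive concentration (mg/L), got {value}"
                )
        for name in ("log_lc50", "log_noec"):
            if getattr(self, name) is not None:
                _check_finite(getattr(self, name), name)

    def resolved_log_lc50(self) -> Optional[float]:
        """log10 LC50, preferring the supplied log over the concentration."""
        if self.log_lc50 is not None:
            return float(self.log_lc50)
        if self.lc50 is not None:
            return math.log10(self.lc50)
        return None

    def resolved_log_noec(self) -> Optional[float]:
        if self.log_noec is not None:
            return float(self.log_noec)
        if self.noec is not None:
            return math.log10(self.noec)
        return None

    def conflicts(self) -> bool:
        """True if any concentration disagrees with its supplied log."""
        for conc, log in ((self.lc50, self.log_lc50), (self.noec, self.log_noec)):
            if conc is not None and log is not None:
                if abs(math.log10(conc) - log) > LOG_CONC_AGREEMENT_TOL:
                    return True
        return False

    @property
    def is_tro_computable(self) -> bool:
        return (
            self.resolved_log_lc50() is not None
            and self.resolved_log_noec() is not None
        )


@dataclass
class CompoundRecord:
    """One compound: identity, hydrophobicity descriptor and endpoints.

    ``log_kow`` is the base-10 log octanol-water partition coefficient,
    the single descriptor of the 2D baseline-toxicity QSAR. ``extra``
    carries passthrough table columns and annotations (e.g. the printed
    reference values of the packaged fixture) verbatim.
    """

    name: str
    endpoints: ToxicityEndpoints = field(default_factory=ToxicityEndpoints)
    cas: Optional[str] = None
    abbreviation: Optional[str] = None
    smiles: Optional[str] = None
    log_kow: Optional[float] = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.name or not str(self.name).strip():
            raise InvalidInputError("compound name must be non-empty")
        if self.cas is not None and not _CAS_PATTERN.match(self.cas):
            raise InvalidInputError(
                f"CAS number {self.cas!r} does not match the digits-digits-digit pattern"
            )
        if self.log_kow is not None:
            self.log_kow = _check_finite(self.log_kow, "log_kow")


@dataclass(frozen=True)
class TROResult:
    """Outcome of evaluating one record: signed and absolute log TRO,
    the assigned MOA class, and any QC flags."""

    log_tro_signed: Optional[float]
    log_tro_abs: Optional[float]
    moa: MOAClass
    flags: frozenset = frozenset()

    def has_flag(self, flag: QCFlag) -> bool:
        return flag in self.flags


def compute_log_tro(
    log_lc50: float,
    log_noec: float,
    convention: TROConvention = TROConvention.ABSOLUTE,
) -> float:
    """log TRO from log-space endpoints.

    Returns ``log_lc50 - log_noec`` under the signed convention and its
    absolute value under the absolute convention (the default, which
    reproduces published tables).
    """
    log_lc50 = _check_finite(log_lc50, "log_lc50")
    log_noec = _check_finite(log_noec, "log_noec")
    diff = log_lc50 - log_noec
    if TROConvention(convention) is TROConvention.ABSOLUTE:
        return abs(diff)
    return diff


def compute_log_tro_from_concentrations(
    lc50: float,
    noec: float,
    convention: TROConvention = TROConvention.ABSOLUTE,
) -> float:
    """log TRO from linear-scale concentrations (mg/L, same units both)."""
    lc50 = _check_finite(lc50, "lc50")
    noec = _check_finite(noec, "noec")
    if lc50 <= 0:
        raise InvalidInputError(f"lc50 must be > 0, got {lc50}")
    if noec <= 0:
        raise InvalidInputError(f"noec must be > 0, got {noec}")
    return compute_log_tro(math.log10(lc50), math.log10(noec), convention)


def classify_moa(
    log_tro: float,
    thresholds: Optional[ClassThresholds] = None,
) -> MOAClass:
    """Assign the MOA class from |log TRO|.

    Half-open intervals: narcosis [0, 1), transition [1, 3), reactive
    [3, inf) under the default thresholds. A signed value may be passed;
    its absolute value is classified.
    """
    thresholds = thresholds or ClassThresholds()
    magnitude = abs(_check_finite(log_tro, "log_tro"))
    if magnitude < thresholds.narcosis_upper:
        return MOAClass.NARCOSIS
    if magnitude < thresholds.reactive_lower:
        return MOAClass.TRANSITION
    return MOAClass.REACTIVE


def evaluate_record(
    record: CompoundRecord,
    thresholds: Optional[ClassThresholds] = None,
    convention: TROConvention = TROConvention.ABSOLUTE,
) -> TROResult:
    """Evaluate one record: TRO, MOA class and QC flags.

    Never raises on incomplete data — records whose endpoints do not
    determine a TRO come back UNCLASSIFIED with a ``MISSING_ENDPOINT``
    flag.
    """
    thresholds = thresholds or ClassThresholds()
    convention = TROConvention(convention)
    flags = set()
    ep = record.endpoints
    log_lc50 = ep.resolved_log_lc50()
    log_noec = ep.resolved_log_noec()
    if log_lc50 is None or log_noec is None:
        flags.add(QCFlag.MISSING_ENDPOINT)
        return TROResult(None, None, MOAClass.UNCLASSIFIED, frozenset(flags))
    if ep.conflicts():
        flags.add(QCFlag.CONFLICTING_ENDPOINT)
    signed = log_lc50 - log_noec
    if signed < 0:
        flags.add(QCFlag.NOEC_EXCEEDS_LC50)
    moa = classify_moa(signed, thresholds)
    return TROResult(signed, abs(signed), moa, frozenset(flags))
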