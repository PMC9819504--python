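"""Descriptor provenance and a convenience log KOW estimator.

User-supplied log KOW values (e.g. from a published table) are always
primary; estimation only fills gaps, and every estimated value carries a
provenance label naming the estimator. The estimator offered here is
RDKit's Crippen atom-contribution logP — a transparent, open method; it
is not, and does not claim to be, any particular proprietary
fragment-contribution program.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from .core import CompoundRecord
from .exceptions import InvalidInputError
from .io import Finding

__all__ = [
    "DescriptorSource",
    "estimate_log_kow",
    "fill_missing_log_kow",
    "validate_descriptor_table",
    "LOG_KOW_SANITY_BOUND",
]

#: |log KOW| beyond this is flagged OUT_OF_RANGE (generous margin over
#: the most hydrophobic compounds in the packaged fixture).
LOG_KOW_SANITY_BOUND = 12.0

PROVENANCE_KEY = "log_kow_source"


@dataclass(frozen=True)
class DescriptorSource:
    """Where a descriptor value came from."""

    source: str  # "USER_SUPPLIED" | "ESTIMATED"
    method_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.source not in ("USER_SUPPLIED", "ESTIMATED"):
            raise InvalidInputError(f"unknown descriptor source {self.source!r}")
        if self.source == "ESTIMATED" and not self.method_label:
            raise InvalidInputError("ESTIMATED descriptors must carry a method_label")


def _method_label() -> str:
    import rdkit

    return f"rdkit-crippen-logp-{rdkit.__version__}"


def estimate_log_kow(smiles: str) -> Tuple[float, DescriptorSource]:
    """Estimate log KOW from SMILES via Crippen atom contributions.

    Deterministic for a given input and RDKit version; the molecule is
    canonicalised on parse, so equivalent SMILES give identical values.
    Raises InvalidInputError for unparseable SMILES.
    """
    from rdkit import Chem
    from rdkit.Chem import Crippen

    if not smiles or not smiles.strip():
        raise InvalidInputError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidInputError(f"cannot parse SMILES {smiles!r}")
    return float(Crippen.MolLogP(mol)), DescriptorSource("ESTIMATED", _method_label())


def fill_missing_log_kow(records: Sequence[CompoundRecord]) -> List[CompoundRecord]:
    """Return copies with log KOW estimated where absent and SMILES given.

    User-supplied values are never overwritten; provenance is recorded in
    each record's ``extra`` under ``log_kow_source``.
    """
    out: List[CompoundRecord] = []
    for rec in records:
        rec = copy.deepcopy(rec)
        if rec.log_kow is not None:
            rec.extra.setdefault(PROVENANCE_KEY, "USER_SUPPLIED")
        elif rec.smiles is not None:
            value, source = estimate_log_kow(rec.smiles)
            rec.log_kow = value
            rec.extra[PROVENANCE_KEY] = f"{source.source}:{source.method_label}"
        out.append(rec)
    return out


def validate_descriptor_table(records: Sequence[CompoundRecord]) -> List[Finding]:
    """QC scan of descriptor values; pure (records are not mutated).

    Flags missing log KOW (MISSING_DESCRIPTOR), implausible magnitudes
    (OUT_OF_RANGE), and a mixture of user-supplied and estimated values
    within one table (MIXED_PROVENANCE).
    """
    findings: List[Finding] = []
    provenances = set()
    for i, rec in enumerate(records, start=1):
        if rec.log_kow is None:
            hint = "" if rec.smiles else " and no SMILES to estimate from"
            findings.append(
                Finding(
                    "MISSING_DESCRIPTOR",
                    f"row {i} ({rec.name}): no log_kow{hint}",
                    i,
                    "log_kow",
                )
            )
            continue
        if abs(rec.log_kow) > LOG_KOW_SANITY_BOUND:
            findings.append(
                Finding(
                    "OUT_OF_RANGE",
                    f"row {i} ({rec.name}): log_kow = {rec.log_kow} exceeds "
                    f"|log KOW| <= {LOG_KOW_SANITY_BOUND}",
                    i,
                    "log_kow",
                )
            )
        prov = rec.extra.get(PROVENANCE_KEY, "USER_SUPPLIED")
        provenances.add("ESTIMATED" if str(prov).startswith("ESTIMATED") else "USER_SUPPLIED")
    if len(provenances) > 1:
        findings.append(
            Finding(
                "MIXED_PROVENANCE",
                "table mixes user-supplied and estimated log KOW values",
            )
        )
    return findings
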