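"""Shared data model for TP53 evidence integration.

The objects here mirror the tables a cell-line pharmacogenomics screen
produces: per-line TP53 mutation calls, one expression value for the TP53
probe set (201746_at, on the MAS5-150 scale), a copy-number ratio at the
TP53 locus, and per-compound binary signature predictions alongside the
observed drug-sensitivity calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum


class FormatError(ValueError):
    """A table does not conform to the expected dialect."""


class DomainError(ValueError):
    """An input violates a precondition of the analysis."""


class UncallableLineError(DomainError):
    """A cell line with no usable evidence channel cannot be status-called."""


class MutClass(str, Enum):
    """Coarse protein-level consequence classes parsed from HGVS p. notation."""

    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    INFRAME_INDEL = "inframe_indel"
    SPLICE = "splice"
    SILENT = "silent"
    OTHER = "other"


class Label(str, Enum):
    """Binary sensitivity label, for both predictions and observations."""

    SENSITIVE = "sensitive"
    INSENSITIVE = "insensitive"
    MISSING = "missing"


class Status(str, Enum):
    INACTIVATED = "inactivated"
    LIKELY_WT = "likely_wt"


class Evidence(str, Enum):
    """Evidence channels that, when firing, inactivate TP53."""

    MUTATION = "mutation"
    MRNA_LOSS = "mrna_loss"
    BIALLELIC_LOSS = "biallelic_loss"


class Annotation(str, Enum):
    """Flags that qualify a call without changing it."""

    ALLELIC_LOSS = "allelic_loss"
    NMD_LIKELY = "nmd_likely"
    BORDERLINE_MRNA = "borderline_mrna"


@dataclass(frozen=True)
class MutationCall:
    """One TP53 variant on one cell line.

    ``alt_reads``/``ref_reads`` are the supporting/reference read counts when
    the source table provides them; both are ``None`` otherwise. Read counts
    never gate a status call — they are carried for reporting (variant allele
    fraction) only.
    """

    cell_line: str
    protein_change: str
    mut_class: MutClass
    alt_reads: int | None = None
    ref_reads: int | None = None

    def __post_init__(self) -> None:
        if (self.alt_reads is None) != (self.ref_reads is None):
            raise DomainError(
                f"{self.cell_line} {self.protein_change}: alt and ref read "
                "counts must be given together or not at all"
            )
        if self.alt_reads is not None:
            if self.alt_reads < 0 or self.ref_reads < 0:
                raise DomainError("read counts must be non-negative")
            if self.alt_reads + self.ref_reads == 0:
                raise DomainError("alt_reads + ref_reads must be positive")

    @property
    def vaf(self) -> float | None:
        """Variant allele fraction alt/(alt+ref); None without read counts."""
        if self.alt_reads is None:
            return None
        return self.alt_reads / (self.alt_reads + self.ref_reads)


@dataclass
class CellLineRecord:
    """One cell line's full evidence bundle.

    ``mutations is None`` means the mutation channel was not assayed, while an
    empty list means assayed with no TP53 call. ``tp53_mrna``/``cn_ratio`` are
    ``None`` when missing.
    """

    cell_line: str
    mutations: list[MutationCall] | None = field(default_factory=list)
    tp53_mrna: float | None = None
    cn_ratio: float | None = None
    signature_prediction: dict[str, Label] = field(default_factory=dict)
    observed_sensitivity: dict[str, Label] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tp53_mrna is not None and self.tp53_mrna < 0:
            raise DomainError(f"{self.cell_line}: tp53_mrna must be >= 0")
        if self.cn_ratio is not None and self.cn_ratio < 0:
            raise DomainError(f"{self.cell_line}: cn_ratio must be >= 0")

    def prediction_for(self, compound: str) -> Label:
        return self.signature_prediction.get(compound, Label.MISSING)

    def observation_for(self, compound: str) -> Label:
        return self.observed_sensitivity.get(compound, Label.MISSING)


@dataclass(frozen=True)
class TP53StatusCall:
    """Output of the multi-evidence caller for one cell line."""

    cell_line: str
    status: Status
    evidence: frozenset[Evidence]
    annotations: frozenset[Annotation]
    trail: tuple[str, ...]

    def __post_init__(self) -> None:
        if (self.status is Status.INACTIVATED) != bool(self.evidence):
            raise DomainError(
                f"{self.cell_line}: status must be inactivated iff evidence "
                "is non-empty"
            )


def _ratio(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


@dataclass(frozen=True)
class ConfusionMetrics:
    """Confusion counts and derived diagnostics for one binary evaluation.

    Positive class = observed sensitive; test-positive = the signature
    predicts sensitive. Metrics with a zero denominator are NaN (undefined),
    never an exception.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float:
        return _ratio(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _ratio(self.tn, self.tn + self.fp)

    @property
    def ppv(self) -> float:
        return _ratio(self.tp, self.tp + self.fp)

    @property
    def npv(self) -> float:
        return _ratio(self.tn, self.tn + self.fn)

    @property
    def response_rate(self) -> float:
        return _ratio(self.tp + self.fn, self.n)

    def exact(self, name: str):
        """Metric as an exact rational (fractions.Fraction); None if undefined.

        Float division cannot represent e.g. 24/35 exactly, so identities on
        counts (ppv * (tp+fp) == tp) only hold on the exact form.
        """
        from fractions import Fraction

        num, den = {
            "sensitivity": (self.tp, self.tp + self.fn),
            "specificity": (self.tn, self.tn + self.fp),
            "ppv": (self.tp, self.tp + self.fp),
            "npv": (self.tn, self.tn + self.fn),
            "response_rate": (self.tp + self.fn, self.n),
        }[name]
        return Fraction(num, den) if den else None

    def fractions(self) -> dict[str, str]:
        """Metrics as exact ``numerator/denominator`` strings."""
        return {
            "sensitivity": f"{self.tp}/{self.tp + self.fn}",
            "specificity": f"{self.tn}/{self.tn + self.fp}",
            "ppv": f"{self.tp}/{self.tp + self.fp}",
            "npv": f"{self.tn}/{self.tn + self.fn}",
            "response_rate": f"{self.tp + self.fn}/{self.n}",
        }


@dataclass(frozen=True)
class EvaluationScenario:
    """One evaluation of a signature on a (possibly reduced) cohort."""

    label: str
    compound: str
    removed_lines: tuple[str, ...]
    metrics: ConfusionMetrics
    excluded_missing: tuple[str, ...] = ()
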