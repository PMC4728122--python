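"""Multi-evidence TP53 status calling.

TP53 can be inactivated through several mechanisms — inactivating mutations,
DNA loss, or loss of mRNA expression — and a cell line carrying any of them
cannot respond to a TP53-MDM2 inhibitor. The caller integrates the three
evidence channels with deterministic threshold rules:

R1  any mutation of an inactivating consequence class (by default every
    non-silent coding/splice class) inactivates;
R2  TP53 mRNA below 32 on the MAS5-150 scale (probe 201746_at) is mRNA loss
    and inactivates;
R3  copy-number ratio below 0.25 is bi-allelic loss and inactivates.

A line is called ``inactivated`` iff at least one rule fires. Hemizygous
loss (0.25 <= CN < 0.6) alone does NOT inactivate — one wild-type allele can
suffice — and is recorded as an annotation only. Two further annotations
qualify calls without changing them: ``nmd_likely`` when a frameshift or
nonsense mutation co-occurs with mRNA loss (the nonsense-mediated-decay
pattern), and ``borderline_mrna`` when expression sits just above the loss
cutoff (default zone [32, 40): wide enough to flag a value of 33, narrow
enough to leave clearly expressed lines, >= 40, unflagged).

All cutoffs are strict inequalities: expression of exactly 32 is not loss.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from sklearn.base import BaseEstimator

from .model import (
    Annotation,
    CellLineRecord,
    DomainError,
    Evidence,
    MutClass,
    Status,
    TP53StatusCall,
    UncallableLineError,
)

log = logging.getLogger(__name__)

DEFAULT_INACTIVATING_CLASSES = frozenset(
    {
        MutClass.MISSENSE,
        MutClass.NONSENSE,
        MutClass.FRAMESHIFT,
        MutClass.INFRAME_INDEL,
        MutClass.SPLICE,
    }
)


@dataclass(frozen=True)
class Thresholds:
    """Cutoffs the three rules and the annotations depend on.

    ``cn_allelic_loss``/``cn_biallelic_loss`` are CN ratios (1.0 = diploid);
    ``mrna_loss`` and the borderline margin are in MAS5-150 expression units.
    The borderline zone is ``[mrna_loss, mrna_loss + mrna_borderline_margin)``.
    """

    cn_allelic_loss: float = 0.6
    cn_biallelic_loss: float = 0.25
    mrna_loss: float = 32.0
    mrna_borderline_margin: float = 8.0
    inactivating_classes: frozenset[MutClass] = DEFAULT_INACTIVATING_CLASSES

    def __post_init__(self) -> None:
        if not 0 <= self.cn_biallelic_loss < self.cn_allelic_loss:
            raise DomainError("need 0 <= cn_biallelic_loss < cn_allelic_loss")
        if self.mrna_loss <= 0:
            raise DomainError("mrna_loss must be positive")
        if self.mrna_borderline_margin < 0:
            raise DomainError("mrna_borderline_margin must be >= 0")

    def as_dict(self) -> dict:
        return {
            "cn_allelic_loss": self.cn_allelic_loss,
            "cn_biallelic_loss": self.cn_biallelic_loss,
            "mrna_loss": self.mrna_loss,
            "mrna_borderline_margin": self.mrna_borderline_margin,
            "inactivating_classes": sorted(c.value for c in self.inactivating_classes),
        }


def call_tp53_status(record: CellLineRecord, t: Thresholds | None = None) -> TP53StatusCall:
    """Call one cell line's TP53 status from its evidence bundle.

    The three rules are tested independently; the trail records every rule
    with its inputs, including rules that did not fire or were skipped for
    missing evidence. A line with no usable channel at all is uncallable.
    """
    t = t or Thresholds()
    has_mut = record.mutations is not None
    has_mrna = record.tp53_mrna is not None
    has_cn = record.cn_ratio is not None
    if not (has_mut or has_mrna or has_cn):
        raise UncallableLineError(f"{record.cell_line}: no evidence channel present")

    evidence: set[Evidence] = set()
    annotations: set[Annotation] = set()
    trail: list[str] = []
    fired_classes: set[MutClass] = set()

    if has_mut:
        for m in record.mutations:
            inact = m.mut_class in t.inactivating_classes
            vaf = f", VAF={m.vaf:.2f}" if m.vaf is not None else ""
            trail.append(
                f"R1 mutation {m.protein_change} class={m.mut_class.value}{vaf}: "
                + ("inactivating" if inact else "not inactivating")
            )
            if inact:
                evidence.add(Evidence.MUTATION)
                fired_classes.add(m.mut_class)
        if not record.mutations:
            trail.append("R1 mutation: no TP53 calls")
    else:
        trail.append("R1 mutation: channel missing, skipped")

    if has_mrna:
        v = record.tp53_mrna
        if v < t.mrna_loss:
            evidence.add(Evidence.MRNA_LOSS)
            trail.append(f"R2 mRNA {v:g} < {t.mrna_loss:g}: mRNA loss")
        elif v < t.mrna_loss + t.mrna_borderline_margin:
            annotations.add(Annotation.BORDERLINE_MRNA)
            trail.append(
                f"R2 mRNA {v:g} in borderline zone "
                f"[{t.mrna_loss:g}, {t.mrna_loss + t.mrna_borderline_margin:g})"
            )
        else:
            trail.append(f"R2 mRNA {v:g} >= {t.mrna_loss:g}: expressed")
    else:
        trail.append("R2 mRNA: channel missing, skipped")

    if has_cn:
        c = record.cn_ratio
        if c < t.cn_biallelic_loss:
            evidence.add(Evidence.BIALLELIC_LOSS)
            trail.append(f"R3 CN {c:g} < {t.cn_biallelic_loss:g}: bi-allelic loss")
        elif c < t.cn_allelic_loss:
            annotations.add(Annotation.ALLELIC_LOSS)
            trail.append(
                f"R3 CN {c:g} in [{t.cn_biallelic_loss:g}, {t.cn_allelic_loss:g}): "
                "allelic loss (annotation only)"
            )
        else:
            trail.append(f"R3 CN {c:g} >= {t.cn_allelic_loss:g}: no loss")
    else:
        trail.append("R3 CN: channel missing, skipped")

    if (
        Evidence.MUTATION in evidence
        and Evidence.MRNA_LOSS in evidence
        and fired_classes & {MutClass.FRAMESHIFT, MutClass.NONSENSE}
    ):
        annotations.add(Annotation.NMD_LIKELY)
        trail.append("NMD: frameshift/nonsense mutation with mRNA loss -> nmd_likely")

    status = Status.INACTIVATED if evidence else Status.LIKELY_WT
    trail.append(f"status={status.value}")
    return TP53StatusCall(
        cell_line=record.cell_line,
        status=status,
        evidence=frozenset(evidence),
        annotations=frozenset(annotations),
        trail=tuple(trail),
    )


class TP53Caller(BaseEstimator):
    """Rule-based TP53-inactivation classifier over evidence bundles.

    A deterministic, threshold-based classifier in estimator clothing so it
    composes with sklearn tooling: ``fit`` validates the thresholds (there is
    nothing to learn), ``predict`` maps :class:`CellLineRecord` objects to
    :class:`TP53StatusCall` objects.

    Parameters mirror :class:`Thresholds`; ``inactivating_classes`` accepts
    any iterable of :class:`MutClass` or their string values.
    """

    def __init__(
        self,
        cn_allelic_loss: float = 0.6,
        cn_biallelic_loss: float = 0.25,
        mrna_loss: float = 32.0,
        mrna_borderline_margin: float = 8.0,
        inactivating_classes=tuple(sorted(c.value for c in DEFAULT_INACTIVATING_CLASSES)),
    ):
        self.cn_allelic_loss = cn_allelic_loss
        self.cn_biallelic_loss = cn_biallelic_loss
        self.mrna_loss = mrna_loss
        self.mrna_borderline_margin = mrna_borderline_margin
        self.inactivating_classes = inactivating_classes

    def _thresholds(self) -> Thresholds:
        return Thresholds(
            cn_allelic_loss=self.cn_allelic_loss,
            cn_biallelic_loss=self.cn_biallelic_loss,
            mrna_loss=self.mrna_loss,
            mrna_borderline_margin=self.mrna_borderline_margin,
            inactivating_classes=frozenset(
                MutClass(c) for c in self.inactivating_classes
            ),
        )

    def fit(self, X=None, y=None):
        self.thresholds_ = self._thresholds()
        return self

    def predict(self, records: list[CellLineRecord]) -> list[TP53StatusCall]:
        if not hasattr(self, "thresholds_"):
            self.fit()
        return call_cohort(records, self.thresholds_)


def call_cohort(
    records: list[CellLineRecord], t: Thresholds | None = None
) -> list[TP53StatusCall]:
    """Call every record, preserving order; logs summary counts.

    Per-record errors are re-raised with the offending cell line named.
    """
    if not records:
        raise DomainError("cannot call an empty cohort")
    t = t or Thresholds()
    calls = []
    for rec in records:
        try:
            calls.append(call_tp53_status(rec, t))
        except DomainError as e:
            raise type(e)(f"{rec.cell_line}: {e}") from e
    n_inact = sum(c.status is Status.INACTIVATED for c in calls)
    n_border = sum(Annotation.BORDERLINE_MRNA in c.annotations for c in calls)
    log.info(
        "called %d lines: %d inactivated, %d likely_wt, %d borderline",
        len(calls), n_inact, len(calls) - n_inact, n_border,
    )
    return calls
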