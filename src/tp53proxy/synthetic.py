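"""Synthetic multi-omic cohorts with the structure the proxy argument assumes.

The generator emulates a cell-line panel screened against a TP53-MDM2
inhibitor: a latent binary TP53 status per line, one inactivation mechanism
per inactivated line (mutation, mRNA loss, or bi-allelic DNA loss), a binary
signature prediction that tracks the latent status with configurable
concordance, and observed sensitivity that is Bernoulli among truly
wild-type lines and always "insensitive" for inactivated lines (the
mechanistic premise: only WT-TP53 lines can respond). Expression lives on
the MAS5-150 scale — log-normal for mRNA-intact lines with a near-zero
point mass for mRNA-loss lines — and CN ratios are normal around 1 with
loss tails. Frameshift-mutant lines additionally lose expression with
probability ``nmd_rate`` so the nonsense-mediated-decay annotation path is
exercised.

Defaults encode the study conditions of the re-analysis this package
implements: 23% of a nominally wild-type panel inactivated (12/52), a WT
response rate of 0.675 (27/40), mechanism mix ~9:2:1
mutation : mRNA-loss : CN-loss (mutations dominate, as in the observed
twelve), signature concordance 0.9 (a good but imperfect proxy).

Randomness: one global seed feeds a per-line counter-based SeedSequence
stream, so draws for line *i* never depend on how many lines precede it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import CellLineRecord, DomainError, Label, MutationCall
from .io import load_table1, parse_protein_change

#: protein-change templates spanning every inactivating consequence class;
#: frameshift templates trigger the simulated-NMD branch.
MUTATION_TEMPLATES = (
    "p.R175H", "p.R248Q", "p.R273H", "p.C135R", "p.P27L",   # missense
    "p.R196*", "p.R213*",                                    # nonsense
    "p.C229fs", "p.T284fs", "p.F270fs",                      # frameshift
    "p.PPQH190del",                                          # in-frame indel
    "p.I332_splice",                                         # splice
)


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """All generator knobs; defaults are the study conditions (see module doc)."""

    n_lines: int = 52
    frac_inactivated: float = 12 / 52
    wt_response_rate: float = 0.675
    signature_concordance: float = 0.9
    mech_by_mutation: float = 9 / 12
    mech_by_mrna_loss: float = 2 / 12
    mech_by_cn_loss: float = 1 / 12
    nmd_rate: float = 0.5
    expr_wt_logmean: float = math.log(250.0)
    expr_wt_logsd: float = 0.5
    expr_loss_max: float = 20.0
    cn_mean: float = 1.0
    cn_sd: float = 0.15
    cn_loss_max: float = 0.25
    compound: str = "NVP-CGM097"
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines <= 0:
            raise DomainError("n_lines must be positive")
        for name in ("frac_inactivated", "wt_response_rate", "signature_concordance"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise DomainError(f"{name} must be in [0, 1]")
        mix = self.mech_by_mutation + self.mech_by_mrna_loss + self.mech_by_cn_loss
        if abs(mix - 1.0) > 1e-9:
            raise DomainError("mechanism mix must sum to 1")
        if min(self.mech_by_mutation, self.mech_by_mrna_loss, self.mech_by_cn_loss) < 0:
            raise DomainError("mechanism fractions must be non-negative")
        if not 0 <= self.nmd_rate <= 1:
            raise DomainError("nmd_rate must be in [0, 1]")
        if not 0 < self.expr_loss_max < 32.0:
            raise DomainError("expr_loss_max must be in (0, 32): below the mRNA-loss cutoff")
        if self.expr_wt_logsd <= 0 or self.cn_sd <= 0:
            raise DomainError("scale parameters must be positive")
        if not 0 < self.cn_loss_max <= 0.25:
            raise DomainError("cn_loss_max must be in (0, 0.25]: within bi-allelic loss")


def _line_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(i,)))


def _truncated_normal(rng, mean, sd) -> float:
    for _ in range(100):
        v = rng.normal(mean, sd)
        if v >= 0:
            return float(v)
    return 0.0


def generate_cohort(
    cfg: SyntheticCohortConfig,
) -> tuple[list[CellLineRecord], dict[str, str]]:
    """Draw a cohort; returns (records, truth map cell line -> status).

    Truth values are "inactivated" / "wt". Fully reproducible from the
    config seed; line *i*'s draws are independent of every other line.
    """
    cfg.validate()
    width = len(str(cfg.n_lines))
    records, truth = [], {}
    mechs = ("mutation", "mrna_loss", "cn_loss")
    probs = (cfg.mech_by_mutation, cfg.mech_by_mrna_loss, cfg.mech_by_cn_loss)
    for i in range(cfg.n_lines):
        rng = _line_rng(cfg.seed, i)
        name = f"SYN-{i:0{width}d}"
        inactivated = bool(rng.random() < cfg.frac_inactivated)
        truth[name] = "inactivated" if inactivated else "wt"

        mutations: list[MutationCall] = []
        expr = float(rng.lognormal(cfg.expr_wt_logmean, cfg.expr_wt_logsd))
        cn = _truncated_normal(rng, cfg.cn_mean, cfg.cn_sd)
        if inactivated:
            mech = mechs[rng.choice(3, p=probs)]
            if mech == "mutation":
                pchange = str(rng.choice(MUTATION_TEMPLATES))
                alt = int(rng.integers(5, 200))
                ref = int(rng.integers(0, alt + 1))
                mutations.append(
                    MutationCall(
                        cell_line=name,
                        protein_change=pchange,
                        mut_class=parse_protein_change(pchange),
                        alt_reads=alt,
                        ref_reads=ref,
                    )
                )
                is_fs = pchange.endswith("fs")
                if is_fs and rng.random() < cfg.nmd_rate:
                    expr = float(rng.uniform(0, cfg.expr_loss_max))
            elif mech == "mrna_loss":
                expr = float(rng.uniform(0, cfg.expr_loss_max))
            else:  # cn_loss
                cn = float(rng.uniform(0, cfg.cn_loss_max))

        if inactivated:
            obs = Label.INSENSITIVE
            concordant_pred = Label.INSENSITIVE
        else:
            obs = (
                Label.SENSITIVE
                if rng.random() < cfg.wt_response_rate
                else Label.INSENSITIVE
            )
            concordant_pred = Label.SENSITIVE
        if rng.random() < cfg.signature_concordance:
            pred = concordant_pred
        else:
            pred = (
                Label.SENSITIVE
                if concordant_pred is Label.INSENSITIVE
                else Label.INSENSITIVE
            )

        records.append(
            CellLineRecord(
                cell_line=name,
                mutations=mutations,
                tp53_mrna=expr,
                cn_ratio=cn,
                signature_prediction={cfg.compound: pred},
                observed_sensitivity={cfg.compound: obs},
            )
        )
    return records, truth


# ---------------------------------------------------------------------------
# Fixed cohorts


def synthetic_sd1_validation40(compound: str = "NVP-CGM097") -> list[CellLineRecord]:
    """SYNTHETIC stand-in for the 40-line likely-WT validation set.

    The real supplementary per-line table is not redistributed here; this
    reconstruction realizes every published marginal of that set exactly:
    tp=24, fn=3, fp=11, tn=2 (sensitivity 24/27, specificity 2/13, PPV
    24/35, NPV 2/5, response rate 27/40), with DAN-G one of the two true
    negatives carrying TP53 mRNA of 33 (just above the loss cutoff, hence
    borderline) and HCC-95 the other. All 40 lines are clean of qualifying
    evidence, so the status caller leaves the set intact. Line names other
    than DAN-G and HCC-95 are synthetic placeholders.
    """
    cells = (
        [("sensitive", "sensitive")] * 24      # tp
        + [("insensitive", "sensitive")] * 3   # fn (predicted insensitive)
        + [("sensitive", "insensitive")] * 11  # fp
    )
    records = []
    for i, (pred, obs) in enumerate(cells):
        records.append(
            CellLineRecord(
                cell_line=f"WTV-{i + 1:02d}",
                mutations=[],
                tp53_mrna=60.0 + 10.0 * i,
                cn_ratio=0.85 + 0.01 * (i % 30),
                signature_prediction={compound: Label(pred)},
                observed_sensitivity={compound: Label(obs)},
            )
        )
    for name, mrna in (("DAN-G", 33.0), ("HCC-95", 180.0)):  # the two tn lines
        records.append(
            CellLineRecord(
                cell_line=name,
                mutations=[],
                tp53_mrna=mrna,
                cn_ratio=1.0,
                signature_prediction={compound: Label.INSENSITIVE},
                observed_sensitivity={compound: Label.INSENSITIVE},
            )
        )
    return records


def synthetic_validation52() -> list[CellLineRecord]:
    """SYNTHETIC 52-line validation panel: the 12 printed inactivated-line
    evidence rows plus the 40-line likely-WT reconstruction."""
    return load_table1() + synthetic_sd1_validation40()


def synthetic_panel113(compound: str = "NVP-CFC218") -> list[CellLineRecord]:
    """SYNTHETIC stand-in for the 113-line nominally-WT panel.

    Realizes the published marginals: 29 of 113 lines carry inactivating
    TP53 alterations (all observed insensitive), and 43 of the remaining 84
    likely-WT lines respond — response rate 43/84 = 51% after filtering vs
    43/113 = 38% before. Inactivated lines cycle through the three
    mechanisms with mutations dominating. Per-line identities and evidence
    values are synthetic placeholders.
    """
    records = []
    for i in range(29):
        name = f"INA-{i + 1:02d}"
        mutations, mrna, cn = [], 150.0 + 5.0 * i, 0.9 + 0.01 * i
        if i < 20:  # mutation mechanism
            pchange = MUTATION_TEMPLATES[i % len(MUTATION_TEMPLATES)]
            mutations = [
                MutationCall(
                    cell_line=name,
                    protein_change=pchange,
                    mut_class=parse_protein_change(pchange),
                    alt_reads=40 + i,
                    ref_reads=i,
                )
            ]
        elif i < 26:  # mRNA loss
            mrna = 2.0 + 3.0 * (i - 20)
        else:  # bi-allelic DNA loss
            cn = 0.05 * (i - 25)
        records.append(
            CellLineRecord(
                cell_line=name,
                mutations=mutations,
                tp53_mrna=mrna,
                cn_ratio=cn,
                signature_prediction={compound: Label.INSENSITIVE},
                observed_sensitivity={compound: Label.INSENSITIVE},
            )
        )
    for i in range(84):
        records.append(
            CellLineRecord(
                cell_line=f"PWT-{i + 1:02d}",
                mutations=[],
                tp53_mrna=80.0 + 4.0 * i,
                cn_ratio=0.9 + 0.005 * i,
                signature_prediction={compound: Label.SENSITIVE},
                observed_sensitivity={
                    compound: Label.SENSITIVE if i < 43 else Label.INSENSITIVE
                },
            )
        )
    return records


# ---------------------------------------------------------------------------
# Writers (emit the dialects tp53proxy.io reads)


def write_cohort(records: list[CellLineRecord], outdir, truth: dict | None = None):
    """Write a cohort as the four evidence tables (+ truth map if given).

    Emits mutations.tsv, expression.tsv (single-probe matrix for 201746_at),
    cn.tsv, calls.tsv and optionally truth.tsv under ``outdir``. Output is
    byte-stable for fixed input.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    mut_rows = []
    for r in records:
        for m in r.mutations or []:
            mut_rows.append(
                {
                    "cell_line": m.cell_line,
                    "gene": "TP53",
                    "protein_change": m.protein_change,
                    "alt_reads": "" if m.alt_reads is None else m.alt_reads,
                    "ref_reads": "" if m.ref_reads is None else m.ref_reads,
                }
            )
    pd.DataFrame(
        mut_rows, columns=["cell_line", "gene", "protein_change", "alt_reads", "ref_reads"]
    ).to_csv(outdir / "mutations.tsv", sep="\t", index=False)

    expressed = [r for r in records if r.tp53_mrna is not None]
    expr = pd.DataFrame(
        {r.cell_line: [r.tp53_mrna] for r in expressed}, index=["201746_at"]
    )
    expr.index.name = "probe_id"
    expr.to_csv(outdir / "expression.tsv", sep="\t", float_format="%.6g")

    cn_rows = [
        {"cell_line": r.cell_line, "cn_ratio": f"{r.cn_ratio:.6g}"}
        for r in records
        if r.cn_ratio is not None
    ]
    pd.DataFrame(cn_rows, columns=["cell_line", "cn_ratio"]).to_csv(
        outdir / "cn.tsv", sep="\t", index=False
    )

    call_rows = []
    for r in records:
        for compound in sorted(set(r.signature_prediction) | set(r.observed_sensitivity)):
            call_rows.append(
                {
                    "cell_line": r.cell_line,
                    "compound": compound,
                    "signature_prediction": r.prediction_for(compound).value,
                    "observed_sensitivity": r.observation_for(compound).value,
                }
            )
    pd.DataFrame(
        call_rows,
        columns=["cell_line", "compound", "signature_prediction", "observed_sensitivity"],
    ).to_csv(outdir / "calls.tsv", sep="\t", index=False)

    if truth is not None:
        pd.DataFrame(
            [{"cell_line": k, "true_status": v} for k, v in truth.items()],
            columns=["cell_line", "true_status"],
        ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    return outdir


def write_fixture_table1(outdir):
    """Emit the 12 printed evidence rows in the four io dialects."""
    return write_cohort(load_table1(), outdir)
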