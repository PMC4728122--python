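"""Filter-then-re-evaluate engine for binary sensitivity signatures.

A signature that was trained without regard to TP53 status can look
predictive on a mixed panel simply by tracking TP53 status: inactivated
lines are mechanistically insensitive to TP53-MDM2 inhibition, so any proxy
for inactivation scores them as easy true negatives. The honest question is
performance *within* the truly wild-type stratum. This module computes
confusion-matrix diagnostics (sensitivity, specificity, PPV, NPV) and the
cohort response rate, filters out caller-flagged inactivated lines, and
re-evaluates — including borderline-removal scenarios for lines whose mRNA
sits just above the loss cutoff.

Conventions: positive class = observed sensitive; test-positive = the
signature predicts sensitive. PPV close to the response rate is the
hallmark of a proxy signature adding no information within the stratum.
"""

from __future__ import annotations

import logging

from .model import (
    Annotation,
    CellLineRecord,
    ConfusionMetrics,
    DomainError,
    EvaluationScenario,
    Label,
    Status,
    TP53StatusCall,
)

log = logging.getLogger(__name__)


def _evaluable(records: list[CellLineRecord], compound: str):
    """Split records into (complete, names-with-missing) for a compound."""
    ok, missing = [], []
    for r in records:
        if (
            r.prediction_for(compound) is Label.MISSING
            or r.observation_for(compound) is Label.MISSING
        ):
            missing.append(r.cell_line)
        else:
            ok.append(r)
    if missing:
        log.warning("%s: excluded %d lines with missing prediction/observation: %s",
                    compound, len(missing), missing)
    return ok, missing


def confusion(records: list[CellLineRecord], compound: str) -> ConfusionMetrics:
    """Tally the confusion matrix of signature prediction vs observed call.

    Every record must carry both a prediction and an observation for the
    compound (incomplete records are excluded upstream); an empty list is a
    domain error. Undefined metrics (zero denominator) come back NaN.
    """
    if not records:
        raise DomainError("cannot evaluate an empty record list")
    tp = fp = tn = fn = 0
    for r in records:
        pred = r.prediction_for(compound)
        obs = r.observation_for(compound)
        if Label.MISSING in (pred, obs):
            raise DomainError(
                f"{r.cell_line}: missing prediction or observation for {compound}"
            )
        if obs is Label.SENSITIVE:
            if pred is Label.SENSITIVE:
                tp += 1
            else:
                fn += 1
        else:
            if pred is Label.SENSITIVE:
                fp += 1
            else:
                tn += 1
    return ConfusionMetrics(tp=tp, fp=fp, tn=tn, fn=fn)


def filter_likely_wt(
    records: list[CellLineRecord], calls: list[TP53StatusCall]
) -> tuple[list[CellLineRecord], list[CellLineRecord]]:
    """Partition records into (likely-WT kept, inactivated removed) by call.

    Pure filter: no record is modified. Every record must have a call.
    """
    by_line = {c.cell_line: c for c in calls}
    kept, removed = [], []
    for r in records:
        call = by_line.get(r.cell_line)
        if call is None:
            raise DomainError(f"no TP53 status call for {r.cell_line}")
        (kept if call.status is Status.LIKELY_WT else removed).append(r)
    return kept, removed


def scenario_remove(
    records: list[CellLineRecord],
    lines_to_remove: list[str],
    label: str,
    compound: str,
) -> EvaluationScenario:
    """Re-evaluate after removing named lines (e.g. a borderline line)."""
    names = {r.cell_line for r in records}
    unknown = sorted(set(lines_to_remove) - names)
    if unknown:
        raise DomainError(f"cannot remove unknown line(s) {unknown}")
    kept = [r for r in records if r.cell_line not in set(lines_to_remove)]
    ok, missing = _evaluable(kept, compound)
    return EvaluationScenario(
        label=label,
        compound=compound,
        removed_lines=tuple(sorted(lines_to_remove)),
        metrics=confusion(ok, compound),
        excluded_missing=tuple(missing),
    )


def evaluate(
    records: list[CellLineRecord],
    calls: list[TP53StatusCall],
    compound: str,
    borderline_policy: str = "both",
) -> list[EvaluationScenario]:
    """Run the standard scenario ladder for one compound.

    Scenarios: (a) all lines; (b) the likely-WT stratum after filtering
    caller-flagged inactivated lines; (c) likely-WT minus lines annotated
    borderline_mrna. ``borderline_policy``: "keep" emits a+b, "drop" emits
    a plus the borderline-free WT scenario, "both" emits all three.
    """
    if borderline_policy not in ("keep", "drop", "both"):
        raise DomainError("borderline_policy must be keep, drop or both")
    by_line = {c.cell_line: c for c in calls}
    kept, removed = filter_likely_wt(records, calls)
    borderline = [
        r.cell_line
        for r in kept
        if Annotation.BORDERLINE_MRNA in by_line[r.cell_line].annotations
    ]

    def scenario(label, recs, removed_names):
        ok, missing = _evaluable(recs, compound)
        return EvaluationScenario(
            label=label,
            compound=compound,
            removed_lines=tuple(sorted(removed_names)),
            metrics=confusion(ok, compound),
            excluded_missing=tuple(missing),
        )

    out = [scenario("all_lines", records, [])]
    wt = scenario("likely_wt", kept, [r.cell_line for r in removed])
    no_border = scenario(
        "likely_wt_no_borderline",
        [r for r in kept if r.cell_line not in set(borderline)],
        [r.cell_line for r in removed] + borderline,
    )
    if borderline_policy in ("keep", "both"):
        out.append(wt)
    if borderline_policy in ("drop", "both"):
        out.append(no_border)
    return out


def wilson_interval(successes: int, n: int, alpha: float = 0.05):
    """Wilson score interval for a binomial proportion (optional extension;
    the core reports print exact fractions only)."""
    from statsmodels.stats.proportion import proportion_confint

    if n == 0:
        return (float("nan"), float("nan"))
    return proportion_confint(successes, n, alpha=alpha, method="wilson")


def waterfall_data(
    records: list[CellLineRecord],
    calls: list[TP53StatusCall],
    compound: str,
):
    """Deterministic per-line table behind the waterfall plot.

    One row per evaluable line, grouped by observed call (sensitive first),
    alphabetical within a group; bar height +1 for observed-sensitive, -1
    for observed-insensitive; color keyed to the signature prediction;
    borderline-annotated lines marked.
    """
    import pandas as pd

    by_line = {c.cell_line: c for c in calls}
    ok, _ = _evaluable(records, compound)
    if not ok:
        raise DomainError("no evaluable lines to plot")
    rows = []
    for r in ok:
        obs = r.observation_for(compound)
        rows.append(
            {
                "cell_line": r.cell_line,
                "observed": obs.value,
                "predicted": r.prediction_for(compound).value,
                "height": 1.0 if obs is Label.SENSITIVE else -1.0,
                "borderline": Annotation.BORDERLINE_MRNA
                in by_line[r.cell_line].annotations,
            }
        )
    df = pd.DataFrame(rows)
    df = df.sort_values(["height", "cell_line"], ascending=[False, True])
    return df.reset_index(drop=True)


def waterfall_plot(
    records: list[CellLineRecord],
    calls: list[TP53StatusCall],
    compound: str,
    path,
):
    """Render the waterfall overview to ``path``; returns the plot table."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    df = waterfall_data(records, calls, compound)
    colors = ["#1f77b4" if p == "sensitive" else "#d62728" for p in df["predicted"]]
    fig, ax = plt.subplots(figsize=(max(6, 0.22 * len(df)), 4))
    ax.bar(range(len(df)), df["height"], color=colors, edgecolor="black", linewidth=0.3)
    for i, b in enumerate(df["borderline"]):
        if b:
            ax.annotate("*", (i, df["height"].iloc[i]), ha="center",
                        va="bottom" if df["height"].iloc[i] > 0 else "top")
    ax.set_xticks(range(len(df)))
    ax.set_xticklabels(df["cell_line"], rotation=90, fontsize=6)
    ax.set_ylabel(f"observed call ({compound})")
    ax.set_yticks([-1, 1])
    ax.set_yticklabels(["insensitive", "sensitive"])
    ax.set_title(
        f"{compound}: bars=observed, color=signature prediction "
        "(blue=sensitive, red=insensitive), *=borderline mRNA"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return df
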