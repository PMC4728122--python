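"""Readers and writers for the evidence tables.

Four plain-text tab-separated inputs are consumed:

* a MAF-dialect mutation table (only four columns are used: sample, gene,
  protein change, read counts — everything else is ignored, so both the
  hybrid-capture and hybrid-capture-plus-RainDance CCLE files load),
* an expression matrix (probes x samples),
* a two-column copy-number-ratio table,
* a four-column predictions/sensitivity table
  (cell line, compound, signature_prediction, observed_sensitivity).

Cell-line names are joined after canonicalization (uppercase, spaces and
hyphens stripped) because public cell-line tables disagree on punctuation;
the spelling from the predictions table is preserved for output.
"""

from __future__ import annotations

import json
import logging
import re
from importlib import resources
from pathlib import Path

import pandas as pd

from .model import (
    Annotation,
    CellLineRecord,
    ConfusionMetrics,
    EvaluationScenario,
    FormatError,
    Label,
    MutationCall,
    MutClass,
    TP53StatusCall,
)

log = logging.getLogger(__name__)

TP53_PROBE = "201746_at"

#: role -> column name maps. DEFAULT_DIALECT matches the tables this package
#: writes; MAF_DIALECT matches CCLE-style MAF files.
DEFAULT_DIALECT = {
    "cell_line": "cell_line",
    "gene": "gene",
    "protein_change": "protein_change",
    "alt_reads": "alt_reads",
    "ref_reads": "ref_reads",
}
MAF_DIALECT = {
    "cell_line": "Tumor_Sample_Barcode",
    "gene": "Hugo_Symbol",
    "protein_change": "Protein_Change",
    "alt_reads": "Alt_Count",
    "ref_reads": "Ref_Count",
}

_HGVS_SUB = re.compile(r"([A-Za-z]+)(\d+)([A-Za-z]+|\*)$")
_FRAMESHIFT = re.compile(r"fs(\*?\d*)?$")
_INDEL = re.compile(r"(del|ins|dup)$")


def parse_protein_change(s: str) -> MutClass:
    """Classify an HGVS p.-notation string into a coarse consequence class.

    Total and deterministic: any string yields a class, unrecognised forms
    fall through to ``other``. A space after the ``p.`` prefix (as printed in
    some tables) is tolerated.
    """
    if not isinstance(s, str):
        return MutClass.OTHER
    t = re.sub(r"^p\.\s*", "", s.strip())
    if not t:
        return MutClass.OTHER
    if "_splice" in t.lower():
        return MutClass.SPLICE
    if _FRAMESHIFT.search(t):
        return MutClass.FRAMESHIFT
    if _INDEL.search(t):
        return MutClass.INFRAME_INDEL
    m = _HGVS_SUB.fullmatch(t)
    if m:
        old, _, new = m.groups()
        if new == "*":
            return MutClass.NONSENSE
        if new == old:
            return MutClass.SILENT
        return MutClass.MISSENSE
    return MutClass.OTHER


def canonical_name(name: str) -> str:
    """Canonical join key for a cell-line name: uppercase, no spaces/hyphens."""
    return name.upper().replace(" ", "").replace("-", "")


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, comment="#")


def read_mutation_table(
    path, dialect: dict[str, str] | None = None, gene: str = "TP53"
) -> list[MutationCall]:
    """Read a MAF-dialect TSV into MutationCalls for ``gene``.

    Only the columns named by ``dialect`` are consumed; read-count columns are
    optional. If the table has no gene column every row is taken. Rows whose
    protein change does not parse get class ``other`` with a logged warning.
    An empty table (header only) yields an empty list.
    """
    d = dict(DEFAULT_DIALECT if dialect is None else dialect)
    df = _read_tsv(path)
    _require_columns(df, [d["cell_line"], d["protein_change"]], path)
    if d.get("gene") in df.columns:
        df = df[df[d["gene"]] == gene]
    have_reads = d.get("alt_reads") in df.columns and d.get("ref_reads") in df.columns
    calls: list[MutationCall] = []
    for _, row in df.iterrows():
        pchange = str(row[d["protein_change"]])
        mclass = parse_protein_change(pchange)
        if mclass is MutClass.OTHER:
            log.warning("%s: unparseable protein change %r -> class=other",
                        row[d["cell_line"]], pchange)
        alt = ref = None
        if have_reads and pd.notna(row[d["alt_reads"]]) and pd.notna(row[d["ref_reads"]]):
            alt, ref = int(row[d["alt_reads"]]), int(row[d["ref_reads"]])
        calls.append(
            MutationCall(
                cell_line=str(row[d["cell_line"]]),
                protein_change=pchange,
                mut_class=mclass,
                alt_reads=alt,
                ref_reads=ref,
            )
        )
    return calls


def read_expression_matrix(path) -> pd.DataFrame:
    """Read a probes x samples TSV matrix (first column = probe-set id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    return df.astype(float)


def read_cn_table(path) -> pd.Series:
    """Read a two-column TSV (cell line, CN ratio) into a Series."""
    df = _read_tsv(path)
    _require_columns(df, list(df.columns[:2]), path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected two columns (cell line, CN ratio)")
    return pd.Series(
        df.iloc[:, 1].astype(float).values, index=df.iloc[:, 0].astype(str).values
    )


def read_calls_table(path) -> pd.DataFrame:
    """Read the predictions/sensitivity table.

    Columns: cell_line, compound, signature_prediction, observed_sensitivity.
    """
    df = _read_tsv(path)
    _require_columns(
        df,
        ["cell_line", "compound", "signature_prediction", "observed_sensitivity"],
        path,
    )
    dup = df[df.duplicated(["cell_line", "compound"], keep=False)]
    if not dup.empty:
        names = sorted(dup["cell_line"].unique())
        raise FormatError(f"{path}: duplicate cell-line rows for {names}")
    return df


def _label(x) -> Label:
    if pd.isna(x) or x == "":
        return Label.MISSING
    return Label(str(x))


def read_cohort(
    mut_path,
    expr_path,
    cn_path,
    calls_path,
    probe_id: str = TP53_PROBE,
    compound: str | None = None,
    dialect: dict[str, str] | None = None,
) -> list[CellLineRecord]:
    """Join the four evidence tables into one record per cell line.

    One record is produced per cell line in the predictions table; evidence is
    joined by canonicalized name. Lines absent from the expression or CN
    tables get ``None`` markers and a logged warning — missing evidence is
    never imputed.
    """
    muts = read_mutation_table(mut_path, dialect=dialect)
    expr = read_expression_matrix(expr_path)
    if probe_id not in expr.index:
        raise FormatError(f"{expr_path}: probe {probe_id!r} not in matrix index")
    cn = read_cn_table(cn_path)
    calls = read_calls_table(calls_path)
    if compound is not None:
        calls = calls[calls["compound"] == compound]

    mut_by_line: dict[str, list[MutationCall]] = {}
    for m in muts:
        mut_by_line.setdefault(canonical_name(m.cell_line), []).append(m)
    expr_by_line = {canonical_name(c): float(expr.loc[probe_id, c]) for c in expr.columns}
    cn_by_line = {canonical_name(k): float(v) for k, v in cn.items()}

    records: dict[str, CellLineRecord] = {}
    for _, row in calls.iterrows():
        name = str(row["cell_line"])
        key = canonical_name(name)
        if key not in records:
            mrna = expr_by_line.get(key)
            ratio = cn_by_line.get(key)
            if mrna is None:
                log.warning("%s: no expression value; mRNA rule will be skipped", name)
            if ratio is None:
                log.warning("%s: no CN ratio; CN rules will be skipped", name)
            records[key] = CellLineRecord(
                cell_line=name,
                mutations=mut_by_line.get(key, []),
                tp53_mrna=mrna,
                cn_ratio=ratio,
            )
        rec = records[key]
        rec.signature_prediction[str(row["compound"])] = _label(row["signature_prediction"])
        rec.observed_sensitivity[str(row["compound"])] = _label(row["observed_sensitivity"])
    return list(records.values())


def load_table1() -> list[CellLineRecord]:
    """Load the in-repo fixture of the 12 printed evidence rows.

    These are the 12 cell lines, from the 52-line validation panel, carrying
    an inactivating TP53 alteration by mutation, mRNA loss or DNA loss.
    """
    with resources.files("tp53proxy.data").joinpath("table1_fixture.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    records: dict[str, CellLineRecord] = {}
    for _, row in df.iterrows():
        name = row["cell_line"]
        if name not in records:
            records[name] = CellLineRecord(
                cell_line=name,
                mutations=[],
                tp53_mrna=float(row["tp53_mrna"]),
                cn_ratio=float(row["cn_ratio"]),
                signature_prediction={"NVP-CGM097": _label(row["signature_prediction"])},
                observed_sensitivity={"NVP-CGM097": _label(row["observed_sensitivity"])},
            )
        if pd.notna(row["protein_change"]) and row["protein_change"]:
            records[name].mutations.append(
                MutationCall(
                    cell_line=name,
                    protein_change=row["protein_change"],
                    mut_class=parse_protein_change(row["protein_change"]),
                    alt_reads=int(row["alt_reads"]) if pd.notna(row["alt_reads"]) else None,
                    ref_reads=int(row["ref_reads"]) if pd.notna(row["ref_reads"]) else None,
                )
            )
    return list(records.values())


def _fmt(x: float) -> str:
    import math

    return "NA" if isinstance(x, float) and math.isnan(x) else f"{x:.3f}"


def write_report(
    calls: list[TP53StatusCall],
    metrics: list[EvaluationScenario],
    outdir,
    thresholds: dict | None = None,
    records: list[CellLineRecord] | None = None,
) -> tuple[Path, Path]:
    """Write the evidence trail (TSV) and metrics document (JSON).

    Both files are byte-stable for fixed input: rows keep call order, JSON
    keys are sorted and floats are fixed at three decimals. Thresholds in
    force are echoed into both files so reports are self-describing. When
    ``records`` is given, per-compound prediction/observation columns are
    appended to the trail, making every metrics number recomputable from
    the trail file alone.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trail_path = outdir / "evidence_trail.tsv"
    metrics_path = outdir / "metrics.json"

    compounds: list[str] = []
    rec_by_line: dict[str, CellLineRecord] = {}
    if records is not None:
        rec_by_line = {r.cell_line: r for r in records}
        compounds = sorted(
            {c for r in records for c in set(r.signature_prediction) | set(r.observed_sensitivity)}
        )

    lines = []
    if thresholds:
        lines.append("# thresholds: " + json.dumps(thresholds, sort_keys=True))
    header = ["cell_line", "status", "evidence", "annotations"]
    for comp in compounds:
        header += [f"pred:{comp}", f"obs:{comp}"]
    lines.append("\t".join(header + ["trail"]))
    for c in calls:
        row = [
            c.cell_line,
            c.status.value,
            ",".join(sorted(e.value for e in c.evidence)),
            ",".join(sorted(a.value for a in c.annotations)),
        ]
        for comp in compounds:
            rec = rec_by_line.get(c.cell_line)
            row.append(rec.prediction_for(comp).value if rec else "missing")
            row.append(rec.observation_for(comp).value if rec else "missing")
        lines.append("\t".join(row + [" | ".join(c.trail)]))
    trail_path.write_text("\n".join(lines) + "\n")

    doc = {"thresholds": thresholds or {}, "scenarios": {}}
    for sc in metrics:
        m = sc.metrics
        doc["scenarios"][sc.label] = {
            "compound": sc.compound,
            "removed_lines": sorted(sc.removed_lines),
            "excluded_missing": sorted(sc.excluded_missing),
            "n": m.n,
            "counts": {"tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn},
            "fractions": m.fractions(),
            "sensitivity": _fmt(m.sensitivity),
            "specificity": _fmt(m.specificity),
            "ppv": _fmt(m.ppv),
            "npv": _fmt(m.npv),
            "response_rate": _fmt(m.response_rate),
        }
    metrics_path.write_text(json.dumps(doc, sort_keys=True, indent=2) + "\n")
    return trail_path, metrics_path
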