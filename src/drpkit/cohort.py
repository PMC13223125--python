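"""Cohort containers, curation, labeling, and on-disk round-tripping.

A cohort couples three entity tables (cell lines, drugs, response records)
with per-cell-line omics blocks and per-gene sequences. Curation applies
three sequential exclusion filters and keeps an audit log whose counts
telescope, mirroring the usual bookkeeping of pharmacogenomic cohort
papers: drop pairs with no usable IC50, then pairs whose cell line lacks a
required omics block, then pairs whose drug has no structural encoding.

IC50 values are carried in micromolar throughout; readers converting from
natural-log or molar representations must do so explicitly via the
``ic50_unit`` flag of :func:`read_cohort`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

SENSITIVE = "sensitive"
RESISTANT = "resistant"

REQUIRED_OMICS = ("mutation", "cnv", "expression")

#: Curation steps in application order, with the reason strings used in the
#: audit log and the emitted CSV.
CURATION_STEPS = (
    ("invalid_response", "No usable IC50 or invalid response summary"),
    ("incomplete_profile", "Missing required molecular feature information"),
    ("no_drug_structure", "Missing or unusable structural representation"),
)


class CurationError(ValueError):
    """Raised when curation empties the cohort or contracts are violated."""


@dataclass
class CellLine:
    """A cancer cell line with its molecular profile.

    ``mutation_calls`` holds binary calls, ``cnv`` and ``expression``
    continuous values; all three share the cohort's gene index. ``protein``
    is optional and never triggers curation exclusion.
    """

    id: str
    lineage: str = "unknown"
    subtype: Optional[str] = None
    mutation_calls: Optional[np.ndarray] = None
    cnv: Optional[np.ndarray] = None
    expression: Optional[np.ndarray] = None
    protein: Optional[np.ndarray] = None

    def has_complete_profile(self) -> bool:
        return all(
            getattr(self, attr) is not None
            for attr in ("mutation_calls", "cnv", "expression")
        )


@dataclass
class Drug:
    id: str
    name: str = ""
    targets: list[str] = field(default_factory=list)
    smiles: str = ""
    inchi: str = ""

    def has_structure(self) -> bool:
        return bool(self.smiles) or bool(self.inchi)


@dataclass
class ResponseRecord:
    cell_line_id: str
    drug_id: str
    ic50_uM: Optional[float] = None
    label: Optional[str] = None

    def has_valid_ic50(self) -> bool:
        return (
            self.ic50_uM is not None
            and math.isfinite(self.ic50_uM)
            and self.ic50_uM > 0
        )


@dataclass
class Cohort:
    """Cell lines, drugs, responses, gene index and sequences, audit log."""

    cell_lines: dict[str, CellLine] = field(default_factory=dict)
    drugs: dict[str, Drug] = field(default_factory=dict)
    responses: list[ResponseRecord] = field(default_factory=list)
    genes: list[str] = field(default_factory=list)
    sequences: dict[str, str] = field(default_factory=dict)
    reference_sequences: dict[str, str] = field(default_factory=dict)
    curation_log: list[tuple[str, int, int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.responses)

    def validate_references(self) -> None:
        for rec in self.responses:
            if rec.cell_line_id not in self.cell_lines:
                raise CurationError(f"unknown cell line id {rec.cell_line_id!r}")
            if rec.drug_id not in self.drugs:
                raise CurationError(f"unknown drug id {rec.drug_id!r}")


def curate_cohort(raw: Cohort) -> Cohort:
    """Apply the three sequential exclusion filters and log the audit trail.

    Step 1 drops pairs without a usable (positive, finite) IC50; step 2
    drops pairs whose cell line is missing any required omics block
    (mutation, CNV, expression -- the optional protein block never
    excludes); step 3 drops pairs whose drug has neither SMILES nor InChI.
    The returned cohort keeps only entities still referenced by a response.

    Raises
    ------
    CurationError
        If no response records survive curation.
    """
    raw.validate_references()
    log: list[tuple[str, int, int, str]] = [
        ("initial", len(raw.responses), 0, "Initial matched candidate cohort")
    ]
    kept = list(raw.responses)

    predicates = {
        "invalid_response": lambda r: r.has_valid_ic50(),
        "incomplete_profile": lambda r: raw.cell_lines[
            r.cell_line_id
        ].has_complete_profile(),
        "no_drug_structure": lambda r: raw.drugs[r.drug_id].has_structure(),
    }
    for step, reason in CURATION_STEPS:
        keep = predicates[step]
        before = len(kept)
        kept = [r for r in kept if keep(r)]
        log.append((step, len(kept), before - len(kept), reason))

    if not kept:
        raise CurationError("empty cohort: no responses survived curation")

    cl_ids = {r.cell_line_id for r in kept}
    drug_ids = {r.drug_id for r in kept}
    return Cohort(
        cell_lines={k: v for k, v in raw.cell_lines.items() if k in cl_ids},
        drugs={k: v for k, v in raw.drugs.items() if k in drug_ids},
        responses=kept,
        genes=list(raw.genes),
        sequences=dict(raw.sequences),
        reference_sequences=dict(raw.reference_sequences),
        curation_log=log,
    )


def assign_labels(cohort: Cohort, threshold_uM: float = 1.0) -> Cohort:
    """Label each pair sensitive (IC50 strictly below threshold) or resistant.

    The boundary value itself is resistant. Idempotent, and the sensitive
    set grows monotonically with the threshold.
    """
    if threshold_uM <= 0:
        raise ValueError("threshold_uM must be positive")
    for rec in cohort.responses:
        if not rec.has_valid_ic50():
            raise CurationError(
                f"record ({rec.cell_line_id},{rec.drug_id}) lacks IC50; "
                "curate the cohort before labeling"
            )
        rec.label = SENSITIVE if rec.ic50_uM < threshold_uM else RESISTANT
    return cohort


def _pct(count: int, total: int) -> float:
    """Percentage with two-decimal half-up rounding."""
    frac = Decimal(count) / Decimal(total) * 100
    return float(frac.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def class_balance(cohort: Cohort) -> dict[str, dict[str, float]]:
    """Counts and percentages per label; percentages rounded half-up."""
    total = len(cohort.responses)
    if total == 0:
        raise CurationError("empty cohort")
    counts = {SENSITIVE: 0, RESISTANT: 0}
    for rec in cohort.responses:
        if rec.label not in counts:
            raise CurationError("all labels must be assigned before summarizing")
        counts[rec.label] += 1
    return {
        label: {"count": n, "percent": _pct(n, total)}
        for label, n in counts.items()
    }


# ---------------------------------------------------------------------------
# I/O: CSV tables + wide omics CSVs + FASTA sequences
# ---------------------------------------------------------------------------


def _omics_frame(cohort: Cohort, attr: str) -> Optional[pd.DataFrame]:
    cols = {}
    for cid, cl in cohort.cell_lines.items():
        vec = getattr(cl, attr)
        if vec is not None:
            cols[cid] = np.asarray(vec, dtype=float)
    if not cols:
        return None
    return pd.DataFrame(cols, index=pd.Index(cohort.genes, name="gene"))


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Persist a cohort to a directory of CSV/FASTA files.

    Layout: responses.csv, cell_lines.csv, drugs.csv, {mutation,cnv,
    expression,protein}.csv as genes x cell-lines wide tables,
    sequences.fasta / reference_sequences.fasta, curation_log.csv.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "cell_line_id": r.cell_line_id,
                "drug_id": r.drug_id,
                "ic50_uM": repr(float(r.ic50_uM)) if r.ic50_uM is not None else "",
                "label": r.label or "",
            }
            for r in cohort.responses
        ]
    ).to_csv(outdir / "responses.csv", index=False)

    pd.DataFrame(
        [
            {
                "id": c.id,
                "lineage": c.lineage,
                "subtype": c.subtype or "",
            }
            for c in cohort.cell_lines.values()
        ]
    ).to_csv(outdir / "cell_lines.csv", index=False)

    pd.DataFrame(
        [
            {
                "id": d.id,
                "name": d.name,
                "targets": ";".join(d.targets),
                "smiles": d.smiles,
                "inchi": d.inchi,
            }
            for d in cohort.drugs.values()
        ]
    ).to_csv(outdir / "drugs.csv", index=False)

    for block in REQUIRED_OMICS + ("protein",):
        attr = "mutation_calls" if block == "mutation" else block
        frame = _omics_frame(cohort, attr)
        if frame is not None:
            frame.to_csv(outdir / f"{block}.csv", float_format="%.17g")

    for fname, seqs in (
        ("sequences.fasta", cohort.sequences),
        ("reference_sequences.fasta", cohort.reference_sequences),
    ):
        if seqs:
            with open(outdir / fname, "w") as fh:
                for name, seq in seqs.items():
                    fh.write(f">{name}\n{seq}\n")

    if cohort.curation_log:
        write_curation_log(cohort.curation_log, outdir / "curation_log.csv")


def write_curation_log(
    log: Sequence[tuple[str, int, int, str]], path: str | Path
) -> None:
    pd.DataFrame(
        log, columns=["step", "retained", "excluded", "reason"]
    ).to_csv(path, index=False)


def _read_fasta(path: Path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_cohort(indir: str | Path, ic50_unit: str = "uM") -> Cohort:
    """Read a cohort directory written by :func:`write_cohort`.

    ``ic50_unit`` must be one of ``uM`` (as-is), ``M`` (molar, scaled by
    1e6) or ``ln_uM`` (natural log of micromolar, exponentiated).
    """
    indir = Path(indir)
    converters = {
        "uM": lambda v: v,
        "M": lambda v: v * 1e6,
        "ln_uM": math.exp,
    }
    if ic50_unit not in converters:
        raise ValueError(f"unknown ic50_unit {ic50_unit!r}")
    conv = converters[ic50_unit]

    omics: dict[str, pd.DataFrame] = {}
    genes: list[str] = []
    for block in REQUIRED_OMICS + ("protein",):
        path = indir / f"{block}.csv"
        if path.exists():
            frame = pd.read_csv(path, index_col=0, float_precision="round_trip")
            omics[block] = frame
            if block != "protein" and not genes:
                genes = list(frame.index)

    cell_lines: dict[str, CellLine] = {}
    for _, row in pd.read_csv(indir / "cell_lines.csv", dtype=str).iterrows():
        cid = row["id"]
        kwargs = {}
        for block, attr in (
            ("mutation", "mutation_calls"),
            ("cnv", "cnv"),
            ("expression", "expression"),
            ("protein", "protein"),
        ):
            frame = omics.get(block)
            if frame is not None and cid in frame.columns:
                kwargs[attr] = frame[cid].to_numpy(dtype=float)
        cell_lines[cid] = CellLine(
            id=cid,
            lineage=row.get("lineage", "unknown") or "unknown",
            subtype=row.get("subtype") or None,
            **kwargs,
        )

    drugs: dict[str, Drug] = {}
    for _, row in pd.read_csv(
        indir / "drugs.csv", dtype=str, keep_default_na=False
    ).iterrows():
        drugs[row["id"]] = Drug(
            id=row["id"],
            name=row.get("name", ""),
            targets=[t for t in row.get("targets", "").split(";") if t],
            smiles=row.get("smiles", ""),
            inchi=row.get("inchi", ""),
        )

    responses: list[ResponseRecord] = []
    resp = pd.read_csv(indir / "responses.csv", keep_default_na=False, dtype=str)
    for _, row in resp.iterrows():
        raw_ic50 = row["ic50_uM"]
        ic50 = None if raw_ic50 in ("", None) else conv(float(raw_ic50))
        responses.append(
            ResponseRecord(
                cell_line_id=str(row["cell_line_id"]),
                drug_id=str(row["drug_id"]),
                ic50_uM=ic50,
                label=str(row["label"]) or None,
            )
        )

    sequences = {}
    references = {}
    if (indir / "sequences.fasta").exists():
        sequences = _read_fasta(indir / "sequences.fasta")
    if (indir / "reference_sequences.fasta").exists():
        references = _read_fasta(indir / "reference_sequences.fasta")

    return Cohort(
        cell_lines=cell_lines,
        drugs=drugs,
        responses=responses,
        genes=genes,
        sequences=sequences,
        reference_sequences=references,
    )
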