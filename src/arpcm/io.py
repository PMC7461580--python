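"""Readers and writers for the package's plain-text file formats.

Formats (all CSV with fixed headers, or line-oriented text):

* dose-response curves — ``mutant_id,drug_id,concentration_uM,activation_pct``,
  long format, one row per grid point;
* drugs — ``drug_id,smiles``;
* mutants — one spec token per line (``W742C``, ``T878A+L702H``); blank lines
  and ``#`` comments ignored;
* labels — ``mutant_id,drug_id,label_code,label_name``;
* predictions — ``mutant_id,drug_id,label_code,label_name,export_code,p0,p1,p2,p3``.

Validation is strict and parse errors carry the offending line number.
"""

from __future__ import annotations

import csv
import json
import warnings
from collections import OrderedDict
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .curves import DoseResponseCurve, LabelledCurve, PhenotypeLabel
from .exceptions import FileFormatError, MalformedCurveError
from .mutants import MutantSpec, parse_mutant_spec

CURVES_HEADER = ["mutant_id", "drug_id", "concentration_uM", "activation_pct"]
DRUGS_HEADER = ["drug_id", "smiles"]
LABELS_HEADER = ["mutant_id", "drug_id", "label_code", "label_name"]
PREDICTIONS_HEADER = [
    "mutant_id", "drug_id", "label_code", "label_name",
    "export_code", "p0", "p1", "p2", "p3",
]


def _open_rows(path: str | Path, expected_header: list[str]):
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise FileFormatError(f"{path}: empty file") from None
        if [h.strip() for h in header] != expected_header:
            raise FileFormatError(
                f"{path}: line 1: expected header {','.join(expected_header)!r}, "
                f"got {','.join(header)!r}"
            )
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(expected_header):
                raise FileFormatError(
                    f"{path}: line {lineno}: expected {len(expected_header)} "
                    f"fields, got {len(row)}"
                )
            yield lineno, [c.strip() for c in row]


def read_curves(path: str | Path) -> list[DoseResponseCurve]:
    """Read long-format curve CSV and pivot to one curve per (mutant, drug)."""
    points: "OrderedDict[tuple[str, str], list[tuple[float, float]]]" = OrderedDict()
    for lineno, (mutant, drug, conc, act) in _open_rows(path, CURVES_HEADER):
        try:
            c, a = float(conc), float(act)
        except ValueError:
            raise FileFormatError(
                f"{path}: line {lineno}: non-numeric value in {conc!r}/{act!r}"
            ) from None
        points.setdefault((mutant, drug), []).append((c, a))
    curves = []
    for (mutant, drug), pts in points.items():
        pts.sort(key=lambda p: p[0])
        try:
            curves.append(
                DoseResponseCurve(
                    mutant, drug,
                    tuple(p[0] for p in pts), tuple(p[1] for p in pts),
                )
            )
        except MalformedCurveError as exc:
            raise FileFormatError(f"{path}: {exc}") from exc
    return curves


def write_curves(curves: Iterable[DoseResponseCurve], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CURVES_HEADER)
        for c in curves:
            for conc, act in zip(c.concentrations, c.activations):
                w.writerow([c.mutant_id, c.drug_id, repr(conc), repr(act)])


def read_drugs(path: str | Path) -> dict[str, str]:
    """Read the ``drug_id,smiles`` table."""
    out: dict[str, str] = {}
    for lineno, (drug, smiles) in _open_rows(path, DRUGS_HEADER):
        if drug in out:
            raise FileFormatError(f"{path}: line {lineno}: duplicate drug_id {drug!r}")
        out[drug] = smiles
    if not out:
        raise FileFormatError(f"{path}: no drugs")
    return out


def write_drugs(smiles_by_drug: dict[str, str], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(DRUGS_HEADER)
        for drug in sorted(smiles_by_drug):
            w.writerow([drug, smiles_by_drug[drug]])


def read_mutants(path: str | Path) -> list[MutantSpec]:
    """Read one mutant token per line; ``#`` comments and blanks skipped."""
    specs = []
    seen = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        token = line.split("#", 1)[0].strip()
        if not token:
            continue
        try:
            spec = parse_mutant_spec(token)
        except Exception as exc:
            raise FileFormatError(f"{path}: line {lineno}: {exc}") from exc
        if spec.mutant_id in seen:
            raise FileFormatError(f"{path}: line {lineno}: duplicate mutant {token!r}")
        seen.add(spec.mutant_id)
        specs.append(spec)
    if not specs:
        raise FileFormatError(f"{path}: no mutants")
    return specs


def write_mutants(specs: Iterable[MutantSpec], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s.mutant_id}\n" for s in specs))


def read_wt_fasta(path: str | Path) -> str:
    """Read the wild-type protein sequence (first FASTA record)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FileFormatError(f"{path}: no FASTA records")
    if len(records) > 1:
        warnings.warn(
            f"{path}: {len(records)} FASTA records; using the first "
            f"({records[0].id})",
            stacklevel=2,
        )
    return str(records[0].seq).upper()


def write_wt_fasta(sequence: str, path: str | Path, name: str = "wildtype") -> None:
    Path(path).write_text(f">{name}\n{sequence}\n")


def write_labels(records: Iterable[LabelledCurve], path: str | Path) -> None:
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(LABELS_HEADER)
        for r in records:
            w.writerow([r.mutant_id, r.drug_id, int(r.label), r.label.label])


def read_labels(path: str | Path) -> list[LabelledCurve]:
    out = []
    for lineno, (mutant, drug, code, name) in _open_rows(path, LABELS_HEADER):
        try:
            label = PhenotypeLabel(int(code))
        except ValueError:
            raise FileFormatError(f"{path}: line {lineno}: bad label code {code!r}") from None
        if label.label != name:
            raise FileFormatError(
                f"{path}: line {lineno}: code {code} does not match name {name!r}"
            )
        out.append(LabelledCurve(mutant, drug, label))
    return out


#: Export coding of Fig-style reports: the three non-agonist classes map to
#: −1/0/1; an agonist prediction has no code in this scheme and is exported
#: by name with the code column left empty.
EXPORT_CODES = {
    PhenotypeLabel.ANTAGONIST: -1,
    PhenotypeLabel.NON_RESPONSIVE: 0,
    PhenotypeLabel.MIXED_RESPONSE: 1,
}


def write_predictions(records: Iterable, path: str | Path) -> None:
    """Write prediction records (see :mod:`arpcm.pipeline`)."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(PREDICTIONS_HEADER)
        for r in records:
            export = EXPORT_CODES.get(r.label, "")
            w.writerow(
                [r.mutant_id, r.drug_id, int(r.label), r.label.label, export]
                + [f"{p:.6f}" for p in r.proba]
            )


def write_report(report_dict: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report_dict, indent=1) + "\n")
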