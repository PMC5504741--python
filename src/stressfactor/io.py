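"""Readers and writers for the plain-text formats used by the pipeline.

Matrices travel as TSV with a header row of sample ids and the variable id
in the first column.  Missing metabolite intensities are encoded as empty
cells or ``NA`` on read and written back as empty cells.  Term sets use the
GMT convention (term, description, tab-separated members); networks are
serialized as GraphML through networkx.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import validate_design
from .matrix import OmicsMatrix

_NA_TOKENS = {"", "NA", "NaN", "nan"}


def read_omics_matrix(path: str | Path, layer: str = "transcriptome") -> OmicsMatrix:
    """Read a variables x samples TSV into an :class:`OmicsMatrix`.

    Empty/``NA`` cells are allowed only for metabolome layers and become
    masked entries; zeros are treated as missing for metabolome layers and
    rejected for the transcriptome (log2 applicability).
    """
    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows:
        raise ValueError(f"{path}: empty file")
    header = rows[0]
    sample_ids = [c.strip() for c in header[1:]]
    if len(set(sample_ids)) != len(sample_ids):
        raise ValueError(f"{path}: duplicate sample id in header")
    n_cols = len(header)
    variable_ids: list[str] = []
    values = np.empty((len(rows) - 1, len(sample_ids)))
    mask = np.zeros_like(values, dtype=bool)
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != n_cols:
            raise ValueError(f"{path}: ragged row {i + 1}")
        variable_ids.append(row[0].strip())
        for j, cell in enumerate(row[1:]):
            tok = cell.strip()
            if tok in _NA_TOKENS:
                if layer == "transcriptome":
                    raise ValueError(
                        f"{path}: missing value in transcriptome layer "
                        f"(row {i + 1}, column {j + 2})"
                    )
                mask[i - 1, j] = True
                values[i - 1, j] = np.nan
            else:
                v = float(tok)
                if v == 0.0:
                    if layer == "transcriptome":
                        raise ValueError(
                            f"{path}: zero intensity in transcriptome layer"
                        )
                    mask[i - 1, j] = True
                    values[i - 1, j] = np.nan
                else:
                    values[i - 1, j] = v
    if len(set(variable_ids)) != len(variable_ids):
        raise ValueError(f"{path}: duplicate variable id")
    return OmicsMatrix(values, variable_ids, sample_ids, mask, layer=layer)


def write_omics_matrix(m: OmicsMatrix, path: str | Path) -> None:
    """Write the matrix as TSV; masked cells become empty strings."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["variable_id", *m.sample_ids])
        for i, vid in enumerate(m.variable_ids):
            row: list[str] = [vid]
            for j in range(m.n_samples):
                if m.missing_mask[i, j]:
                    row.append("")
                else:
                    row.append(repr(float(m.values[i, j])))
            w.writerow(row)


def read_design(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample design TSV; derives condition labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("drought", "heat"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return validate_design(df)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class AnnotationSets:
    """Named term sets (e.g. GO-style categories) over variable ids."""

    term_ids: list[str]
    term_names: dict[str, str]
    members: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        if len(set(self.term_ids)) != len(self.term_ids):
            raise ValueError("duplicate term id")
        for t in self.term_ids:
            if not self.members[t]:
                raise ValueError(f"term {t!r} has no members")

    def __len__(self) -> int:
        return len(self.term_ids)

    def restrict(self, universe: set[str]) -> "AnnotationSets":
        """Intersect every term with a universe, dropping emptied terms."""
        kept = []
        members = {}
        for t in self.term_ids:
            inter = frozenset(self.members[t] & universe)
            if inter:
                kept.append(t)
                members[t] = inter
        return AnnotationSets(kept, {t: self.term_names[t] for t in kept}, members)


def read_gmt(path: str | Path) -> AnnotationSets:
    """Read GMT term sets; duplicate members on a line are collapsed."""
    term_ids: list[str] = []
    names: dict[str, str] = {}
    members: dict[str, frozenset[str]] = {}
    with Path(path).open() as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {ln} has fewer than 3 fields")
            term, desc, *genes = fields
            if term in members:
                raise ValueError(f"{path}: duplicate term {term!r}")
            term_ids.append(term)
            names[term] = desc
            members[term] = frozenset(g for g in genes if g)
    return AnnotationSets(term_ids, names, members)


def write_gmt(sets: AnnotationSets, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for t in sets.term_ids:
            fh.write(
                "\t".join([t, sets.term_names[t], *sorted(sets.members[t])]) + "\n"
            )


def file_digest(path: str | Path) -> str:
    """SHA-256 hex digest of a file, for run manifests."""
    h = hashlib.sha256()
    with Path(path).open("rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj: object, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
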