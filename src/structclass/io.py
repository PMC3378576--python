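"""Readers and writers for the formats the predictor touches.

FASTA sequences (via Biopython), PSI-BLAST ASCII PSSM profiles (the
``-Q``-style text matrix), domain interval tables, secondary-structure
and label tables, labelled feature matrices, and versioned model files.

PSSM profiles are computed per protein sequence; a domain's profile is
the contiguous slice of its parent's.  Intervals are 1-based inclusive
in files and converted to 0-based half-open indices internally.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .features import N_FEATURES, feature_labels
from .scales import PSSM_COLUMNS

__all__ = [
    "FormatError",
    "PssmParseError",
    "SequenceRecord",
    "PSSM",
    "DomainInterval",
    "read_fasta",
    "write_fasta",
    "read_pssm",
    "write_pssm",
    "slice_domain",
    "read_domain_table",
    "write_domain_table",
    "read_labels",
    "write_labels",
    "read_ss_table",
    "write_ss_table",
    "read_feature_table",
    "write_feature_table",
    "write_model",
    "read_model",
]

MODEL_FORMAT = "structclass-model"
MODEL_VERSION = 1


class FormatError(ValueError):
    """A file does not conform to its expected format."""


class PssmParseError(FormatError):
    """A PSI-BLAST ASCII PSSM file could not be parsed."""


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str


@dataclass(frozen=True)
class PSSM:
    """A log-odds profile: the query sequence plus an L x 20 score matrix."""

    sequence: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(f"PSSM scores must be L x 20, got {scores.shape}")
        if scores.shape[0] != len(self.sequence):
            raise ValueError(
                f"PSSM has {scores.shape[0]} score rows but a "
                f"length-{len(self.sequence)} sequence"
            )
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class DomainInterval:
    """A domain as a 1-based inclusive interval in its parent sequence."""

    domain_id: str
    parent_id: str
    start: int
    end: int
    class_label: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(
                f"{self.domain_id}: invalid interval [{self.start}, {self.end}]"
            )


def read_fasta(path) -> list[SequenceRecord]:
    """Read FASTA records; sequences are uppercased, whitespace-free."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().replace(" ", "")
        if not seq:
            raise FormatError(f"FASTA record {rec.id!r} has an empty sequence")
        records.append(SequenceRecord(rec.id, seq))
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records, path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def _is_int(tok: str) -> bool:
    try:
        int(tok)
        return True
    except ValueError:
        return False


def read_pssm(path) -> PSSM:
    """Parse a PSI-BLAST ASCII PSSM, keeping only the log-odds block.

    Body rows carry: position index, residue letter, 20 log-odds
    integers, 20 weighted-percentage integers, then trailing statistics.
    The percentage block and trailing columns are ignored.
    """
    residues: list[str] = []
    rows: list[list[int]] = []
    in_body = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                if in_body:
                    break
                continue
            if not (_is_int(tokens[0]) and len(tokens) >= 2 and len(tokens[1]) == 1
                    and tokens[1].isalpha()):
                if in_body:
                    break  # footer statistics
                continue
            numeric = tokens[2:]
            if len(numeric) < 40 or not all(_is_int(t) for t in numeric[:40]):
                raise PssmParseError(
                    f"{path}: line {lineno}: expected 40 integer score fields, "
                    f"found {sum(_is_int(t) for t in numeric)}"
                )
            in_body = True
            residues.append(tokens[1].upper())
            rows.append([int(t) for t in numeric[:20]])
    if not rows:
        raise PssmParseError(f"{path}: no PSSM matrix rows found")
    return PSSM("".join(residues), np.array(rows, dtype=int))


def write_pssm(pssm: PSSM, path) -> None:
    """Write a profile in the PSI-BLAST ASCII matrix layout."""
    with open(path, "w") as fh:
        fh.write(
            "\nLast position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapped matches\n"
        )
        header = "".join(f"{a:>4}" for a in PSSM_COLUMNS)
        fh.write("         " + header + header + "\n")
        for i, (res, row) in enumerate(zip(pssm.sequence, pssm.scores), start=1):
            scores = "".join(f"{int(v):>4d}" for v in row)
            pcts = "".join(f"{0:>4d}" for _ in range(20))
            fh.write(f"{i:>5d} {res} {scores}{pcts}  0.00 0.00\n")
        fh.write("\n")


def slice_domain(pssm: PSSM, interval: DomainInterval) -> PSSM:
    """Extract a domain's profile as a contiguous slice of its parent's."""
    if interval.end > len(pssm):
        raise ValueError(
            f"{interval.domain_id}: interval [{interval.start}, {interval.end}] "
            f"exceeds parent length {len(pssm)}"
        )
    lo, hi = interval.start - 1, interval.end  # to 0-based half-open
    return PSSM(pssm.sequence[lo:hi], pssm.scores[lo:hi])


DOMAIN_COLUMNS = ["domain_id", "parent_id", "start", "end", "class"]


def read_domain_table(path) -> list[DomainInterval]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in DOMAIN_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: domain table lacks columns {missing}")
    out = []
    for _, row in df.iterrows():
        label = row.get("class")
        label = None if label is None or pd.isna(label) or label == "" else str(label)
        out.append(
            DomainInterval(str(row["domain_id"]), str(row["parent_id"]),
                           int(row["start"]), int(row["end"]), label)
        )
    return out


def write_domain_table(intervals, path) -> None:
    rows = [
        (iv.domain_id, iv.parent_id, iv.start, iv.end, iv.class_label or "")
        for iv in intervals
    ]
    pd.DataFrame(rows, columns=DOMAIN_COLUMNS).to_csv(path, sep="\t", index=False)


def _read_two_column(path, value_name: str) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected 2 columns (domain_id, {value_name})")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def read_labels(path) -> dict[str, str]:
    """domain_id -> structural class, from a 2-column TSV."""
    return _read_two_column(path, "class")


def write_labels(labels: dict[str, str], path) -> None:
    pd.DataFrame(labels.items(), columns=["domain_id", "class"]).to_csv(
        path, sep="\t", index=False
    )


def read_ss_table(path) -> dict[str, str]:
    """domain_id -> secondary-structure string, from a 2-column TSV."""
    return _read_two_column(path, "ss")


def write_ss_table(ss: dict[str, str], path) -> None:
    pd.DataFrame(ss.items(), columns=["domain_id", "ss"]).to_csv(
        path, sep="\t", index=False
    )


def read_feature_table(path) -> tuple[list[str], np.ndarray]:
    """Read a labelled feature matrix; returns (domain ids, n x 440 array)."""
    df = pd.read_csv(path, sep="\t", index_col="domain_id")
    expected = list(feature_labels())
    if list(df.columns) != expected:
        raise FormatError(
            f"{path}: feature columns do not match the {N_FEATURES} expected labels"
        )
    return list(df.index.astype(str)), df.to_numpy(dtype=float)


def write_feature_table(ids, X, path) -> None:
    X = np.asarray(X, dtype=float)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"feature matrix must have {N_FEATURES} columns")
    df = pd.DataFrame(X, index=pd.Index(ids, name="domain_id"),
                      columns=list(feature_labels()))
    df.to_csv(path, sep="\t")


def write_model(model, path) -> None:
    """Serialize a trained model (coefficients + standardization) to JSON."""
    payload = {
        "format": MODEL_FORMAT,
        "version": MODEL_VERSION,
        **model.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_model(path):
    """Load a model file written by :func:`write_model`."""
    from .model import ModelMatrix

    payload = json.loads(Path(path).read_text())
    if payload.get("format") != MODEL_FORMAT or payload.get("version") != MODEL_VERSION:
        raise FormatError(
            f"{path}: not a {MODEL_FORMAT} v{MODEL_VERSION} file "
            f"(found format={payload.get('format')!r}, "
            f"version={payload.get('version')!r})"
        )
    if "standardization" not in payload:
        raise FormatError(f"{path}: model file lacks the standardization block")
    return ModelMatrix.from_dict(payload)
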