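"""Readers and writers for every external format the pipeline touches.

Formats
-------
* FASTA (multi-record, wrapped lines) — via Biopython.
* PSI-BLAST ASCII PSSM (the ``-out_ascii_pssm`` dialect). Both the
  40-column (log-odds + weighted percentages) and the bare 20-column
  variants are accepted; only the first 20 numeric columns — the
  log-odds block — are kept.
* Feature tables: CSV with header ``label,f<i>,...`` and labels in
  {+1, -1}, lossless at full float precision.
* Ranking tables: CSV ``feature_index,rank,iteration_eliminated,criterion``.
* Label tables: CSV ``id,label``.

Positions are 1-based in files and 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq as _BioSeq
from Bio.SeqRecord import SeqRecord

#: PSI-BLAST column order of the 20 canonical residues.
AA_ORDER = "ARNDCQEGHILKMFPSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AA_ORDER)}

#: Non-canonical letters tolerated on input (kept verbatim; the encoder
#: decides what to do with them).
EXTENDED_LETTERS = set("XBZUO")


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


@dataclass(frozen=True)
class Sequence:
    """A named amino-acid sequence.

    Residues are upper-cased on ingest; non-canonical letters
    (X, B, Z, U, O) are allowed.
    """

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} has empty residues")


@dataclass
class PSSMProfile:
    """Per-sequence position-specific scoring matrix.

    ``scores`` holds the L×20 log-odds block; ``column_order`` gives the
    residue identity of the 20 score columns (PSI-BLAST order).
    """

    sequence_id: str
    residues: str
    scores: np.ndarray
    column_order: str = AA_ORDER

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.ndim != 2 or self.scores.shape[1] != 20:
            raise ValueError(
                f"profile {self.sequence_id!r}: scores must be L x 20, "
                f"got shape {self.scores.shape}"
            )
        if self.scores.shape[0] != len(self.residues):
            raise ValueError(
                f"profile {self.sequence_id!r}: {len(self.residues)} residues "
                f"but {self.scores.shape[0]} score rows"
            )
        if len(self.residues) < 1:
            raise ValueError(f"profile {self.sequence_id!r} is empty")
        if sorted(self.column_order) != sorted(AA_ORDER):
            raise ValueError("column_order must be a permutation of the 20 residues")

    def __len__(self) -> int:
        return len(self.residues)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PSSMProfile):
            return NotImplemented
        return (
            self.sequence_id == other.sequence_id
            and self.residues == other.residues
            and self.column_order == other.column_order
            and np.array_equal(self.scores, other.scores)
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path) -> list[Sequence]:
    """Read a multi-record FASTA file into :class:`Sequence` objects.

    Wrapped sequence lines are concatenated, bodies are upper-cased and
    record order is preserved.
    """
    path = Path(path)
    with open(path) as fh:
        head = fh.read(4096)
    first = head.lstrip()
    if not first.startswith(">"):
        raise FormatError(f"{path}: not a FASTA file (does not start with '>')")
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        body = str(rec.seq).upper()
        if not body:
            raise FormatError(f"{path}: record {rec.id!r} has an empty body")
        out.append(Sequence(id=rec.id, residues=body))
    return out


def write_fasta(sequences, path, width: int = 60) -> None:
    """Write sequences as wrapped FASTA; inverse of :func:`read_fasta`."""
    records = [
        SeqRecord(_BioSeq(s.residues), id=s.id, description="") for s in sequences
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def _position_row_tokens(tokens: list[str]) -> bool:
    """True if a whitespace-split line looks like a PSSM position row."""
    if len(tokens) < 2:
        return False
    try:
        int(tokens[0])
    except ValueError:
        return False
    return len(tokens[1]) == 1 and tokens[1].isalpha()


def parse_pssm(path) -> PSSMProfile:
    """Parse one PSI-BLAST ASCII PSSM file.

    Only the first 20 numeric columns of each position row (the log-odds
    block) are kept; the weighted-percentage block and per-position
    statistics, if present, are ignored, as is the Lambda/K footer after
    the blank line terminating the matrix. The profile's ``sequence_id``
    is the file stem.
    """
    path = Path(path)
    residues: list[str] = []
    rows: list[list[float]] = []
    in_matrix = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.strip()
            if not stripped:
                if in_matrix:
                    break  # blank line terminates the matrix block
                continue
            tokens = stripped.split()
            if _position_row_tokens(tokens):
                in_matrix = True
                values: list[float] = []
                for tok in tokens[2:]:
                    try:
                        values.append(float(tok))
                    except ValueError:
                        break
                if len(values) < 20:
                    raise FormatError(
                        f"{path}: line {lineno}: position row has "
                        f"{len(values)} numeric fields, expected >= 20"
                    )
                residues.append(tokens[1].upper())
                rows.append(values[:20])
            elif in_matrix:
                break  # footer reached without a blank separator
    if not rows:
        raise FormatError(f"{path}: no position rows found")
    return PSSMProfile(
        sequence_id=path.stem, residues="".join(residues), scores=np.array(rows)
    )


def _format_score(v: float) -> str:
    if float(v).is_integer() and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def write_pssm(profile: PSSMProfile, path) -> None:
    """Write a profile in the dialect :func:`parse_pssm` accepts.

    ``parse_pssm(write_pssm(p))`` reproduces ``p`` exactly when the file
    stem equals ``p.sequence_id``.
    """
    path = Path(path)
    lines = [
        "",
        "Last position-specific scoring matrix computed, weighted observed "
        "percentages rounded down, information per position, and relative "
        "weight of gapless real matches to pseudocounts",
        "            " + "   ".join(profile.column_order),
    ]
    for i, (res, row) in enumerate(zip(profile.residues, profile.scores), 1):
        cells = " ".join(f"{_format_score(v):>4s}" for v in row)
        lines.append(f"{i:5d} {res}  {cells}")
    lines += [
        "",
        "                      K         Lambda",
        "Standard Ungapped    0.1337     0.3198",
        "",
    ]
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------

_LABEL_MAP = {"+1": 1, "1": 1, "-1": -1}


def read_feature_table(path):
    """Read a ``label,f0,...`` CSV into a :class:`~snaresap.encoding.FeatureMatrix`."""
    from .encoding import FeatureMatrix

    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty feature table") from None
    if df.shape[1] < 2 or df.columns[0] != "label":
        raise FormatError(
            f"{path}: expected header 'label,f0,...', got {list(df.columns)[:3]}"
        )
    feature_cols = list(df.columns[1:])
    for c in feature_cols:
        if not (c.startswith("f") and c[1:].isdigit()):
            raise FormatError(f"{path}: bad feature column name {c!r}")
    if len(df) == 0:
        raise FormatError(f"{path}: feature table has no rows")

    y = np.empty(len(df), dtype=int)
    for i, raw in enumerate(df["label"]):
        lab = _LABEL_MAP.get(str(raw).strip())
        if lab is None:
            raise FormatError(
                f"{path}: row {i + 1}, column 'label': invalid label {raw!r} "
                "(expected +1 or -1)"
            )
        y[i] = lab

    X = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, c in enumerate(feature_cols):
        raw = df[c].to_numpy(dtype=str)
        try:
            # numpy's parser is correctly rounded, unlike pandas' fast path
            X[:, j] = raw.astype(np.float64)
        except ValueError:
            for i, cell in enumerate(raw):
                try:
                    float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: row {i + 1}, column {c!r}: "
                        f"non-numeric value {cell!r}"
                    ) from None
            raise

    feature_ids = np.array([int(c[1:]) for c in feature_cols])
    return FeatureMatrix(X=X, y=y, feature_ids=feature_ids)


def write_feature_table(matrix, path) -> None:
    """Write a feature matrix as CSV; lossless inverse of :func:`read_feature_table`."""
    if matrix.y is None:
        raise ValueError("feature table requires labels")
    # repr gives the shortest decimal that round-trips each float64 exactly
    as_str = np.frompyfunc(lambda v: repr(float(v)), 1, 1)(matrix.X)
    df = pd.DataFrame(as_str, columns=[f"f{i}" for i in matrix.feature_ids])
    df.insert(0, "label", matrix.y)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Ranking tables
# ---------------------------------------------------------------------------

def write_ranking(ranking, path) -> None:
    """Write a feature ranking as ``feature_index,rank,iteration_eliminated,criterion``."""
    df = pd.DataFrame(
        {
            "feature_index": ranking.order,
            "rank": np.arange(1, len(ranking.order) + 1),
            "iteration_eliminated": ranking.iteration_eliminated,
            "criterion": [repr(float(c)) for c in ranking.criterion],
        }
    )
    df.to_csv(path, index=False)


def read_ranking(path):
    """Read a ranking table written by :func:`write_ranking`."""
    from .selection import FeatureRanking

    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty ranking table") from None
    expected = ["feature_index", "rank", "iteration_eliminated", "criterion"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected header {expected}, got {list(df.columns)}")
    df = df.sort_values("rank")
    return FeatureRanking(
        order=df["feature_index"].to_numpy(dtype=int),
        iteration_eliminated=df["iteration_eliminated"].to_numpy(dtype=int),
        criterion=df["criterion"].to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# Label tables
# ---------------------------------------------------------------------------

def write_labels(ids, labels, path) -> None:
    pd.DataFrame({"id": list(ids), "label": np.asarray(labels, dtype=int)}).to_csv(
        path, index=False
    )


def read_labels(path) -> dict[str, int]:
    """Read an ``id,label`` CSV into a mapping."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"id": str})
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty label table") from None
    if list(df.columns) != ["id", "label"]:
        raise FormatError(f"{path}: expected header 'id,label'")
    out = {}
    for i, (sid, raw) in enumerate(zip(df["id"], df["label"])):
        lab = _LABEL_MAP.get(str(raw).strip())
        if lab is None:
            raise FormatError(f"{path}: row {i + 1}: invalid label {raw!r}")
        out[str(sid)] = lab
    return out
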