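"""Readers and writers for every file the pipeline touches.

All parsing and validation happens here, once, at the boundary: downstream
modules only ever see the typed records defined in this module.  Per-residue
tracks (PSSM rows, secondary-structure states, disorder scores) are 1-based
in the files and 0-based in memory; the readers own that conversion.

Formats
-------
* FASTA (protein, 20-letter alphabet) via Biopython.
* PSI-BLAST ASCII position-specific scoring matrices (the classic ``-Q`` /
  ``-out_ascii_pssm`` layout); only the log-odds block is read, never the
  percentage block.
* PSIPRED ``.ss2`` VFORMAT secondary-structure files.
* Disorder score tracks as TSV (index, residue, score in [0, 1]).
* Domain annotations as TSV (protein id, accession).
* Feature matrices as CSV with an ``id`` column and an optional ``label``
  column; numeric text is written with :data:`TEXT_PRECISION` significant
  digits so write -> read -> write is byte-stable.
* Trained ensemble models as a directory archive (JSON config + joblib
  members).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from Bio import SeqIO

#: canonical amino-acid alphabet, alphabetical one-letter order
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: the three secondary-structure states: helix, strand, coil
SS_STATES = "HEC"

#: significant digits used for all numeric text output
TEXT_PRECISION = 10

#: PSI-BLAST's native column order for the 20 score columns
PSIBLAST_AA_ORDER = "ARNDCQEGHILKMFPSTWYV"

_AA_SET = frozenset(AMINO_ACIDS)


class ParseError(ValueError):
    """An input file violated its format contract."""


def _fmt(x: float) -> str:
    return f"{x:.{TEXT_PRECISION}g}"


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class ProteinRecord:
    """A protein identifier plus a validated 20-letter sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ParseError(f"invalid protein id {self.id!r}: must be a non-empty token")
        if not self.sequence:
            raise ParseError(f"record {self.id!r}: empty sequence")
        for pos, residue in enumerate(self.sequence):
            if residue not in _AA_SET:
                raise ParseError(
                    f"record {self.id!r}: illegal residue {residue!r} at position {pos + 1}"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclasses.dataclass(frozen=True)
class PSSMProfile:
    """Raw log-odds profile from an iterative profile search (L x 20)."""

    id: str
    residues: str
    scores: np.ndarray
    aa_order: str = PSIBLAST_AA_ORDER

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ParseError(f"profile {self.id!r}: scores must be L x 20")
        if scores.shape[0] != len(self.residues):
            raise ParseError(
                f"profile {self.id!r}: {scores.shape[0]} score rows for "
                f"{len(self.residues)} residues"
            )
        if sorted(self.aa_order) != sorted(AMINO_ACIDS):
            raise ParseError(f"profile {self.id!r}: column order is not a 20-letter permutation")

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclasses.dataclass(frozen=True)
class SecondaryStructureTrack:
    """Per-residue secondary-structure states: helix H, strand E, coil C."""

    id: str
    states: str

    def __post_init__(self) -> None:
        bad = set(self.states) - set(SS_STATES)
        if bad:
            raise ParseError(f"track {self.id!r}: illegal state(s) {sorted(bad)}")
        if not self.states:
            raise ParseError(f"track {self.id!r}: empty state string")

    def __len__(self) -> int:
        return len(self.states)


@dataclasses.dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder scores in [0, 1]."""

    id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1 or scores.size == 0:
            raise ParseError(f"track {self.id!r}: scores must be a non-empty vector")
        if np.any(scores < 0) or np.any(scores > 1):
            raise ParseError(f"track {self.id!r}: disorder scores must lie in [0, 1]")

    def __len__(self) -> int:
        return int(self.scores.size)


@dataclasses.dataclass(frozen=True)
class DomainAnnotation:
    """Mapping from protein id to its set of domain accession strings.

    Accessions are opaque tokens; a protein absent from the mapping simply
    has no annotated domains.
    """

    assignments: Mapping[str, frozenset]

    def domains_of(self, protein_id: str) -> frozenset:
        return self.assignments.get(protein_id, frozenset())

    @property
    def protein_ids(self) -> list:
        return sorted(self.assignments)


@dataclasses.dataclass(frozen=True)
class DroppedRecord:
    record: ProteinRecord
    reason: str


class FeatureMatrix:
    """Named n x d numeric table with sample ids and optional binary labels.

    Labels are stored internally as integers (1 = positive / ECM,
    0 = negative) and serialized as the strings ``positive`` / ``negative``.
    """

    def __init__(
        self,
        ids: Sequence[str],
        feature_names: Sequence[str],
        values,
        labels=None,
    ) -> None:
        self.ids = list(ids)
        self.feature_names = list(feature_names)
        self.values = np.asarray(values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape != (len(self.ids), len(self.feature_names)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with {len(self.ids)} ids "
                f"and {len(self.feature_names)} feature names"
            )
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sample ids")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("feature matrix contains missing or non-finite values")
        if labels is None:
            self.labels = None
        else:
            self.labels = np.asarray(labels, dtype=int)
            if self.labels.shape != (len(self.ids),):
                raise ValueError("labels length must match number of samples")
            if not set(np.unique(self.labels)) <= {0, 1}:
                raise ValueError("labels must be binary (1 = positive, 0 = negative)")

    # -- basic protocol ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    def __eq__(self, other) -> bool:
        if not isinstance(other, FeatureMatrix):
            return NotImplemented
        same_labels = (self.labels is None) == (other.labels is None) and (
            self.labels is None or np.array_equal(self.labels, other.labels)
        )
        return (
            self.ids == other.ids
            and self.feature_names == other.feature_names
            and np.array_equal(self.values, other.values)
            and same_labels
        )

    # -- views -------------------------------------------------------------

    def subset_features(self, names: Sequence[str]) -> "FeatureMatrix":
        index = {name: j for j, name in enumerate(self.feature_names)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"unknown feature name {missing[0]!r}")
        cols = [index[n] for n in names]
        return FeatureMatrix(self.ids, list(names), self.values[:, cols], self.labels)

    def take_rows(self, indices: Sequence[int]) -> "FeatureMatrix":
        idx = np.asarray(indices, dtype=int)
        labels = None if self.labels is None else self.labels[idx]
        return FeatureMatrix(
            [self.ids[i] for i in idx], self.feature_names, self.values[idx], labels
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> list:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    Sequences are upper-cased before validation.  Any residue outside the
    20-letter alphabet (including the ambiguity codes B, J, O, U, X, Z) is a
    parse error naming the record and position.
    """
    path = Path(path)
    text = path.read_text()
    stripped = text.lstrip()
    if stripped and not stripped.startswith(">"):
        raise ParseError(f"{path}: not a FASTA file (first record lacks '>')")
    records = []
    seen = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        if not entry.id:
            raise ParseError(f"{path}: malformed header (empty id)")
        if entry.id in seen:
            raise ParseError(f"{path}: duplicate id {entry.id!r}")
        seen.add(entry.id)
        records.append(ProteinRecord(entry.id, str(entry.seq).upper()))
    return records


def write_fasta(records: Iterable[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def sanitize_dataset(
    records: Sequence[ProteinRecord], min_len: int = 50, max_len: int = 3000
):
    """Split records into (kept, dropped) by the length screen.

    Bounds are inclusive: sequences of exactly ``min_len`` or ``max_len``
    residues are kept; shorter or longer ones are dropped with a
    machine-readable reason.  Ambiguous residues never reach this stage —
    they are rejected at parse time.
    """
    kept, dropped = [], []
    for rec in records:
        if len(rec) < min_len:
            dropped.append(DroppedRecord(rec, "too_short"))
        elif len(rec) > max_len:
            dropped.append(DroppedRecord(rec, "too_long"))
        else:
            kept.append(rec)
    return kept, dropped


# ---------------------------------------------------------------------------
# PSSM
# ---------------------------------------------------------------------------


def read_pssm(path, protein_id: str | None = None) -> PSSMProfile:
    """Parse a PSI-BLAST ASCII PSSM.

    The first 20 numeric columns of each row (the log-odds block) are kept;
    the weighted-percentage block, information content and weight columns
    are ignored.  Column order follows the file's header line.
    """
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    lines = path.read_text().splitlines()
    aa_order = None
    residues = []
    rows = []
    for lineno, line in enumerate(lines, start=1):
        tokens = line.split()
        if aa_order is None:
            # header: a run of >= 20 single amino-acid letters
            if len(tokens) >= 20 and all(t in _AA_SET and len(t) == 1 for t in tokens[:20]):
                aa_order = "".join(tokens[:20])
            continue
        if not tokens:
            continue
        if not tokens[0].isdigit():
            break  # footer (K/lambda statistics) ends the matrix
        if len(tokens) < 2 or tokens[1] not in _AA_SET:
            raise ParseError(f"{path}:{lineno}: expected 'index residue scores...'")
        numeric = tokens[2:22]
        if len(numeric) < 20:
            raise ParseError(
                f"{path}:{lineno}: expected 20 log-odds columns, found {len(numeric)}"
            )
        try:
            row = [float(t) for t in numeric]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric score cell ({exc})") from None
        residues.append(tokens[1])
        rows.append(row)
    if aa_order is None or not rows:
        raise ParseError(f"{path}: no PSSM header/rows found")
    return PSSMProfile(protein_id, "".join(residues), np.array(rows), aa_order)


def write_pssm(profile: PSSMProfile, path) -> None:
    """Write a profile in the PSI-BLAST ASCII layout :func:`read_pssm` reads."""
    with open(path, "w") as fh:
        fh.write("\nLast position-specific scoring matrix computed\n")
        fh.write("      " + "  ".join(profile.aa_order) + "\n")
        for i, (res, row) in enumerate(zip(profile.residues, profile.scores), start=1):
            cells = " ".join(f"{v:6.0f}" if float(v).is_integer() else f"{_fmt(v):>8}" for v in row)
            fh.write(f"{i:5d} {res} {cells}\n")


# ---------------------------------------------------------------------------
# per-residue tracks
# ---------------------------------------------------------------------------


def read_ss2(path, protein_id: str | None = None) -> SecondaryStructureTrack:
    """Parse a PSIPRED VFORMAT ``.ss2`` file into a state track."""
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    states = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split()
        if len(tokens) != 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns, found {len(tokens)}")
        _, residue, state, *probs = tokens
        if state not in SS_STATES:
            raise ParseError(f"{path}:{lineno}: illegal state {state!r}")
        try:
            pvals = [float(p) for p in probs]
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric probability") from None
        if any(p < 0 or p > 1.000001 for p in pvals):
            raise ParseError(f"{path}:{lineno}: probability outside [0, 1]")
        states.append(state)
    if not states:
        raise ParseError(f"{path}: no state rows found")
    return SecondaryStructureTrack(protein_id, "".join(states))


def write_ss2(track: SecondaryStructureTrack, residues: str, path) -> None:
    if len(residues) != len(track):
        raise ValueError("residue string length must match track length")
    probs = {"C": (1.0, 0.0, 0.0), "H": (0.0, 1.0, 0.0), "E": (0.0, 0.0, 1.0)}
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT\n\n")
        for i, (res, state) in enumerate(zip(residues, track.states), start=1):
            c, h, e = probs[state]
            fh.write(f"{i:4d} {res} {state}   {c:.3f}  {h:.3f}  {e:.3f}\n")


def read_disorder(path, protein_id: str | None = None) -> DisorderTrack:
    """Parse a per-residue disorder TSV: index, residue, score in [0, 1]."""
    path = Path(path)
    if protein_id is None:
        protein_id = path.stem
    scores = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split("\t")
        if len(tokens) != 3:
            raise ParseError(f"{path}:{lineno}: expected 3 tab-separated columns")
        try:
            score = float(tokens[2])
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric score") from None
        if score < 0 or score > 1:
            raise ParseError(f"{path}:{lineno}: disorder score {score} outside [0, 1]")
        scores.append(score)
    if not scores:
        raise ParseError(f"{path}: no score rows found")
    return DisorderTrack(protein_id, np.array(scores))


def write_disorder(track: DisorderTrack, residues: str, path) -> None:
    if len(residues) != len(track):
        raise ValueError("residue string length must match track length")
    with open(path, "w") as fh:
        for i, (res, score) in enumerate(zip(residues, track.scores), start=1):
            fh.write(f"{i}\t{res}\t{_fmt(score)}\n")


# ---------------------------------------------------------------------------
# domain annotations
# ---------------------------------------------------------------------------


def read_domains(path) -> DomainAnnotation:
    """Parse a two-column TSV (protein id, domain accession)."""
    path = Path(path)
    mapping: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if not stripped or stripped.startswith("#"):
            continue
        tokens = stripped.split("\t")
        if len(tokens) != 2:
            raise ParseError(f"{path}:{lineno}: expected 2 tab-separated columns")
        protein_id, accession = tokens
        mapping.setdefault(protein_id, set()).add(accession)
    return DomainAnnotation({pid: frozenset(accs) for pid, accs in mapping.items()})


def write_domains(annotation: DomainAnnotation, path) -> None:
    with open(path, "w") as fh:
        for pid in sorted(annotation.assignments):
            for acc in sorted(annotation.assignments[pid]):
                fh.write(f"{pid}\t{acc}\n")


# ---------------------------------------------------------------------------
# feature matrices
# ---------------------------------------------------------------------------

_LABEL_STR = {1: "positive", 0: "negative"}
_STR_LABEL = {"positive": 1, "negative": 0}


def write_feature_matrix(matrix: FeatureMatrix, path) -> None:
    with open(path, "w") as fh:
        header = ["id"] + matrix.feature_names
        if matrix.labels is not None:
            header.append("label")
        fh.write(",".join(header) + "\n")
        for i, sample_id in enumerate(matrix.ids):
            cells = [sample_id] + [_fmt(v) for v in matrix.values[i]]
            if matrix.labels is not None:
                cells.append(_LABEL_STR[int(matrix.labels[i])])
            fh.write(",".join(cells) + "\n")


def read_feature_matrix(path) -> FeatureMatrix:
    path = Path(path)
    frame = pd.read_csv(path, dtype={0: str})
    if frame.columns[0] != "id":
        raise ParseError(f"{path}: first column must be 'id'")
    labels = None
    if "label" in frame.columns:
        raw = frame.pop("label")
        try:
            labels = raw.map(_STR_LABEL).to_numpy(dtype=float)
        except Exception:
            raise ParseError(f"{path}: labels must be 'positive' or 'negative'") from None
        if np.any(np.isnan(labels)):
            raise ParseError(f"{path}: labels must be 'positive' or 'negative'")
        labels = labels.astype(int)
    ids = frame.pop("id").tolist()
    values = frame.to_numpy(dtype=float)
    if np.any(~np.isfinite(values)):
        raise ParseError(f"{path}: missing or non-finite feature value")
    return FeatureMatrix(ids, list(frame.columns), values, labels)


# ---------------------------------------------------------------------------
# model archives
# ---------------------------------------------------------------------------


def save_model(model, path) -> None:
    """Serialize an ensemble model to a directory archive.

    The archive holds a JSON config (feature names, seed, vote rule,
    forest parameters, optional domain vocabulary) plus the trained members
    in a joblib file.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    config = {
        "feature_names": list(model.feature_names),
        "seed": int(model.seed),
        "tie_rule": model.tie_rule,
        "rf_params": dataclasses.asdict(model.rf_params),
        "vocabulary": list(model.vocabulary) if model.vocabulary is not None else None,
    }
    (path / "config.json").write_text(json.dumps(config, indent=2) + "\n")
    joblib.dump(model.members, path / "members.joblib")


def load_model(path):
    from .ensemble import EnsembleModel, RFParams  # local import avoids a cycle

    path = Path(path)
    config = json.loads((path / "config.json").read_text())
    members = joblib.load(path / "members.joblib")
    vocab = config.get("vocabulary")
    return EnsembleModel(
        members=members,
        feature_names=tuple(config["feature_names"]),
        seed=config["seed"],
        rf_params=RFParams(**config["rf_params"]),
        tie_rule=config["tie_rule"],
        vocabulary=tuple(vocab) if vocab is not None else None,
    )
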