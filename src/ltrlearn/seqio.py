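"""Sequence and motif I/O.

Reads and writes the formats the toolkit touches -- FASTA with labels
carried in the header, JASPAR position frequency matrices, and the MEME
minimal motif format -- and normalizes records into the internal types
:class:`LabeledSequence` and :class:`PWMotif`.

Conventions
-----------
* Coordinates are 0-based, half-open, in the given (element) orientation.
* Lower-case bases and U are normalized to the upper-case T-alphabet.
* FASTA headers carry labels in a configurable ``|``-separated scheme,
  default ``id|species|superfamily|family``; unparseable fields are left
  unset rather than guessed.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO, motifs as bio_motifs
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SUPERFAMILIES = ("Ty1/Copia", "Ty3/Gypsy")
ALPHABET = "ACGT"
DEFAULT_HEADER_SCHEME = ("id", "species", "superfamily", "family")


class FastaFormatError(ValueError):
    """Malformed FASTA input."""


class MotifFormatError(ValueError):
    """Malformed motif matrix input."""


def _normalize_sequence(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - set(ALPHABET + "N")
    if bad:
        raise ValueError(f"sequence contains non-DNA characters: {sorted(bad)}")
    return s


@dataclass
class LabeledSequence:
    """One DNA sequence with identity and task labels.

    ``is_ltr`` / ``superfamily`` / ``family`` correspond to the three
    classification tasks (LTR detection, superfamily, family).  A family
    label implies a superfamily label.
    """

    id: str
    sequence: str
    species: str | None = None
    is_ltr: bool | None = None
    superfamily: str | None = None
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for record {self.id!r}")
        self.sequence = _normalize_sequence(self.sequence)
        if self.superfamily is not None and self.superfamily not in SUPERFAMILIES:
            raise ValueError(
                f"unknown superfamily {self.superfamily!r}; expected one of {SUPERFAMILIES}"
            )
        if self.family is not None and self.superfamily is None:
            raise ValueError(f"record {self.id!r}: family label requires a superfamily label")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PWMotif:
    """A named position frequency/probability matrix over A,C,G,T.

    ``matrix`` has shape (4, width); row order is A, C, G, T.
    """

    name: str
    matrix: np.ndarray
    kind: str = "counts"  # "counts" | "probabilities"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != 4:
            raise MotifFormatError(
                f"motif {self.name!r}: matrix must have shape (4, width), got {self.matrix.shape}"
            )
        if self.matrix.shape[1] < 1:
            raise MotifFormatError(f"motif {self.name!r}: zero-width matrix")
        if np.any(self.matrix < 0):
            raise ValueError(f"motif {self.name!r}: negative matrix entries")
        if self.kind not in ("counts", "probabilities"):
            raise ValueError(f"motif {self.name!r}: unknown kind {self.kind!r}")
        colsums = self.matrix.sum(axis=0)
        if self.kind == "probabilities":
            if not np.allclose(colsums, 1.0, atol=1e-6):
                raise ValueError(f"motif {self.name!r}: probability columns must sum to 1")
        else:
            if np.any(colsums <= 0):
                raise ValueError(f"motif {self.name!r}: count columns must have a positive entry")

    @property
    def width(self) -> int:
        return int(self.matrix.shape[1])

    def to_probabilities(self, pseudocount: float = 0.0) -> "PWMotif":
        """Column-normalize counts to probabilities, optionally smoothed."""
        if self.kind == "probabilities" and pseudocount == 0.0:
            return self
        m = self.matrix + pseudocount
        return PWMotif(self.name, m / m.sum(axis=0, keepdims=True), kind="probabilities")

    def log_odds(self, background: Sequence[float] | None = None, pseudocount: float = 0.8) -> np.ndarray:
        """Log-odds scoring matrix against a background distribution.

        The pseudocount is added to counts (or to probabilities scaled as
        counts) before taking logs so that zero cells stay finite.
        """
        bg = np.asarray(background if background is not None else [0.25] * 4, dtype=float)
        if bg.shape != (4,) or not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-6):
            raise ValueError("background must be 4 probabilities summing to 1")
        probs = self.to_probabilities(pseudocount=pseudocount).matrix
        return np.log2(probs / bg[:, None])

    def reverse_complement(self) -> "PWMotif":
        return PWMotif(self.name + "_rc", self.matrix[::-1, ::-1], kind=self.kind)


# ---------------------------------------------------------------------------
# FASTA


def _parse_header(header: str, scheme: Sequence[str]) -> dict:
    fields = header.split("|")
    out: dict = {}
    for key, value in zip(scheme, fields):
        value = value.strip()
        if not value or value in ("NA", "None", "."):
            continue
        if key == "is_ltr":
            out[key] = value.lower() in ("1", "true", "ltr", "yes")
        elif key == "superfamily":
            if value in SUPERFAMILIES:
                out[key] = value
        else:
            out[key] = value
    # a family without a parseable superfamily cannot be represented
    if "family" in out and "superfamily" not in out:
        del out["family"]
    return out


def read_fasta(
    path: str | Path,
    header_scheme: Sequence[str] = DEFAULT_HEADER_SCHEME,
    is_ltr: bool | None = None,
) -> list[LabeledSequence]:
    """Read FASTA into labeled records.

    Labels are parsed from ``|``-separated header fields according to
    ``header_scheme``; fields that fail to parse are left unset.  ``is_ltr``
    applies a blanket detection label to every record (positive/negative
    set files usually carry it implicitly).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise FastaFormatError(f"{path}: empty FASTA file")
    first = next((ln for ln in text.splitlines() if ln.strip()), "")
    if not first.startswith(">"):
        raise FastaFormatError(f"{path}: line 1: expected '>' header, got {first[:30]!r}")
    records = []
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        labels = _parse_header(rec.description, header_scheme)
        labels.setdefault("id", rec.id)
        if is_ltr is not None:
            labels["is_ltr"] = is_ltr
        if not str(rec.seq):
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        records.append(LabeledSequence(sequence=str(rec.seq), **labels))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return records


def format_header(seq: LabeledSequence, header_scheme: Sequence[str] = DEFAULT_HEADER_SCHEME) -> str:
    parts = []
    for key in header_scheme:
        value = getattr(seq, key, None)
        if key == "is_ltr" and value is not None:
            value = "LTR" if value else "nonLTR"
        parts.append("" if value is None else str(value))
    return "|".join(parts).rstrip("|")


def write_fasta(
    seqs: Iterable[LabeledSequence],
    path: str | Path,
    header_scheme: Sequence[str] = DEFAULT_HEADER_SCHEME,
    width: int = 70,
) -> None:
    """Write records with labels serialized into the header scheme."""
    records = [
        SeqRecord(Seq(s.sequence), id=format_header(s, header_scheme), description="")
        for s in seqs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# JASPAR PFM


def read_jaspar_pfm(path: str | Path) -> list[PWMotif]:
    """Read JASPAR-style position frequency matrices.

    Accepts both the bracketed dialect (``A  [ 0  3 79 ... ]``) and the bare
    four-row dialect (four whitespace-separated count rows per ``>`` header,
    in A, C, G, T order).  Returns counts-kind motifs.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    motifs: list[PWMotif] = []
    name: str | None = None
    rows: dict[str, list[float]] = {}
    order: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal name, rows, order
        if name is None:
            return
        if len(order) != 4:
            raise MotifFormatError(f"{path}: motif {name!r} has {len(order)} rows, expected 4")
        widths = {len(rows[b]) for b in order}
        if len(widths) != 1:
            raise MotifFormatError(
                f"{path}: motif {name!r} near line {lineno}: row lengths differ ({sorted(widths)})"
            )
        matrix = np.array([rows[b] for b in "ACGT"], dtype=float)
        if np.any(matrix < 0):
            raise ValueError(f"{path}: motif {name!r}: negative count")
        motifs.append(PWMotif(name, matrix, kind="counts"))
        name, rows, order = None, {}, []

    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush(i)
            name = line[1:].strip().split("\t")[0].split()[0] or f"motif_{len(motifs) + 1}"
        else:
            if name is None:
                raise MotifFormatError(f"{path}: line {i}: matrix row before any '>' header")
            tokens = line.replace("[", " ").replace("]", " ").split()
            base = None
            if tokens and tokens[0].upper() in "ACGT" and len(tokens[0]) == 1:
                base = tokens[0].upper()
                tokens = tokens[1:]
            if base is None:
                base = "ACGT"[len(order)]
            if base in rows:
                raise MotifFormatError(f"{path}: line {i}: duplicate {base} row in motif {name!r}")
            try:
                rows[base] = [float(t) for t in tokens]
            except ValueError as exc:
                raise MotifFormatError(f"{path}: line {i}: non-numeric matrix entry") from exc
            order.append(base)
            if len(order) == 4:
                flush(i)
    flush(len(lines))
    if not motifs:
        raise MotifFormatError(f"{path}: no motifs found")
    return motifs


def write_jaspar_pfm(motifs: Iterable[PWMotif], path: str | Path) -> None:
    """Write counts-kind motifs in the bracketed JASPAR dialect."""
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.name}\n")
            for base, row in zip("ACGT", m.matrix):
                cells = " ".join(f"{v:g}" for v in row)
                fh.write(f"{base}  [ {cells} ]\n")


# ---------------------------------------------------------------------------
# MEME minimal format

_MEME_HEADER = """MEME version 4

ALPHABET= ACGT

strands: +

Background letter frequencies
A {0:.6f} C {1:.6f} G {2:.6f} T {3:.6f}
"""


def write_meme(
    motifs: Sequence[PWMotif],
    background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
    nsites: int = 1_000_000,  # readers rebuild counts as p*nsites; keep quantization < 1e-6
) -> str:
    """Render probability motifs as MEME minimal motif format v4 text.

    Counts-kind motifs are rejected: call ``to_probabilities()`` first so
    the normalization (and its pseudocount) is an explicit choice.
    """
    bg = np.asarray(background, dtype=float)
    if bg.shape != (4,) or not math.isclose(float(bg.sum()), 1.0, abs_tol=1e-6):
        raise ValueError("background must be 4 probabilities summing to 1")
    out = [_MEME_HEADER.format(*bg)]
    for m in motifs:
        if m.kind != "probabilities":
            raise ValueError(
                f"motif {m.name!r} is counts-kind; call to_probabilities() before MEME export"
            )
        out.append(f"\nMOTIF {m.name}\n")
        out.append(
            f"letter-probability matrix: alength= 4 w= {m.width} nsites= {nsites} E= 0\n"
        )
        for col in m.matrix.T:
            out.append(" " + " ".join(f"{p:.6f}" for p in col) + "\n")
    return "".join(out)


def read_meme(source: str | Path) -> list[PWMotif]:
    """Read MEME minimal format text (or a path to it) into probability motifs."""
    text = source if isinstance(source, str) and "\n" in source else Path(source).read_text()
    records = bio_motifs.parse(io.StringIO(text), "minimal")
    out = []
    for rec in records:
        matrix = np.array([rec.pwm[b] for b in "ACGT"], dtype=float)
        out.append(PWMotif(rec.name, matrix, kind="probabilities"))
    return out
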