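"""Readers and writers for every on-disk format the pipeline touches.

Formats handled:

* FASTA chain files (via :mod:`Bio.SeqIO`),
* PSI-BLAST ASCII position-specific scoring matrices,
* PSIPRED ``.ss2`` three-state secondary-structure predictions,
* a two-line-per-chain binary label format (``>chain_id`` then a 0/1 string),
* the per-residue TSV prediction output.

Positions are 1-based in all files and 0-based in memory.  Unknown residue
letters are mapped to ``X`` (never dropped) so label and profile rows stay
aligned with the sequence.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger("atpres")

#: The 20 standard one-letter amino-acid codes.
STANDARD_AA = "ARNDCQEGHILKMFPSTWYV"

#: Column order of the 20 log-odds columns in PSI-BLAST ASCII output.
PSSM_COLUMNS = "ARNDCQEGHILKMFPSTWYV"

_VALID_LETTERS = set(STANDARD_AA) | {"X"}


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class LengthMismatchError(ValueError):
    """Per-residue tracks disagree in length with the chain sequence."""


@dataclass
class ChainRecord:
    """One protein chain: identifier, sequence and optional binding labels.

    ``labels`` (when present) holds one 0/1 entry per residue, 1 marking an
    ATP-binding residue.
    """

    chain_id: str
    sequence: str
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"chain {self.chain_id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_LETTERS
        if bad:
            raise ValueError(
                f"chain {self.chain_id!r}: invalid letters {sorted(bad)}"
            )
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=np.int8)
            if self.labels.shape != (len(self.sequence),):
                raise LengthMismatchError(
                    f"chain {self.chain_id!r}: {self.labels.size} labels for "
                    f"{len(self.sequence)} residues"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class RawProfile:
    """Raw L x 20 integer log-odds profile in PSI-BLAST column order."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2 or self.values.shape[1] != 20:
            raise ValueError(f"profile must be Lx20, got {self.values.shape}")
        if not np.isfinite(self.values).all():
            raise ValueError("profile contains non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass
class SSTrack:
    """L x 3 secondary-structure probabilities, columns ordered (C, H, E)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != 3:
            raise ValueError(f"ss track must be Lx3, got {self.probs.shape}")
        if (self.probs < 0).any():
            raise ValueError("ss probabilities must be nonnegative")

    def __len__(self) -> int:
        return self.probs.shape[0]


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def sanitize_sequence(seq: str, chain_id: str = "?") -> str:
    """Uppercase *seq* and map non-standard letters (other than X) to X."""
    seq = seq.upper()
    out = []
    warned = False
    for ch in seq:
        if ch in _VALID_LETTERS:
            out.append(ch)
        else:
            if not warned:
                logger.warning(
                    "chain %s: non-standard residue %r mapped to X", chain_id, ch
                )
                warned = True
            out.append("X")
    return "".join(out)


def read_fasta(path: str | Path) -> list[ChainRecord]:
    """Read a FASTA file into :class:`ChainRecord` objects.

    Sequences are uppercased; letters outside the 20 standard codes plus X
    are replaced by X with a logged warning.  An empty file yields an empty
    list.
    """
    path = Path(path)
    records: list[ChainRecord] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        seq = sanitize_sequence(str(rec.seq), rec.id)
        records.append(ChainRecord(chain_id=rec.id, sequence=seq))
    return records


def write_fasta(chains: Sequence[ChainRecord], path: str | Path) -> None:
    """Write chains to FASTA, 60 columns per line."""
    with open(path, "w") as fh:
        for c in chains:
            fh.write(f">{c.chain_id}\n")
            for i in range(0, len(c.sequence), 60):
                fh.write(c.sequence[i : i + 60] + "\n")


# ---------------------------------------------------------------------------
# PSI-BLAST ASCII PSSM
# ---------------------------------------------------------------------------

def read_pssm_ascii(
    path: str | Path, chain: ChainRecord | None = None
) -> RawProfile:
    """Parse a PSI-BLAST ASCII matrix, returning the 20 log-odds columns.

    Both the 40-column (log-odds + percentages) and bare 20-column body
    variants are accepted; only the log-odds block is returned.  When *chain*
    is supplied the residue column is cross-checked against its sequence.
    """
    path = Path(path)
    rows: list[list[int]] = []
    letters: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            # data rows start "index letter <numbers...>"
            if len(tokens) < 22 or not tokens[0].isdigit():
                continue
            idx, letter = tokens[0], tokens[1]
            if len(letter) != 1 or not letter.isalpha():
                continue
            body = tokens[2:22]
            try:
                values = [int(t) for t in body]
            except ValueError as exc:
                raise FormatError(
                    f"{path}:{lineno}: non-integer token in log-odds block "
                    f"({exc})"
                ) from None
            expected = len(rows) + 1
            if int(idx) != expected:
                raise FormatError(
                    f"{path}:{lineno}: residue index {idx}, expected {expected}"
                )
            rows.append(values)
            letters.append(letter.upper())
    profile = RawProfile(np.asarray(rows, dtype=np.int64).reshape(-1, 20))
    if chain is not None:
        if len(profile) != len(chain):
            raise LengthMismatchError(
                f"{path}: {len(profile)} profile rows for chain "
                f"{chain.chain_id!r} of length {len(chain)}"
            )
        for i, (a, b) in enumerate(zip(letters, chain.sequence)):
            # X in the chain stands for an unknown letter; skip the check there
            if b != "X" and a != b:
                raise FormatError(
                    f"{path}: residue mismatch at row {i + 1}: "
                    f"profile has {a!r}, chain has {b!r}"
                )
    return profile


def write_pssm_ascii(
    profile: RawProfile, sequence: str, path: str | Path
) -> None:
    """Emit a profile in the PSI-BLAST ASCII dialect (40-column body).

    The percentage block is filled with zeros and the two trailing floats
    with placeholder values; readers only consume the log-odds block.
    """
    values = np.asarray(profile.values, dtype=np.int64)
    if values.shape[0] != len(sequence):
        raise LengthMismatchError(
            f"{values.shape[0]} profile rows for {len(sequence)} residues"
        )
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write(
            "Last position-specific scoring matrix computed, weighted "
            "observed percentages rounded down, information per position, "
            "and relative weight of gapless real matches to pseudocounts\n"
        )
        fh.write(" " * 11 + "  ".join(PSSM_COLUMNS) + "   "
                 + "  ".join(PSSM_COLUMNS) + "\n")
        for i, (letter, row) in enumerate(zip(sequence, values), start=1):
            lod = " ".join(f"{v:3d}" for v in row)
            pct = " ".join(f"{0:3d}" for _ in range(20))
            fh.write(f"{i:5d} {letter} {lod}  {pct}  0.00 0.00\n")
        fh.write("\n")


# ---------------------------------------------------------------------------
# PSIPRED ss2
# ---------------------------------------------------------------------------

def read_ss2(path: str | Path) -> SSTrack:
    """Parse a PSIPRED ``.ss2`` file into an L x 3 (C, H, E) track.

    Rows are renormalized to sum to 1.  Probabilities outside [0, 1] before
    normalization raise :class:`FormatError`.  An empty body yields a
    zero-row track.
    """
    path = Path(path)
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split()
            if len(tokens) != 6:
                raise FormatError(
                    f"{path}:{lineno}: expected 6 fields, got {len(tokens)}"
                )
            try:
                probs = [float(t) for t in tokens[3:6]]
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric probability"
                ) from None
            if any(p < 0.0 or p > 1.0 for p in probs):
                raise FormatError(
                    f"{path}:{lineno}: probability outside [0, 1]"
                )
            rows.append(probs)
    probs = np.asarray(rows, dtype=float).reshape(-1, 3)
    if len(probs):
        sums = probs.sum(axis=1)
        if (sums <= 0).any():
            raise FormatError(f"{path}: all-zero probability row")
        probs = probs / sums[:, None]
    return SSTrack(probs)


def write_ss2(track: SSTrack, sequence: str, path: str | Path) -> None:
    """Write an (C, H, E) track in the PSIPRED ``.ss2`` dialect."""
    if len(track) != len(sequence):
        raise LengthMismatchError(
            f"{len(track)} ss rows for {len(sequence)} residues"
        )
    states = "CHE"
    with open(path, "w") as fh:
        fh.write("# PSIPRED VFORMAT (PSIPRED V4.0)\n\n")
        for i, (letter, row) in enumerate(zip(sequence, track.probs), start=1):
            state = states[int(np.argmax(row))]
            fh.write(
                f"{i:4d} {letter} {state}  {row[0]:6.3f} {row[1]:6.3f} "
                f"{row[2]:6.3f}\n"
            )


# ---------------------------------------------------------------------------
# Binary label files
# ---------------------------------------------------------------------------

def read_labels(path: str | Path) -> dict[str, np.ndarray]:
    """Read the two-line-per-chain label format into ``{chain_id: 0/1 array}``."""
    path = Path(path)
    labels: dict[str, np.ndarray] = {}
    chain_id: str | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                chain_id = line[1:].strip()
                if not chain_id:
                    raise FormatError(f"{path}:{lineno}: empty chain id")
            else:
                if chain_id is None:
                    raise FormatError(
                        f"{path}:{lineno}: label line before any header"
                    )
                if set(line) - {"0", "1"}:
                    raise FormatError(
                        f"{path}:{lineno}: labels must be a 0/1 string"
                    )
                labels[chain_id] = np.fromiter(
                    (int(c) for c in line), dtype=np.int8, count=len(line)
                )
                chain_id = None
    return labels


def write_labels(labels: dict[str, np.ndarray], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chain_id, vec in labels.items():
            fh.write(f">{chain_id}\n")
            fh.write("".join(str(int(v)) for v in vec) + "\n")


def attach_labels(
    chains: Sequence[ChainRecord], labels: dict[str, np.ndarray]
) -> list[ChainRecord]:
    """Return chains with labels attached, validating lengths per chain."""
    out = []
    for c in chains:
        if c.chain_id not in labels:
            raise KeyError(f"no labels for chain {c.chain_id!r}")
        vec = labels[c.chain_id]
        if vec.size != len(c):
            raise LengthMismatchError(
                f"chain {c.chain_id!r}: label string length {vec.size} for "
                f"{len(c)}-residue chain"
            )
        out.append(ChainRecord(c.chain_id, c.sequence, vec))
    return out


# ---------------------------------------------------------------------------
# Prediction TSV
# ---------------------------------------------------------------------------

PREDICTION_COLUMNS = [
    "chain_id",
    "position",
    "residue",
    "prob_incepres",
    "prob_xception",
    "prob_gbm",
    "prob_ensemble",
    "template_hit",
    "final_label",
]


def write_predictions(
    chains: Sequence[ChainRecord],
    tracks: dict[str, dict[str, np.ndarray]],
    path: str | Path,
    template_hits: dict[str, np.ndarray] | None = None,
    final_labels: dict[str, np.ndarray] | None = None,
) -> None:
    """Write the per-residue prediction TSV.

    *tracks* maps chain_id to a dict with keys ``incepres``, ``xception``,
    ``gbm``, ``ensemble`` (probability arrays over residues).  Missing
    template tracks default to all-zero; missing final labels default to 0.
    Positions are written 1-based; probabilities with 6 decimals.
    """
    rows = []
    for c in chains:
        t = tracks[c.chain_id]
        arrays = {k: np.asarray(v, dtype=float) for k, v in t.items()}
        for name, arr in arrays.items():
            if arr.shape != (len(c),):
                raise LengthMismatchError(
                    f"chain {c.chain_id!r}: track {name!r} has length "
                    f"{arr.size}, expected {len(c)}"
                )
        tmpl = (
            np.asarray(template_hits[c.chain_id], dtype=int)
            if template_hits and c.chain_id in template_hits
            else np.zeros(len(c), dtype=int)
        )
        final = (
            np.asarray(final_labels[c.chain_id], dtype=int)
            if final_labels and c.chain_id in final_labels
            else np.zeros(len(c), dtype=int)
        )
        if tmpl.shape != (len(c),) or final.shape != (len(c),):
            raise LengthMismatchError(
                f"chain {c.chain_id!r}: template/final track length mismatch"
            )
        for i in range(len(c)):
            rows.append(
                (
                    c.chain_id,
                    i + 1,
                    c.sequence[i],
                    round(float(arrays["incepres"][i]), 6),
                    round(float(arrays["xception"][i]), 6),
                    round(float(arrays["gbm"][i]), 6),
                    round(float(arrays["ensemble"][i]), 6),
                    int(tmpl[i]),
                    int(final[i]),
                )
            )
    df = pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_predictions(path: str | Path) -> pd.DataFrame:
    """Re-read a prediction TSV written by :func:`write_predictions`."""
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Optional external-tool wrappers (disabled by default; require the tools
# and their databases on the host — never exercised by tests)
# ---------------------------------------------------------------------------

def run_psiblast(
    chain: ChainRecord,
    database: str,
    out_pssm: str | Path,
    iterations: int = 3,
    evalue: float = 1e-3,
) -> RawProfile:  # pragma: no cover - requires external tool + database
    """Generate a real evolutionary profile with psiblast (3 iterations,
    E-value 1e-3) and parse the resulting ASCII matrix."""
    import subprocess
    import tempfile

    if shutil.which("psiblast") is None:
        raise RuntimeError("psiblast executable not found on PATH")
    with tempfile.NamedTemporaryFile("w", suffix=".fasta") as fh:
        fh.write(f">{chain.chain_id}\n{chain.sequence}\n")
        fh.flush()
        subprocess.run(
            [
                "psiblast", "-query", fh.name, "-db", database,
                "-num_iterations", str(iterations), "-evalue", str(evalue),
                "-out_ascii_pssm", str(out_pssm),
            ],
            check=True, capture_output=True,
        )
    return read_pssm_ascii(out_pssm, chain)


def run_psipred(
    chain: ChainRecord, out_ss2: str | Path
) -> SSTrack:  # pragma: no cover - requires external tool
    """Predict secondary structure with a local PSIPRED install."""
    import subprocess
    import tempfile

    if shutil.which("runpsipred") is None:
        raise RuntimeError("runpsipred executable not found on PATH")
    with tempfile.NamedTemporaryFile(
        "w", suffix=".fasta", delete=False
    ) as fh:
        fh.write(f">{chain.chain_id}\n{chain.sequence}\n")
        fasta = fh.name
    subprocess.run(["runpsipred", fasta], check=True, capture_output=True)
    produced = Path(fasta).with_suffix(".ss2")
    produced.replace(out_ss2)
    return read_ss2(out_ss2)
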