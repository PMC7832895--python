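"""Homology template transfer: annotate a query from similar training chains.

Homologous chains tend to bind ATP at equivalent positions, so a query is
locally aligned against every labeled training chain; when an alignment
scores at least 50 bits, binding annotations are copied across the matched
(non-gap) columns.  The transferred track is OR-combined with the
thresholded ensemble call — the template route is precise but has low
coverage, so it only ever adds positives.

The default backend is Smith–Waterman local alignment (Biopython's pairwise
aligner) with BLOSUM62 and affine gaps (open 11, extend 1); raw scores S
are converted to bits with the standard gapped Karlin–Altschul parameters
for that scoring system:

    bits = (lambda * S - ln K) / ln 2,   lambda = 0.267, K = 0.041.

An optional ``psiblast`` subprocess backend reproduces database-search bit
scores exactly when the external tool is installed; it is never required.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .io_formats import ChainRecord

logger = logging.getLogger("atpres")

KARLIN_LAMBDA = 0.267
KARLIN_K = 0.041
DEFAULT_MIN_BIT_SCORE = 50.0
GAP_OPEN = 11
GAP_EXTEND = 1


def bit_score(raw_score: float, lam: float = KARLIN_LAMBDA,
              k: float = KARLIN_K) -> float:
    """Rescale a raw alignment score into base-2 information units."""
    return (lam * raw_score - np.log(k)) / np.log(2.0)


@dataclass
class TemplateHit:
    query_id: str
    template_id: str
    bit_score: float
    aligned_pairs: list[tuple[int, int]]  # 0-based matched columns


@dataclass
class TemplateDB:
    """Labeled training chains plus the alignment parameterization."""

    chains: list[ChainRecord]
    matrix_name: str = "BLOSUM62"
    gap_open: int = GAP_OPEN
    gap_extend: int = GAP_EXTEND
    lam: float = KARLIN_LAMBDA
    k: float = KARLIN_K

    def __post_init__(self) -> None:
        for c in self.chains:
            if c.labels is None:
                raise ValueError(
                    f"template chain {c.chain_id!r} has no labels"
                )

    def __len__(self) -> int:
        return len(self.chains)


def _make_aligner(db: TemplateDB) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(db.matrix_name)
    # a gap of length g costs open + (g - 1) * extend
    aligner.open_gap_score = -float(db.gap_open)
    aligner.extend_gap_score = -float(db.gap_extend)
    return aligner


def _aligned_pairs(alignment) -> list[tuple[int, int]]:
    pairs: list[tuple[int, int]] = []
    for (qs, qe), (ts, te) in zip(*alignment.aligned):
        pairs.extend(zip(range(qs, qe), range(ts, te)))
    return pairs


def search_templates(
    query: ChainRecord,
    db: TemplateDB,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
) -> list[TemplateHit]:
    """Align the query against every template; keep hits >= the bit cutoff.

    Hits are sorted by bit score, descending.  A chain in the database with
    the query's own id is skipped (self-hit guard for cross-validation).
    An empty database yields an empty list with a warning.
    """
    if len(db) == 0:
        logger.warning("template search against an empty database")
        return []
    aligner = _make_aligner(db)
    hits: list[TemplateHit] = []
    for template in db.chains:
        if template.chain_id == query.chain_id:
            continue
        alignments = aligner.align(query.sequence, template.sequence)
        try:
            best = alignments[0]
        except IndexError:
            continue
        bits = bit_score(best.score, db.lam, db.k)
        if bits >= min_bit_score:
            hits.append(
                TemplateHit(
                    query_id=query.chain_id,
                    template_id=template.chain_id,
                    bit_score=float(bits),
                    aligned_pairs=_aligned_pairs(best),
                )
            )
    hits.sort(key=lambda h: h.bit_score, reverse=True)
    return hits


def transfer_annotations(
    hits: list[TemplateHit], db: TemplateDB, query_length: int
) -> np.ndarray:
    """Union of transferred labels: query position q is 1 iff some hit
    aligns it to a template position labeled 1.  No hits -> all zero."""
    track = np.zeros(query_length, dtype=np.int8)
    by_id = {c.chain_id: c for c in db.chains}
    for hit in hits:
        template = by_id[hit.template_id]
        for q, t in hit.aligned_pairs:
            if template.labels[t] == 1:
                track[q] = 1
    return track


def combine_final(
    ensemble_track: np.ndarray, threshold: float, template_track: np.ndarray
) -> np.ndarray:
    """Final binary call: ensemble probability above threshold OR template."""
    ensemble_track = np.asarray(ensemble_track, dtype=float)
    template_track = np.asarray(template_track).astype(bool)
    if ensemble_track.shape != template_track.shape:
        raise ValueError("ensemble and template tracks differ in length")
    return ((ensemble_track > threshold) | template_track).astype(np.int8)


def hits_to_tsv(hits: list[TemplateHit], db: TemplateDB, path) -> None:
    by_id = {c.chain_id: c for c in db.chains}
    with open(path, "w") as fh:
        fh.write("query\ttemplate\tbit_score\tn_aligned\tn_transferred\n")
        for h in hits:
            template = by_id[h.template_id]
            n_transferred = sum(
                1 for _, t in h.aligned_pairs if template.labels[t] == 1
            )
            fh.write(
                f"{h.query_id}\t{h.template_id}\t{h.bit_score:.2f}\t"
                f"{len(h.aligned_pairs)}\t{n_transferred}\n"
            )


# ---------------------------------------------------------------------------
# Optional psiblast subprocess backend (never used by tests)
# ---------------------------------------------------------------------------


def psiblast_available() -> bool:
    return shutil.which("psiblast") is not None


def search_templates_psiblast(
    query: ChainRecord,
    db: TemplateDB,
    min_bit_score: float = DEFAULT_MIN_BIT_SCORE,
) -> list[TemplateHit]:  # pragma: no cover - requires external tool
    """Bit scores from an actual psiblast run against the template set.

    Disabled by default; requires the `psiblast` and `makeblastdb`
    executables on PATH.
    """
    if not psiblast_available():
        raise RuntimeError("psiblast executable not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        dbfasta = tmp / "db.fasta"
        with open(dbfasta, "w") as fh:
            for c in db.chains:
                fh.write(f">{c.chain_id}\n{c.sequence}\n")
        subprocess.run(
            ["makeblastdb", "-in", str(dbfasta), "-dbtype", "prot"],
            check=True, capture_output=True,
        )
        qfasta = tmp / "q.fasta"
        qfasta.write_text(f">{query.chain_id}\n{query.sequence}\n")
        out = subprocess.run(
            [
                "psiblast", "-query", str(qfasta), "-db", str(dbfasta),
                "-outfmt", "6 sseqid bitscore qstart qend sstart send",
            ],
            check=True, capture_output=True, text=True,
        ).stdout
    hits = []
    for line in out.splitlines():
        sseqid, bits, qs, qe, ss, se = line.split("\t")
        if float(bits) < min_bit_score:
            continue
        # approximate pair list from the ungapped envelope
        pairs = list(zip(range(int(qs) - 1, int(qe)),
                         range(int(ss) - 1, int(se))))
        hits.append(TemplateHit(query.chain_id, sseqid, float(bits), pairs))
    hits.sort(key=lambda h: h.bit_score, reverse=True)
    return hits
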