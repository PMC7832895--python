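"""Download-free synthetic fixtures with the pipeline's assumed structure.

The generator emits chains, evolutionary profiles, secondary-structure
tracks and binding labels in exactly the on-disk formats the io layer
reads.  The stated world it emulates:

* residues i.i.d. uniform over the 20 standard letters;
* binding residues occur in contiguous runs (``motif_width``), placed
  uniformly without overlap until a target ``binding_fraction`` of
  1/26 ~ 0.038 is met, giving the ~25:1 nonbinding:binding imbalance the
  real training sets show;
* profile rows are background integers in [-3, 3]; at binding positions
  the columns for {G, K, T, S} are boosted by ``round(signal_strength)``
  — a nod to the glycine-rich P-loop composition of many ATP-binding
  motifs, though any fixed column subset would serve;
* secondary-structure probabilities are Dirichlet draws with coil favored
  inside binding runs (only while a signal is planted: a null world with
  ``signal_strength`` 0 carries no label information in any track).

Everything is reproducible bit-for-bit under the seed.  What the generator
does *not* emulate: real PSI-BLAST score correlations along the chain,
database-dependent profile sharpness, and homology between chains (except
through :func:`simulate_homolog`).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io_formats import (
    ChainRecord,
    RawProfile,
    SSTrack,
    STANDARD_AA,
    PSSM_COLUMNS,
    write_fasta,
    write_labels,
    write_pssm_ascii,
    write_ss2,
)

#: Profile columns boosted at binding positions (P-loop-like composition).
SIGNAL_COLUMNS = tuple(PSSM_COLUMNS.index(a) for a in "GKTS")


@dataclass
class SimConfig:
    n_chains: int = 20
    length_range: tuple[int, int] = (80, 120)
    binding_fraction: float = 1.0 / 26.0  # ~25:1 imbalance
    signal_strength: float = 3.0
    motif_width: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.binding_fraction < 1.0):
            raise ValueError("binding_fraction must be in (0, 1)")
        if self.length_range[0] < 17:
            raise ValueError("chains must be at least one window (17) long")
        if self.motif_width < 1:
            raise ValueError("motif_width must be >= 1")


def _place_binding_runs(
    length: int, target: int, motif_width: int, rng: np.random.Generator
) -> np.ndarray:
    """Mark ``target`` positions as binding, in non-overlapping runs."""
    labels = np.zeros(length, dtype=np.int8)
    if target == 0:
        return labels
    if target > length // 2:
        raise ValueError(
            f"cannot place {target} binding residues in a chain of "
            f"{length} (fraction/motif combination infeasible)"
        )
    remaining = target
    attempts = 0
    while remaining > 0:
        width = min(motif_width, remaining)
        start = int(rng.integers(0, length - width + 1))
        if labels[start : start + width].any():
            attempts += 1
            if attempts > 1000 * target:
                raise ValueError(
                    "could not place binding runs without overlap; "
                    "fraction/motif combination infeasible"
                )
            continue
        labels[start : start + width] = 1
        remaining -= width
    return labels


def _dirichlet_rows(alpha: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    gammas = rng.gamma(shape=alpha)
    return gammas / gammas.sum(axis=1, keepdims=True)


def simulate_chain(
    chain_id: str, length: int, config: SimConfig, rng: np.random.Generator
) -> tuple[ChainRecord, RawProfile, SSTrack]:
    letters = rng.integers(0, 20, size=length)
    sequence = "".join(STANDARD_AA[i] for i in letters)
    target = int(round(config.binding_fraction * length))
    labels = _place_binding_runs(length, target, config.motif_width, rng)

    profile = rng.integers(-3, 4, size=(length, 20)).astype(np.int64)
    boost = int(round(config.signal_strength))
    if boost:
        rows = np.flatnonzero(labels)
        for col in SIGNAL_COLUMNS:
            profile[rows, col] += boost

    alpha = np.ones((length, 3))
    if config.signal_strength > 0:
        # coil favored inside binding runs; part of the planted signal, so
        # a null world (signal_strength 0) carries no label information
        alpha[labels == 1, 0] = 4.0
    ss = _dirichlet_rows(alpha, rng)

    chain = ChainRecord(chain_id, sequence, labels)
    return chain, RawProfile(profile), SSTrack(ss)


def simulate_dataset(
    config: SimConfig | None = None, out_dir: str | Path | None = None
) -> tuple[list[ChainRecord], dict[str, RawProfile], dict[str, SSTrack]]:
    """Generate the full fixture set; optionally write it to ``out_dir``.

    On disk the layout is ``chains.fasta``, ``labels.txt``,
    ``pssm/<chain>.pssm`` and ``ss2/<chain>.ss2`` — exactly the formats
    the io layer reads back.
    """
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    chains: list[ChainRecord] = []
    profiles: dict[str, RawProfile] = {}
    ss_tracks: dict[str, SSTrack] = {}
    lo, hi = config.length_range
    for i in range(config.n_chains):
        length = int(rng.integers(lo, hi + 1))
        chain, profile, ss = simulate_chain(f"sim{i:03d}", length, config, rng)
        chains.append(chain)
        profiles[chain.chain_id] = profile
        ss_tracks[chain.chain_id] = ss

    if out_dir is not None:
        out_dir = Path(out_dir)
        (out_dir / "pssm").mkdir(parents=True, exist_ok=True)
        (out_dir / "ss2").mkdir(parents=True, exist_ok=True)
        write_fasta(chains, out_dir / "chains.fasta")
        write_labels({c.chain_id: c.labels for c in chains},
                     out_dir / "labels.txt")
        for c in chains:
            write_pssm_ascii(profiles[c.chain_id], c.sequence,
                             out_dir / "pssm" / f"{c.chain_id}.pssm")
            write_ss2(ss_tracks[c.chain_id], c.sequence,
                      out_dir / "ss2" / f"{c.chain_id}.ss2")
    return chains, profiles, ss_tracks


def simulate_homolog(
    template: ChainRecord,
    mutation_rate: float,
    seed: int = 0,
    chain_id: str | None = None,
) -> ChainRecord:
    """Point-substitute each residue with probability ``mutation_rate``.

    Substitutions always change the letter; labels carry over unchanged,
    which is the premise homology transfer relies on.
    """
    if not (0.0 <= mutation_rate <= 1.0):
        raise ValueError("mutation_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = list(template.sequence)
    for i, letter in enumerate(seq):
        if rng.random() < mutation_rate:
            choices = [a for a in STANDARD_AA if a != letter]
            seq[i] = choices[int(rng.integers(0, len(choices)))]
    return ChainRecord(
        chain_id or f"{template.chain_id}_hom",
        "".join(seq),
        None if template.labels is None else template.labels.copy(),
    )
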