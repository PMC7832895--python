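"""Per-residue windowed feature extraction.

Each residue is described by three feature tracks collected over a sliding
window of 17 consecutive residues centred on it:

* the evolutionary profile (PSSM), logistic-normalized to (0, 1) — 17 x 20,
* the predicted three-state secondary structure — 17 x 3,
* a 7-class physicochemical one-hot of the residue letter — 17 x 7.

The flattened concatenation (340 + 51 + 119 = 510 values) feeds the
gradient-boosting subclassifier; the three window matrices feed the
convolutional subclassifiers as separate input streams.  Windows hanging
over a chain terminus are padded with all-zero rows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_formats import ChainRecord, RawProfile, SSTrack

DEFAULT_WINDOW = 17

#: Dipole/volume grouping of the 20 amino acids into 7 classes.
#: Class order A..G; each standard letter belongs to exactly one class,
#: X activates none.
ONEHOT_CLASSES: list[str] = [
    "AGV",      # A: Ala, Gly, Val
    "ILFP",     # B: Ile, Leu, Phe, Pro
    "HNQW",     # C: His, Asn, Gln, Trp
    "YMTS",     # D: Tyr, Met, Thr, Ser
    "RK",       # E: Arg, Lys
    "DE",       # F: Asp, Glu
    "C",        # G: Cys
]

_CLASS_INDEX = {
    letter: k for k, letters in enumerate(ONEHOT_CLASSES) for letter in letters
}

N_PSSM, N_SS, N_ONEHOT = 20, 3, 7
FLAT_DIM = DEFAULT_WINDOW * (N_PSSM + N_SS + N_ONEHOT)  # 510


def normalize_pssm(raw: RawProfile | np.ndarray) -> np.ndarray:
    """Squash raw log-odds scores elementwise to (0, 1) with 1/(1+e^-s)."""
    values = raw.values if isinstance(raw, RawProfile) else np.asarray(raw)
    if not np.isfinite(values).all():
        raise ValueError("profile contains non-finite values")
    return 1.0 / (1.0 + np.exp(-values.astype(float)))


def encode_onehot(sequence: str) -> np.ndarray:
    """Encode each residue as a 7-bit indicator of its physicochemical class.

    X yields an all-zero row; any other letter outside the 20 standard
    codes raises ``ValueError`` (the io layer maps those to X upstream).
    """
    out = np.zeros((len(sequence), N_ONEHOT), dtype=float)
    for i, letter in enumerate(sequence):
        if letter == "X":
            continue
        try:
            out[i, _CLASS_INDEX[letter]] = 1.0
        except KeyError:
            raise ValueError(f"unknown residue letter {letter!r}") from None
    return out


@dataclass
class ProfileSet:
    """All three per-chain feature tracks, length-aligned."""

    chain_id: str
    norm_profile: np.ndarray  # L x 20, in (0, 1)
    ss: np.ndarray            # L x 3
    onehot: np.ndarray        # L x 7

    def __post_init__(self) -> None:
        L = self.norm_profile.shape[0]
        if self.ss.shape != (L, N_SS) or self.onehot.shape != (L, N_ONEHOT):
            raise ValueError(
                f"chain {self.chain_id!r}: track shapes disagree "
                f"({self.norm_profile.shape}, {self.ss.shape}, "
                f"{self.onehot.shape})"
            )

    def __len__(self) -> int:
        return self.norm_profile.shape[0]


def make_profile_set(
    chain: ChainRecord,
    raw_profile: RawProfile,
    ss_track: SSTrack,
    ss_onehot: bool = False,
) -> ProfileSet:
    """Assemble the normalized tracks for one chain.

    With ``ss_onehot`` the secondary-structure track is hardened to a one-hot
    of the argmax state instead of the three confidence values.
    """
    if len(raw_profile) != len(chain) or len(ss_track) != len(chain):
        raise ValueError(
            f"chain {chain.chain_id!r}: track lengths "
            f"(profile {len(raw_profile)}, ss {len(ss_track)}) do not match "
            f"chain length {len(chain)}"
        )
    ss = ss_track.probs
    if ss_onehot:
        hard = np.zeros_like(ss)
        hard[np.arange(len(ss)), ss.argmax(axis=1)] = 1.0
        ss = hard
    return ProfileSet(
        chain_id=chain.chain_id,
        norm_profile=normalize_pssm(raw_profile),
        ss=ss,
        onehot=encode_onehot(chain.sequence),
    )


def extract_windows(track: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Return one ``window x D`` block per row of an ``L x D`` track.

    Window *i* covers rows ``i - h .. i + h`` with ``h = (window - 1) / 2``;
    rows outside the track are all-zero padding.  The centre row of window
    *i* always equals track row *i*.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    track = np.asarray(track, dtype=float)
    L, D = track.shape
    h = (window - 1) // 2
    padded = np.zeros((L + 2 * h, D))
    padded[h : h + L] = track
    # stride trick over the padded track: row i of the result starts at i
    windows = np.lib.stride_tricks.sliding_window_view(padded, (window, D))
    return windows[:, 0].copy()


@dataclass
class WindowedDataset:
    """Per-residue samples over one or more chains.

    Arrays are aligned: sample *k* belongs to ``chain_ids[k]`` at 0-based
    residue ``positions[k]``.  ``flat`` is the row-major concatenation
    pssm-window then ss-window then onehot-window.
    """

    w_pssm: np.ndarray     # n x window x 20
    w_ss: np.ndarray       # n x window x 3
    w_onehot: np.ndarray   # n x window x 7
    chain_ids: np.ndarray  # n, object/str
    positions: np.ndarray  # n, int
    labels: np.ndarray | None = None  # n, 0/1 or None
    window: int = DEFAULT_WINDOW

    @property
    def flat(self) -> np.ndarray:
        n = self.w_pssm.shape[0]
        return np.concatenate(
            [
                self.w_pssm.reshape(n, -1),
                self.w_ss.reshape(n, -1),
                self.w_onehot.reshape(n, -1),
            ],
            axis=1,
        )

    @property
    def n_samples(self) -> int:
        return self.w_pssm.shape[0]

    def __len__(self) -> int:
        return self.n_samples

    def subset(self, mask: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            self.w_pssm[mask],
            self.w_ss[mask],
            self.w_onehot[mask],
            self.chain_ids[mask],
            self.positions[mask],
            None if self.labels is None else self.labels[mask],
            self.window,
        )

    def subset_chains(self, chain_ids) -> "WindowedDataset":
        wanted = set(chain_ids)
        mask = np.fromiter(
            (c in wanted for c in self.chain_ids), dtype=bool, count=len(self)
        )
        return self.subset(mask)

    def unique_chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c, None)
        return list(seen)


def build_dataset(
    chains,
    raw_profiles: dict[str, RawProfile],
    ss_tracks: dict[str, SSTrack],
    window: int = DEFAULT_WINDOW,
    ss_onehot: bool = False,
) -> WindowedDataset:
    """Window every chain's tracks into one dataset, one sample per residue.

    Chain identities are kept on every sample so cross-validation can split
    at chain level (adjacent residues share 16/17 of their windows, so
    residue-level splits would leak).
    """
    w_pssm, w_ss, w_onehot = [], [], []
    ids, positions, labels = [], [], []
    have_labels = True
    for chain in chains:
        if chain.chain_id not in raw_profiles:
            raise KeyError(f"no profile for chain {chain.chain_id!r}")
        if chain.chain_id not in ss_tracks:
            raise KeyError(f"no ss track for chain {chain.chain_id!r}")
        pset = make_profile_set(
            chain,
            raw_profiles[chain.chain_id],
            ss_tracks[chain.chain_id],
            ss_onehot=ss_onehot,
        )
        w_pssm.append(extract_windows(pset.norm_profile, window))
        w_ss.append(extract_windows(pset.ss, window))
        w_onehot.append(extract_windows(pset.onehot, window))
        ids.extend([chain.chain_id] * len(chain))
        positions.extend(range(len(chain)))
        if chain.labels is None:
            have_labels = False
        else:
            labels.extend(chain.labels.tolist())
    return WindowedDataset(
        np.concatenate(w_pssm),
        np.concatenate(w_ss),
        np.concatenate(w_onehot),
        np.asarray(ids, dtype=object),
        np.asarray(positions, dtype=int),
        np.asarray(labels, dtype=np.int8) if have_labels else None,
        window,
    )
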