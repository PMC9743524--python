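"""Model-ready encodings: one-hot sequence tensors and scaled feature matrices.

Sequence windows are encoded with one channel per nucleotide (A, C, G, T);
ambiguous bases (N and any IUPAC code) become all-zero rows. Epigenomic
features are per-track means over the fixed analysis window, MinMax-scaled
to [0, 1] with statistics learned from the training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.preprocessing import MinMaxScaler

__all__ = [
    "ALPHABET",
    "one_hot",
    "one_hot_batch",
    "decode_one_hot",
    "extract_features",
    "minmax_scale",
    "ScaledFeatures",
    "fetch_window_sequence",
]

ALPHABET = "ACGT"
_CHANNEL = {base: i for i, base in enumerate(ALPHABET)}
_AMBIGUOUS = set("NRYSWKMBDHV")


class AlphabetError(ValueError):
    pass


def one_hot(sequence: str, window_length: int = 200) -> np.ndarray:
    """Encode a nucleotide string as a (window_length, 4) binary matrix.

    Rows for A/C/G/T carry a single 1 in the base's channel; rows for N
    (or any ambiguity code) are all zero, so row sums double as a
    known-base mask. Case-insensitive.
    """
    if len(sequence) != window_length:
        raise ValueError(f"sequence length {len(sequence)} != window {window_length}")
    out = np.zeros((window_length, 4), dtype=np.float32)
    for i, base in enumerate(sequence.upper()):
        ch = _CHANNEL.get(base)
        if ch is not None:
            out[i, ch] = 1.0
        elif base not in _AMBIGUOUS:
            raise AlphabetError(f"illegal character {base!r} at position {i}")
    return out


def one_hot_batch(sequences, window_length: int = 200) -> np.ndarray:
    """Stack one-hot encodings into an (n, window_length, 4) tensor."""
    return np.stack([one_hot(s, window_length) for s in sequences])


def decode_one_hot(matrix: np.ndarray) -> str:
    """Inverse of :func:`one_hot`; all-zero rows decode to N."""
    bases = []
    for row in np.asarray(matrix):
        if row.sum() == 0:
            bases.append("N")
        else:
            bases.append(ALPHABET[int(np.argmax(row))])
    return "".join(bases)


def fetch_window_sequence(fasta, chrom: str, start: int, end: int) -> str:
    """Forward-strand sequence for a half-open window from an indexed FASTA.

    ``fasta`` is a ``pyfaidx.Fasta`` (or any mapping of chrom -> sliceable
    sequence). Windows outside chromosome bounds raise.
    """
    seq = fasta[chrom]
    if start < 0 or end > len(seq):
        raise IndexError(f"window [{start}, {end}) outside {chrom} (length {len(seq)})")
    return str(seq[start:end])


def extract_features(
    track_signals: dict[str, pd.DataFrame],
    chrom: str,
    start: int,
    end: int,
) -> pd.Series:
    """Per-track mean signal over a window, uncovered bases counting as 0.

    Each track is a bedGraph-style table with columns
    (chrom, start, end, value); intervals are half-open and assumed
    non-overlapping within a track. Track order in the output is
    lexicographic for reproducibility.
    """
    if start < 0 or end <= start:
        raise ValueError(f"bad window [{start}, {end})")
    width = end - start
    values = {}
    for name in sorted(track_signals):
        df = track_signals[name]
        on_chrom = df[df["chrom"] == chrom]
        if len(on_chrom) == 0:
            values[name] = 0.0
            continue
        lo = np.maximum(on_chrom["start"].to_numpy(), start)
        hi = np.minimum(on_chrom["end"].to_numpy(), end)
        overlap = np.clip(hi - lo, 0, None)
        values[name] = float((overlap * on_chrom["value"].to_numpy()).sum() / width)
    return pd.Series(values, dtype=float)


def read_bedgraph(path) -> pd.DataFrame:
    """Read a 4-column bedGraph / TSV signal track."""
    return pd.read_csv(
        path, sep="\t", comment="#",
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": int, "end": int, "value": float},
    )


@dataclass
class ScaledFeatures:
    """MinMax-scaled feature matrices with the fitted per-column range.

    Scaling statistics come from the training matrix alone, so values in
    the other matrices may fall outside [0, 1]; they are deliberately not
    clipped (``clipped`` records this for downstream metadata).
    """

    train: pd.DataFrame
    others: tuple[pd.DataFrame, ...]
    data_min: pd.Series
    data_max: pd.Series
    clipped: bool = False


def minmax_scale(train: pd.DataFrame, *others: pd.DataFrame) -> ScaledFeatures:
    """Scale columns to [0, 1] using the training rows' min and max.

    Constant columns map to 0 everywhere. All matrices must share the
    training matrix's column set (order is aligned to it).
    """
    for i, other in enumerate(others):
        if set(other.columns) != set(train.columns):
            raise ValueError(f"matrix {i + 1}: column set differs from training matrix")
    scaler = MinMaxScaler(clip=False)
    scaled_train = pd.DataFrame(
        scaler.fit_transform(train.to_numpy(dtype=float)),
        index=train.index, columns=train.columns,
    )
    scaled_others = tuple(
        pd.DataFrame(
            scaler.transform(other[train.columns].to_numpy(dtype=float)),
            index=other.index, columns=train.columns,
        )
        for other in others
    )
    return ScaledFeatures(
        train=scaled_train,
        others=scaled_others,
        data_min=pd.Series(scaler.data_min_, index=train.columns),
        data_max=pd.Series(scaler.data_max_, index=train.columns),
    )
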